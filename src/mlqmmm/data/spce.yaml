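# SPC/E rigid three-site water model, standard published constants.
# Units: charges in e, sigma in Å, epsilon in kcal/mol, r_oh in Å, angle in deg.
version: 1
q_oxygen: -0.8476
q_hydrogen: 0.4238
sigma_oo: 3.166
epsilon_oo: 0.1553
r_oh: 1.0
angle_hoh: 109.47
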