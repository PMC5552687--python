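# Lennard-Jones parameters for solute (QM-region) atom types used in the
# QM/MM coupling term.  Amber-style generic types keyed by element.
# sigma in Å, epsilon in kcal/mol.
version: 1
types:
  C: {sigma: 3.3997, epsilon: 0.0860}
  N: {sigma: 3.2500, epsilon: 0.1700}
  O: {sigma: 2.9599, epsilon: 0.2100}
  H: {sigma: 2.4714, epsilon: 0.0157}
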