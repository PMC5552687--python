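{
  "version": 1,
  "description": "Reference worked-example tables for the guanine-damage ring-opening study: transition-state internal coordinates of the solvated system at two basis sets, stationary-point energetics, solvation free energies and hydrogen-bond statistics. Bond lengths in angstrom, angles/dihedrals in degrees, energies in kcal/mol.",
  "ts_bonds": {
    "sites": [["N7", "C8"], ["C8", "O10"], ["C8", "N9"], ["N9", "C4"]],
    "aug-cc-pVDZ": {"v": [1.358, 1.363, 2.014, 1.312], "src": "solution-phase TS bond lengths N7-C8, C8-O10, C8-N9, N9-C4 with the aug-cc-pVDZ basis"},
    "6-311++G**": {"v": [1.336, 1.344, 2.103, 1.293], "src": "solution-phase TS bond lengths N7-C8, C8-O10, C8-N9, N9-C4 with the 6-311++G** basis"}
  },
  "ts_angles": {
    "sites": [["N7", "C8", "O10"], ["N9", "C8", "O10"], ["C8", "O10", "H10"]],
    "aug-cc-pVDZ": {"v": [112.6, 123.7, 106.2], "src": "solution-phase TS bending angles with the aug-cc-pVDZ basis"},
    "6-311++G**": {"v": [114.4, 121.3, 106.9], "src": "solution-phase TS bending angles with the 6-311++G** basis"}
  },
  "ts_dihedrals": {
    "sites": [["C5", "N7", "C8", "O10"], ["C5", "N7", "C8", "H8"], ["N7", "C8", "O10", "H10"], ["C8", "H8", "N9", "H9"], ["C8", "H8", "O10", "H10"]],
    "aug-cc-pVDZ": {"v": [-134.1, 86.1, 8.5, -145.5, -34.1], "src": "solution-phase TS dihedral angles with the aug-cc-pVDZ basis"},
    "6-311++G**": {"v": [-132.3, 78.6, 7.8, -147.1, -25.1], "src": "solution-phase TS dihedral angles with the 6-311++G** basis"}
  },
  "geometry_diff_means": {
    "bond": {"v": 0.04, "src": "upper bound on the unsigned mean bond-length difference between the two basis sets"},
    "angle": {"v": 1.6, "src": "unsigned mean bending-angle difference between the two basis sets"},
    "dihedral": {"v": 4.1, "src": "unsigned mean dihedral difference between the two basis sets"}
  },
  "hbonds": {
    "ts_aug_mean": {"v": 2.777, "n": 5, "src": "mean length of the five weak hydrogen bonds at the aug-cc-pVDZ TS"},
    "ts_6311_mean": {"v": 2.572, "n": 6, "src": "mean length of the six weak hydrogen bonds at the 6-311++G** TS"},
    "rc_strong": {"v": 1.766, "src": "strong hydroxyl-to-water hydrogen bond at the solvated reactant complex"},
    "rc_weak_mean": {"v": 2.524, "n": 4, "src": "mean of the four weak hydrogen bonds at the solvated reactant complex"}
  },
  "breakable_bond": {
    "reactant": {"v": 1.466, "src": "C8-N9 length at the solvated reactant complex"},
    "ts": {"v": 2.103, "src": "C8-N9 length at the solvated transition state"},
    "product": {"v": 2.812, "src": "C8-N9 length at the solvated product complex"},
    "product_gas": {"v": 2.802, "src": "C8-N9 length at the gas-phase product complex"}
  },
  "imaginary_frequencies": {
    "gas": {"v": 236.2, "src": "single imaginary TS frequency in the gas phase, cm^-1"},
    "solution": {"v": 280.9, "src": "single imaginary TS frequency in aqueous solution, cm^-1"}
  },
  "energies": {
    "gas_barrier_low": {"v": 17.3, "src": "gas-phase barrier at the cheaper (DFT) tier"},
    "gas_barrier_high": {"v": 19.2, "src": "gas-phase barrier at the accurate (coupled-cluster) tier"},
    "gas_reaction_high": {"v": 7.6, "src": "gas-phase reaction energy at the accurate tier"},
    "pmf_barrier_low": {"v": 28.8, "src": "aqueous PMF barrier at the cheaper tier"},
    "pmf_barrier_high": {"v": 31.6, "src": "aqueous PMF barrier at the accurate tier"},
    "pmf_reaction_high": {"v": 15.9, "src": "aqueous PMF reaction free energy at the accurate tier"},
    "solvent_barrier": {"v": 6.0, "src": "solvent-energy contribution to the PMF barrier"},
    "solvent_reaction": {"v": 27.9, "src": "solvent-energy contribution to the PMF reaction free energy"},
    "polarization_reactant": {"v": 9.4, "src": "polarization (internal minus gas) at the reactant state"},
    "polarization_ts": {"v": 8.7, "src": "polarization at the transition state"},
    "polarization_product": {"v": 8.6, "src": "polarization at the product state"},
    "net_polarization_ts": {"v": -0.7, "src": "net polarization contribution to the barrier"},
    "net_polarization_product": {"v": -0.8, "src": "net polarization contribution to the reaction energy"},
    "aqueous_barrier_contribution": {"v": 5.3, "src": "total aqueous contribution to the barrier (solvent + net polarization)"},
    "aqueous_reaction_contribution": {"v": 27.1, "src": "total aqueous contribution to the reaction energy"}
  },
  "solvation": {
    "reactant": {"v": -25.2, "src": "continuum solvation free energy of the reactant complex"},
    "ts": {"v": -17.3, "src": "continuum solvation free energy of the transition state"},
    "product": {"v": -17.3, "src": "continuum solvation free energy of the product complex"},
    "estimated_solution_barrier": {"v": 27.1, "src": "solution barrier composed from the gas profile and solvation free energies"},
    "estimated_solution_reaction": {"v": 15.5, "src": "solution reaction energy composed from the gas profile and solvation free energies"}
  },
  "rates": {
    "gas_power_of_ten": {"v": -21, "src": "order of magnitude of the TST rate at the 19.2 kcal/mol gas barrier, cm^3/molecule/s"},
    "solution_power_of_ten": {"v": -30, "src": "order of magnitude of the TST rate at the 31.6 kcal/mol solution barrier"},
    "orders_ratio": {"v": 9, "src": "orders of magnitude by which solvation slows the reaction"}
  },
  "box": {
    "edge": {"v": 37.5, "src": "cubic water box edge length, angstrom"},
    "n_waters": {"v": 1752, "src": "number of explicit waters in the box"},
    "cutoff": {"v": 15.0, "src": "full-coupling cutoff radius around the QM region, angstrom"},
    "density": {"v": 0.994, "src": "derived box density, g/cm^3 (1752 x 18.0153 g/mol over N_A x (37.5 A)^3)"}
  }
}
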