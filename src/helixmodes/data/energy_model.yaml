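# Self-contained coarse-grained bead parameter table (one bead per residue).
# epsilon in kJ/mol, sigma and radius in nm. Pair parameters combine by
# Lorentz-Berthelot rules. The switch window and thresholds are the package
# defaults used by the dimer/oligomer criteria.
beads:
  C: {epsilon: 20.0, sigma: 0.47, radius: 0.23}
  N: {epsilon: 20.0, sigma: 0.47, radius: 0.23}
  P: {epsilon: 18.0, sigma: 0.47, radius: 0.23}
  Q: {epsilon: 18.0, sigma: 0.47, radius: 0.23}
r_switch: 0.9
r_cut: 1.2
coulomb_cutoff: 1.2
relative_dielectric: 15.0
dimer_cutoff: -200.0
oligomer_cutoff: -800.0
bsa_fraction_cutoff: 0.10
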