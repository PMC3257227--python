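# Poly-DL-alanine reference rate parameters for backbone amide exchange
# (protein in D2O, low salt), with nearest-neighbour side-chain factors.
# Version 1 of the shipped parameter set. log10 scale throughout.
#
# Rate model for the amide of residue i with left neighbour i-1:
#   k_rc = kA*10^(AL_i + AR_{i-1} - pD)
#        + kB*10^(BL_i + BR_{i-1} + pD - pKD)
#        + kW*10^(BL_i + BR_{i-1})
# each term Arrhenius-corrected from the 293 K reference temperature.
# pD = pH_read + 0.4 (glass-electrode correction).
version: 1
reference_temperature_K: 293.0
pKD: 15.05
log_kA_ref: 1.62      # per (M min)
log_kB_ref: 10.05     # per (M min)
log_kW_ref: -1.5      # per min
activation_energy_kcal:
  acid: 14.0
  base: 17.0
  water: 19.0
# Side-chain pKa values in D2O used to mix protonated/deprotonated factors.
pka_D2O:
  ASP: 4.48
  GLU: 4.93
  HIS: 7.00
# Factors: [AL, AR, BL, BR] = acid-left, acid-right, base-left, base-right.
# "left" applies to the residue contributing the NH; "right" to the residue
# preceding it in sequence.
factors:
  ALA: [0.00, 0.00, 0.00, 0.00]
  ARG: [-0.59, -0.32, 0.08, 0.22]
  ASN: [-0.58, -0.13, 0.49, 0.32]
  ASP_deprot: [0.90, 0.58, 0.10, -0.18]
  ASP_prot: [-0.90, -0.12, 0.69, 0.60]
  CYS: [-0.54, -0.46, 0.62, 0.55]
  GLY: [-0.22, 0.22, 0.27, 0.17]
  GLN: [-0.47, -0.27, 0.06, 0.20]
  GLU_deprot: [-0.90, 0.31, -0.11, -0.15]
  GLU_prot: [-0.60, -0.27, 0.24, 0.39]
  HIS_deprot: [0.00, 0.00, -0.10, 0.14]
  HIS_prot: [-0.80, -0.51, 0.80, 0.83]
  ILE: [-0.91, -0.59, -0.73, -0.23]
  LEU: [-0.57, -0.13, -0.58, -0.21]
  LYS: [-0.56, -0.29, -0.04, 0.12]
  MET: [-0.64, -0.28, -0.01, 0.11]
  PHE: [-0.52, -0.43, -0.24, 0.06]
  PRO: [0.00, -0.19, 0.00, -0.24]
  SER: [-0.44, -0.39, 0.37, 0.30]
  THR: [-0.79, -0.47, -0.07, 0.20]
  TRP: [-0.40, -0.44, -0.41, -0.11]
  TYR: [-0.41, -0.37, -0.27, 0.05]
  VAL: [-0.74, -0.30, -0.70, -0.14]
  UNK: [0.00, 0.00, 0.00, 0.00]
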