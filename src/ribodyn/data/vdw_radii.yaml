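# Van der Waals radii (Angstrom) used for surface-distance and
# exposed-volume calculations. Bondi-style values; 'default' covers
# elements not listed.
H: 1.20
C: 1.70
N: 1.55
O: 1.52
S: 1.80
P: 1.80
default: 1.70
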