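# van der Waals radii, Angstrom (Bondi 1964; Na from Mantina et al. 2009)
H   1.20
C   1.70
N   1.55
O   1.52
F   1.47
P   1.80
S   1.80
CL  1.75
NA  2.27
K   2.75
MG  1.73
CA  2.31
ZN  1.39
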