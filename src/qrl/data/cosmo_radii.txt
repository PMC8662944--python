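# COSMO cavity radii (Å), element  radius
# Optimized element radii from the COSMO-RS parametrization line
# (≈1.17 × vdW); metals are overridden to 2.0 Å by the cavity builder.
H  1.30
C  2.00
N  1.83
O  1.72
F  1.72
Si 2.48
P  2.11
S  2.16
Cl 2.05
Br 2.16
I  2.32
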