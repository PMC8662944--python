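"""Physical constants and unit conversions.

Internal conventions: coordinates in Å, energies in kJ/mol at every module
interface; the COSMO electrostatics work in atomic units internally.
"""

HARTREE_TO_KJMOL = 2625.4996
BOHR_TO_ANGSTROM = 0.529177
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Coulomb constant e²/(4πε₀) in kJ·Å/mol — energy of two unit charges 1 Å apart.
COULOMB_KJMOL_ANGSTROM = 1389.35
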