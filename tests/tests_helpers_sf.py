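"""Shared brute-force structure-factor oracle for occupancy-weighted models.

Kept independent of the package's vectorized engine: explicit per-atom,
per-reflection summation using the same published form-factor coefficients.
"""

import numpy as np

from qrl.scattering import FormFactorTable


def occupancy_weighted_brute_force(model, hkl):
    table = FormFactorTable.default()
    out = np.zeros(len(hkl), dtype=complex)
    finv = np.linalg.inv(model.cell.orth_matrix)
    for ih, h in enumerate(np.asarray(hkl)):
        d = model.cell.d_spacing(np.array(h)[None, :])[0]
        s2 = (0.5 / d) ** 2
        for a in model.atoms:
            ca, cb, cc = table.coefficients(a.element)
            f = float(np.sum(ca * np.exp(-cb * s2)) + cc)
            frac = finv @ a.pos
            out[ih] += (a.occupancy * f * np.exp(-a.b_iso * s2)
                        * np.exp(2j * np.pi * (np.array(h) @ frac)))
    return out
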