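"""Energy of system 1 (the refined region) behind a pluggable backend.

The builtin surrogate is a classical model: the region's bonded restraint
terms plus point-charge Coulomb (1-2/1-3 excluded), a 12-6 Lennard-Jones
term, and the COSMO solvation energy at the requested dielectric constant.
It replaces an electronic-structure backend entirely; the refinement
machinery only sees the :class:`BackendContract` surface, so a real QM
program can be plugged in through the external-process file exchange
(XYZ coordinates in, one-line-per-atom gradients out).
"""

from __future__ import annotations

import dataclasses
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from . import cosmo as _cosmo
from .crystal_model import Atom, AugmentedRegion, StructureModel, UnitCell
from .restraints import RestraintParams, mm_energy
from .units import (BOHR_TO_ANGSTROM, COULOMB_KJMOL_ANGSTROM,
                    HARTREE_TO_KJMOL)


class RegionEnergyError(ValueError):
    pass


# Lennard-Jones well parameters (r_min in Å summed pairwise /2, ε in kJ/mol).
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.066), "C": (1.91, 0.36), "N": (1.82, 0.71),
    "O": (1.66, 0.88), "S": (2.00, 1.05), "P": (2.10, 0.84),
    "F": (1.65, 0.25), "Cl": (1.98, 1.11),
}
LJ_DEFAULT = (2.00, 0.40)  # metals and anything untabulated


@dataclasses.dataclass
class RegionEnergyResult:
    """total = vacuum + solvation (kJ/mol); gradient incl. link atoms."""

    total: float
    vacuum: float
    solvation: float
    grad: np.ndarray

    def __post_init__(self):
        assert abs(self.total - (self.vacuum + self.solvation)) < 1e-9


@dataclasses.dataclass
class BackendContract:
    """External region-energy program: executable + declared units.

    Invoked as ``executable coords.xyz epsilon result.txt``; the result file
    must contain ``energy <value> <unit>`` on line 1 and one ``gx gy gz``
    line per atom (same order as the XYZ file), in ``grad_unit``.
    """

    executable: str
    energy_unit: str = "hartree"
    grad_unit: str = "hartree/bohr"

    def __post_init__(self):
        if self.energy_unit.lower() not in ENERGY_UNITS:
            raise RegionEnergyError(f"undeclared energy unit {self.energy_unit!r}")
        if self.grad_unit.lower() not in GRADIENT_UNITS:
            raise RegionEnergyError(f"undeclared gradient unit {self.grad_unit!r}")


ENERGY_UNITS = {
    "hartree": HARTREE_TO_KJMOL,
    "kj/mol": 1.0,
    "kcal/mol": 4.184,
    "ev": 96.4853,
}
GRADIENT_UNITS = {
    "hartree/bohr": HARTREE_TO_KJMOL / BOHR_TO_ANGSTROM,
    "kj/mol/a": 1.0,
    "kcal/mol/a": 4.184,
}


def _pairwise_nonbonded(elements, xyz, charges, params: RestraintParams,
                        use_lj: bool = True):
    """Coulomb + LJ energy/gradient with 1-2/1-3 exclusions."""
    n = len(xyz)
    energy = 0.0
    grad = np.zeros((n, 3))
    if n < 2:
        return energy, grad
    excl = params.excluded_pairs()
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            dvec = xyz[i] - xyz[j]
            r = float(np.linalg.norm(dvec))
            if r < 1e-8:
                raise RegionEnergyError(f"atoms {i} and {j} coincide")
            qq = charges[i] * charges[j]
            if qq != 0.0:
                energy += COULOMB_KJMOL_ANGSTROM * qq / r
                g = -COULOMB_KJMOL_ANGSTROM * qq / r**3 * dvec
                grad[i] += g
                grad[j] -= g
            if use_lj:
                ri, ei = LJ_PARAMS.get(elements[i], LJ_DEFAULT)
                rj, ej = LJ_PARAMS.get(elements[j], LJ_DEFAULT)
                rmin = ri + rj
                eps = np.sqrt(ei * ej)
                x6 = (rmin / r) ** 6
                energy += eps * (x6 * x6 - 2.0 * x6)
                dedr = eps * (-12.0 * x6 * x6 + 12.0 * x6) / r
                grad[i] += dedr * dvec / r
                grad[j] -= dedr * dvec / r
    return energy, grad


def region_energy(region_atoms: AugmentedRegion, params: RestraintParams,
                  epsilon: float = 1.0, backend="builtin",
                  cosmo_radii: dict[str, float] | None = None,
                  cosmo_n_points: int = 302, cosmo_seed: int = 0,
                  cavity: "_cosmo.CosmoCavity | None" = None,
                  use_lj: bool = True) -> RegionEnergyResult:
    """E_QM1: region energy with gradient per region atom (incl. link atoms).

    ``params`` uses region-local atom indices (0..n_aug−1).  The solvation
    term is zero at ε = 1; otherwise it comes from the COSMO module with the
    fixed-cavity gradient (pass ``cavity`` to reuse/freeze a cavity).
    """
    if isinstance(backend, BackendContract):
        return run_external_backend(backend, region_atoms, epsilon)
    if backend != "builtin":
        raise RegionEnergyError(f"unknown backend {backend!r}")
    xyz = region_atoms.xyz
    n = len(xyz)
    if n == 0:
        return RegionEnergyResult(0.0, 0.0, 0.0, np.zeros((0, 3)))
    # bonded part reuses the restraint machinery on a local pseudo-model
    pseudo = _local_model(region_atoms)
    bonded = mm_energy(pseudo, params)
    nb_e, nb_g = _pairwise_nonbonded(region_atoms.elements, xyz,
                                     region_atoms.charges, params, use_lj)
    vacuum = bonded.energy + nb_e
    grad = bonded.grad + nb_g
    solvation = 0.0
    if epsilon > 1.0 and np.any(region_atoms.charges != 0.0):
        if cavity is None:
            cavity = _cosmo.build_cavity(region_atoms.elements, xyz,
                                         cosmo_radii, cosmo_n_points, cosmo_seed)
        sol = _cosmo.cosmo_solve(cavity, region_atoms.charges, xyz, epsilon)
        solvation = sol.dg_solv
        grad = grad + _cosmo.cosmo_gradient(cavity, region_atoms.charges, xyz,
                                            epsilon, solution=sol)
    return RegionEnergyResult(vacuum + solvation, vacuum, solvation, grad)


def _local_model(region_atoms: AugmentedRegion) -> StructureModel:
    cell = UnitCell(1000.0, 1000.0, 1000.0)
    atoms = [Atom(element=el, pos=p, charge=q)
             for el, p, q in zip(region_atoms.elements, region_atoms.xyz,
                                 region_atoms.charges)]
    m = StructureModel(cell, atoms)
    m.xyz[:] = region_atoms.xyz
    return m


# --------------------------------------------------------------------------
# External backend file exchange
# --------------------------------------------------------------------------

def write_xyz(path, elements, xyz, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, xyz):
            fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def run_external_backend(contract: BackendContract, region_atoms: AugmentedRegion,
                         epsilon: float) -> RegionEnergyResult:
    """Invoke the external program and parse energy + gradient.

    The external total is reported as vacuum energy (an external backend
    declares a single total; the split is only meaningful for the builtin
    surrogate).
    """
    with tempfile.TemporaryDirectory(prefix="qrl_backend_") as tmp:
        tmp = Path(tmp)
        coords = tmp / "coords.xyz"
        result = tmp / "result.txt"
        write_xyz(coords, region_atoms.elements, region_atoms.xyz,
                  comment=f"epsilon={epsilon}")
        proc = subprocess.run(
            [contract.executable, str(coords), str(epsilon), str(result)],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise RegionEnergyError(
                f"backend exited with status {proc.returncode}; "
                f"stderr:\n{proc.stderr[-2000:]}")
        if not result.exists():
            raise RegionEnergyError("backend produced no result file")
        lines = [l for l in result.read_text().splitlines() if l.strip()]
    if not lines or not lines[0].lower().startswith("energy"):
        raise RegionEnergyError("result file must start with 'energy <value> <unit>'")
    tok = lines[0].split()
    unit = tok[2].lower()
    if unit not in ENERGY_UNITS:
        raise RegionEnergyError(f"backend declared unknown energy unit {unit!r}")
    energy = float(tok[1]) * ENERGY_UNITS[unit]
    n = len(region_atoms.elements)
    if len(lines) - 1 < n:
        raise RegionEnergyError(
            f"gradient file too short: {len(lines)-1} lines for {n} atoms")
    grad = np.array([[float(x) for x in lines[1 + i].split()[:3]] for i in range(n)])
    grad *= GRADIENT_UNITS[contract.grad_unit.lower()]
    if not np.all(np.isfinite(grad)) or not np.isfinite(energy):
        raise RegionEnergyError("NaN/inf in backend results")
    return RegionEnergyResult(energy, energy, 0.0, grad)
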