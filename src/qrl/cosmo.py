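"""Conductor-like screening model (COSMO) for point-charge solutes.

The solute sits in a cavity of atom-centred spheres tessellated with a
deterministic Fibonacci lattice; surface points buried inside a neighbouring
sphere fade out through a smooth switching weight (half a lattice spacing
wide) so the energy is continuous as atoms move.  Apparent surface charges
q solve

    A q = −f(ε) Φ,   f(ε) = (ε−1)/(ε+x),  x = 0.5 by default,

with A_kl = 1/|r_k−r_l| (k≠l) and the standard self-interaction closure
A_kk = 1.07·√(4π/area_k), everything in atomic units.  The solvation energy
is ΔG_solv = ½ ΦᵀQ ≤ 0, reported in kJ/mol.

The geometric gradient keeps the cavity fixed (segment positions frozen);
an optional finite-difference cavity-rebuild correction can be switched on.
No outlying-charge correction and no self-consistency with a polarizable
solute: charges are fixed point charges.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .crystal_model import METAL_ELEMENTS
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_KJMOL

DEFAULT_PROBE_RADIUS = 1.3   # Å, water
DEFAULT_METAL_RADIUS = 2.0   # Å
SELF_INTERACTION = 1.07      # A_kk = 1.07·√(4π/area)


class CosmoError(ValueError):
    pass


def f_eps(epsilon: float, x: float = 0.5) -> float:
    """Dielectric scaling f = (ε−1)/(ε+x); 0 in vacuum, →1 for a conductor."""
    if epsilon < 1.0:
        raise CosmoError("dielectric constant must be ≥ 1")
    return (epsilon - 1.0) / (epsilon + x)


def load_radii(path=None) -> dict[str, float]:
    """Element → cavity radius (Å) from the shipped or a user table."""
    if path is None:
        ref = importlib.resources.files("qrl.data").joinpath("cosmo_radii.txt")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    radii = {}
    for line in text.splitlines():
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        radii[tok[0]] = float(tok[1])
    return radii


def element_radius(element: str, radii: dict[str, float],
                   metal_radius: float = DEFAULT_METAL_RADIUS) -> float:
    if element in METAL_ELEMENTS:
        return metal_radius
    if element in radii:
        return radii[element]
    raise CosmoError(f"no COSMO radius for element {element!r}")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


@dataclasses.dataclass
class CosmoCavity:
    """Exposed surface segments: centres (Å), areas (Å²), owner atom index."""

    centers: np.ndarray
    areas: np.ndarray
    owners: np.ndarray
    atom_radii: np.ndarray
    probe_radius: float
    n_points: int

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def build_cavity(elements, xyz, radii: dict[str, float] | None = None,
                 n_points: int = 590, seed: int = 0,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 metal_radius: float = DEFAULT_METAL_RADIUS) -> CosmoCavity:
    """Tessellate atom spheres and drop buried points (binary exposure).

    Each surviving point becomes one segment with area 4πR²/n_points.  The
    lattice orientation is drawn from ``seed`` so discretization artefacts
    can be averaged over; results are deterministic per seed.
    """
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    n_at = len(xyz)
    if radii is None:
        radii = load_radii()
    rads = np.array([element_radius(el, radii, metal_radius) for el in elements])
    if n_at > 1:
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise CosmoError("two atoms coincide; cannot build a cavity")
    rng = np.random.default_rng(seed)
    # one random proper rotation shared by all atoms (deterministic per seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    unit = fibonacci_sphere(n_points) @ rot.T
    centers, areas, owners = [], [], []
    for ia in range(n_at):
        pts = xyz[ia] + rads[ia] * unit
        spacing = math.sqrt(4.0 * math.pi * rads[ia] ** 2 / n_points)
        # smoothly switched exposure: weight ramps 0→1 over half a lattice
        # spacing outside a neighbouring sphere.  Keeps the energy continuous
        # as atoms move (buried segments fade out instead of flipping) and
        # bounds cross-sphere segment distances from below at full weight,
        # which keeps the Coulomb matrix positive definite.
        w = np.ones(len(pts))
        for jb in range(n_at):
            if jb == ia:
                continue
            d = np.linalg.norm(pts - xyz[jb], axis=1)
            t = np.clip((d - rads[jb]) / (0.5 * spacing), 0.0, 1.0)
            w *= t * t * (3.0 - 2.0 * t)  # smoothstep
        keep = w > 1e-3
        if keep.any():
            centers.append(pts[keep])
            base = 4.0 * math.pi * rads[ia] ** 2 / n_points
            areas.append(base * w[keep])
            owners.append(np.full(keep.sum(), ia, dtype=int))
    if not centers:
        raise CosmoError("no exposed surface segments")
    return CosmoCavity(np.vstack(centers), np.concatenate(areas),
                       np.concatenate(owners), rads, probe_radius, n_points)


@dataclasses.dataclass
class CosmoSolution:
    charges: np.ndarray          # screening charges per segment (e)
    dg_solv: float               # kJ/mol
    epsilon: float
    f: float
    phi: np.ndarray              # solute potential at segments (a.u.)


def _segment_matrix(cavity: CosmoCavity) -> np.ndarray:
    r = cavity.centers * ANGSTROM_TO_BOHR
    d = np.linalg.norm(r[:, None] - r[None, :], axis=2)
    np.fill_diagonal(d, 1.0)
    a = 1.0 / d
    areas_bohr = cavity.areas * ANGSTROM_TO_BOHR**2
    diag = SELF_INTERACTION * np.sqrt(4.0 * math.pi / areas_bohr)
    # Seam segments of neighbouring spheres can nearly coincide; cap their
    # Coulomb interaction at the self-interaction scale to keep A positive
    # definite (inactive on a single sphere, e.g. the Born test).
    cap = 0.95 * np.sqrt(np.outer(diag, diag))
    a = np.minimum(a, cap)
    np.fill_diagonal(a, diag)
    return a


def _potential(cavity: CosmoCavity, charges, positions) -> np.ndarray:
    rseg = cavity.centers * ANGSTROM_TO_BOHR
    rsol = np.asarray(positions, float).reshape(-1, 3) * ANGSTROM_TO_BOHR
    d = np.linalg.norm(rseg[:, None] - rsol[None, :], axis=2)
    if d.min() < 1e-6:
        raise CosmoError("surface segment coincides with a solute charge")
    return (1.0 / d) @ np.asarray(charges, float)


def cosmo_solve(cavity: CosmoCavity, charges, positions, epsilon: float,
                x: float = 0.5) -> CosmoSolution:
    """Screening charges and solvation energy for point charges in the cavity."""
    if len(cavity) < 1:
        raise CosmoError("cavity has no segments")
    f = f_eps(epsilon, x)
    phi = _potential(cavity, charges, positions)
    if f == 0.0:
        return CosmoSolution(np.zeros(len(cavity)), 0.0, epsilon, f, phi)
    factor = getattr(cavity, "_chol", None)
    if factor is None:
        a = _segment_matrix(cavity)
        try:
            factor = cho_factor(a)
        except np.linalg.LinAlgError as exc:
            raise CosmoError(f"singular segment matrix ({exc}); "
                             "cavity discretization is degenerate") from exc
        object.__setattr__(cavity, "_chol", factor)  # A depends only on the cavity
    q = -f * cho_solve(factor, phi)
    dg = 0.5 * float(phi @ q) * HARTREE_TO_KJMOL
    return CosmoSolution(q, dg, epsilon, f, phi)


def cosmo_gradient(cavity: CosmoCavity, charges, positions, epsilon: float,
                   x: float = 0.5, solution: CosmoSolution | None = None,
                   cavity_response: bool = False,
                   fd_step: float = 1e-3, elements=None,
                   radii: dict[str, float] | None = None) -> np.ndarray:
    """∂ΔG_solv/∂x per solute atom (kJ/mol/Å), cavity held fixed.

    Since ΔG = −(f/2)·ΦᵀA⁻¹Φ at fixed A, the exact fixed-cavity gradient is
    qᵀ·∂Φ/∂x.  With ``cavity_response=True`` a central finite-difference
    correction that rebuilds the cavity is added (slow; off by default).
    The result is approximate with respect to cavity motion and documented
    as such.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    charges = np.asarray(charges, float)
    if solution is None:
        solution = cosmo_solve(cavity, charges, positions, epsilon, x)
    rseg = cavity.centers * ANGSTROM_TO_BOHR
    rsol = positions * ANGSTROM_TO_BOHR
    diff = rseg[:, None, :] - rsol[None, :, :]          # (nseg, nat, 3)
    d = np.linalg.norm(diff, axis=2)
    # ∂Φ_k/∂x_i = z_i (r_k − r_i)/|r_k − r_i|³
    dphi = charges[None, :, None] * diff / d[:, :, None] ** 3
    grad_au = np.einsum("k,kid->id", solution.charges, dphi)
    grad = grad_au * HARTREE_TO_KJMOL / BOHR_TO_ANGSTROM
    if cavity_response:
        if elements is None:
            raise CosmoError("cavity_response requires the element list")
        for i in range(len(positions)):
            for dim in range(3):
                for sgn, store in ((1, "p"), (-1, "m")):
                    pos2 = positions.copy()
                    pos2[i, dim] += sgn * fd_step
                    cav2 = build_cavity(elements, pos2, radii,
                                        cavity.n_points, 0,
                                        cavity.probe_radius)
                    sol2 = cosmo_solve(cav2, charges, pos2, epsilon, x)
                    if sgn > 0:
                        ep = sol2.dg_solv
                    else:
                        em = sol2.dg_solv
                fd = (ep - em) / (2 * fd_step)
                # replace the fixed-cavity component with the full derivative
                grad[i, dim] = fd
    return grad


def born_energy(radius_ang: float, charge: float, epsilon: float,
                x: float = 0.5) -> float:
    """Analytic conductor-Born solvation energy −f·q²/(2R) in kJ/mol."""
    r_bohr = radius_ang * ANGSTROM_TO_BOHR
    return -f_eps(epsilon, x) * charge**2 / (2.0 * r_bohr) * HARTREE_TO_KJMOL
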