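"""Deterministic synthetic toy crystals.

Generates the test substrate for the whole refinement stack: a P1 cell with
a small, bonded, net-charged "active-site" cluster (the refined region),
frozen environment atoms, ideal or noisy structure-factor amplitudes with a
seeded free set, and a start model perturbed to a requested RMSD.  All
randomness is driven by the mandatory seed; the same spec and seed give
bit-identical outputs.

The default cluster mimics the charge situation of a small metallocluster
region: one metal centre surrounded by bonded S/O ligands, net charge −5,
so continuum-solvation trends (strain and RSZD falling with ε) are
meaningful on the demo fixture.

Noise model: |Fobs| = |Ftrue|·(1 + N(0, noise)), truncated at 0.1·|Ftrue|;
the σ column is noise·|Ftrue| (with a 1%·|Ftrue| floor so σ > 0 holds on
noise-free fixtures).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .crystal_model import (Atom, ModelError, RegionSelection, ReflectionSet,
                            StructureModel, UnitCell)
from .restraints import AngleTerm, BondTerm, RestraintParams
from .scattering import SFCalculation, generate_hkl

SIGMA_FLOOR_FRAC = 0.01


@dataclasses.dataclass
class ToySpec:
    """Study conditions for one synthetic crystal."""

    seed: int
    cell: tuple[float, float, float] = (18.0, 16.0, 15.0)
    n_env: int = 20
    region_net_charge: float = -5.0
    d_min: float = 1.5
    noise: float = 0.0
    free_fraction: float = 0.05
    perturb_rmsd: float = 0.3
    env_b_iso: float = 12.0
    region_b_iso: float = 8.0

    def __post_init__(self):
        if self.seed is None:
            raise ModelError("seed is mandatory")
        if self.d_min <= 0.5:
            raise ModelError("d_min must exceed 0.5 Å")
        if self.noise < 0:
            raise ModelError("noise must be non-negative")
        if not 0.0 <= self.free_fraction <= 0.5:
            raise ModelError("free fraction must lie in [0, 0.5]")


@dataclasses.dataclass
class ToyCrystal:
    true_model: StructureModel
    start_model: StructureModel
    reflections: ReflectionSet
    region: RegionSelection
    mm_params: RestraintParams
    spec: ToySpec


def _cluster_geometry(center: np.ndarray) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Fe(S–O)₄-like cluster: tetrahedral thiolate sulfurs, each carrying a
    terminal oxygen.  Distal S···O and O···O pairs are 1-4/1-5, so the net
    charge produces genuine Coulomb repulsion in the region surrogate
    (1-2/1-3 pairs are excluded by convention)."""
    t = 1.0 / np.sqrt(3.0)
    s_dirs = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    elements = ["Fe"] + ["S"] * 4 + ["O"] * 4
    s_xyz = center + 2.25 * s_dirs
    # terminal O tilted ~30° off the Fe–S axis (keeps angle terms regular)
    perp = np.array([[t, -t, 0], [t, t, 0], [-t, -t, 0], [-t, t, 0]])
    perp /= np.linalg.norm(perp, axis=1)[:, None]
    o_dirs = np.cos(np.radians(30.0)) * s_dirs + np.sin(np.radians(30.0)) * perp
    o_xyz = s_xyz + 1.45 * o_dirs
    xyz = np.vstack([center, s_xyz, o_xyz])
    charges = np.array([0.0] + [-0.75] * 4 + [-0.5] * 4)
    return elements, xyz, charges


def _angle_deg(xyz, a, apex, b) -> float:
    va = xyz[a] - xyz[apex]
    vb = xyz[b] - xyz[apex]
    cosang = float(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def _cluster_params(xyz: np.ndarray) -> RestraintParams:
    """Bond/angle restraints with ideal values equal to the true geometry."""
    params = RestraintParams()
    for j in range(1, 5):  # Fe–S
        params.bonds.append(BondTerm(0, j, float(np.linalg.norm(xyz[j] - xyz[0])), 2000.0))
    for j in range(1, 5):  # S–O
        params.bonds.append(BondTerm(j, j + 4, float(np.linalg.norm(xyz[j + 4] - xyz[j])), 2500.0))
    for a in range(1, 5):  # S–Fe–S
        for b in range(a + 1, 5):
            params.angles.append(AngleTerm(a, 0, b, _angle_deg(xyz, a, 0, b), 300.0))
    for j in range(1, 5):  # Fe–S–O
        params.angles.append(AngleTerm(0, j, j + 4, _angle_deg(xyz, 0, j, j + 4), 250.0))
    return params


def _scatter_environment(rng, cell: UnitCell, n_env: int,
                         avoid: np.ndarray, min_sep: float = 2.3) -> np.ndarray:
    """Random well-separated environment atom positions (rejection sampling)."""
    placed = []
    lengths = np.array([cell.a, cell.b, cell.c])
    taken = list(avoid)
    attempts = 0
    while len(placed) < n_env:
        attempts += 1
        if attempts > 20000:
            raise ModelError("cannot place environment atoms without clashes")
        p = rng.uniform(0.05, 0.95, size=3) * lengths
        if all(np.linalg.norm(p - q) >= min_sep for q in taken):
            placed.append(p)
            taken.append(p)
    return np.array(placed)


def _amplitudes(model: StructureModel, hkl: np.ndarray) -> np.ndarray:
    return SFCalculation(model, hkl).amplitudes


def _make_reflections(model: StructureModel, spec: ToySpec,
                      rng: np.random.Generator) -> ReflectionSet:
    hkl = generate_hkl(model.cell, spec.d_min)
    ftrue = _amplitudes(model, hkl)
    keep = ftrue > 1e-6  # discard accidental systematic absences
    hkl, ftrue = hkl[keep], ftrue[keep]
    if spec.noise > 0:
        factor = 1.0 + rng.normal(0.0, spec.noise, size=len(ftrue))
        fobs = np.maximum(ftrue * factor, 0.1 * ftrue)
    else:
        fobs = ftrue.copy()
    sigma = np.maximum(spec.noise, SIGMA_FLOOR_FRAC) * ftrue
    free = rng.random(len(ftrue)) < spec.free_fraction
    # guard the invariant: Bernoulli draws may exceed the 0.5 cap on tiny sets
    if free.mean() > 0.5:
        free[:] = False
        free[: int(spec.free_fraction * len(ftrue))] = True
    return ReflectionSet(hkl, fobs, sigma, free)


def _perturb(model: StructureModel, region: RegionSelection, rmsd: float,
             rng: np.random.Generator) -> StructureModel:
    """Displace region atoms by a random vector rescaled to the exact RMSD."""
    start = model.copy()
    if rmsd <= 0 or len(region.indices) == 0:
        return start
    disp = rng.normal(size=(len(region.indices), 3))
    disp *= rmsd / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    start.xyz[region.indices] += disp
    start.sync_atoms()
    return start


def make_toy_crystal(spec: ToySpec) -> ToyCrystal:
    """Build (true model, perturbed start model, reflections, region, params)."""
    rng = np.random.default_rng(spec.seed)
    cell = UnitCell(*spec.cell)
    center = np.array([cell.a, cell.b, cell.c]) / 2.0
    elements, cluster_xyz, base_charges = _cluster_geometry(center)
    n_region = len(elements)
    charges = base_charges * (spec.region_net_charge / base_charges.sum())
    env_xyz = _scatter_environment(rng, cell, spec.n_env, cluster_xyz)
    env_elements = [("C", "N", "O")[i % 3] for i in range(spec.n_env)]
    atoms = []
    for i, (el, p) in enumerate(zip(elements, cluster_xyz)):
        atoms.append(Atom(element=el, pos=p, b_iso=spec.region_b_iso,
                          charge=float(charges[i]), chain="A", resnum=1,
                          resname="CLU", name=f"{el}{i}"))
    for i, (el, p) in enumerate(zip(env_elements, env_xyz)):
        atoms.append(Atom(element=el, pos=p, b_iso=spec.env_b_iso,
                          chain="B", resnum=i + 1, resname="ENV", name=el))
    mobile = np.zeros(len(atoms), dtype=bool)
    mobile[:n_region] = True  # environment frozen by construction
    true_model = StructureModel(cell, atoms, mobile=mobile)
    region = RegionSelection(indices=np.arange(n_region))
    mm_params = _cluster_params(cluster_xyz)
    refl = _make_reflections(true_model, spec, rng)
    start_model = _perturb(true_model, region, spec.perturb_rmsd, rng)
    return ToyCrystal(true_model, start_model, refl, region, mm_params, spec)


def demo_spec(seed: int = 2026) -> ToySpec:
    """The shipped demo fixture: net charge −5, 3% amplitude noise, 0.15 Å
    start perturbation — a desk-scale stand-in for a highly charged
    metallocluster region refined against real (noisy) data."""
    return ToySpec(seed=seed, region_net_charge=-5.0, noise=0.03,
                   perturb_rmsd=0.15)


# --------------------------------------------------------------------------
# Two-conformer fixtures
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TwoConformerToy:
    true_model: StructureModel
    start_model: StructureModel
    reflections: ReflectionSet
    region_a: RegionSelection
    region_b: RegionSelection
    mm_params: RestraintParams
    p: float


def make_two_conformer_toy(spec: ToySpec, p: float) -> TwoConformerToy:
    """Shared scaffold + two alternative ligand placements (occ p, 1−p).

    |Fobs| comes from the occupancy-weighted superposition of both
    conformers.  p must lie strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ModelError("occupancy p must lie in the open interval (0, 1)")
    rng = np.random.default_rng(spec.seed)
    cell = UnitCell(*spec.cell)
    center = np.array([cell.a, cell.b, cell.c]) / 2.0
    t = 1.0 / np.sqrt(3.0)
    s_dirs = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    scaffold_el = ["Fe"] + ["S"] * 4
    scaffold_xyz = np.vstack([center, center + 2.25 * s_dirs])
    lig_a = center + np.array([0.0, 2.05, 0.6])
    lig_b = center + np.array([0.0, 1.55, -1.45])  # S2B-like alternative
    if np.linalg.norm(lig_a - lig_b) < 0.3:
        import warnings
        warnings.warn("conformers closer than 0.3 Å; discrimination is degenerate")
    atoms = []
    for i, (el, pos) in enumerate(zip(scaffold_el, scaffold_xyz)):
        atoms.append(Atom(element=el, pos=pos, b_iso=spec.region_b_iso,
                          charge=(-1.0 if el == "S" else 0.0), chain="A",
                          resnum=1, resname="CLU", name=f"{el}{i}"))
    atoms.append(Atom(element="O", pos=lig_a, occupancy=p,
                      b_iso=spec.region_b_iso, charge=-0.5, chain="A",
                      resnum=2, resname="LIG", name="O", conformer="A"))
    atoms.append(Atom(element="S", pos=lig_b, occupancy=1.0 - p,
                      b_iso=spec.region_b_iso, charge=-0.5, chain="A",
                      resnum=2, resname="LIG", name="S", conformer="B"))
    env_xyz = _scatter_environment(rng, cell, spec.n_env,
                                   np.vstack([scaffold_xyz, lig_a, lig_b]))
    for i, pos in enumerate(env_xyz):
        atoms.append(Atom(element=("C", "N", "O")[i % 3], pos=pos,
                          b_iso=spec.env_b_iso, chain="B", resnum=i + 1,
                          resname="ENV", name="X"))
    n_scaffold = len(scaffold_el)
    idx_a = np.arange(n_scaffold + 1)                      # scaffold + ligand A
    idx_b = np.concatenate([np.arange(n_scaffold), [n_scaffold + 1]])
    mobile = np.zeros(len(atoms), dtype=bool)
    mobile[: n_scaffold + 2] = True
    true_model = StructureModel(cell, atoms, mobile=mobile)
    params = RestraintParams()
    for j in range(1, n_scaffold):
        params.bonds.append(BondTerm(0, j, float(np.linalg.norm(
            scaffold_xyz[j] - scaffold_xyz[0])), 2000.0))
    params.bonds.append(BondTerm(0, n_scaffold, float(np.linalg.norm(
        lig_a - scaffold_xyz[0])), 2000.0))
    params.bonds.append(BondTerm(0, n_scaffold + 1, float(np.linalg.norm(
        lig_b - scaffold_xyz[0])), 2000.0))
    refl = _make_reflections(true_model, spec, rng)
    region_a = RegionSelection(indices=idx_a)
    region_b = RegionSelection(indices=idx_b)
    start = true_model.copy()
    if spec.perturb_rmsd > 0:
        both = np.arange(n_scaffold + 2)
        disp = rng.normal(size=(len(both), 3))
        disp *= spec.perturb_rmsd / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        start.xyz[both] += disp
        start.sync_atoms()
    return TwoConformerToy(true_model, start, refl, region_a, region_b, params, p)
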