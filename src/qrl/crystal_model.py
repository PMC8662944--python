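"""Crystal data model and I/O.

Holds the atomic model (unit cell, symmetry operators, atoms with occupancy,
isotropic B, partial charge, conformer tag), the reflection data, region
selections, and link-atom construction at the region boundary.

Coordinates are Cartesian Å internally; fractional coordinates appear only at
the scattering boundary. The orthogonalization convention is the standard one
(a along x, b in the xy-plane), identical to gemmi's.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd


class ModelError(ValueError):
    """Raised for malformed models, cells or selections."""


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ModelError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ModelError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ModelError("degenerate cell (non-positive volume)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            raise ModelError("degenerate cell (non-positive metric determinant)")
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3×3 matrix M with x_cart = M @ x_frac (a along x, b in xy)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    @property
    def recip_matrix(self) -> np.ndarray:
        """Rows are the reciprocal basis vectors; |B @ hkl| = 1/d."""
        return self.frac_matrix  # B* = M^{-T}; used as hkl @ frac_matrix

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) for an (N,3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        s_vec = hkl @ self.frac_matrix  # reciprocal-space vectors, |.| = 1/d
        inv_d = np.linalg.norm(s_vec, axis=1)
        return 1.0 / inv_d

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Fractional → Cartesian (Å), standard orthogonalization convention."""
    return np.asarray(frac, dtype=float) @ cell.orth_matrix.T


def cart_to_frac(cell: UnitCell, cart) -> np.ndarray:
    """Cartesian (Å) → fractional."""
    return np.asarray(cart, dtype=float) @ cell.frac_matrix.T


# --------------------------------------------------------------------------
# Symmetry
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SymmetryOps:
    """Explicit symmetry operator list: (3×3 rotation, fractional translation).

    P1 (identity only) by default.  User-supplied operator lists are accepted
    as-is; group closure is not enforced.
    """

    rotations: list[np.ndarray] = dataclasses.field(
        default_factory=lambda: [np.eye(3)])
    translations: list[np.ndarray] = dataclasses.field(
        default_factory=lambda: [np.zeros(3)])

    def __post_init__(self):
        if len(self.rotations) != len(self.translations):
            raise ModelError("rotation/translation count mismatch")
        self.rotations = [np.asarray(r, dtype=float) for r in self.rotations]
        self.translations = [np.asarray(t, dtype=float) for t in self.translations]
        has_identity = any(
            np.allclose(r, np.eye(3)) and np.allclose(t, 0)
            for r, t in zip(self.rotations, self.translations))
        if not has_identity:
            raise ModelError("symmetry operator list must contain the identity")
        for r in self.rotations:
            det = abs(np.linalg.det(r))
            if not math.isclose(det, 1.0, abs_tol=1e-9):
                raise ModelError("rotation determinant must be ±1")

    def __len__(self) -> int:
        return len(self.rotations)


# --------------------------------------------------------------------------
# Atoms and the structure model
# --------------------------------------------------------------------------

KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca "
    "V Cr Mn Fe Co Ni Cu Zn Se Br Mo I W".split())

METAL_ELEMENTS = frozenset(
    "Li Be Na Mg Al K Ca V Cr Mn Fe Co Ni Cu Zn Mo W".split())


@dataclasses.dataclass
class Atom:
    """One atom record; `conformer` is the PDB altLoc ('' when unique)."""

    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 10.0
    charge: float = 0.0
    chain: str = "A"
    resnum: int = 1
    resname: str = "UNK"
    name: str = ""
    conformer: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.element not in KNOWN_ELEMENTS:
            raise ModelError(
                f"unknown element {self.element!r}; supported: "
                + " ".join(sorted(KNOWN_ELEMENTS)))
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelError("occupancy must lie in [0, 1]")
        if self.b_iso < 0:
            raise ModelError("B_iso must be non-negative")


class StructureModel:
    """Ordered atom list in a unit cell with a mobile-atom mask.

    Field arrays (positions, occupancies, B, charges) are exposed as numpy
    views so the energy modules can work vectorized; frozen atoms (mobile
    mask False) never move during refinement.
    """

    def __init__(self, cell: UnitCell, atoms: Sequence[Atom],
                 ops: SymmetryOps | None = None,
                 mobile: np.ndarray | None = None):
        self.cell = cell
        self.ops = ops if ops is not None else SymmetryOps()
        self.atoms = list(atoms)
        n = len(self.atoms)
        self.xyz = np.array([a.pos for a in self.atoms], dtype=float).reshape(n, 3)
        self.occupancy = np.array([a.occupancy for a in self.atoms], dtype=float)
        self.b_iso = np.array([a.b_iso for a in self.atoms], dtype=float)
        self.charge = np.array([a.charge for a in self.atoms], dtype=float)
        self.elements = [a.element for a in self.atoms]
        if mobile is None:
            mobile = np.ones(n, dtype=bool)
        self.mobile = np.asarray(mobile, dtype=bool)
        if self.mobile.shape != (n,):
            raise ModelError("mobile mask length must equal atom count")

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "StructureModel":
        atoms = [dataclasses.replace(a, pos=a.pos.copy()) for a in self.atoms]
        m = StructureModel(self.cell, atoms, self.ops, self.mobile.copy())
        m.xyz[:] = self.xyz
        m.occupancy[:] = self.occupancy
        m.b_iso[:] = self.b_iso
        m.charge[:] = self.charge
        return m

    def sync_atoms(self) -> None:
        """Push the field arrays back into the per-atom records."""
        for i, a in enumerate(self.atoms):
            a.pos = self.xyz[i].copy()
            a.occupancy = float(self.occupancy[i])
            a.b_iso = float(self.b_iso[i])
            a.charge = float(self.charge[i])

    def residue_groups(self) -> dict[tuple, list[int]]:
        """Atom indices grouped by (chain, resnum, conformer tag)."""
        groups: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.chain, a.resnum, a.conformer), []).append(i)
        return groups


# --------------------------------------------------------------------------
# Region selection and link atoms
# --------------------------------------------------------------------------

DEFAULT_LINK_SCALE = 0.709  # C–H / C–C bond-length ratio


@dataclasses.dataclass
class RegionSelection:
    """System 1: the atoms whose energy comes from the region backend.

    ``boundary_bonds`` lists covalent bonds cut by the region boundary as
    (inside-atom index, outside-atom index); each gets a hydrogen link atom.
    """

    indices: np.ndarray
    boundary_bonds: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    link_scale: float = DEFAULT_LINK_SCALE
    link_scale_overrides: dict[tuple[int, int], float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ModelError("region indices must be unique")

    def validate(self, n_atoms: int) -> None:
        if len(self.indices) and (self.indices.min() < 0 or self.indices.max() >= n_atoms):
            raise ModelError("region index out of range")
        inside = set(self.indices.tolist())
        for i, o in self.boundary_bonds:
            if (i in inside) == (o in inside):
                raise ModelError(
                    f"boundary bond ({i},{o}) must have exactly one endpoint in the region")

    def contains(self, idx: int) -> bool:
        return idx in set(self.indices.tolist())


@dataclasses.dataclass
class LinkAtom:
    """Hydrogen cap on a cut bond: x_link = x_in + scale·(x_out − x_in)."""

    inside: int
    outside: int
    scale: float
    pos: np.ndarray


@dataclasses.dataclass
class AugmentedRegion:
    """Region atoms plus link atoms, ready for a backend call.

    ``indices`` maps the first len(indices) rows back to model atoms; link
    atoms follow, with chain-rule weights through their defining bond.
    """

    indices: np.ndarray
    elements: list[str]
    xyz: np.ndarray
    charges: np.ndarray
    links: list[LinkAtom]

    @property
    def n_real(self) -> int:
        return len(self.indices)

    def scatter_gradient(self, grad: np.ndarray, n_atoms: int) -> np.ndarray:
        """Map a (n_real+n_link, 3) gradient onto all model atoms.

        Link-atom forces are distributed onto the two atoms of the defining
        bond with weights (1−s) and s (chain rule through the placement).
        """
        out = np.zeros((n_atoms, 3))
        np.add.at(out, self.indices, grad[: self.n_real])
        for j, link in enumerate(self.links):
            g = grad[self.n_real + j]
            out[link.inside] += (1.0 - link.scale) * g
            out[link.outside] += link.scale * g
        return out


def place_link_atoms(model: StructureModel, region: RegionSelection) -> AugmentedRegion:
    """Cap cut bonds with hydrogen link atoms along the inside→outside vector.

    The link atom sits at ``scale·|bond|`` from the inside atom (default scale
    0.709 ⇒ ≈1.09 Å on a 1.54 Å C–C bond) and carries zero charge.
    """
    region.validate(len(model))
    idx = region.indices
    links: list[LinkAtom] = []
    for (i, o) in region.boundary_bonds:
        if i not in set(idx.tolist()):
            i, o = o, i  # normalize: first index inside
        bond = model.xyz[o] - model.xyz[i]
        blen = float(np.linalg.norm(bond))
        if blen < 0.5:
            raise ModelError(f"boundary bond ({i},{o}) shorter than 0.5 Å")
        scale = region.link_scale_overrides.get((i, o), region.link_scale)
        links.append(LinkAtom(i, o, scale, model.xyz[i] + scale * bond))
    xyz = np.vstack([model.xyz[idx]] + [l.pos[None, :] for l in links]) \
        if links else model.xyz[idx].copy()
    elements = [model.elements[i] for i in idx] + ["H"] * len(links)
    charges = np.concatenate([model.charge[idx], np.zeros(len(links))])
    return AugmentedRegion(idx.copy(), elements, xyz, charges, links)


def refresh_link_positions(aug: AugmentedRegion, model: StructureModel) -> None:
    """Recompute region + link coordinates from the current model."""
    aug.xyz[: aug.n_real] = model.xyz[aug.indices]
    for j, link in enumerate(aug.links):
        bond = model.xyz[link.outside] - model.xyz[link.inside]
        link.pos = model.xyz[link.inside] + link.scale * bond
        aug.xyz[aug.n_real + j] = link.pos


# --------------------------------------------------------------------------
# Reflections
# --------------------------------------------------------------------------

UNDEFINED_R = float("nan")


class ReflectionSet:
    """Observed amplitudes: Miller indices, |Fobs|, σ, free-set flag."""

    def __init__(self, hkl: np.ndarray, fobs: np.ndarray,
                 sigma: np.ndarray, free: np.ndarray):
        self.hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        self.fobs = np.asarray(fobs, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.free = np.asarray(free, dtype=bool)
        n = len(self.hkl)
        if not (len(self.fobs) == len(self.sigma) == len(self.free) == n):
            raise ModelError("reflection column length mismatch")
        if len(np.unique(self.hkl, axis=0)) != n:
            raise ModelError("duplicate Miller indices")
        if np.any(self.sigma <= 0):
            raise ModelError("sigmas must be strictly positive")
        if np.any(self.fobs <= 0):
            raise ModelError("|Fobs| must be positive")
        if n and not 0.0 <= self.free.mean() <= 0.5:
            raise ModelError("free-set fraction must lie in [0, 0.5]")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def work(self) -> np.ndarray:
        return ~self.free

    def d_spacing(self, cell: UnitCell) -> np.ndarray:
        return cell.d_spacing(self.hkl)

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(self.hkl[mask], self.fobs[mask],
                             self.sigma[mask], self.free[mask])


def read_reflections_tsv(path) -> ReflectionSet:
    """Read the `h k l fobs sigma free` whitespace-separated table."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["h", "k", "l", "fobs", "sigma", "free"], header=None,
                     skiprows=_count_header_rows(path))
    return ReflectionSet(df[["h", "k", "l"]].to_numpy(int),
                         df["fobs"].to_numpy(), df["sigma"].to_numpy(),
                         df["free"].to_numpy(int).astype(bool))


def _count_header_rows(path) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh):
            tok = line.split()
            if not tok or line.lstrip().startswith("#"):
                continue
            try:
                float(tok[0])
                return i
            except ValueError:
                return i + 1
    return 0


def write_reflections_tsv(refl: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# h k l fobs sigma free\n")
        for (h, k, l), fo, sig, fr in zip(refl.hkl, refl.fobs, refl.sigma, refl.free):
            fh.write(f"{h} {k} {l} {fo:.6f} {sig:.6f} {int(fr)}\n")


def read_reflections_mmcif(path, free_flag_value: int | None = 0) -> ReflectionSet:
    """Read a structure-factor mmCIF (`_refln` loop with F_meas_au/sigma).

    ``free_flag_value`` gives the status/flag value marking free reflections
    (pass None when the file has no test-set column).
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    h = block.find_loop("_refln.index_h")
    k = block.find_loop("_refln.index_k")
    l = block.find_loop("_refln.index_l")
    f = block.find_loop("_refln.F_meas_au")
    s = block.find_loop("_refln.F_meas_sigma_au")
    if not list(h):
        raise ModelError("no _refln loop with Miller indices found")
    hkl = np.array([[int(a), int(b), int(c)] for a, b, c in zip(h, k, l)])
    fobs = np.array([float(x) for x in f])
    sigma = np.array([float(x) for x in s]) if list(s) else np.full(len(fobs), 1.0)
    flags = block.find_loop("_refln.pdbx_r_free_flag")
    if list(flags) and free_flag_value is not None:
        free = np.array([int(x) == free_flag_value for x in flags])
    else:
        free = np.zeros(len(fobs), dtype=bool)
    return ReflectionSet(hkl, fobs, sigma, free)


# --------------------------------------------------------------------------
# PDB I/O (via gemmi) and the charge/radius sidecar
# --------------------------------------------------------------------------

def read_model(path, charge_table: dict[tuple[str, str], float] | None = None) -> StructureModel:
    """Read a PDB file into a StructureModel.

    altLoc populates the conformer tag; partial charges default to 0 unless a
    sidecar table keyed by (residue name, atom name) is supplied.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    cellg = st.cell
    if cellg.a <= 0:  # PDB without CRYST1: unit placeholder
        cell = UnitCell(1, 1, 1)
    else:
        cell = UnitCell(cellg.a, cellg.b, cellg.c, cellg.alpha, cellg.beta, cellg.gamma)
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    elem = at.element.name
                    if elem not in KNOWN_ELEMENTS:
                        raise ModelError(
                            f"unknown element {elem!r} in {path.name}; supported: "
                            + " ".join(sorted(KNOWN_ELEMENTS)))
                    charge = 0.0
                    if charge_table is not None:
                        charge = charge_table.get((res.name, at.name), 0.0)
                    atoms.append(Atom(
                        element=elem,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ, b_iso=at.b_iso, charge=charge,
                        chain=chain.name, resnum=res.seqid.num, resname=res.name,
                        name=at.name, conformer=(at.altloc or "").strip()))
        break  # first MODEL only
    if not atoms:
        raise ModelError(f"no ATOM/HETATM records in {path}")
    return StructureModel(cell, atoms)


def write_model(model: StructureModel, path) -> None:
    """Write the model as PDB (CRYST1 + ATOM records, P1)."""
    model.sync_atoms()
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        res = None
        if len(ch) and ch[-1].seqid.num == a.resnum and ch[-1].name == a.resname:
            res = ch[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            res.het_flag = "H"
            ch.add_residue(res)
            res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name or a.element
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        at.altloc = a.conformer if a.conformer else "\0"
        res.add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))


def read_charge_table(path) -> dict[tuple[str, str], float]:
    """Sidecar text table: `resname atomname charge radius` per line.

    Returns the charge map; radii are read by :func:`read_radius_table`.
    """
    table = {}
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        table[(tok[0], tok[1])] = float(tok[2])
    return table


def read_radius_table(path) -> dict[tuple[str, str], float]:
    table = {}
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if len(tok) >= 4:
            table[(tok[0], tok[1])] = float(tok[3])
    return table
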