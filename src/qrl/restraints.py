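"""Empirical (MM) restraints: harmonic bonds and angles, optional cosine
torsions, and a one-sided quadratic nonbonded repulsion.

E_MM = Σ k_b(r−r0)² + Σ k_a(θ−θ0)² + Σ k_t·(1+cos(nφ−γ)) + Σ k_rep(d0−r)²₊

No electrostatics (restraint sets in refinement conventionally exclude
them).  The region-restricted sum E_MM1 counts only terms whose atoms all
lie inside system 1; link atoms are never referenced by restraints.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .crystal_model import RegionSelection, StructureModel
from .scattering import TargetValue


class RestraintError(ValueError):
    pass


@dataclasses.dataclass
class BondTerm:
    i: int
    j: int
    r0: float
    k: float


@dataclasses.dataclass
class AngleTerm:
    i: int
    j: int          # apex
    k_: int
    theta0: float   # degrees
    k: float        # energy/rad²


@dataclasses.dataclass
class TorsionTerm:
    i: int
    j: int
    k_: int
    l: int
    periodicity: int
    phase: float    # degrees
    k: float


@dataclasses.dataclass
class RepulsionTerm:
    """One-sided quadratic repulsion k·(d0−r)² for nonbonded r < d0."""

    cutoff: float
    k: float
    d0: float


@dataclasses.dataclass
class RestraintParams:
    bonds: list[BondTerm] = dataclasses.field(default_factory=list)
    angles: list[AngleTerm] = dataclasses.field(default_factory=list)
    torsions: list[TorsionTerm] = dataclasses.field(default_factory=list)
    repulsions: list[RepulsionTerm] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        for t in self.bonds + self.angles + self.torsions + self.repulsions:
            if t.k < 0:
                raise RestraintError("force constants must be non-negative")
        for b in self.bonds:
            if b.r0 <= 0:
                raise RestraintError("bond r0 must be positive")
        for a in self.angles:
            if not 0.0 < a.theta0 <= 180.0:
                raise RestraintError("theta0 must lie in (0, 180] degrees")

    def n_terms(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.torsions) + len(self.repulsions)

    def max_index(self) -> int:
        idx = [-1]
        idx += [max(b.i, b.j) for b in self.bonds]
        idx += [max(a.i, a.j, a.k_) for a in self.angles]
        idx += [max(t.i, t.j, t.k_, t.l) for t in self.torsions]
        return max(idx)

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {(min(b.i, b.j), max(b.i, b.j)) for b in self.bonds}

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs implied by the bond list."""
        adj: dict[int, set[int]] = {}
        for b in self.bonds:
            adj.setdefault(b.i, set()).add(b.j)
            adj.setdefault(b.j, set()).add(b.i)
        excl = self.bonded_pairs()
        for center, nbrs in adj.items():
            nb = sorted(nbrs)
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    excl.add((nb[x], nb[y]))
        return excl

    def remap(self, index_map: dict[int, int]) -> "RestraintParams":
        """Restrict to terms fully inside `index_map` and renumber atoms."""
        out = RestraintParams()
        for b in self.bonds:
            if b.i in index_map and b.j in index_map:
                out.bonds.append(BondTerm(index_map[b.i], index_map[b.j], b.r0, b.k))
        for a in self.angles:
            if a.i in index_map and a.j in index_map and a.k_ in index_map:
                out.angles.append(AngleTerm(index_map[a.i], index_map[a.j],
                                            index_map[a.k_], a.theta0, a.k))
        for t in self.torsions:
            if all(x in index_map for x in (t.i, t.j, t.k_, t.l)):
                out.torsions.append(TorsionTerm(index_map[t.i], index_map[t.j],
                                                index_map[t.k_], index_map[t.l],
                                                t.periodicity, t.phase, t.k))
        out.repulsions = list(self.repulsions)
        return out


# --------------------------------------------------------------------------
# Energy and gradient
# --------------------------------------------------------------------------

def _angle_terms(xyz, term: AngleTerm):
    """Angle value (rad) and Cartesian gradients for the three atoms."""
    rij = xyz[term.i] - xyz[term.j]
    rkj = xyz[term.k_] - xyz[term.j]
    nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
    cos_t = float(rij @ rkj) / (nij * nkj)
    cos_t = min(1.0, max(-1.0, cos_t))
    theta = np.arccos(cos_t)
    sin_t = max(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
    dth_di = (cos_t * rij / nij - rkj / nkj) / (nij * sin_t)
    dth_dk = (cos_t * rkj / nkj - rij / nij) / (nkj * sin_t)
    return theta, dth_di, dth_dk


def _torsion_terms(xyz, t: TorsionTerm):
    """Dihedral angle (rad) and gradients (standard b1/b2/b3 formulation)."""
    b1 = xyz[t.j] - xyz[t.i]
    b2 = xyz[t.k_] - xyz[t.j]
    b3 = xyz[t.l] - xyz[t.k_]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(nb2 * float(b1 @ n2), float(n1 @ n2))
    # analytic gradients (Blondel & Karplus form)
    n1sq = float(n1 @ n1) + 1e-300
    n2sq = float(n2 @ n2) + 1e-300
    dphi_di = -nb2 / n1sq * n1
    dphi_dl = nb2 / n2sq * n2
    s = float(b1 @ b2) / (nb2**2)
    u = float(b3 @ b2) / (nb2**2)
    dphi_dj = -(1.0 + s) * dphi_di + u * dphi_dl
    dphi_dk = s * dphi_di - (1.0 + u) * dphi_dl
    return phi, dphi_di, dphi_dj, dphi_dk, dphi_dl


def mm_energy(model: StructureModel, params: RestraintParams,
              region: RegionSelection | None = None,
              term_subset: str = "all") -> TargetValue:
    """Restraint energy and analytic gradient.

    ``term_subset='region_internal'`` keeps only terms whose atoms all lie in
    system 1 — the E_MM1 sum subtracted in the combined refinement energy.
    """
    xyz = model.xyz
    n = len(model)
    if params.max_index() >= n:
        raise RestraintError(
            f"restraint references atom {params.max_index()} but model has {n} atoms")
    if term_subset == "region_internal":
        if region is None:
            raise RestraintError("region_internal subset requires a region")
        inside = set(region.indices.tolist())

        def keep(*idx):
            return all(i in inside for i in idx)
    elif term_subset == "all":
        def keep(*idx):
            return True
    else:
        raise RestraintError(f"unknown term subset {term_subset!r}")

    energy = 0.0
    grad = np.zeros((n, 3))
    for b in params.bonds:
        if not keep(b.i, b.j):
            continue
        d = xyz[b.i] - xyz[b.j]
        r = float(np.linalg.norm(d))
        dr = r - b.r0
        energy += b.k * dr * dr
        g = 2.0 * b.k * dr * d / r
        grad[b.i] += g
        grad[b.j] -= g
    for a in params.angles:
        if not keep(a.i, a.j, a.k_):
            continue
        theta, dth_di, dth_dk = _angle_terms(xyz, a)
        dth = theta - np.radians(a.theta0)
        energy += a.k * dth * dth
        coef = 2.0 * a.k * dth
        grad[a.i] += coef * dth_di
        grad[a.k_] += coef * dth_dk
        grad[a.j] -= coef * (dth_di + dth_dk)
    for t in params.torsions:
        if not keep(t.i, t.j, t.k_, t.l):
            continue
        phi, gi, gj, gk, gl = _torsion_terms(xyz, t)
        arg = t.periodicity * phi - np.radians(t.phase)
        energy += t.k * (1.0 + np.cos(arg))
        coef = -t.k * t.periodicity * np.sin(arg)
        grad[t.i] += coef * gi
        grad[t.j] += coef * gj
        grad[t.k_] += coef * gk
        grad[t.l] += coef * gl
    if params.repulsions:
        excl = params.excluded_pairs()
        for rep in params.repulsions:
            dmat = xyz[:, None, :] - xyz[None, :, :]
            dist = np.linalg.norm(dmat, axis=2)
            iu, ju = np.triu_indices(n, k=1)
            for i, j in zip(iu, ju):
                if (i, j) in excl:
                    continue
                r = dist[i, j]
                if r >= min(rep.cutoff, rep.d0) or not keep(i, j):
                    continue
                dr = rep.d0 - r
                energy += rep.k * dr * dr
                g = -2.0 * rep.k * dr * dmat[i, j] / r
                grad[i] += g
                grad[j] -= g
    return TargetValue(float(energy), grad)


# --------------------------------------------------------------------------
# Parameter file I/O
# --------------------------------------------------------------------------
# Line-oriented text, atoms referenced by index with a '#' prefix:
#   BOND #0 #1 0.9572 2000.0
#   ANGL #1 #0 #2 104.52 300.0
#   TORS #0 #1 #2 #3 3 0.0 5.0
#   REPU 6.0 100.0 2.8
# Name-keyed lines (BOND HOH O HOH H1 0.9572 2000) are bound against a model
# with bind_named_params (same residue instance only).

def load_params(path) -> RestraintParams:
    """Parse a restraint parameter file; duplicate definitions → last wins."""
    params = RestraintParams()
    named: list[tuple] = []
    seen: dict[tuple, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        tok = line.split()
        if not tok or tok[0].startswith("#") or tok[0].startswith("!"):
            continue
        kind = tok[0].upper()
        try:
            if kind == "BOND" and tok[1].startswith("#"):
                i, j = int(tok[1][1:]), int(tok[2][1:])
                term = BondTerm(i, j, float(tok[3]), float(tok[4]))
                key = ("BOND", min(i, j), max(i, j))
                if key in seen:
                    warnings.warn(f"duplicate BOND term at line {lineno}; last wins")
                    params.bonds[seen[key]] = term
                else:
                    seen[key] = len(params.bonds)
                    params.bonds.append(term)
            elif kind == "ANGL" and tok[1].startswith("#"):
                term = AngleTerm(int(tok[1][1:]), int(tok[2][1:]), int(tok[3][1:]),
                                 float(tok[4]), float(tok[5]))
                params.angles.append(term)
            elif kind == "TORS" and tok[1].startswith("#"):
                params.torsions.append(TorsionTerm(
                    int(tok[1][1:]), int(tok[2][1:]), int(tok[3][1:]), int(tok[4][1:]),
                    int(tok[5]), float(tok[6]), float(tok[7])))
            elif kind == "REPU":
                params.repulsions.append(
                    RepulsionTerm(float(tok[1]), float(tok[2]), float(tok[3])))
            elif kind in ("BOND", "ANGL", "TORS"):
                named.append((kind, tok[1:]))
            else:
                raise ValueError(f"unknown record {kind}")
        except (IndexError, ValueError) as exc:
            raise RestraintError(f"{path}:{lineno}: cannot parse {line!r}: {exc}") from exc
    if named:
        params.named = named  # bound later against a model
    RestraintParams.__post_init__(params)  # re-validate after mutation
    return params


def bind_named_params(params: RestraintParams, model: StructureModel) -> RestraintParams:
    """Resolve name-keyed terms (resname/atomname, same residue instance)."""
    named = getattr(params, "named", [])
    out = RestraintParams(list(params.bonds), list(params.angles),
                          list(params.torsions), list(params.repulsions))
    by_residue: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(model.atoms):
        by_residue.setdefault((a.chain, a.resnum, a.conformer), {})[a.name] = i
    for kind, tok in named:
        if kind == "BOND":
            resa, atma, resb, atmb, r0, k = tok[0], tok[1], tok[2], tok[3], float(tok[4]), float(tok[5])
            for (ch, num, conf), amap in by_residue.items():
                ra = model.atoms[next(iter(amap.values()))].resname
                if ra == resa and atma in amap and atmb in amap:
                    out.bonds.append(BondTerm(amap[atma], amap[atmb], r0, k))
        elif kind == "ANGL":
            resa, a1, a2, a3, th, k = tok[0], tok[1], tok[2], tok[3], float(tok[4]), float(tok[5])
            for (ch, num, conf), amap in by_residue.items():
                ra = model.atoms[next(iter(amap.values()))].resname
                if ra == resa and all(x in amap for x in (a1, a2, a3)):
                    out.angles.append(AngleTerm(amap[a1], amap[a2], amap[a3], th, k))
    return out


def write_params(params: RestraintParams, path) -> None:
    with open(path, "w") as fh:
        fh.write("# qrl restraint parameters\n")
        for b in params.bonds:
            fh.write(f"BOND #{b.i} #{b.j} {b.r0:.17g} {b.k:.17g}\n")
        for a in params.angles:
            fh.write(f"ANGL #{a.i} #{a.j} #{a.k_} {a.theta0:.17g} {a.k:.17g}\n")
        for t in params.torsions:
            fh.write(f"TORS #{t.i} #{t.j} #{t.k_} #{t.l} {t.periodicity} "
                     f"{t.phase:.17g} {t.k:.17g}\n")
        for r in params.repulsions:
            fh.write(f"REPU {r.cutoff:.17g} {r.k:.17g} {r.d0:.17g}\n")
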