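"""Combined refinement energy and its minimizers.

The refinement target is

    E_total = E_QM1(ε) + w_MM · (E_MM − E_MM1 + w_A · E_X-ray)

where E_QM1 is the region (system 1) energy from the backend, E_MM the full
restraint energy, E_MM1 its region-internal part (subtracted to avoid double
counting), and E_X-ray the crystallographic amplitude target.  Atoms outside
the mobile mask are frozen: their gradient entries are exactly zero and
their coordinates never change.

Coordinate refinement is quasi-Newton (L-BFGS-B) over the mobile atoms; the
dual-conformation (2QM) mode runs two region energies with fixed occupancies
entering only the calculated structure factors.  A separate post-refinement
stage refines isotropic B factors at fixed coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .crystal_model import (AugmentedRegion, ModelError, RegionSelection,
                            ReflectionSet, StructureModel, place_link_atoms)
from .region_energy import RegionEnergyResult, region_energy
from .restraints import BondTerm, RestraintParams, mm_energy
from .scattering import (TargetValue, auto_wA, r_factors, xray_target)

DEFAULT_W_MM = 1.0 / 3.0
LINK_BOND_K = 2500.0  # kJ/mol/Å², harmonic cap-bond used in free optimization


class RefinementError(RuntimeError):
    pass


@dataclasses.dataclass
class RefinementConfig:
    """Weights, dielectric constant, target choice and convergence knobs."""

    w_a: float | str = "auto"
    w_mm: float = DEFAULT_W_MM
    epsilon: float = 1.0
    target: str = "lsq"              # lsq | mlf
    max_cycles: int = 200
    conv_shift: float = 1e-3         # Å
    conv_energy: float = 0.01        # kJ/mol
    occupancies: tuple[float, float] = (0.86, 0.14)
    seed: int = 0
    n_shells: int = 8
    cosmo_n_points: int = 302
    cosmo_seed: int = 0
    use_lj: bool = True
    adp_similarity_weight: float = 0.05
    adp_b_min: float = 1.0

    def __post_init__(self):
        if self.w_mm <= 0:
            raise ModelError("w_MM must be positive")
        p = self.occupancies[0]
        if not 0.0 <= p <= 1.0:
            raise ModelError("occupancy p must lie in [0, 1]")
        if self.conv_shift <= 0 or self.conv_energy <= 0:
            raise ModelError("convergence thresholds must be positive")
        if self.target not in ("lsq", "mlf"):
            raise ModelError(f"unknown target {self.target!r}")

    def resolved_w_a(self) -> float:
        if self.w_a == "auto":
            raise RefinementError(
                "w_A is 'auto' and unresolved; call resolve_auto_wa() "
                "(gradient-norm matching) before evaluating the total energy")
        return float(self.w_a)


def build_region_params(model: StructureModel, region: RegionSelection,
                        mm_params: RestraintParams,
                        aug: AugmentedRegion | None = None) -> RestraintParams:
    """Region-local bonded parameters for the builtin surrogate.

    Region-internal restraint terms are renumbered to local indices; each
    link atom gets a harmonic bond to its inside atom (r0 = placed length)
    so that free optimizations keep the cap in place.
    """
    if aug is None:
        aug = place_link_atoms(model, region)
    index_map = {int(g): l for l, g in enumerate(region.indices)}
    local = mm_params.remap(index_map)
    for j, link in enumerate(aug.links):
        r0 = float(np.linalg.norm(aug.xyz[aug.n_real + j] - model.xyz[link.inside]))
        local.bonds.append(BondTerm(index_map[link.inside], aug.n_real + j,
                                    r0, LINK_BOND_K))
    return local


def resolve_auto_wa(model: StructureModel, region, refl: ReflectionSet,
                    config: RefinementConfig, mm_params: RestraintParams) -> RefinementConfig:
    """Replace w_a='auto' by the gradient-norm-matching value."""
    if config.w_a != "auto":
        return config
    g_mm = mm_energy(model, mm_params).grad
    wa = auto_wA(model, refl, g_mm, target=config.target)
    return dataclasses.replace(config, w_a=wa)


def _region_term(model: StructureModel, region: RegionSelection,
                 config: RefinementConfig, region_params: RestraintParams,
                 cavity=None) -> tuple[RegionEnergyResult, AugmentedRegion]:
    aug = place_link_atoms(model, region)
    res = region_energy(aug, region_params, epsilon=config.epsilon,
                        cosmo_n_points=config.cosmo_n_points,
                        cosmo_seed=config.cosmo_seed, cavity=cavity,
                        use_lj=config.use_lj)
    return res, aug


def total_energy(model: StructureModel, region, refl: ReflectionSet,
                 config: RefinementConfig, mm_params: RestraintParams,
                 region_params=None, cavity=None,
                 shell_params=None) -> TargetValue:
    """Assembled refinement energy and gradient over mobile atoms.

    ``region`` may be a single RegionSelection or a sequence of them (2QM);
    each contributes its own E_QM1 and E_MM1.  Pass ``cavity`` (one per
    region) to freeze the COSMO cavity, e.g. for finite-difference checks.
    """
    regions: Sequence[RegionSelection] = (
        [region] if isinstance(region, RegionSelection) else list(region))
    w_a = config.resolved_w_a()
    if region_params is None:
        region_params = [build_region_params(model, r, mm_params) for r in regions]
    cavities = cavity if isinstance(cavity, (list, tuple)) else [cavity] * len(regions)
    e_qm1 = 0.0
    e_mm1 = 0.0
    grad = np.zeros((len(model), 3))
    for r, rp, cav in zip(regions, region_params, cavities):
        if len(r.indices) == 0:
            continue
        res, aug = _region_term(model, r, config, rp, cav)
        e_qm1 += res.total
        grad += aug.scatter_gradient(res.grad, len(model))
        mm1 = mm_energy(model, mm_params, region=r, term_subset="region_internal")
        e_mm1 += mm1.energy
        grad -= config.w_mm * mm1.grad
    mm_all = mm_energy(model, mm_params)
    xr = xray_target(model, refl, config.target,
                     nshells=config.n_shells, shell_params=shell_params)
    energy = e_qm1 + config.w_mm * (mm_all.energy - e_mm1 + w_a * xr.energy)
    grad += config.w_mm * (mm_all.grad + w_a * xr.grad)
    grad[~model.mobile] = 0.0
    return TargetValue(energy, grad, info={
        "e_qm1": e_qm1, "e_mm": mm_all.energy, "e_mm1": e_mm1,
        "e_xray": xr.energy, "k": xr.info.get("k"),
        "fcalc_amp": xr.info.get("fcalc_amp"),
        "shell_params": xr.info.get("shell_params")})


# --------------------------------------------------------------------------
# Coordinate refinement
# --------------------------------------------------------------------------

@dataclasses.dataclass
class RefinementTrace:
    rows: list[dict] = dataclasses.field(default_factory=list)
    converged: bool = False
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _trace_row(cycle, tv: TargetValue, refl, max_shift) -> dict:
    amp = tv.info["fcalc_amp"]
    r_work, r_free = r_factors(refl, amp)
    g = tv.grad
    return {"cycle": cycle, "e_total": tv.energy, "e_qm1": tv.info["e_qm1"],
            "e_mm": tv.info["e_mm"], "e_mm1": tv.info["e_mm1"],
            "e_xray": tv.info["e_xray"], "r_work": r_work, "r_free": r_free,
            "max_grad": float(np.abs(g).max()) if len(g) else 0.0,
            "max_shift": max_shift}


def _minimize_model(model: StructureModel, energy_fn, config: RefinementConfig,
                    refl: ReflectionSet, step_bound: float | None = None
                    ) -> RefinementTrace:
    """Shared L-BFGS-B loop over mobile coordinates with per-cycle trace."""
    mobile = model.mobile
    frozen_xyz = model.xyz[~mobile].copy()
    trace = RefinementTrace(seed=config.seed)
    state = {"x_prev": model.xyz[mobile].copy(), "cycle": 0,
             "e_prev": None, "bad_cycles": 0}

    def fun(x):
        model.xyz[mobile] = x.reshape(-1, 3)
        tv = energy_fn(model)
        state["last_tv"] = tv
        return tv.energy, tv.grad[mobile].ravel()

    def callback(xk):
        xk = xk.reshape(-1, 3)
        shift = float(np.abs(xk - state["x_prev"]).max()) if len(xk) else 0.0
        state["x_prev"] = xk.copy()
        state["cycle"] += 1
        tv = state["last_tv"]
        trace.rows.append(_trace_row(state["cycle"], tv, refl, shift))
        if state["e_prev"] is not None and tv.energy > state["e_prev"] + config.conv_energy:
            state["bad_cycles"] += 1
            if state["bad_cycles"] >= 5:
                raise RefinementError(
                    f"energy increased for 5 consecutive cycles "
                    f"(E={tv.energy:.4g}); check weights/gradients")
        else:
            state["bad_cycles"] = 0
        state["e_prev"] = tv.energy
        if shift < config.conv_shift:
            trace.converged = True
            raise StopIteration

    x0 = model.xyz[mobile].ravel()
    tv0 = energy_fn(model)
    state["last_tv"] = tv0
    trace.rows.append(_trace_row(0, tv0, refl, 0.0))
    bounds = None
    if step_bound is not None:
        # trust region: a frozen COSMO cavity makes the energy unboundedly
        # negative when an atom reaches the surface, so cap per-run steps
        bounds = [(xi - step_bound, xi + step_bound) for xi in x0]
    if len(x0):
        res = scipy.optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B", callback=callback,
            bounds=bounds,
            options={"maxiter": config.max_cycles, "ftol": 1e-12,
                     "gtol": 1e-10, "maxcor": 20})
        model.xyz[mobile] = res.x.reshape(-1, 3)
        if not trace.converged:
            # L-BFGS-B's own convergence (ftol/gtol) also counts as converged
            trace.converged = bool(res.success)
        tvf = energy_fn(model)
        last_shift = float(np.abs(model.xyz[mobile] - state["x_prev"]).max())
        trace.rows.append(_trace_row(state["cycle"] + 1, tvf, refl, last_shift))
    model.xyz[~mobile] = frozen_xyz  # bit-identical frozen atoms
    model.sync_atoms()
    return trace


def build_cavities(model: StructureModel, regions, region_params,
                   config: RefinementConfig):
    """COSMO cavities at the current geometry (None for uncharged/vacuum)."""
    from . import cosmo as _cosmo
    cavities = []
    for r in regions:
        if (config.epsilon > 1.0 and len(r.indices)
                and np.any(model.charge[r.indices] != 0.0)):
            aug = place_link_atoms(model, r)
            cavities.append(_cosmo.build_cavity(
                aug.elements, aug.xyz, n_points=config.cosmo_n_points,
                seed=config.cosmo_seed))
        else:
            cavities.append(None)
    return cavities


MAX_OUTER_CAVITY_CYCLES = 12


def _refine_regions(model: StructureModel, regions, refl: ReflectionSet,
                    config: RefinementConfig, mm_params: RestraintParams,
                    region_params) -> tuple[StructureModel, RefinementTrace]:
    """Outer loop: freeze the COSMO cavity per quasi-Newton run, rebuild it
    between runs (keeps energy and gradient exactly consistent within a run;
    the rebuilt-cavity energy is only piecewise smooth)."""
    work = model
    full = RefinementTrace(seed=config.seed)
    solvated = config.epsilon > 1.0 and any(
        len(r.indices) and np.any(work.charge[r.indices] != 0.0) for r in regions)
    prev_e = None
    offset = 0
    for outer in range(MAX_OUTER_CAVITY_CYCLES if solvated else 1):
        cavities = build_cavities(work, regions, region_params, config)

        def energy_fn(m):
            return total_energy(m, regions, refl, config, mm_params,
                                region_params=region_params, cavity=cavities)

        trace = _minimize_model(work, energy_fn, config, refl,
                                step_bound=0.25 if solvated else None)
        for row in trace.rows:
            row["cycle"] += offset
        offset = trace.rows[-1]["cycle"] + 1
        full.rows.extend(trace.rows)
        full.converged = trace.converged
        e_now = trace.rows[-1]["e_total"]
        if not solvated:
            break
        if prev_e is not None and abs(e_now - prev_e) < config.conv_energy:
            break
        prev_e = e_now
    return work, full


def refine_coordinates(model: StructureModel, region: RegionSelection,
                       refl: ReflectionSet, config: RefinementConfig,
                       mm_params: RestraintParams
                       ) -> tuple[StructureModel, RefinementTrace]:
    """Quasi-Newton minimization of the combined energy over mobile atoms."""
    work = model.copy()
    config = resolve_auto_wa(work, region, refl, config, mm_params)
    region_params = [build_region_params(work, region, mm_params)]
    return _refine_regions(work, [region], refl, config, mm_params, region_params)


def refine_2qm(model: StructureModel, region_a: RegionSelection,
               region_b: RegionSelection, occupancies: tuple[float, float],
               refl: ReflectionSet, config: RefinementConfig,
               mm_params: RestraintParams
               ) -> tuple[StructureModel, RefinementTrace]:
    """Dual-conformation refinement with fixed occupancies (p, 1−p).

    Both conformer region energies enter unweighted; the occupancies act
    only through the calculated structure factors (conformer-exclusive
    atoms get occupancy p resp. 1−p; shared atoms keep theirs).
    """
    p = occupancies[0]
    if not 0.0 <= p <= 1.0:
        raise ModelError("occupancy p must lie in [0, 1]")
    work = model.copy()
    in_a = set(region_a.indices.tolist())
    in_b = set(region_b.indices.tolist())
    for i in sorted(in_a - in_b):
        work.occupancy[i] = p
    for i in sorted(in_b - in_a):
        work.occupancy[i] = 1.0 - p
    work.sync_atoms()
    regions = [region_a, region_b]
    config = dataclasses.replace(config, occupancies=(p, 1.0 - p))
    config = resolve_auto_wa(work, regions, refl, config, mm_params)
    region_params = [build_region_params(work, r, mm_params) if len(r.indices) else None
                     for r in regions]
    return _refine_regions(work, regions, refl, config, mm_params, region_params)


# --------------------------------------------------------------------------
# Isotropic ADP refinement (post-refinement stage)
# --------------------------------------------------------------------------

def refine_adps(model: StructureModel, refl: ReflectionSet,
                config: RefinementConfig, mm_params: RestraintParams | None = None
                ) -> StructureModel:
    """Refine B_iso of mobile atoms at fixed coordinates.

    Minimizes the X-ray target plus a bonded-pair similarity restraint
    w·Σ(B_i−B_j)²; B is bounded below at ``adp_b_min`` (default 1 Å²).
    """
    work = model.copy()
    mobile = work.mobile
    if not mobile.any():
        import warnings
        warnings.warn("all atoms frozen; ADP refinement is a no-op")
        return work
    pairs = []
    if mm_params is not None:
        pairs = [(b.i, b.j) for b in mm_params.bonds]
    w_sim = config.adp_similarity_weight

    def fun(bvals):
        work.b_iso[mobile] = bvals
        tv = xray_target(work, refl, config.target, with_b_grad=True,
                         nshells=config.n_shells)
        e = tv.energy
        g = tv.b_grad.copy()
        for i, j in pairs:
            db = work.b_iso[i] - work.b_iso[j]
            e += w_sim * db * db
            g[i] += 2.0 * w_sim * db
            g[j] -= 2.0 * w_sim * db
        g[~mobile] = 0.0
        return e, g[mobile]

    b0 = work.b_iso[mobile].copy()
    res = scipy.optimize.minimize(
        fun, b0, jac=True, method="L-BFGS-B",
        bounds=[(config.adp_b_min, 999.0)] * int(mobile.sum()),
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10})
    work.b_iso[mobile] = res.x
    work.sync_atoms()
    return work
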