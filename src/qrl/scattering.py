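"""Structure factors and crystallographic targets.

Independent-atom-model structure factors by direct summation (toy scale:
< 500 atoms, < 20 000 reflections), with isotropic Debye–Waller factors
exp(−B·s²), s = sinθ/λ = 1/(2d).  On top of them: linear amplitude scaling,
R factors, a σ-weighted least-squares amplitude target and a Rice-likelihood
(maximum-likelihood on amplitudes) target, both with analytic coordinate and
B gradients, and the gradient-norm-matching w_A heuristic.

Free-set reflections never contribute to energies, gradients, scales or
shell-parameter estimates.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import gemmi
import numpy as np
from scipy.special import i0e, i1e

from .crystal_model import ReflectionSet, StructureModel, UnitCell


class ScatteringError(ValueError):
    pass


# --------------------------------------------------------------------------
# Form factors (published 4-Gaussian IAM coefficients, via gemmi)
# --------------------------------------------------------------------------

class FormFactorTable:
    """Per-element 4-Gaussian scattering factors f(s) = Σ aᵢ·exp(−bᵢ·s²) + c.

    The default table wraps the standard International-Tables coefficients
    shipped with gemmi; a plain-text table (`element a1 a2 a3 a4 b1 b2 b3 b4 c`)
    can be loaded with :meth:`from_text`.
    """

    def __init__(self, coeffs: dict[str, tuple[np.ndarray, np.ndarray, float]]):
        self._coeffs = coeffs

    @classmethod
    def default(cls) -> "FormFactorTable":
        return cls({})  # lazily filled from gemmi

    @classmethod
    def from_text(cls, path) -> "FormFactorTable":
        coeffs = {}
        for line in Path(path).read_text().splitlines():
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            vals = [float(x) for x in tok[1:10]]
            coeffs[tok[0]] = (np.array(vals[0:4]), np.array(vals[4:8]), vals[8])
        return cls(coeffs)

    def coefficients(self, element: str) -> tuple[np.ndarray, np.ndarray, float]:
        if element not in self._coeffs:
            el = gemmi.Element(element)
            # gemmi maps unknown symbols to the dummy element 'X'
            if el.it92 is None or el.name != element or el.atomic_number == 0:
                raise ScatteringError(f"no form factors for element {element!r}")
            it92 = el.it92
            self._coeffs[element] = (np.array(it92.a), np.array(it92.b), it92.c)
        return self._coeffs[element]

    def factor(self, element: str, s2: np.ndarray) -> np.ndarray:
        """f(s) for an array of s² = (sinθ/λ)² values (Å⁻²)."""
        a, b, c = self.coefficients(element)
        return np.exp(-np.outer(s2, b)) @ a + c


# --------------------------------------------------------------------------
# Direct-summation structure factors with a gradient pullback
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TargetValue:
    """Scalar target with its gradient over atoms (frozen rows exactly 0)."""

    energy: float
    grad: np.ndarray
    b_grad: np.ndarray | None = None
    info: dict = dataclasses.field(default_factory=dict)


class SFCalculation:
    """F(h) for one model/reflection pairing, with derivative pullbacks.

    F(h) = Σ_ops Σ_atoms occ·f(s)·exp(−B·s²)·exp(2πi·h·(R·x_frac + t)).
    Keeps per-op phase matrices so target gradients reuse them.
    """

    def __init__(self, model: StructureModel, hkl: np.ndarray,
                 table: FormFactorTable | None = None):
        self.model = model
        self.hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        table = table or FormFactorTable.default()
        cell = model.cell
        d = cell.d_spacing(self.hkl)
        self.s2 = (0.5 / d) ** 2
        n_at, n_h = len(model), len(self.hkl)
        # occ · f(s) · DW  per atom per reflection
        f_el = {el: table.factor(el, self.s2) for el in set(model.elements)}
        dw = np.exp(-np.outer(model.b_iso, self.s2))
        fmat = np.stack([f_el[el] for el in model.elements])
        self.w = model.occupancy[:, None] * fmat * dw  # (n_at, n_h)
        finv = cell.frac_matrix
        self.f_total = np.zeros(n_h, dtype=complex)
        self._phase_mats = []  # (exp(iφ) matrix, g-vectors (n_h,3)) per op
        hklf = self.hkl.astype(float)
        for rot, tr in zip(model.ops.rotations, model.ops.translations):
            g = 2.0 * np.pi * ((hklf @ rot) @ finv)          # (n_h, 3): ∂φ/∂x_cart
            phase0 = 2.0 * np.pi * (hklf @ tr)               # scalar per refl
            phi = model.xyz @ g.T + phase0[None, :]          # (n_at, n_h)
            e = np.exp(1j * phi)
            self._phase_mats.append((e, g))
            self.f_total += (self.w * e).sum(axis=0)
        self.amplitudes = np.abs(self.f_total)

    def pull_back(self, u: np.ndarray, with_b: bool = False
                  ) -> tuple[np.ndarray, np.ndarray | None]:
        """Chain rule: given u = ∂E/∂|F| per reflection, return ∂E/∂x (N,3).

        d|F|/dp = Re(conj(F)/|F| · dF/dp); zero-amplitude reflections get a
        zero direction (subgradient choice, irrelevant in practice).
        """
        amp = np.where(self.amplitudes > 1e-300, self.amplitudes, 1.0)
        c = u * np.conj(self.f_total) / amp  # complex weights per refl
        grad = np.zeros((len(self.model), 3))
        b_grad = np.zeros(len(self.model)) if with_b else None
        for e, g in self._phase_mats:
            ce = e * c[None, :]
            # Re(i·z) = −Im(z)
            grad += (self.w * (-ce.imag)) @ g
            if with_b:
                b_grad += (self.w * ce.real * (-self.s2)[None, :]).sum(axis=1)
        return grad, b_grad


def calc_structure_factors(model: StructureModel, hkl: np.ndarray,
                           table: FormFactorTable | None = None) -> np.ndarray:
    """Complex structure factors for the given Miller indices."""
    return SFCalculation(model, hkl, table).f_total


def generate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """Unique hemisphere of Miller indices to resolution d_min (P1)."""
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(0, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    # hemisphere: l > 0, or l = 0 and k > 0, or l = k = 0 and h > 0
    keep = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0)) | \
           ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0))
    hkl = hkl[keep]
    d = cell.d_spacing(hkl)
    return hkl[d >= d_min]


# --------------------------------------------------------------------------
# Scaling and R factors
# --------------------------------------------------------------------------

def scale_k(fobs: np.ndarray, fcalc_amp: np.ndarray) -> float:
    """Least-squares scale k minimizing Σ(|Fo| − k|Fc|)²."""
    fobs = np.asarray(fobs, float)
    fcalc_amp = np.asarray(fcalc_amp, float)
    if len(fobs) == 0:
        raise ScatteringError("cannot scale on an empty working set")
    denom = float(fcalc_amp @ fcalc_amp)
    if denom == 0:
        raise ScatteringError("all calculated amplitudes are zero")
    return float(fobs @ fcalc_amp) / denom


def r_factors(refl: ReflectionSet, fcalc_amp: np.ndarray) -> tuple[float, float]:
    """(R_work, R_free); scale from the working set applied to both.

    R_free is NaN when the free set is empty.
    """
    w = refl.work
    k = scale_k(refl.fobs[w], fcalc_amp[w])
    r_work = float(np.abs(refl.fobs[w] - k * fcalc_amp[w]).sum() / refl.fobs[w].sum())
    if refl.free.any():
        f = refl.free
        r_free = float(np.abs(refl.fobs[f] - k * fcalc_amp[f]).sum() / refl.fobs[f].sum())
    else:
        r_free = float("nan")
    return r_work, r_free


# --------------------------------------------------------------------------
# Least-squares amplitude target
# --------------------------------------------------------------------------

def target_lsq(model: StructureModel, refl: ReflectionSet,
               table: FormFactorTable | None = None,
               with_b_grad: bool = False) -> TargetValue:
    """E = Σ_work (|Fo| − k|Fc|)²/σ² with the full analytic chain rule.

    The scale k is itself a function of the coordinates; its derivative is
    included so the gradient vanishes exactly at a perfect model.
    """
    sf = SFCalculation(model, refl.hkl, table)
    amp = sf.amplitudes
    wmask = refl.work
    k = scale_k(refl.fobs[wmask], amp[wmask])
    wts = 1.0 / refl.sigma[wmask] ** 2
    resid = refl.fobs[wmask] - k * amp[wmask]
    energy = float(wts @ resid**2)
    # ∂E/∂A_j = −2 w_j k r_j + (∂k/∂A_j)·Σᵢ(−2 wᵢ rᵢ Aᵢ)
    denom = float(amp[wmask] @ amp[wmask])
    dk_dA = (refl.fobs[wmask] - 2.0 * k * amp[wmask]) / denom
    s_common = float(-2.0 * (wts * resid) @ amp[wmask])
    u = np.zeros(len(refl))
    u[wmask] = -2.0 * wts * resid * k + dk_dA * s_common
    grad, b_grad = sf.pull_back(u, with_b=with_b_grad)
    grad[~model.mobile] = 0.0
    if b_grad is not None:
        b_grad[~model.mobile] = 0.0
    return TargetValue(energy, grad, b_grad,
                       info={"k": k, "fcalc_amp": amp, "target": "lsq"})


# --------------------------------------------------------------------------
# Maximum-likelihood amplitude target (acentric Rice)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ShellParams:
    """Per-resolution-shell σ_A (amplitude correlation) and variance Σ.

    Estimated from the working set by moment matching: D = regression of
    |Fo| on k|Fc| within the shell, Σ = residual second moment (floored).
    Fixed during gradient evaluation; re-estimated per refinement cycle.
    """

    s2_edges: np.ndarray       # shell boundaries in s² = (sinθ/λ)²
    sigma_a: np.ndarray        # per shell
    variance: np.ndarray       # per shell
    k: float                   # overall amplitude scale

    def shell_of(self, s2: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.s2_edges[1:-1], s2, side="right")
        return np.clip(idx, 0, len(self.sigma_a) - 1)


def estimate_shell_params(model_or_sf, refl: ReflectionSet, nshells: int = 8,
                          table: FormFactorTable | None = None) -> ShellParams:
    """Moment-matched σ_A and variance per resolution shell (working set)."""
    sf = (model_or_sf if isinstance(model_or_sf, SFCalculation)
          else SFCalculation(model_or_sf, refl.hkl, table))
    amp = sf.amplitudes
    wmask = refl.work
    k = scale_k(refl.fobs[wmask], amp[wmask])
    s2w = sf.s2[wmask]
    if not np.all(np.isfinite(s2w)):
        raise ScatteringError("unsortable resolutions (non-finite s²)")
    # equal-population shells on the working set
    qs = np.linspace(0, 1, nshells + 1)
    edges = np.quantile(s2w, qs)
    edges[0], edges[-1] = -np.inf, np.inf
    sigma_a = np.zeros(nshells)
    variance = np.zeros(nshells)
    fo = refl.fobs[wmask]
    fc = k * amp[wmask]
    counts = np.zeros(nshells, dtype=int)
    for i in range(nshells):
        sel = (s2w >= edges[i]) & (s2w < edges[i + 1]) if i < nshells - 1 else (s2w >= edges[i])
        counts[i] = sel.sum()
        if counts[i] == 0:
            sigma_a[i], variance[i] = 1.0, 1.0
            continue
        denom = float(fc[sel] @ fc[sel])
        d = float(fo[sel] @ fc[sel]) / denom if denom > 0 else 1.0
        sigma_a[i] = d
        resid2 = float(np.mean(fo[sel] ** 2 - (d * fc[sel]) ** 2))
        floor = 1e-6 * float(np.mean(fo[sel] ** 2)) + 1e-12
        variance[i] = max(resid2, floor)
    return ShellParams(edges, sigma_a, variance, k)


def target_mlf(model: StructureModel, refl: ReflectionSet, nshells: int = 8,
               table: FormFactorTable | None = None,
               shell_params: ShellParams | None = None,
               with_b_grad: bool = False) -> TargetValue:
    """Rice negative log-likelihood for acentric amplitudes.

    −log p(|Fo|; μ, Σ) with μ = σ_A·k·|Fc| per shell; shell parameters are
    held fixed for the gradient (pass ``shell_params`` to pin them, e.g. for
    finite-difference checks).  Falls back to the least-squares target with a
    warning when the shells cannot be populated (≥3 shells × 20 reflections).
    """
    n_work = int(refl.work.sum())
    if shell_params is None and (nshells < 3 or n_work < 20 * nshells):
        usable = max(n_work // 20, 1)
        if usable >= 3:
            nshells = usable
        else:
            warnings.warn("insufficient working reflections for mlf shells; "
                          "falling back to least-squares target")
            return target_lsq(model, refl, table, with_b_grad)
    sf = SFCalculation(model, refl.hkl, table)
    if shell_params is None:
        shell_params = estimate_shell_params(sf, refl, nshells, table)
    sp = shell_params
    amp = sf.amplitudes
    wmask = refl.work
    shell = sp.shell_of(sf.s2[wmask])
    d = sp.sigma_a[shell]
    var = sp.variance[shell]
    fo = refl.fobs[wmask]
    mu = d * sp.k * amp[wmask]
    z = 2.0 * fo * mu / var
    # log I0(z) = log(i0e(z)) + z  (numerically stable)
    log_i0 = np.log(i0e(z)) + z
    nll = -(np.log(2.0 * fo / var) - (fo**2 + mu**2) / var + log_i0)
    energy = float(nll.sum())
    ratio = i1e(z) / i0e(z)
    dnll_dmu = 2.0 * mu / var - (2.0 * fo / var) * ratio
    u = np.zeros(len(refl))
    u[wmask] = dnll_dmu * d * sp.k
    grad, b_grad = sf.pull_back(u, with_b=with_b_grad)
    grad[~model.mobile] = 0.0
    if b_grad is not None:
        b_grad[~model.mobile] = 0.0
    return TargetValue(energy, grad, b_grad,
                       info={"k": sp.k, "fcalc_amp": amp, "target": "mlf",
                             "shell_params": sp})


def xray_target(model: StructureModel, refl: ReflectionSet, kind: str = "lsq",
                table: FormFactorTable | None = None, **kw) -> TargetValue:
    if kind == "lsq":
        kw.pop("nshells", None)
        kw.pop("shell_params", None)
        return target_lsq(model, refl, table, **kw)
    if kind == "mlf":
        return target_mlf(model, refl, table=table, **kw)
    raise ScatteringError(f"unknown target kind {kind!r}")


# --------------------------------------------------------------------------
# Automatic X-ray weight
# --------------------------------------------------------------------------

def auto_wA(model: StructureModel, refl: ReflectionSet, restraint_grad: np.ndarray,
            target: str = "lsq", table: FormFactorTable | None = None) -> float:
    """Gradient-norm matching: w_A = rms(∇E_restraints)/rms(∇E_X-ray).

    Both norms are taken over mobile atoms.  A user-supplied w_A in the
    refinement config always overrides this heuristic.
    """
    tv = xray_target(model, refl, target, table)
    gx = tv.grad[model.mobile]
    gr = np.asarray(restraint_grad)[model.mobile]
    rms_x = float(np.sqrt(np.mean(gx**2)))
    rms_r = float(np.sqrt(np.mean(gr**2)))
    if rms_x < 1e-300:
        raise ScatteringError(
            "X-ray gradient norm is zero (model already perfect?); "
            "start from a perturbed model or supply w_A explicitly")
    return rms_r / rms_x
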