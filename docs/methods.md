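# Methods

`qrl` is a desk-scale implementation of quantum-style crystallographic
refinement: the empirical restraints of a selected region of the model
("system 1") are replaced by a region energy from a pluggable backend, the
region is refined jointly against an amplitude-based X-ray target, and the
result is judged by difference-density Z scores and strain energies, with
an optional continuum-solvation (COSMO) term whose dielectric constant can
be scanned. This note records the model, the numerical choices, and what
the synthetic test substrate does and does not establish.

## The refinement energy

Standard restrained refinement minimizes `w_A·E_X-ray + E_MM`, where
`E_X-ray` measures agreement of calculated amplitudes with the data and
`E_MM` is a molecular-mechanics restraint set. Replacing the restraints of
system 1 by a backend energy gives the combined target used here:

    E_total = E_QM1(ε)  +  w_MM · ( E_MM − E_MM1 + w_A · E_X-ray )

- `E_QM1(ε)` — region energy, including link-atom caps and, for ε > 1, the
  COSMO solvation term.
- `E_MM1` — the restraint terms internal to system 1, subtracted to avoid
  double counting; cross-boundary terms always stay in `E_MM`. Terms never
  reference link atoms.
- `w_MM` (default 1/3) converts restraint ("statistical") units to energy
  units; `w_A` balances data against restraints and defaults to
  gradient-norm matching, `w_A = rms(∇E_restraints)/rms(∇E_X-ray)` over
  mobile atoms, computed at the starting model. Any explicit `w_A`
  overrides the heuristic.

Atoms outside the mobile mask are frozen: their gradient entries are
exactly zero and their coordinates are bit-identical before and after
refinement. In dual-conformation (2QM) mode two region energies enter
unweighted; the fixed occupancies (p, 1−p) act only through the calculated
structure factors. Occupancies are never refined.

## X-ray targets

Structure factors use the independent-atom model with the published
4-Gaussian form factors (via gemmi), isotropic Debye–Waller factors
`exp(−B·s²)` with `s = 1/(2d)`, explicit symmetry-operator lists (P1 by
default) and direct summation — exact at toy scale (< 500 atoms, < 20 000
reflections); there is no FFT path, bulk solvent, anomalous signal or
centric-reflection special-casing.

Two targets are provided, both with analytic coordinate and B gradients:

- **lsq** (default): `Σ_work (|Fo| − k|Fc|)²/σ²` with the least-squares
  scale `k` differentiated through, so the gradient vanishes exactly at a
  perfect model.
- **mlf**: the Rice (acentric) negative log-likelihood with per-shell
  parameters estimated from the working set by moment matching — `σ_A` by
  regression of |Fo| on k|Fc| in each resolution shell, the shell variance
  from the residual second moment (floored at 10⁻⁶ of the shell's mean
  |Fo|²). Shell parameters and the scale are held fixed during gradient
  evaluation and re-estimated each refinement cycle, the standard
  crystallographic practice. With fewer than 3 shells of 20 working
  reflections the target falls back to lsq with a warning.

Free-set reflections never contribute to energies, gradients, scales or
shell estimates; they are included in map synthesis (standard practice,
recorded on the map object).

## COSMO solvation

The region's point charges sit in a cavity of atom-centred spheres
(shipped element radii ≈ 1.17 × van der Waals; metals fixed at 2.0 Å;
water probe 1.3 Å recorded for context). Each sphere carries a
deterministic Fibonacci lattice of `n_points` segments whose orientation
is seeded. Screening charges solve `A q = −f(ε) Φ` in atomic units with
`A_kl = 1/|r_k−r_l|`, the self-interaction closure
`A_kk = 1.07·√(4π/area_k)`, and `f(ε) = (ε−1)/(ε+x)`, x = 0.5;
`ΔG_solv = ½ ΦᵀQ ≤ 0` is reported in kJ/mol (1 hartree = 2625.4996 kJ/mol).

Two numerical choices matter and are deliberate:

1. **Smoothly switched segment exposure.** A segment's area is weighted by
   a smoothstep ramp of its distance outside each neighbouring sphere,
   half a lattice spacing wide, instead of a binary keep/drop. This keeps
   the energy continuous as atoms move (buried segments fade out rather
   than flip) and bounds cross-sphere segment distances from below at full
   weight, which keeps `A` positive definite; a 0.95·√(A_kk·A_ll) cap on
   off-diagonal entries is kept as a safety net. The single-sphere Born
   case is unaffected (ΔG within 0.07% of −f·q²/2R at 2000 segments), and
   the two-sphere exposed area matches the closed-form spherical-cap
   complement within 2%.
2. **Fixed-cavity gradients.** The analytic gradient `qᵀ·∂Φ/∂x` treats the
   cavity as frozen; the cavity-motion force is omitted (an optional
   finite-difference correction exists, off by default). Consequences:
   the net force on a solvated cluster does not sum exactly to zero, and
   optimizers can only converge to the ~1–10 kJ/mol/Å force floor this
   approximation leaves. There is no outlying-charge correction and no
   self-consistency with a polarizable solute — charges are fixed.

During coordinate refinement at ε > 1 the cavity is frozen within each
quasi-Newton run (making energy and gradient exactly consistent, and
letting the Cholesky factor of `A` be cached) and rebuilt between outer
cycles until the energy changes by less than the energy tolerance. Each
frozen-cavity run is step-bounded at 0.25 Å per coordinate because a
frozen conductor surface makes the point-charge energy unboundedly
negative for an atom that reaches it. The strain-energy free optimization
follows the rebuilt-cavity energy directly (smooth thanks to choice 1).

## Optimization

Coordinate, 2QM and ADP refinements use L-BFGS-B over the mobile degrees
of freedom. Convergence: maximum per-cycle coordinate shift below
`conv_shift` (default 10⁻³ Å) or the cycle limit (default 200); energies
must be non-increasing (five consecutive increases abort with a
diagnostic). The trace records per cycle: all energy components, R_work,
R_free, maximum gradient and maximum shift. The ADP stage refines
isotropic B of mobile atoms at fixed coordinates against the X-ray target
plus a bonded-pair similarity restraint `w·Σ(B_i−B_j)²` (default w = 0.05),
bounded below at 1 Å².

## Validation

**Difference maps.** Coefficients `(w_o|Fo| − w_c·k|Fc|)·exp(iφ_c)` on the
unique hemisphere plus Friedel mates, synthesized on a cell-spanning grid
(spacing ≤ d_min/2.5, default d_min/3) by coefficient placement and FFT —
identical to the direct Fourier sum to ~10⁻⁸. Simple weights by default;
σ_A-style `m|Fo| − D|Fc|` weights from the mlf shell estimates.

**RSZD.** For each residue group (chain, number, conformer tag), grid
points within 1.5 Å of its atoms (minimum image) are scored: with
S± the sums of positive/negative ρ/σ_map over the N masked points,

    RSZD± = max(0, (S± − N·c₁) / √(N·c₂·ov)),   RSZD = max(RSZD+, RSZD−)

where c₁ = 1/√(2π) and c₂ = ½ − 1/(2π) are the mean and variance of the
positive part of a standard normal, and `ov` is the map oversampling
factor relative to Nyquist (d_min/2) sampling. Subtracting the noise
expectation is what makes this a Z score: a pure-noise map scores ≈ 0.4 on
average, a null map exactly 0, and a deleted atom ≫ 3 — so the
conventional |RSZD| < 3 reading of a locally good model applies. This is
an EDSTATS-inspired estimator, not a bit-compatible reimplementation.

**Strain energy.** `E_QM1(refined geometry) − E_QM1(freely optimized
geometry)`, the free optimization starting from the refined region (link
atoms free, held by a harmonic cap bond, k = 2500 kJ/mol/Å², r0 = the
placed length) with the same backend and ε. Non-negative within the
energy tolerance for any converged refinement, because the free
optimization descends from the refined point.

**Dielectric scan.** One independent pipeline per ε (refine → ADP → map →
RSZD → strain), rows starting from the same input model; a failing ε marks
its row and the scan continues. The conventional grid is ε = 1…20 in steps
of 1 and 25…80 in steps of 5 (32 values).

## The synthetic test substrate

The generator builds P1 toy crystals: a bonded Fe(S–O)₄ cluster (9 atoms)
as the mobile region and ~20 frozen environment atoms, with bond/angle
restraints whose ideal values equal the generating geometry. The cluster's
terminal oxygens are 1-4/1-5 to each other and to distal sulfurs, so a net
region charge produces genuine Coulomb repulsion in the surrogate (1-2/1-3
pairs are excluded by force-field convention). Amplitudes are computed
from the true model to d_min (default 1.5 Å), optionally corrupted as
`|Fobs| = |Ftrue|·(1 + N(0, noise))` truncated at 0.1·|Ftrue|, with
σ = noise·|Ftrue| floored at 1%·|Ftrue| so σ > 0 holds on noise-free
fixtures; free flags are seeded Bernoulli draws (5%). Start models displace
the region by a rescaled Gaussian to an exact requested RMSD. Everything
is bit-reproducible per seed.

The **demo fixture** (seed 2026) carries net region charge −5 — the charge
scale of a small metallocluster region — with 3% amplitude noise and a
0.15 Å start perturbation. On it, vacuum refinement is visibly degraded by
the artificial Coulomb repulsion of the unscreened −5 charge (sum RSZD
≈ 17, strain ≈ 8 kJ/mol), while ε = 80 screens that repulsion (sum RSZD
≈ 6, strain ≈ 0) — the qualitative behaviour continuum solvation is meant
to deliver for highly charged regions. The **recovery fixture** is neutral
with the bonded-only surrogate, so the combined target's global minimum is
exactly the generating model and refinement accuracy can be measured
without surrogate bias.

What the toys do *not* emulate: realistic protein geometry and packing,
bulk-solvent scattering, experimental error correlations, space groups
beyond P1, anisotropic displacement, or an electronic-structure region
energy. Passing tests therefore demonstrate the correctness and internal
consistency of the refinement machinery and the direction of the
solvent-screening effect — not quantitative agreement with any particular
protein system.

## Known limitations

- The builtin region surrogate is classical; chemistry that needs electronic
  structure (bond making/breaking, spin states, charge transfer) is out of
  scope by design — plug in an external backend via the file-exchange
  contract for that.
- Fixed-cavity COSMO gradients limit achievable optimization tightness in
  solvent (see above); strain energies in solvent inherit a ~0.1 kJ/mol
  discretization floor at the default 302 points per sphere.
- The mlf target is a moment-matched Rice likelihood, adequate for ranking
  and refinement on toys but not a reimplementation of any production
  likelihood code; all reflections are treated as acentric.
- RSZD values are calibrated to the 0–1 (noise) / >3 (defect) scale but are
  not numerically comparable to EDSTATS output.
- ε-scan rows re-estimate σ_A at map time, after the ADP stage; small
  (≈0.1–0.3) fluctuations in per-residue scores between neighbouring ε
  values stem mostly from the B-factor re-refinement.
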