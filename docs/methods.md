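# Methods

`sarcomech` studies how the two sarcomere-length parameters of a
time-varying-elastance (TVE) myocardial contraction model — the unloaded
reference length `L_r` and the zero-tension threshold length `L_0` — shape
active stress at the tissue scale and pump function at the organ scale.
This note records the models, their assumptions, the numerical choices, and
the limits of what the tests demonstrate.

## Passive myocardium

The passive wall is the orthotropic Holzapfel–Ogden hyperelastic law with an
isotropic exponential matrix term, exponential fiber and sheet reinforcement
terms in the squared pseudo-invariant excess `(I4 − 1)²`, a fiber–sheet
coupling term in `I8fs²`, and a volumetric penalty
`(1/D)((J² − 1)/2 − ln J)`.  Conventions:

* **Tension-only reinforcement.** The fiber/sheet terms contribute only for
  `I4 > 1`; collagen-like reinforcement cannot support compression.  The
  isotropic matrix term is *not* clipped — it legitimately resists
  compression.
* **Incompressibility.** The analytical biaxial path takes `J = 1` and
  `λn = 1/(λf λs)`; the volumetric term is implemented but only participates
  if a compressible state is constructed explicitly.
* **Coupling term.** `a_fs` defaults to 0: all axis-aligned states have
  `I8fs = 0` and no verification value is published for it; the term is
  implemented and exercised by the energy tests.
* **Units.** Stresses and energy densities are MPa throughout.

For homogeneous axis-aligned biaxial stretch with traction-free sheet-normal
faces the Cauchy stresses have closed forms (the reaction pressure
eliminated by the zero-normal-stress condition).  These are verified against
an independent oracle: central finite differences of the
constraint-substituted strain energy with respect to log-stretch,
`σii = ∂Ŵ/∂ln λi`.  With step `h = 1e−6` the agreement is limited by
floating-point cancellation at roughly 1e−6 relative — comfortably inside
the 1e−5 verification tolerance used for the report (absolute floor
1e−9 MPa for near-zero entries).  Default parameters are the published
verification set `a = 0.004, b = 8, a_f = 0.005, b_f = 5, a_s = 0.002,
b_s = 2` (MPa / dimensionless).

## Active contraction

Active fiber stress is the product of a length-dependent calcium-sensitivity
factor and a cosine activation envelope,

    σ_af(t, E_ff) = (T_max/2) · Ca0²/(Ca0² + ECa50(E_ff)²) · (1 − cos ω),
    ECa50 = Ca0_max / sqrt(exp(B (L − L_0)) − 1),
    L = L_r sqrt(2 E_ff + 1),   t_r(L) = m L + b_relax,

with ω ramping 0→π over `t0` and π→2π over `t_r`.  Defaults:
`T_max = 0.1 MPa`, `Ca0 = Ca0_max = 4.35`, `B = 4750 mm⁻¹`, `t0 = 0.1 s`,
`m = 1048.9 s/mm`, `b_relax = −1.429 s`, `L_r = 1.85 µm`, `L_0 = 1.58 µm`.

**Unit convention.** The constants `B` and `m` are per millimetre of
sarcomere length; the API accepts lengths in micrometres and converts
internally.  This is the only convention under which the constants are
mutually consistent: it gives `B·(L_r − L_0) = 1.2825` (a finite length
sensitivity) and `t_r(1.85 µm) = 0.511 s`, matching a sub-second beat.

Two structural consequences drive everything downstream:

* the isometric peak stress `T_max·Ca0²/(Ca0² + ECa50(0)²)` depends on the
  *difference* `SLD = L_r − L_0` only; and
* the duration of contraction `DOC = t0 + t_r(L_r)` depends on `L_r` only,
  affinely with slope `m` (unit-converted, 1.0489 ms per nm of `L_r`).

Behavior at and below the threshold (`L ≤ L_0`) is defined as zero stress
rather than an error so organ-level sweeps remain well-posed; `eca50`
itself raises a typed exception so misuse is still visible.  The reading of
the envelope argument follows the definition of `ECa50` as a function of
`E_ff` (a multiplicative reading would produce zero stress at `E_ff = 0`,
contradicting the isometric benchmark).  During a beat, `ECa50` is evaluated
with the time-varying `E_ff(t)`.

## Verification benchmarks

Both benchmarks use homogeneous single-point states, where the constitutive
response *is* the element response, so no finite-element solve is involved:

1. **Passive biaxial:** closed-form `σff`, `σss` vs the finite-difference
   oracle at equibiaxial and fiber-only stretches 1.10 / 1.20 / 1.30.
2. **Isometric twitch:** `E_ff` held at zero on a 0.7 s window, `dt = 1e−4 s`;
   the sampled peak must sit at `t0` and the return to zero at
   `t0 + t_r(L_r)`, each within one grid step, and the sampled peak converges
   to the closed form at O(dt²).

Reports are deterministic (byte-identical CSV for identical inputs).

## Scenario design

Thirteen scenarios around the control pair (1.85, 1.58) µm: the S0 series
varies `L_r` ∈ {1.75…1.95}, the S1 series varies `L_0` ∈ {1.48…1.68}, and
the S2 series moves both along the diagonal at fixed SLD = 0.27 µm.  The
control S00 belongs to all three series and is emitted once.  The tissue
sweep evaluates the two closed-form summaries per scenario; its invariants
(equal peaks across S2, peak monotone in SLD, DOC flat across S1 and affine
across S0) are exactly the structural consequences listed above.

## 0D closed-loop surrogate

The organ level is an invented four-compartment closed loop: a TVE-driven
thick-walled-sphere LV, a passive linear-elastance LA, and linear arterial
and venous reservoirs, joined by ideal-diode valves (mitral, aortic) and
linear resistances (peripheral, venous return).  Cavity pressure follows
from midwall fiber stress via `P = 2 σ ln(r_out/r_in)` with the midwall
stretch referenced to the unloaded cavity volume; the passive wall
contribution is the equibiaxial fiber stress clipped at zero in compression
(see below).  Integration is fixed-step explicit Euler at `dt = 1e−4 s`;
each flow leaves one compartment and enters another, so total blood volume
is conserved to round-off by construction.  Each 1 s cycle restarts the
twitch at beat onset; EDV is the volume at beat onset and ESV the cycle
minimum.  Runs start from a common filled state; the control is periodic to
<1 % in EDV by cycle five.

**Design choices.**

* *Envelope timing at the reference length.* The relaxation duration inside
  the activation phase is evaluated at `L_r` (the isometric DOC of the
  scenario) while the sensitivity amplitude follows the instantaneous
  length.  Evaluating `t_r` at the instantaneous length would terminate the
  envelope almost simultaneously across scenarios at end-systolic lengths,
  erasing every organ-level distinction that the tissue-level DOC law
  expresses; the reference-timed envelope preserves it.
* *Compression clipping.* The compressive (recoil) branch of the isotropic
  wall term is excluded by default (`wall_recoil = False`).  With recoil
  enabled, elastic energy stored by deeper systolic compression is returned
  as diastolic suction, which in a 0D chamber systematically *rewards*
  stronger contraction during refill and suppresses the diastolic
  distinctions the study targets.  The switch is exposed for
  experimentation.
* *Calibration.* Geometry, compliances, resistances and total volume were
  tuned once and frozen in the packaged defaults so that the control lands
  inside the published normal ranges (EDV 102–202 mL, ESV 24–92 mL,
  SV 57–150 mL, LVEF 50–65 %, CO 4–8 L/min) at heart rate 60; no per-scenario
  retuning.  Published absolute volumes are *not* fitting targets.

**What the surrogate reproduces, and what it cannot.**  With the frozen
calibration the surrogate reproduces, directionally: the full S0-series
sign pattern (EDV and ESV decrease, SV/LVEF/CO increase with `L_r`), driven
by SLD-dependent ejection strength plus the DOC-dependent encroachment of
relaxation on filling; and reduced filling (EDV below baseline) for the
low-threshold scenarios S11/S12, driven by the larger short-length tension
tail that delays mitral opening.  It does **not** reproduce two organ-level
phenotypes of the reference study:

* *S11 stroke volume below baseline.*  In this law, scenarios with equal
  SLD have identical tension–stretch curves; S11 (1.85/1.48) and S04
  (1.95/1.58) differ only through `t_r` and the `L = L_r λ` scaling.  Any
  homogeneous chamber therefore gives S11 an ejection (ESV) advantage of
  order 10 mL that its filling penalty (order 5 mL) cannot overcome while
  the S0 pattern and a normal baseline are maintained — the surrogate's
  SV(S11) sits *above* baseline.  The corresponding acceptance check is
  left failing rather than forced.
* *The S2-series pathology ordering.*  `t_r` increases with absolute
  length, so the short-length member S21 relaxes *earlier* and fills
  *better* in a 0D chamber — the reference study's opposite, emergent
  ordering (S21 worst, S24 near-normal) evidently requires mechanisms
  outside this surrogate (regional strain heterogeneity, the preload
  pre-stress procedure, electrophysiological activation patterns).

These limits are inherent to the homogeneous reduction, not to the
calibration; they are documented here and in the project's test suite
rather than patched with ad-hoc mechanisms.

## Metric analytics

* **Derived metrics.** `SV = EDV − ESV`, `LVEF = 100·SV/EDV`,
  `CO = SV·HR/1000` with HR = 60 (one 1 s cycle per second).
* **Display conventions.** Derived values are displayed at three decimals;
  percent changes at two decimals, rounding half away from zero, and are
  computed from the values *as displayed* — the convention under which the
  reference table's CO percent column is self-consistent with its SV
  column.  Full precision is kept internally.
* **Sensitivities.** Ordinary least squares per series (five scenarios) or
  segment (three scenarios), regressing on `L_r` (S0 and the diagonal S2
  path) or `L_0` (S1).  Normalised sensitivity `S* = (p_base/Y_base)·dY/dp`
  with baselines from the control row.  R² of a zero-variance response is
  defined as 0, never NaN.
* **Deviation scores.** Band score `max(0, |x − μ|/σ − 1)` for mean ± SD
  references (zero inside one SD) and range score
  `max(0,(L−x)/(U−L)) + max(0,(x−U)/(U−L))` for interval references; both
  are invariant under affine re-unit-ing of a metric together with its
  bounds.  Totals are summed over EDV, ESV, SV, LVEF, CO and ranked
  descending with lexicographic tie-break on the scenario id.
* **Strain conversions.** Nominal strain `e = λ − 1` and the Green–Lagrange
  conversion `e = sqrt(2E + 1) − 1`; their composition with
  `E = (λ² − 1)/2` is an exact round-trip.

The published 13-scenario metric table and its normal ranges ship as
packaged CSV data and are the canonical input to the sensitivity and
deviation stages.

## Synthetic data and recovery

The generators emulate the statistical structure the analytics assume, not
the physics that produced the reference numbers:

* **Metric tables** are linear in the varied length parameter around the
  control with i.i.d. Gaussian noise on EDV and ESV; derived columns are
  computed exactly.  Real tables have correlated, heteroscedastic,
  nonlinearly saturating responses — the piecewise analysis exists
  precisely because the linearity is only local — so slope-recovery tests
  certify the estimator, not the linearity of any real heart.
* **Twitch peaks** are the closed-form peak plus Gaussian noise truncated
  at zero.  The SLD inversion is exact for noiseless input; with noise it
  averages per-measurement inversions, a consistent (slightly biased at
  finite n, vanishing as noise → 0) estimator.
* **APS records** place each region/direction at its reference mean plus a
  scenario shift in SD units plus noise; a packaged *synthetic* reference
  set with plausible magnitudes (radial thickening ≈ +0.35, circumferential
  ≈ −0.19, longitudinal ≈ −0.15, the latter two negative) supports the
  scoring pipeline because the study's literature reference values are not
  published numerically.  Nothing spatial (stress/stretch fields) is
  emulated.

All generators take explicit integer seeds (`numpy.random.default_rng`);
fixed seed implies byte-identical output.

## Problem sizes and runtimes

The default test suite runs in well under a minute: property tests are
capped at 40–100 examples, the surrogate module tests use `dt = 2e−4 s`
with 2–5 cycles, and the acceptance-level surrogate run is 13 scenarios ×
5 cycles at `dt = 1e−4 s` (≈3 s).  The Monte-Carlo recovery study uses 200
replicates at 1 mL noise and n = 100 twitch measurements at 1 % noise —
sizes at which the 2-standard-error and 0.005 µm bounds are comfortably
discriminating.

## Known limitations

* The organ model is a homogeneous sphere: no regional strain, no fiber
  architecture, no atrial contraction, no valve inertance or regurgitation,
  no pericardium.  Its outputs are directional phenotypes, never
  quantitative hemodynamics (see the two documented sign failures above).
* The active law has no descending limb of the length–tension relation, no
  velocity dependence, and no calcium transient dynamics.
* The passive analytics cover axis-aligned biaxial states only; shear modes
  are out of scope.
* The venous pressure of the frozen calibration is elevated relative to
  physiology — a consequence of driving rate-limited filling through a
  single linear mitral resistance — and should be read as an abstraction,
  not a prediction.
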