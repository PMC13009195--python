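# Methods and modeling decisions

This document records how the models and analyses are implemented, the
conventions chosen where a published description leaves freedom, and the
reasoning behind the package's fixed parameter values.

## Arm plant

The hand is modeled per spatial dimension as five states `[p, ṗ, f, g, ξ]`
at `δ = 0.01 s` (100 Hz): position (mm), speed, the force output of a
low-pass muscle filter (`τ₂ = 40 ms`), the control filter feeding it
(`τ₁ = 40 ms`), and a constant bias state `ξ`.  The control signal enters
`g`; `f/m` accelerates the hand (`m = 1`).  Motor noise is
*signal-dependent*: each control channel is perturbed multiplicatively with
scale `σ_c = 0.3` (`C = σ_c B`), so larger commands are noisier — the
scaling that makes speed–accuracy trade-offs emerge from optimal control.
Additive dynamics noise of variance 8000 enters the control-filter state;
position, speed and force are observed with noise scaled by `σ_s = 0.5`.

`ξ` is held at 1 per dimension and used as a *unit bias*: the distance of
the hand to any target center `c` is expressed in a quadratic state cost by
the vector `+1` on `p` and `−c` on `ξ`.  One plant therefore serves every
via-point without re-encoding targets into the state.

## vpSOC: flat via-point control

The whole sequence is one finite-horizon problem.  Target `i` contributes a
state cost at its via time `t_i = 0.7 s · (i+1)`:
`h_i² ‖p − c_i‖² + ω_v²‖ṗ‖² + ω_f²‖f‖²` with `ω_v = 0.4`, `ω_f = 0.6`;
control costs `r‖u‖²` accrue every step.  Because of the signal-dependent
noise, optimal feedback gains `L_t` and Kalman gains `K_t` are coupled; they
are found by alternating a backward control recursion (given the filter)
with a forward filter recursion (given the controller) until the gains stop
changing.  With all noise off this collapses exactly to the classical
finite-horizon LQR/Kalman solution, which is the package's oracle test.

## HiSeq: hierarchical sequencing

Two vpSOC building blocks — a two-target block (targets 1–2) and a return
block (target 3, indexed on the global trial clock) — run their own
estimators for the whole trial.  Motor commands mix as
`u = Σᵢ (zᵢ/αᵢ) u⁽ᵐᵃᵖ⁽ⁱ⁾⁾` where `z` follows generalized Lotka–Volterra
dynamics `ż = τ z (α − ρ z) + η` forming a stable heteroclinic channel:
each one-hot equilibrium except the last is a saddle whose single unstable
direction points at the next attractor.  The package uses **one attractor
per sub-controller** (two for the canonical three-target task); the
attractor's sub-goal is its own block's final target, so the monitor fires
when the hand completes the two-target block and hands control to the
return block.

Connectivity is built from the recipe `ρ_next = 0.85`, `ρ_other = 1.5`,
`α = 1`, `τ = 33 /s`, validated by an eigenvalue check at every
equilibrium.  The timing algebra fixes these numbers: the escape rate of a
triggered transition is `τ(1 − ρ_next) ≈ 5 /s`, fast enough that a
monitor-triggered hand-off completes within ~0.2–0.3 s, while baseline
noise (`η_base = 10⁻⁴`, Euler contribution scaled by `dt`) amplifies slowly
enough that untriggered escapes take ~2.8 s — longer than the 2.1 s trial,
so spontaneous transitions are rare.  Monitor pulses have amplitude 10 and
stop once the next activation exceeds 0.2 (`pulse_cutoff`): the pulse's job
is to seed the escape from the saddle, and continued kicks during the
hand-off itself would scramble the competition (empirically, sustained
pulsing produced stalled or disordered sequences; with the cutoff, 1000/1000
seeded trials complete in order).  Activations are floored at 10⁻⁶ to keep
the Lotka–Volterra state positive.

Trials whose sequencing never reaches the final attractor are flagged
`stuck` and excluded from feature analysis (and rejected by the synthetic
generator).

## Task geometry

Published sizes and distances constrain but do not pin the target
coordinates, so the package fixes one canonical symmetric layout in a
versioned geometry file (`reachseq/data/layout.json`): start at the origin
(radius 35), primary targets blue `(−65, 157)` and red `(65, 157)` (radius
55), secondary targets olive `(−215, 120)`, pink `(215, 120)` (radius 35)
and lilac `(0, 330)` (radius 45), all in mm.  The six sequences are the
`{blue, red} × {olive, pink, lilac}` products, each executed as
start → primary → secondary → home.  Sequences 0 and 4, 1 and 3, 2 and 5
are mirror images, and all crossing/curvature features are
reflection-invariant (verified by test), so single-sequence analyses are
representative.

## Kinematic features

- **Halfway cross (hc1)**: signed lateral offset where the path first
  crosses the perpendicular at the midpoint of the start→target-1 line;
  positive toward the next target's side.
- **Transitional cross (tc1)**: signed distance from the target center to
  the path's crossing of the interior angle bisector at target 1; positive
  when the path cuts the corner, negative when it overshoots the turn.
  Near-collinear geometry (< 5°) falls back to the travel normal.
- **Curvature**: `C = (x′y″ − y′x″)/v³` from central differences after
  Savitzky–Golay smoothing (window 7, order 3).  Samples slower than 10% of
  the trial's peak speed get `NaN`: when the hand pauses, path direction —
  and hence curvature — is undefined, and the ratio otherwise explodes.
  `maxcurv_n` is the maximum absolute curvature inside target `n`'s circle.
- **Segmentation / fusion**: trials split at the speed minimum inside each
  intermediate target; the fusion index is the minimum speed inside the
  target divided by the mean of the two adjacent segments' peak speeds
  (1 = fused pass-through, 0 = full stop).

## Speed window

Accepted trials must have their **peak** speed in 600–900 mm/s.  The task's
speed feedback is stated against a single bound in some places and a range
in others; the package resolves this as a window on the per-trial peak
speed, which is the statistic the task's online feedback most directly
constrains, and applies it by rejection-resampling in the synthetic
generator (more than 100 consecutive rejections raises a parameterization
error instead of looping forever).

## Statistics

Zero-mean tests of signed coarticulation are gated by Shapiro–Wilk
(p ≥ 0.05 → one-sample t, otherwise Wilcoxon signed-rank), evaluated at
α = 0.01 without multiple-testing correction.  Correlations are Pearson
with Fisher-z 95% CIs.  Group differences in fusion use a label-permutation
bootstrap (group sizes preserved, ties counted as exceedances).  Its null
p-values are approximately uniform; note that *certifying* uniformity by a
KS distance below 0.05 requires on the order of 1000 repeats — the KS
statistic of a genuinely uniform sample of size 200 exceeds 0.05 more often
than not — so the calibration test uses 1000 repeats at 10⁴ resamples.

## Model-coverage classification

Each model is simulated over a packaged grid of `(r, h1, h2)` (second and
third target weights tied).  Per cell, 99% t-based confidence half-widths
of four features (`hc1`, `tc1`, `maxcurv1`, `maxcurv2`) are computed after
dropping trials whose feature extraction fails; cells with fewer than three
valid trials are recorded as failures and excluded — lax-control cells that
never visit a target are expected, not fatal.  Coverage regions are built
on three criterion surfaces: the `hc1` interval, the `(hc1, maxcurv2)`
plane, and the `(maxcurv1, maxcurv2)` plane (concave hulls loosened until
they contain all generating cell means).  An observed cell is *covered* by
a model when its 99% CI rectangle intersects the region on all three
surfaces, and *incompatible* only when additionally its hc1 coarticulation
is significantly nonzero; the resulting labels are `both`, `vpsoc_only`,
`hiseq_only`, `neither`.

### Grid calibration

Grid node values are calibrated so the simulated feature tables reproduce
the models' characteristic structure on the canonical geometry (the precise
original grids are not published):

- vpSOC(3): `r ∈ logspace(−8, −4.5, 6)`, 17 `h1` values in `[1.15, 16]`,
  `h2 ∈ {1, 2, 4}`, 120 trials/cell.  This reproduces the weak positive
  `hc1`–`tc1` correlation (~0.23) and the strong positive `SD(hc1)`–`tc1`
  correlation (~0.51–0.54) across seeds; the 120 trials/cell de-attenuates
  the per-cell SD estimate the latter depends on.
- HiSeq: `r ∈ {10⁻⁸ … 10⁻³}` including `1.7×10⁻⁴`, 12 `h1` values in
  `[0.05, 48]`, 12 `h2` values in `[0.25, 8]`, 20 trials/cell.  The
  `1.7×10⁻⁴` node sits in the model's decoupled regime: mean `hc1` below
  −10 mm with second-target curvature above anything the flat planner
  produces at comparable `hc1`.

For the decoupling contrast the two models are additionally simulated over
an *identical* matched grid (`matched_grids()`): the HiSeq `h1` range,
`h2 ∈ {1, 2, 4}`, and `r ∈ {10⁻⁸, 10⁻⁷, 10⁻⁶, 10⁻⁵, 1.7×10⁻⁴}`, making the
within-grid feature correlations directly comparable.  "Comparable hc1" in
the ceiling comparison means vpSOC cells whose mean `hc1` is at most 2 mm
above the candidate HiSeq cell's.

## Limitations

- The plant is a point-hand model: no joint-space dynamics, posture, or 3D.
- Marker occlusion, timeouts, and online feedback logic of a live
  experiment are not emulated; the synthetic generator enforces only the
  speed window and sequencing completion.
- The two-attractor SHC covers the canonical three-target task; longer
  sequences would chain more blocks but are untested beyond the dynamics
  layer (which supports arbitrary chain lengths).
- Coverage regions are built from grid means; very small observed CIs
  between grid nodes could in principle fall between generating points of
  the concave hull, which is why the hull ratio is relaxed until all
  generating cells are contained.
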