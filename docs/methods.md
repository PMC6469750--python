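# Methods

## Statistical model

Every standard curve is a 5PL (or 4PL, `g = 1`) in the natural-log
concentration `x`:

    Y_ijk = a + (d − a) / (1 + e^((xmid + S_i − x_ij)/scal))^g + ε_ijk

with batch `i`, standard level `j`, replicate well `k`, and additive
measurement error `ε`. All batches share `(a, d, scal, g)`; batch `i` differs
from the reference only through the midpoint offset `S_i` — its shift factor.
The interpretation is that a batch's standards are *mislabelled* by a common
log-fold: a standard labelled `c` pg/mL behaves like `c·e^(−S_i)` on the true
response curve. Within-batch curve-to-curve differences are random error;
between-batch differences are the fixed shifts.

Because only `xmid + S_i` enters the likelihood, the pair `(xmid, S_i)` has a
gauge freedom; it is resolved by designating one batch the **reference** and
pinning `S_ref = 0` exactly. Consequences used as test invariants:

* **Scale equivariance.** Multiplying a batch's concentration labels by `N`
  moves its estimated `S` by exactly `ln N` (the estimator inherits this from
  the model; verified to 1e−6 noiseless for `N ∈ {0.5, 2, 10}`).
* **Adjustment identity.** Quantification reads an unknown's OD off the
  batch's shifted curve (`x̂`, the raw value) and then applies
  `x_adj = x̂ − S_i`; equivalently `conc_adj = conc_raw·e^(−S_i)`. In the
  noiseless limit this equals reading the OD directly off the reference
  curve, so a batch-invariant sample gets a batch-invariant adjusted value.

Sign convention: with `scal > 0` (increasing curve), a positive `S` means the
batch's effective midpoint sits at higher log-concentration, i.e. the
batch's standards contain *less* analyte than labelled, raw concentration
read-outs of real samples are inflated by `e^S`, and the adjustment deflates
them back. All shift factors in this package follow this convention
consistently end to end.

## Estimation

Two modes, both ordinary (unweighted) nonlinear least squares on individual
replicate wells — replicates are never averaged before fitting:

* **fixed_reference** (default, the operational workflow): the reference
  curve is fit once by pooling all standard wells of the designated reference
  plates into a single fit; each batch's `S` is then a one-dimensional least
  squares with every other parameter frozen. A coarse grid over
  `S ∈ [−6, 6]` (61 points) seeds the trust-region refinement so a far-shifted
  batch cannot strand the optimizer in a flat asymptote region. `±6` natural
  logs is a ±400-fold mislabelling — far beyond any plausible kit defect.
* **joint**: simultaneous least squares over `(a, d, xmid, scal[, g])` and
  all non-reference shifts, started from the fixed-reference solution. In the
  noiseless limit both modes coincide (tested to 1e−6).

Curve fits use `scipy.optimize.least_squares` (trust-region reflective),
cost tolerance 1e−10 (and tighter step/gradient tolerances), at most 500
iterations per parameter; the asymmetry factor is log-parameterized and
bounded in `[0.1, 10]` to exclude degenerate asymmetric fits on 8-point
curves. The self-start heuristic places the asymptotes 5% of the OD range
beyond the observed extremes, interpolates `xmid` at the half-height, and
takes `scal` from the central slope (`slope = (d−a)/(4·scal)` for the 4PL).
If a fit fails, up to 10 restarts perturb the heuristic start log-normally
(factor 1.2) under a fixed internal seed, so fitting is deterministic.

`se_S` is the linearized standard error from the curvature of the 1-D
profile at the optimum, `sqrt(rss/(n−1) / Σ(∂f/∂S)²)`. It **conditions on
the reference curve**: uncertainty in the reference parameters is not
propagated. With a reference fit from many curves (the intended design —
e.g. 28 reference plates against single-plate shifts) the empirical coverage
of `S ± 2·se` is ~95%; with a single-plate reference it drops to ~85%.
A batch whose ODs all lie outside the reference asymptote band has no
identifiable shift and raises an error rather than returning a clamped `S`.

Degenerate inputs: fits require ≥ 4 distinct standard levels (≥ 5 for the
5PL); all-equal ODs, non-finite readings (the offending well is named) and
zero/negative standard concentrations are rejected up front. Blank wells are
carried through I/O but never enter fits; blank subtraction is available as
a pre-step decision for the caller and is off by default.

## Quantification and flags

Replicate wells aggregate to a mean OD and percent CV (sample sd, `n−1`;
CV = 0 for a single well). Flags, never silent censoring except where the
value is mathematically undefined:

* `high_cv` — replicate CV above the 15% acceptance gate; the value is still
  reported (disposition is a laboratory decision).
* `below_range` / `above_range` — OD at or beyond an asymptote; no inverse
  exists, concentrations are absent.
* `below_lloq` / `above_uloq` — adjusted concentration outside the plate's
  standard range (lowest/highest standard level); value retained.

Concentrations are reported in pg/mL (`e^x`); log values are carried
internally.

## Quality control

* Inter-assay control charting: per-control mean ± sd of OD and of raw vs
  adjusted concentration across plates, CV rounded half-up to integer
  percent (the bench-reporting convention; 100·0.095/0.759 → 13%).
* Per-lot shift summaries: mean/min/max/N of the per-plate `S` values
  (4-decimal rounding), plus the CV of `S` within the lot. The CV of `S` is
  relative to the lot-mean `S` and becomes arbitrarily large (and
  uninformative) when that mean is near zero, as it is for the reference
  lot; it is meaningful only for clearly shifted lots.
* Outlier curves: a plate is flagged when its `S` deviates from the
  leave-one-out mean of its lot peers by more than `k = 3` leave-one-out
  standard deviations. The informal bench practice is flagging by
  inspection; this rule makes it reproducible. With very few curves per lot
  the leave-one-out sd is itself noisy and occasional false flags are
  expected — flags mean "review", not "reject". The fold-of-lot-mean ratio
  accompanying a flag is rounded to 1 decimal and is undefined (an absolute
  difference is carried instead) when the peer mean is zero.

## Synthetic data

The simulator realizes the generative model above: 8 two-fold standard
dilutions from 8000 pg/mL in triplicate (rows A–H, columns 1–3), per-batch
true shifts, additive homoscedastic Gaussian OD noise (default sd 0.02 OD),
and control samples in triplicate on every plate. Default true curve:
`a = −0.01`, `d = 3.20` OD, midpoint 1300 pg/mL, inverse slope 1/1.30,
symmetric — the scale of a typical plasma-biomarker sandwich ELISA. The
default batch structure is five lots with true shifts
(0, 0.07, 0.55, 0.65, 0.70).

Standards are generated from the *shifted* curve at their nominal labels
(mislabelled standards); controls and unknowns from the *reference* curve at
their true concentration (real specimens respond through the true chemistry,
which is what makes their raw read-outs drift across lots while their ODs do
not). Output is bitwise-reproducible under a seed.

What the simulator does **not** emulate — and therefore what passing tests do
not establish about real plates: heteroscedastic or non-Gaussian OD error,
spatial plate effects (edge wells, washer gradients), operator and time
drift, matrix effects, partial shifts affecting only some standard levels,
and real lots whose per-plate `S` dispersion mixes sources beyond
well-level noise. No attempt is made to calibrate the noise level to any
particular laboratory's data.

## Problem sizes in the shipped checks

The test suite and acceptance script run the five-lot design at the study's
per-lot plate counts (28/19/8/4/9) once, and replicate smaller designs
(five lots × 1 plate) 200–500 times for the Monte-Carlo properties
(CV-reduction win rate, `±2·se` coverage, `±3·se` concentration checks).
These sizes give stable Monte-Carlo fractions at a few seconds per check.

## Known limitations

* The shift factor captures a *uniform* log-fold mislabelling; a lot whose
  standards are distorted non-uniformly (slope or asymptote changes) will
  show a poor shifted-curve fit that `S` alone cannot absorb. Inspect the
  per-batch rss before trusting the adjustment.
* `se_S` is conditional on the reference curve (above).
* Mixed-effects / random-batch formulations and continuous-in-time drift
  models are deliberately out of scope; the batch effect here is fixed and
  discrete.
* Choice of the reference batch is a judgement call; the package takes the
  designation as given and never second-guesses it.
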