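# Methods

This note records the models, conventions and numerical choices behind the
package, including the decisions made where the underlying procedures are
conventionally under-specified.

## Signal model and the MR extraction

The input to everything is the normalized fluorescence Rn of one reaction,
reporter emission divided cycle-by-cycle by the passive-reference emission.
All Rn values must be strictly positive; the ratio series
R_n = S_n/S_{n−1} − 1 is otherwise undefined, so non-positive values raise
before any arithmetic (an opt-in `floor_epsilon` clamp exists for rescue
work, off by default).

The MR pipeline is: ratio series (cycles 2..N) → centered 5-point moving
average → natural cubic spline → argmax on a 0.01-cycle grid.

* **Filter edges.** The moving average shrinks symmetrically at the series
  ends (width 1 at the first/last point, 3 at the second/penultimate).
  This keeps the series length, is exactly neutral on linear trends, and
  avoids inventing padding values.
* **Spline type.** Natural boundary conditions (zero second derivative at
  the end knots). Clamped splines would need end-slope estimates that the
  data do not supply.
* **Grid.** Inclusive from the first to the last knot, anchored on the
  integer knots so knot values lie exactly on the grid; the spline maximum
  therefore always dominates the knot maximum. Ties break toward the
  earliest cycle, so a flat plateau reports its first grid point.
* **Convention.** MR is read off the spline of the smoothed series — the
  same object that defines FCN. All cutoffs are learned in this same
  convention, so classification is internally consistent regardless of how
  a raw-ratio MR would differ.

Accuracy of the 0.01 grid: against a 10^-4-step dense evaluation of the
same spline, FCN agrees to the grid step and MR to ~f''·(Δ/2)²/2, which is
below 10^-6 for peaks a few cycles wide — and the 5-point filter guarantees
peaks of roughly that width.

## The CT reference caller

The curve is baselined by subtracting a least-squares *line* fitted over
the baseline window (a line rather than a constant, to absorb drift). Cq
is the first upward crossing of ΔRn over the threshold (default 0.2
units) at or after the baseline end, linearly interpolated between the
flanking cycles; later re-crossings are ignored, which is precisely what
makes early transient spikes CT-positive. No crossing ⇒ negative; with a
`cq_max` rule active, a later Cq is retained but the call is negative.

Instrument baseline algorithms are proprietary, so the automatic baseline
here is a documented stand-in: starting from the default window (cycles
3–15), the end is pulled back to two cycles before *lift-off*, the first
cycle exceeding the mean + 10 SD of the five cycles at the window start.
One refinement was needed to make the rule self-consistent: the reference
window is truncated to the cycles *preceding* the candidate cycle (with a
trailing-3-cycle fallback for very early candidates), because a lift-off
inside its own reference window would otherwise inflate the reference SD
and mask itself. The end never drops below start + 2. SDs use the sample
(n − 1) convention. Cq values are therefore comparable in behaviour, not
bit-identical, to any particular instrument's output.

## The two-cutoff model

* **Watershed** = lowest FCN among training positives. A query FCN exactly
  at the watershed uses the late cutoff (the watershed is itself a
  positive's FCN).
* **Early cutoff** = 1.5 × max training MR below the watershed. The 1.5
  multiplier is the moderate-outlier whisker convention. With no training
  reactions below the watershed the early cutoff degenerates to the late
  cutoff.
* **EM mixture.** Two-component univariate Gaussian mixture on the
  late-region training MR values. Initialization is deterministic:
  means at the 25th/75th percentiles, both SDs at the pooled sample SD,
  equal weights; E/M iterations stop when the relative log-likelihood
  change drops below 10^-8 (cap 1000 iterations; non-convergence is
  flagged, the best fit returned). Component SDs are floored at
  max(1e-12, 1e-9·SD) to survive tied values. All-equal inputs are a
  degeneracy error, not a fit.
* **Candidates.** lower = μ_low + zσ_low, upper = μ_high − zσ_high with
  z = 3 by default; mid is their midpoint. How the published candidate
  range emerges from the mixture is not recoverable, so the z-sigma
  envelope is this package's documented construction; when the components
  overlap enough that lower > upper, all candidates collapse to the
  equal-posterior crossing between the components (bisection between the
  means, dense-scan fallback).
* **Selection.** Each candidate is scored by FP + FN on the late-region
  training reactions; ties prefer mid, then lower. Boundary inclusive:
  MR equal to a cutoff is positive (rule-in posture of a screening assay).

Pooling: all targets are trained as a single population by default;
stratified per-target training is a caller-side choice (filter the
labelled results before training).

## Statistics

* **Consensus** is the median of binary rater calls; an even split has no
  median, and the default policy resolves it positive with a warning
  (configurable).
* **Metrics** are computed in exact rational arithmetic and reported
  rounded half-up to 3 decimals (so 13 639/13 824 prints as 0.987).
  Rounding is applied to the shortest decimal representation of the value,
  which makes half-up behave as a reader expects (0.0265 → 0.027) despite
  binary floats. Zero-denominator ratios are undefined (`None`), not 0.
* **Cohen's κ** uses marginal-product chance agreement and the simple
  large-sample SE √(p_o(1−p_o)/(n(1−p_e)²)) with normal quantiles for the
  95% CI. Undefined when p_e = 1.
* **Fleiss' κ** is the standard two-category form; its p-value tests
  κ = 0 with the classic large-sample SE. At m = 2 raters it is the Fleiss
  formula (pooled marginals), which differs in general from Cohen's κ.
* **Bands**: slight/fair/moderate/substantial/almost-perfect at upper
  edges 0.20/0.40/0.60/0.80/1, implemented half-open so that 0.20 is
  slight and 0.205 is fair; negative κ reports "poor (below slight)".
* **Standard curves** regress Cq or FCN on log10 relative quantity (the
  log of the reciprocal dilution factor — efficiency is defined per
  10-fold step) and report E = 10^(−1/s) − 1; a zero slope leaves E
  undefined.

## Synthetic plates

Curves are baseline b0 + drift·c + a four-parameter logistic
A/(1 + e^(−k(c−m))) + an optional Gaussian transient bump + N(0, σ) noise,
clamped at b0/100 (a spec forcing ≥10% clamped cycles is rejected —
clamping with an error threshold keeps generation deterministic, which
rejection sampling would not). Defaults: N = 45 cycles, b0 ~ U(0.9, 1.1),
drift ~ U(0, 0.002), σ = 0.005.

Class-conditional draws (uniform ranges):

| class | A | k | m | transient |
|---|---|---|---|---|
| clear_positive | 2–4 | 0.6–1.0 | 18–35 | — |
| weak_positive | 0.55–0.8 | 0.5–0.9 | 28–38 | — |
| slow_riser | 0.8–1.4 | 0.045–0.075 | 46–54 | — |
| transient_negative | 0 | — | — | pos 2–4, height 0.03–0.08, width 0.6–1.2 |
| flat_negative | 0 | — | — | — |

Rationale for the two artefact classes, which were calibrated once while
designing the generator:

* *slow_riser* sits astride the CT threshold-crossing boundary: the total
  rise (≈ 0.1–0.4 ΔRn after baseline absorption) makes roughly half the
  draws CT-positive, while the per-cycle relative increment (≈ k × rise)
  stays near 0.01–0.02, far below weak-positive MR (≳ 0.05). This is the
  non-sigmoid CT-false-positive mechanism the MR filter exists to remove.
* *transient_negative* heights are chosen so early-spike MR lands in the
  ~0.01–0.07 band *below* typical positive MR. This matches the observed
  geometry of real plates — early transients are high only relative to
  other early-cycle reactions — and it is what lets an early genuine
  positive clear the inflated early cutoff.

What the generator does **not** emulate: inter-plate batch effects,
target-specific amplification idiosyncrasies, reaction inhibition,
heteroscedastic noise, or the FCN density of any particular assay. Passing
end-to-end tests therefore demonstrate that the pipeline recovers the
generator's class structure at realistic noise, not clinical performance
on any real panel.

## Problem sizes

The end-to-end fixtures use 360-well plates (60/30/40/30/200 across the
five classes) for training and query, 200 draws for per-class rate
estimates, 1000 MR values for mixture-recovery checks and 10 000 paired
calls for the independence null — sizes at which every estimate under test
is stable to well within its asserted tolerance. The acceptance script
rebuilds a 1920-reaction training set (962 positive/958 negative, 600
early-region negatives) mirroring the published split.

## Known limitations

* The late-region candidate construction (z-sigma envelope) is a surrogate
  for an unrecoverable published procedure; its midpoint arithmetic and
  selection logic reproduce the published behaviour, but the candidate
  values themselves are construction-dependent.
* K-fold cross-validation of the cutoffs is not implemented (single
  random split, as published).
* The watershed rule is sensitive to the lower tail of the positive FCN
  distribution: a query positive with FCN just below the training minimum
  is judged by the inflated early cutoff and survives only if its MR is
  high (as early genuine positives typically are).
* Cq values are method-faithful but not instrument-identical (see the CT
  section).
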