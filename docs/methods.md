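# Methods

## Rating model

Confidence ratings on the 10-point face/car scale are made continuous by
jittering: each integer rating r becomes r + u with u ~ Uniform(0, 1),
giving support [1, 11) = [1, L).  Flooring a jittered value recovers the
integer exactly, so jittering is information-preserving; it exists to let
continuous densities model the data.

A cell X(k1, k2) — one subject's jittered ratings for the images whose
no-cue rating was k1, observed under cue k2 ∈ {1, 5, 10} — is modelled
as a two-component mixture of gamma variants.  The *shifted gamma*
g(x; α, β) lives on [1, ∞) and models face-leaning components; the
*negative gamma* ng(x; α, β) = g(L + 1 − x; α, β) lives on (−∞, L] and
models car-leaning ones.  β is a rate parameter.  The shape is restricted
to α ≥ 1 so that every component has a mode, at 1 + (α−1)/β or
L − (α−1)/β.  The family is a function of (k1, k2): SS (both shifted)
when k1 ≤ 5 and k2 ∈ {1, 5}; NN (both negative) when k1 ≥ 6 and
k2 = 10; SN (one of each) otherwise.  Same-kind components are ordered by
mode; in SN the shifted component is listed first (its mode is the
smaller one under the family rules).  Only cells with more than 10
observations are fit.

## Estimation

EM with standard responsibilities.  The M-step updates the mixing weight
to the mean responsibility and solves, per component, the weighted gamma
MLE on the transformed values y = x − 1 (shifted) or y = L − x
(negative):

    ln α − ψ(α) = ln(Σwᵢyᵢ/Σwᵢ) − Σwᵢ ln yᵢ / Σwᵢ,    β = α / weighted-mean(y)

by Newton–Raphson from the standard closed-form starting point, with a
bisection fallback (the left side is strictly decreasing in α, so
bisection on [1e−8, 1e6] always succeeds).  Shapes are projected onto
[1, 1e6]; given a projected shape the rate update above remains the
conditional MLE, so the M-step still maximizes the constrained
likelihood and EM monotonicity is preserved.  Numerical guards:
transformed values at exactly 0 (a data point on the boundary) are
clamped to 1e−12 before logarithms; a component whose responsibility
mass collapses below 1e−12 keeps its previous parameters; the mixing
weight is clipped to [1e−6, 1 − 1e−6].

Initialization is bimodality-aware: the data are split at the midpoint
between the two largest unit-bin histogram peaks (median fallback when
the peaks are adjacent or one-sided), each side is summarized by
method-of-moments on its component's transform, and the initial weight
is the left-mass fraction.  Five seeded multiplicative perturbations of
this initializer serve as restarts; the best final log-likelihood wins.
Convergence: relative log-likelihood change below 1e−8, or 500
iterations.  EM is deterministic given data and initialization; the seed
only drives the restart perturbations.

The Gaussian baseline is a two-component Gaussian mixture
(unconstrained means, positive variances, 1e−6 variance floor) fit by
the standard EM with five initializations.

## Validation machinery

**Goodness of fit.**  The KS statistic D = sup|ecdf − F̂| is tested
against the asymptotic KS null.  No correction is made for the fact that
F̂ has estimated parameters; this makes acceptance conservative (the
measured null rejection rate at n = 200 is far below nominal), which is
documented rather than corrected because the validation claims are about
acceptance rates.  Per subject, the Nᵢ cell tests are Holm–Bonferroni
corrected at FWER 0.05.

**HPDR.**  The 100(1−α)% highest-probability-density region of a fitted
density f is R(f_α) = {x : f(x) ≥ f_α} with f_α the largest threshold
whose region holds mass ≥ 1−α.  It is computed on a 10,001-point grid
over [1, 11]: grid densities are sorted, the threshold located by
bisection over them, and interval masses evaluated with the fitted CDF
(exact, not grid sums).  Because the true level-set boundary falls
between the last included and first excluded grid point, interval
endpoints are extended by half a grid step; the returned mass is
therefore ≥ the nominal level with a small positive margin rather than
marginally above it, which keeps independent quadrature checks of the
mass on the right side of the level.  Membership tests tolerate half a
grid step.  For a bimodal fit the region is a union of disjoint
intervals, one per retained mode.

**Predictive check.**  10-fold cross-validation with seeded shuffled
folds (no stratification): fit on the training folds, compute the 95%
HPDR, record the fraction of held-out points outside it.

A sampling-noise caveat documented here because it shapes expectations
at small n: even for an oracle region with exact 95% coverage, per-fold
error rates are binomial proportions, so with 50 cells × 20 held-out
points per fold the per-fold mean has standard deviation ≈ 0.7% and the
*maximum* over 10 folds sits near 5% + 1.5 sd ≈ 6%.  In addition the
plug-in HPDR of an ML fit trained on ~180 points under-covers the truth
by roughly 0.5–1% (measured true coverage of fitted 95% regions:
0.93–0.96), a generic property of plug-in predictive regions.  Summary
statistics of the per-fold error at these problem sizes should therefore
be read against a ~6% noise floor, not against 5% exactly; only
aggregates over much larger pools (tens of thousands of points per fold)
concentrate tightly at the nominal error.

**Model comparison.**  Per cell, 10-fold CV; on each fold both models
are fit to the training part and the ratio of held-out likelihoods
(gamma-variant / Gaussian, product over test points) recorded; the fold
median summarizes the cell.  Folds where either fit fails are excluded
and counted.

## Social-influence metrics

* **Shift distance.**  x = (k1 − m1, k1 − m2)'; D = x'x when k1 = k2,
  else x'Σ⁻¹x with Σ the 2×2 covariance of mode estimates across the
  subjects available for that (k1, k2).  A singular Σ is
  ridge-regularized with a warning.
* **Proportion toward cue.**  Fitted mass on [min(k1,k2), max(k1,k2)];
  undefined (NaN) when k1 = k2.
* **Concurrence gain.**  Mass difference, concurring minus neutral fit,
  over the printed own-decision regions: [1, 6] for face decisions and
  [7, 11] for car decisions.  These regions are kept literal even though
  they are not mirror images (the band [6, 7) belongs to neither); the
  mirror identity for gains therefore holds only for fits without mass
  in that band.
* **Crossover.**  Declared when a component mode lies strictly on the
  opposite side of the decision boundary from k1; the boundary is 6.0 on
  the jittered scale (ratings 1–5 jitter into [1, 6), 6–10 into
  [6, 11)).  The reported crossover mass is the crossing component's
  weight times its own mass beyond the boundary.  At moderate cell sizes
  the *binary* flag saturates — EM places a residual low-weight
  component across the boundary even when the true cue-side weight is
  near zero — so cohort-level gradients are carried by the crossover
  mass, which tracks the true cue-side weight monotonically.
* **Bootstrap.**  Percentile CIs; the achieved significance level (ASL)
  is the fraction of bootstrap statistics on the null side of zero.
  All resampling is seeded.
* **Social-bias score.**  Wᵢ = (p̄ᵢ − 0.5)/(σ/√n) with σ the sample SD
  of the per-subject mean proportions and n the number of valid
  subjects; this one-sample z-form is the reading under which the 1.96
  selection threshold is meaningful.  A zero-σ cohort is flagged
  degenerate rather than scored.

## Synthetic data

**Behavior.**  The design fixes 250 images (125 face, 125 car), each
shown once per cue condition (FF, FC/CF, CC, none) — 1,000 trials in 40
sessions, 250 per condition — in seeded random order.  Each image
carries a latent percept mode, an integer drawn uniformly from 1–5
(faces) or 6–10 (cars).  A subject is parameterized by a
*susceptibility* s ∈ [0, 1] (the true cue-side mixture weight) and a
*confidence sharpness* β > 0 (the rate of every component; default 2.0,
which gives component SDs of roughly 1–2 rating points, matching
visually bimodal but overlapping cells).  Cued ratings are floored draws
from the mixture with the own-side component's mode at the latent
percept and the cue-side mode at k2; no-cue ratings are draws from the
own-side component alone.  Keying the generative mixture on the latent
percept (rather than on the realized no-cue rating) makes cued and
no-cue ratings exchangeable at s = 0, the defining property of zero
influence; the analysis pipeline still groups cells by the realized
no-cue rating k1, exactly as an analyst would.

Draws from `simulate_cell` are by default rejection-sampled into
[1, L], the jittered-rating support.  For rating-scale parameters the
redrawn mass is < 1%; `truncate=False` returns the exact untruncated
mixture, which is what parameter-recovery checks against the EM (which
fits the untruncated density) should use.

**EEG.**  Epochs are trials × channels × samples at 512 Hz over
[−200, 500] ms by default.  The class signal is a Gaussian temporal bump
(center 250 ms, SD 40 ms, zero before stimulus onset) times a fixed
cosine topography spanning three half-cycles across the cap, positive
for faces and negative for cars, scaled per condition by an SNR knob.
Noise is spatially correlated (exponential channel covariance, length 5
channels) with a 1/f amplitude spectrum, RMS-normalized.  Epochs are
baseline-corrected on [−200, 0] ms.  What this emulates: a
late-latency, spatially structured discriminative component in realistic
colored noise.  What it does not: real ERP morphology (N170 and later
components), artifacts, inter-subject variability, or any genuine link
between behavioral susceptibility and neural SNR — the condition-SNR
ordering is imposed, so decoder tests verify the pipeline's sensitivity
and calibration, not a neuroscientific claim.

## Decoding stage

Epochs flagged by the hygiene rule (per channel: epoch summary deviating
from the cross-epoch median by more than 5×IQR; summary = mean
amplitude, configurable) are excluded from ERP averages; with IQR = 0
(identical epochs) nothing is flagged.  Decoding flattens post-stimulus
samples to channel×time vectors; classwise PCA keeps each class's
principal subspace at 99% explained variance, adds the class-mean
difference direction, and orthonormalizes (dropping numerically null
directions), yielding at most n_train dimensions.  The classifier is
linear discriminant analysis with analytic shrinkage of the pooled
covariance — a Gaussian shared-covariance Bayes rule with affine
log-odds.  Cross-validation is stratified 10-fold, transforms and
classifier fit on training folds only; AUC is computed from pooled
out-of-fold posteriors via the Mann–Whitney U statistic (ties 0.5).
Windowed analysis slices post-stimulus samples into consecutive 50 ms
windows; each window's one-sided above-chance Mann–Whitney p-value is
Benjamini–Hochberg corrected across windows.  Cross-validated AUC at
small trial counts is noisy (SD ≈ 0.04 at 300 trials, larger below), so
chance-level calibration claims are made about means over seeds or
permutations, not single runs.

## Problem sizes used in validation

Goodness-of-fit acceptance: 15 subjects × 30 cells × 150 ratings
(heterogeneous susceptibilities 0.15–0.65, sharpness 1.5–3.0).  HPDR
cross-validation: 50 bimodal cells (modes ≥ 3 apart, weight 0.3–0.6),
n = 200, 10 folds.  Model comparison: 30 such cells, n = 200.  HPDR
mass: 100 random parameter sets with modes drawn on the rating scale and
off-scale leakage > 0.1% redrawn (a fit for data on [1, 11) concentrates
there; an unconstrained draw can put most of its mass beyond L, where no
on-scale region can hold 95%).  Recovery and ranking checks: n = 2,000
ratings per recovery cell; cohorts of five subjects with susceptibilities
0.9/0.7/0.5/0.3/0.1 and ~2,000 ratings each for the Kendall-τ ranking
check.

## Known limitations

* The KS p-values ignore parameter estimation; acceptance rates are
  conservative by construction.
* The plug-in HPDR inherits ML estimation noise; its cross-validated
  error exceeds the nominal 5% by up to ~1–2% at n ≈ 200 (see the
  sampling-noise caveat above).
* The likelihood-ratio comparison at n = 200 flips sign on weakly
  separated cells whose components are nearly symmetric; the Gaussian
  mixture is a genuinely competitive model there.
* Binary crossover detection saturates at realistic cell sizes; use the
  crossover mass for graded comparisons.
* The EEG generator's SNR knob is an imposed condition label, not a
  model of the cue-confidence interaction.
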