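# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic cohort does and does not emulate, and the
problem sizes at which the validation suite exercises each claim.

## Cohort model

A synthetic cohort is a set of independent lesions (one lesion per
synthetic patient by default; distinct `patient_id`/`lesion_id` fields are
kept so patient-grouped cross-validation remains possible). Each lesion
carries:

* **Labels.** ER%, PR% and Ki67% follow two-component mixtures split at
  the clinical positivity cutoffs (1%, 20%, 20%): with configurable
  probability the value is a scaled Beta draw above the cutoff, otherwise
  below it. This makes positivity rates exact by construction; default
  rates (ER+ 58/68, PR+ 33/68, Ki67+ 47/68, HER2+ 16/68, grades
  14/28/26 per 68) emulate a malignant screening population. ER and PR are
  coupled — P(PR+ | ER−) defaults to 0.10, with P(PR+ | ER+) solved to
  preserve the PR marginal — because hormone receptors co-occur
  clinically; this also yields a realistic triple-negative prevalence of
  about 7/68 instead of the ~4/68 that independence would give. HER2 and
  grade are independent of the receptors; clinically plausible
  grade–Ki67 dependence is deliberately not modeled.

* **Images.** A low-energy (LE) view with a bright, label-independent
  Gaussian background, and a recombined (RC) view with near-zero
  background and an enhancing ROI, both 16-bit scale. The ROI is a filled
  disc (default radius 15 px in a 64-px frame, ≈ 700 pixels) shared by
  both views. Pixels outside the representable range clip to it, as a
  saturating detector would.

## Texture model and effect planting

In-ROI gray levels follow a four-parameter sinh-arcsinh (SAS) intensity
distribution: location ξ, scale ω, skewness ε, tail weight δ
(`q(u) = sinh((asinh(Φ⁻¹(u)) + ε)/δ)`). The ROI receives the *stratified*
standardized quantiles of this distribution at probabilities (i+0.5)/N in
a random spatial arrangement, plus optional i.i.d. Gaussian pixel noise
(default sd 300, small against ω₀ ≈ 2500–4000). Stratification makes the
ROI's sample moments deterministic functions of (ξ, ω, ε, δ): with zero
pixel noise and no saturation, the in-ROI population variance is exactly
ω². First-order features are therefore driven almost noiselessly by four
latent channels per image:

| channel | parameter | features moved |
| --- | --- | --- |
| location | ξ (affine in latent) | Mean |
| scale | ω (log-affine) | VC, Max-Min, RelativeSmoothness |
| skew | ε (affine) | Skewness |
| tail | δ (log-affine) | Kurtosis (+), Entropy (−) |

Features sharing a channel co-move; that is intentional — dispersion
statistics are not independent quantities in real images either — and it
is why an effect map may address each (label, channel) pair only once.

A planted effect `(label, feature, target)` mixes the lesion's
standardized label value u into the feature's driving latent,
`m = c·u + √(1−c²)·e`, `e ~ N(0,1)`. Because the feature maps are
nonlinear, c is obtained by dividing the requested feature-space effect by
the feature's measured latent response ("attenuation"), a Pearson
correlation between extracted feature and driving latent measured once on
60 000 null lesions under the default configuration
(`scripts/calibrate.py`, constants in `calibration.py`; responses range
from 0.79 for kurtosis to 1.00 for the mean). Requests that imply a
mixing coefficient ≥ 1, duplicate a (label, channel) pair, or jointly
overload a channel (Σc² ≥ 1) are rejected with the offending triples
named.

Accuracy: planted Pearson targets on continuous labels are recovered
within the Monte-Carlo tolerance of the validation suite (±0.05 at
n = 2000; measured ≈ 0.001 bias for the Ki67↔RC_VC benchmark).
Standardized-mean-difference targets on HER2/grade are exact under the
locally-linear approximation and hence accurate for near-linear features
(Mean: within ~2%) but amplified by convexity for log-scale features
(VC ~9%, RelativeSmoothness up to ~20% at d = 1). SMD planting is used
for power demonstrations, where over-delivery is conservative in the
direction that matters for calibration claims (null behavior), and is
documented rather than corrected.

Randomness: one root seed; each lesion draws from its own
`SeedSequence` child stream (labels first, then latents, then pixels), so
cohorts are byte-identically reproducible and stable under reordering.

## What the phantom does not emulate

No anatomy, no dual-energy physics, no contrast kinetics, no correlated
spatial texture (features here are first-order, so spatial arrangement is
irrelevant by construction), no segmentation error (one shared, perfectly
known disc mask), and no patient-level clustering of lesions. Passing
tests therefore demonstrate that the *analysis machinery* is correct and
calibrated — not that real CESM textures carry these associations.

## Feature conventions

The seven statistics use population central moments by default (sample
moments, excess kurtosis and natural-log entropy are config switches,
since first-order radiomics conventions vary):

* entropy: 256 equal-width bins spanning the ROI's own [min, max]
  (the common first-order radiomics convention); 0·log 0 := 0; a constant
  ROI has entropy 0 by convention;
* relative smoothness: 1 − 1/(1+σₙ²) with σₙ computed on intensities
  rescaled to [0,1] by the image's representable range (bit depth), so the
  feature is comparable across lesions; the ROI-range alternative is a
  config option;
* VC: flagged undefined (NaN) when |μ| falls below 1e-9 of the
  representable range — subtraction images can have near-zero means and a
  near-infinite VC would silently dominate the LDA — or when σ = 0, where
  a dispersion ratio carries no information; skewness and kurtosis are
  undefined at σ = 0. Undefined values propagate as missing: association
  tests delete pairwise and report n, classification drops the lesion
  with a logged count.

## Association analysis

Pearson correlation (two-sided t test, n−2 df) for the three continuous
outcomes; two-sided Mann–Whitney U for HER2 and grade. Grade is split
G3 vs G1∪G2 — matching the classification task's high/low definition —
because a two-group rank test on a three-level ordinal scale requires
choosing a split. The Mann–Whitney exact null is enumerated by a rank-sum
subset recurrence whenever the pooled sample is tie-free and ≤ 25
(configurable); otherwise the tie-corrected normal approximation with
continuity correction is used, with two-sidedness defined by distance of
U from its null mean. Bonferroni families default to the 14 tests per
outcome (the weakest assumption consistent with per-outcome reporting); a
global 70-test family is a config option. Rendered tables star raw
p-values at 0.10/0.05/0.01.

## Classification

Tasks use inclusive cutoffs (value ≥ cutoff → positive), following the
clinical ER ≥ 1% convention. Triple-negative means ER−, PR− *and* HER2−,
the standard clinical definition. LDA is computed in closed form with the
unbiased pooled covariance (n−2 denominator) plus a ridge of
1e-6 × (total feature variance)/p on the diagonal — at these sample sizes
the ridge changes nothing detectable but guarantees a Cholesky-factorable
matrix. Scores are positive-minus-negative discriminants; the ROC pools
the scores of all leave-one-out folds into a single curve per task (the
standard LOO practice) and integrates by trapezoid, which with the
threshold sweep used here equals the tie-aware Mann–Whitney pair-count
identity exactly. Features are not standardized by default: LDA with a
full pooled covariance is equivariant under affine feature maps, so
z-scoring (within-fold or even globally) provably cannot change the
ranking beyond ridge-sized perturbations; a within-fold standardization
option exists and is tested for non-inflation on null data. Leave-one-out
is lesion-level, matching the one-lesion-per-patient default; tasks whose
smaller class has fewer than 3 members are reported infeasible rather
than crashing the run.

## Validation problem sizes

The suite validates each claim at the smallest size that makes it sharp:
exact statistics are enumerated for all group sizes ≤ 8; feature oracles
on 100 random ROIs of 16–4096 pixels; null calibration (family-wise error
within the 99% binomial envelope of 5%; ≥ 95% of LOO AUCs below 0.75) on
200 replicate cohorts of 68 lesions; planted-correlation recovery at
n = 2000 (±0.05); Bayes-AUC attainment Φ(D/√2) at n = 4000 for
D ∈ {0.5, 1, 2} (±0.02); determinism on full 68-lesion pipeline reruns.

## Known limitations

* Calibration constants are tied to the default texture/noise/ROI-size
  configuration; planted effects under modified configurations are
  approximate until recalibrated.
* Entropy and kurtosis share the tail channel, so their effects cannot be
  planted independently of one another (nor can VC/Max-Min/Relative-
  Smoothness within the scale channel).
* The exact Mann–Whitney path requires tie-free data; integer-valued
  cohorts at n = 68 always route to the normal approximation.
* LOO AUC on null data is biased below 0.5 (each held-out lesion shifts
  the training means away from itself); the null-calibration bounds
  account for this, but single-cohort AUCs near 0.4 should not be read as
  signal.
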