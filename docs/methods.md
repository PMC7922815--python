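# Methods

`pyrasense` implements the chemosensory analysis chain used to study how
pyrazines — alone and in mixture — shape the roasted aroma of soy-sauce-aroma
Baijiu (SSAB): quantitation QC, odor-activity-value (OAV) profiling, a
concentration–aroma rank-correlation screen, exact 3-AFC discrimination
testing, group odor-threshold estimation on geometric dilution series, and a
Feller-independence analysis of perceptual interaction between a
sub-threshold and a supra-threshold odorant bundle. This note records the
models, the defaults and why, the numerical choices, and the known limits.

## Quantitation QC

Calibration regresses the response ratio (analyte area / internal-standard
area) on known standard concentrations by unweighted ordinary least squares;
a `1/x`-weighted option exists but is off by default, since nothing in the
underlying protocol indicates weighting. Linearity is gated at R² ≥ 0.99.
Inverse predictions below zero are flagged and reported as 0 in summary
tables while the raw value is preserved for QC — physical non-negativity
without silently hiding an instrument problem. LOD and LOQ are the
concentrations at which the expected signal reaches 3× and 10× a supplied
baseline-noise standard deviation (so LOQ/LOD ≡ 10/3); the noise SD is an
input because raw chromatograms are out of scope, which deliberately
abstracts over whether limits were derived from blanks or diluted standards.
Replicate RSD is 100·sd/mean with the sample (n−1) standard deviation;
triplicates are the norm but any n ≥ 2 is accepted.

## OAV profiling

OAV = concentration / odor threshold, both in μg·L⁻¹. Banding: OAV < 0.1
negligible, 0.1 ≤ OAV < 1 sub-threshold, OAV ≥ 1 supra-threshold — the
threshold itself counts as reached, which matches how spike designs group an
OAV of exactly 1.00 with the supra-threshold additions. Report rounding is
half-up: 1 decimal for profile OAVs, 2 decimals for spike-design OAVs,
nearest integer for percent-of-threshold. One value in the reference tables
(80/172 = 46.5%, conventionally printed 46%) does not follow half-up
rounding; we document rather than special-case it.

Thresholds carry a matrix tag (here, 53% v/v ethanol/water) and the profiler
warns when a threshold is applied to samples from a different matrix —
ethanol-solution thresholds are known to overstate detectability in whole
Baijiu, and that extrapolation should stay visible. Missing concentrations
propagate as missing and never count as zero in summaries.

"Supra-threshold contributor" defaults to the mean rule — a compound whose
across-sample mean concentration exceeds its threshold — under which exactly
four pyrazines (26DM, 235TM, 2E6M, 2E35DM) qualify in the packaged dataset.
An `on="any"` rule (any single sample with OAV ≥ 1) additionally picks up
23DE, which crosses only in its strongest sample; the profiler reports both
honestly.

## Sensory correlation screen

Panel intensities (0–7 scale, assessor × replicate) aggregate to per-sample
means; the omnibus one-way ANOVA across samples is computed, but
compact-letter multiple comparisons are out of scope. Spearman ρ is the
Pearson correlation of mid-ranks (average ranks on ties). The p-value is an
exact permutation tail for n ≤ 9 common samples and the
t = ρ√((n−2)/(1−ρ²)) approximation beyond — at the study's n = 11 the
approximation applies, matching common statistical-package practice. A
compound is flagged when ρ > 0.5 and p < α = 0.05.

The screen looks for *positive* relationships, so the default p-value is
one-sided (`alternative="greater"`); with the directional flag rule, a
two-sided p would make the effective null flag rate ≈ α/2 rather than α.
Negative correlations are reported but never flagged. No multiple-testing
correction is applied by default (none was applied in the original
16-compound screen); a Benjamini–Hochberg option exists and its use is
recorded in the output.

## 3-AFC discrimination

The 3-AFC chance rate is 1/3. Significance of k correct out of n is the
exact binomial upper tail, summed term by term — panel sizes of 12–20 are
squarely where normal approximations distort the */**/*** ladder
(cuts at 0.05/0.01/0.001). Proportion-correct converts to detection
probability by Abbott's correction p_d = (p_c − 1/3)/(2/3), the standard
m-AFC adjustment; below-chance observations clip to 0 with the raw value
retained upstream.

## Threshold estimation

Dose ladders are geometric (factor 2), i.e. uniform on the log scale; a
printed ladder supplied as data is used verbatim (published ladders are
often iteratively halved-and-rounded and are not exactly base·2^i).
The group threshold is where the detection curve crosses a criterion —
default 50% of panelists correct, the literal reading of the protocol.
Because the 3-AFC guessing floor (1/3) is close to 0.5, a
`chance_corrected` scale (50% of detection probability ≈ 66.7% correct) is
provided and every estimate records which scale was used.

The estimator pools-adjacent-violators (weights = panelists per dose) to
enforce monotonicity, then interpolates linearly in log-dose between the
bracketing steps; an exact criterion hit returns that dose. Curves that
never reach the criterion raise a no-crossing error carrying the maximum
smoothed proportion; curves entirely above it return a left-censored
estimate at the lowest dose. A maximum-likelihood logistic psychometric fit
(guessing floor 1/3, zero lapse, log₁₀-dose abscissa) is available as an
alternative estimator; it refuses separated or flat data.

Thresholds measured as stock volumes (mL into 15 mL of matrix) stay in
volume units; an explicitly labelled conversion to in-glass concentration,
c = stock·v/(v+15), assumes additive volumes.

## Feller interaction analysis

Under independent detection, p(AB) = p(A) + p(B) − p(A)p(B); equivalently
the complements multiply. Detection above the prediction is synergy, below
is suppression. (Published prose on the direction of this comparison is
internally inconsistent; we follow the usage consistent with the reported
result: observed detection above prediction — equivalently an observed
threshold *below* the predicted one — is synergy.) All model arithmetic is
on the chance-corrected detection scale; raw-scale "independence" would
double-count guessing. Component A (the fixed-composition sub-threshold
bundle) contributes one dose-independent p(A), pooled over its replicate
trials; whether p(A) is measured or assumed 0 must be chosen explicitly.

Departure from additivity is embedded in a one-parameter family,
1 − p(AB; θ) = [(1 − p(A))(1 − p(B))]^θ, with θ = 1 the additive null,
θ > 1 synergy, θ < 1 suppression — the same family the synthetic generator
uses, chosen because it has a clean null at 1 and a monotone effect
direction. The test statistic is the signed-root likelihood ratio of the
mixture counts over θ, with p(A) estimated from the A trials (unclipped
internally, so estimation error stays symmetric) and the B curve smoothed
by a maximum-likelihood logistic fit on a (midpoint × slope) grid.

A naive exact binomial test of mixture counts against this prediction is
badly oversized (~30% false interaction calls at α = 0.05 in simulation at
n = 20/dose): the prediction is itself an estimate. The null distribution
is therefore a parametric bootstrap that redraws the A counts, the B counts
(around their raw per-dose proportions, so the resampled B and AB share one
realized curve as in a real single-panel study), and additive-null mixture
counts, re-estimating every nuisance on each draw. The verdict is
non-additive only if the two-sided bootstrap p falls below α *and* the
fitted threshold shift reaches half a dilution step (fold √2) — the
resolution of a factor-2 ladder; this minimal-effect gate suppresses
significant-but-unresolvable calls. For designs where the component
detection probabilities are truly known, `prediction_uncertainty="none"`
gives the exact convolution tail at the doses bracketing the criterion.

Measured operating characteristics at the study conditions (20
panelists/dose, nine-dose factor-2 ladder, log-normal panelist
heterogeneity of one dilution step, p(A) = 0.2, 500 simulated experiments):
false non-additive rate ≈ 6% at α = 0.05 (≈ 4% synergy, 2% suppression),
detection of a θ = 2 synergy ≈ 48%, of θ = 0.5 suppression ≈ 40%. Two
limitations are intrinsic at this panel size: (i) a residual 1–2 point
type-I excess remains because panelist heterogeneity makes the realized
group curve a random function that an aggregate-count bootstrap cannot
condition on; (ii) θ = 2 corresponds to roughly a one-step threshold shift
and sits near 50% power. Larger panels or replicate series resolve both;
the verdict's p-values and threshold estimates are reported so users are
never reduced to the three-way call alone.

## Synthetic data generator

The generator emulates the study's structure with known ground truth:

- **Concentrations.** A latent roasted-aroma intensity per sample, uniform
  on [1, 6.3] (echoing the observed 0.93–6.26 spread without claiming its
  distribution); log₁₀-concentration = log₁₀(stock) + loading·z + Gaussian
  noise (default σ = 0.15 log units). `loading_for_rank_correlation`
  converts a target Spearman ρ into a loading via the Gaussian-copula
  relation — approximate for the uniform latent, adequate at ρ ≤ 0.95.
  Default stocks/thresholds are the eight mixture pyrazines' values.
- **Ratings.** score = latent + N(0, 0.8), rounded and clipped to 0–7, for
  12 assessors × 3 replicates.
- **3-AFC responses.** Logistic psychometric in log₁₀-dose, slope 4.87 per
  log₁₀ unit (10–90% span ≈ three factor-2 steps); individual thresholds
  log-normal around the group threshold with geometric SD one dilution step
  (set `threshold_gsd_log10=0` for a homogeneous oracle panel); answers
  correct with probability 1/3 + (2/3)·p_detect.
- **Mixtures.** One panel attends the B and AB sessions — thresholds drawn
  once and shared, responses independent. This matters: per-panelist
  additivity then aggregates to additivity of the realized group curves,
  which is what makes the additive null testable from group counts at all.
  True mixture detection is 1 − [(1 − p_A)(1 − p_B)]^θ; p(A) defaults to
  0.2 (a perceptible but weak fixed bundle).

What the generator does not emulate: chromatographic artefacts, assessor
drift or session effects, correlated compound families beyond the single
latent factor, dose-order (ascending-presentation) effects, and panelist
lapses. Passing tests therefore demonstrate statistical correctness of the
estimators under clean psychophysical assumptions, not robustness to every
real-world sensory artefact.

## Problem sizes used in checks

The packaged checks run the screen calibration at 16 compounds × 11 samples
× 2000 replicates, verdict calibration at 500 replicates of 20
panelists/dose on the nine-step ladder, and threshold recovery at 300–500
replicates — sizes chosen to keep Monte-Carlo error around a point on the
rates of interest while the whole suite stays comfortably runnable on one
CPU.
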