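# Methods

## The study being modelled

A 2AFC low-contrast detectability experiment: a reader sees two cropped CT
images of the same phantom insert — one containing low-contrast lesions
(signal-present), one homogeneous background — and must pick the
signal-present one. Chance performance is 50% correct. Detectability is the
fraction of correct choices, assessed per dose level (CTDIvol, mGy) and
reconstruction algorithm. The default design is 20 readers (10
radiologists, 10 non-radiologists) × 2 signal-present slices × 3 repeated
scans × 4 lesion inserts (4 mm hyperdense, 6 mm hyperdense, 8 mm
hyperdense, 8 mm hypodense) × 5 doses {5, 10, 15, 20, 25} mGy × 5
algorithms {FBP, IR50, DLL, DLM, DLH} — 600 comparisons per reader, 12 000
in total. One response is flagged invalid by default, leaving 11 999, which
mirrors the published study this package's defaults emulate.

## Psychometric model

Detectability as a function of dose is modelled as

    D(d) = ½ (1 + erf(α d^β / √2)) = Φ(α d^β),   α > 0 [1/mGy^β], β > 0,

i.e. a cumulative-Gaussian psychometric function of the transformed dose
α·d^β with a hard 0.5 floor at d = 0 and saturation at 1. The placement of
the √2 inside the erf is a pure reparametrization of α (absorbable by
α → α/√2 against the no-√2 convention); a test verifies that all derived
doses are invariant to it.

**Fitting.** The default target is one point per dose: the pooled
proportion correct over readers, inserts, scans and slices (480 trials per
point in the full design). The objective is unweighted least squares
(equal trials per dose make weighting moot in the balanced design; weights
by n are available for unbalanced data), minimized over (log α, log β) by
bounded L-BFGS-B from a 5×5 multistart grid, α log-spaced in [1e-4, 10],
β in [0.1, 5]; ties between starts are broken toward smaller β. A
trial-level binomial maximum-likelihood mode is provided as an
alternative. Fits where all observed proportions are at or below 0.5 are
flagged non-identifiable.

**Dose reduction.** Curves invert in closed form,
d = (Φ⁻¹(D)/α)^(1/β). The equivalent dose of a test algorithm at a
reference dose d_ref is the dose where the test curve matches the
*fitted* reference curve's detectability at d_ref (not the raw observed
score); the reduction is 100·(1 − d_eq/d_ref) %. Per-dose reductions are
kept unrounded internally; averages over investigated doses are computed
from unrounded values and only report files round to whole percent. Near
saturation (α·d^β ≳ 5.5, D within ~1e-8 of 1) double-precision rounding
of D itself erases dose information, so inversion identities are only
meaningful below that region.

## Paired comparisons

Algorithms are compared per dose with a paired Student's t-test on
per-reader detectability scores — the reader is the pairing unit, giving
n − 1 = 19 degrees of freedom with 20 readers. Differences are reported in
percentage points with t-based 95% CIs; no multiple-testing correction is
applied (comparisons are reported with raw p, as is conventional for this
design's descriptive tables). A zero-variance nonzero-mean sample returns
infinite t with p = 0 and a warning rather than an exception.

## Mixed logistic regression

Trial correctness is regressed on algorithm, dose (continuous, uncentered
mGy) and lesion type, with crossed Gaussian random intercepts for reader
(20 levels) and for the signal-present image unit. The image unit is
defined as the unique dose × lesion type × scan × slice combination (120
levels by default); the exact level count in the original study is not
documented, so it is configurable. Because the two groupings are crossed,
the marginal likelihood does not factor and is evaluated by a Laplace
approximation: random effects are scaled as u = σb with b ~ N(0, I), an
inner penalized IRLS solve finds the joint mode of (β, b) given
(σ_reader, σ_image), and an outer Nelder-Mead maximizes

    ℓ(β̂, b̂) − ‖b̂‖²/2 − ½ log det(Λ'Z'WZΛ + I)

over the two standard deviations. The σ = 0 boundary is smooth in this
parametrization and reduces exactly to ordinary logistic regression (used
as an oracle in tests). Standard errors are Wald, from the fixed-effects
block of the inverse joint penalized Hessian; odds ratios are exp(b) with
CIs exp(b ± 1.96·SE) and two-sided Wald p. Changing the algorithm
reference is an exact linear recoding of coefficients and covariance — no
refit. Random-effects design matrices are sparse; a full-size fit takes
about a second on one core.

Joint-mode profiling of β (rather than optimizing β in the outer loop) is
known to shrink variance components slightly for binary data; simulation
at the default design size shows relative bias under ~10% on the variance
components and under ~1% on fixed effects, which the recovery tests bound.

## Synthetic data generator

Two generative modes mirror the two analysis models.

**Curve mode** draws each response from Ψ(α, β, dose) for the record's
(algorithm, lesion type). The default parameters are anchored to the
published summary of the emulated study: per algorithm, (α, β) are solved
so the curve matches FBP's detectability at the published equivalent doses
for the 5 and 25 mGy anchors, with FBP pooled detectability set to 0.72 at
5 mGy and 0.93 at 25 mGy (the study's aggregate scale). This gives

| algorithm | α (1/mGy^β) | β |
|---|---|---|
| FBP | 0.2302 | 0.5772 |
| IR50 | 0.2929 | 0.5371 |
| DLL | 0.2446 | 0.6051 |
| DLM | 0.3259 | 0.5460 |
| DLH | 0.3902 | 0.5409 |

Per-insert difficulty multiplies α by {0.45, 1.75, 1.45, 1.00} for the
4 mm hyperdense, 6 mm hyperdense, 8 mm hyperdense and 8 mm hypodense
inserts — ordered like the study's adjusted per-insert odds ratios, with
near-unit geometric mean so pooled behaviour stays close to the aggregate
curves. Note that pooling over insert-specific curves is a *mixture* of
Gaussians in α·d^β, not exactly a single curve, so pipeline estimates on
the lesion-scaled default can differ by a few percentage points from the
aggregate-parameter arithmetic; end-to-end recovery tests therefore use a
truth with a shared curve per algorithm, where the average reduction has
a closed form.

**Logit mode** draws responses from the mixed model itself: intercept
ln 0.44, dose slope ln 1.14 per mGy, lesion-type offsets ln 15.6 / ln 8.81
/ ln 4.07 (vs 4 mm hyperdense), algorithm offsets ln 1.44 / ln 1.41 /
ln 2.05 / ln 3.20 (vs FBP) — the emulated study's adjusted odds ratios —
with reader SD 0.5 and image SD 0.3 (log-odds; the study reports no
variance components, these are plausible reader-study magnitudes). No 0.5
guessing floor is imposed in this mode, matching a logistic model of raw
correctness; with the default coefficients predicted probabilities stay
well above 0.5 except for the smallest lesions at the lowest doses.

What the generator does **not** emulate: actual image content and noise
texture, reader learning/fatigue and response latency, non-Gaussian or
correlated reader effects, and any dependence between trials beyond the
two random intercepts. Passing recovery tests therefore demonstrates the
estimators are correct and calibrated under the stated models — not that
the models capture every feature of real reader data.

## Randomness and reproducibility

One user seed (default 20220402) expands into fixed-purpose child streams
(side assignment, presentation order, responses, random effects, invalid
flags) via `numpy.random.SeedSequence` spawn keys, so stages can be rerun
independently and every output is byte-identical for a given config. The
pipeline manifest records a SHA-256 of the canonical key-sorted config
JSON, the seed and each output file's checksum.

## Numerical choices and degenerate inputs

- Curve evaluation uses `scipy.special.ndtr`/`ndtri` (no explicit erf).
- Inversion targets ≤ 0.5 return dose 0 (with a warning below 0.5);
  targets ≥ 1 raise.
- The psychometric optimizer's box is wider (α ∈ [1e-8, 1e3],
  β ∈ [0.01, 10]) than the multistart grid so noisy fits are not pinned at
  grid edges.
- PIRLS re-evaluates the Hessian at the final iterate before inverting it
  for standard errors; step-halving guards each Newton step.
- Coefficients beyond |15| log-odds flag possible complete separation.
- The outer variance search runs on unconstrained σ (the objective is even
  in each σ), reporting |σ|; tolerances 1e-3 on σ and 1e-6 on the
  objective.

## Problem sizes in the shipped tests

Simulation-based tests use the full 12 000-trial design where the property
concerns it (GLMM recovery: 100 replicates; end-to-end dose-reduction
recovery: 100 replicate two-algorithm studies) and scaled-down designs
elsewhere (type-I-error calibration: 2 000 simulated 20-reader single-cell
studies; fit recovery: 200 replicates at 4 800 trials per dose). These
sizes give Monte-Carlo standard errors small enough to detect biases of a
percent or two while keeping the whole suite at a few minutes.
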