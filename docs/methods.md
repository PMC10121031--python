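# Methods

## The observation model

A camera-trap study yields photo events indexed by station, species and
timestamp. Events are first reduced to *independent records*: within each
(station, species) stream a record is kept iff it is the first or falls
strictly more than the independence window (default 60 minutes) after the
last **kept** record. This rolling-window rule is the convention for
unmarked individuals; distinguishing individuals from images is not
attempted, so bursts by different animals of one species at one station are
collapsed too (a known limitation of window-based filters).

Multi-year data are *stacked*: the study span is cut into survey blocks
(default 120 days) anchored at the study start date, and each station ×
block combination becomes an independent site row. Each block is divided
into equal occasions (default 10 × 12 days; the design validates
occasions × occasion-length = block length). Detection is Bernoulli per
occasion — within-occasion counts are collapsed to 0/1 — and occasions with
zero camera effort are missing, not zero. Trailing partial blocks are kept
and padded with missing occasions; site rows with no effort at all are
dropped. The per-occasion effort (0–12 active days, from merged deployment
intervals) is carried alongside the history, and the effort matrix sums
exactly to the reported trap-nights, which keeps the trapping-rate
denominator and the detection model consistent.

## The co-occurrence model

The latent presence pair of the two focal species at a site follows a
four-cell multivariate Bernoulli distribution, parameterised by natural
log-odds parameters f₁, f₂ (each species alone vs neither) and f₁₂ (the
co-occurrence log odds-ratio), each a linear function of z-scored site
covariates. The inverse map to cell probabilities is computed in log space
(log-sum-exp), so extreme linear predictors cannot overflow; the forward
and inverse maps are exact inverses and the four cells always sum to one.
f₁₂ = 0 is exactly the independence model ψ₁₁ψ₀₀ = ψ₁₀ψ₀₁, and fixing it at
zero gives the independence null used to test for spatial association.

Detection is logit-linear per species with an intercept plus optional
covariates; survey effort enters as a z-scored occasion-level covariate
(standardised over observed cells), not as an exposure offset, matching how
effort is usually treated as a candidate detectability covariate in this
literature. The site likelihood marginalises the latent state: given
presence the occasion products of pᵞ(1−p)¹⁻ᵞ apply, given absence a history
is possible only if it is all zeros. The implementation is vectorised over
sites and verified in the tests against brute-force latent-state
enumeration to 1e−12.

**Fitting.** L-BFGS-B on the negative log-likelihood (ftol 1e−11) from a
zero start plus optional seeded random restarts; restarts matter mainly for
small data where the likelihood can be multimodal or have boundary optima
(e.g. f₁₂ → ∞ when the rarer species is never seen alone — reported, not
suppressed). Standard errors come from the inverse of a central-difference
observed information matrix at the MLE; a singular information matrix
leaves them NaN and flags the coefficients as undefined rather than
guessing. Wald intervals use z = 1.96 exactly at the 95% level so printed
two-decimal intervals reproduce field-report rounding; a covariate is
"important" when its interval excludes zero.

**Model selection.** Candidate models carry at most one occupancy covariate
per natural parameter (an anti-overparameterisation rule for sparse felid
data). The staged builder mirrors common practice: all single-covariate
occupancy structures per species first, then detection covariates on the
best occupancy structure, then co-occurrence covariates, the f₁₂ = 0 null
and the all-constant null. Covariate pairs with Spearman |ρ| ≥ 0.7 are
barred from sharing a model (skipped with a logged reason). Non-converged
fits are excluded from the AIC table; AIC ties break by fewer parameters,
then label; Akaike weights are normalised over the converged set and
models within ΔAIC < 2 are flagged as supported.

## Temporal overlap

Clock times map to radians (24 h = 2π; naive local clock time, no
solar-time or DST arithmetic). Each species' activity density is a von
Mises kernel estimate whose concentration is the standard plug-in rule
ν = [3nκ̂²I₂(2κ̂)/(4√π I₁(κ̂)²)]^{2/5}, κ̂ the ML von Mises concentration of
the sample (capped at 500 for degenerate samples), times a bandwidth
multiplier (0.8 for Δ̂₁, 1.0 for Δ̂₄, the convention of the estimators'
source literature). Densities are evaluated on a 128-point grid and
integrate to 1 on the circle to 1e−6 by wraparound trapezoid.

The coefficient of overlap Δ is the integral of the pointwise minimum of
the two densities. Δ̂₁ computes that integral on the grid and is used when
either sample has fewer than 75 records; Δ̂₄ averages min(1, f̂ⱼ/f̂ᵢ) over the
pooled observed times and is used otherwise; both are always reported.
Confidence intervals come from smoothed bootstrap resampling (a resampled
data point plus von Mises kernel noise), default 10,000 draws, reported as
the basic (reflected percentile) interval 2Δ̂ − q, clipped to [0, 1], with
the raw percentile interval alongside. The activity level is
1/(2π·max f̂) — 1 for uniform activity, → 0 for concentrated activity —
with a smoothed-bootstrap SE; two levels are compared by a Wald statistic
referred to χ²₁. The randomization test draws both samples from the kernel
fitted to the pooled data and counts how often the null overlap is ≤ the
observed one (ties count; a sample compared with itself therefore has
p = 1). Because the evaluation grid is fixed, rotation of both samples
leaves all statistics invariant only up to grid discretisation (≲1e−3 on
Δ̂), which the tests account for.

## The synthetic generator

`camcooccur.synth` emulates a small semi-arid ranch survey: 24 stations,
eight 120-day survey blocks from 2018-08-01, station covariates (percent
tree cover, distance to water, distance to plantation) drawn from truncated
normals whose *realised* moments match the emulated survey's summary table
— the parent (μ, σ) are solved for, because truncating a normal
parameterised by the reported moments would shift the mean. Latent
presence is drawn per station × block (closure within a block, independence
across blocks — the stacking assumption made explicit) from the four-cell
model with defaults: tree-cover slope 3.14 on f₁, plantation slope −0.88 on
f₂, constant co-occurrence log odds-ratio 2.56, and occupancy intercepts
(0.449, −2.087) solved once so the mean marginal occupancies are 0.62 and
0.43 under the covariate distribution. Detection defaults give mean
per-occasion probabilities ≈0.22 and ≈0.10 with a water-distance effect
(+0.27 and −0.80 on the logit; the negative jaguarundi slope keeps the
documented sign but a moderate magnitude, since the printed estimate for
that effect is internally inconsistent with its own interval). Two domestic
species are simulated as independent single-species occupancy processes
(ψ, p) = (0.45, 0.13) and (0.35, 0.15).

Cameras are deployed per station × block with probability 0.4 and each
occasion fails to a shortened effort with probability 0.15 (uniform 0–11
days), giving ≈8,500 trap-nights and record counts of the emulated study's
order. Photo timestamps follow per-species von Mises mixtures — a mostly
nocturnal tiger cat, a strictly diurnal jaguarundi, a cathemeral dog, a
largely nocturnal domestic cat — whose true pairwise overlaps are
0.47/0.73/0.90/0.71/0.49. Sub-hour duplicate bursts are injected so the
independence filter has real work; event times are arranged so that
filtering and re-binning the records reproduces the generated detection
matrices *exactly* (a tested round-trip), which pins the whole ingestion
path. Everything flows from one seeded generator.

What the generator does **not** emulate: spatial autocorrelation of
covariates or occupancy, animal movement and home-range structure,
individual heterogeneity in detection, seasonality of activity, and
sun-anchored (rather than clock-anchored) diel timing. Passing tests
therefore validate the estimators under the stated model, not robustness
to these violations.

## Problem sizes and numerical choices

The test suite and the acceptance script scale Monte-Carlo work to keep
runs reproducible on one CPU: parameter-recovery uses 200 replicates of 500
full-effort sites (observed bias < 0.03, 95% Wald coverage 0.91–0.97);
null calibration of the randomization test uses 50 repeats of 200
iterations; bootstrap examples use 150–2,000 draws against the 10,000-draw
default. The acceptance script estimates occupancy quantities from an
enlarged synthetic replicate (240 stations, ≈770 sites) because at the
24-station study scale the co-occurrence log odds-ratio is occasionally a
boundary estimate (the rarer species never observed alone), exactly as
small real studies experience; activity quantities use the study-scale
record table so sample sizes (and hence the Δ̂₁ estimator choice) match the
emulated survey. AIC differences scale with site count, so the independence
model's ΔAIC is reported at the size that produced it. Tolerances worth
knowing: ψ normalisation 1e−10, likelihood-vs-enumeration 1e−12, kernel
integral 1e−6, grid-stability of Δ̂₁ under 128→4096 refinement < 0.005.
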