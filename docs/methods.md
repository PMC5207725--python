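# Methods

## Model

Parent-compound loss from the exposure medium is modelled as first-order:
C(t) = a·e^(−k·t), with a the time-zero concentration (µg/L) and k the
depletion rate constant (h⁻¹); t½ = ln 2/k. The fit is an unweighted
nonlinear least squares over *individual wells* (not per-time-point means):
replicate scatter carries information about measurement error, and the
balanced design means both choices give the same point estimates on average.
k is constrained non-negative by bounded least squares — negative depletion
has no biological meaning in a sealed plate, and apparently negative slopes
are the business of the NSD classifier, not the fitter. Initialisation:
a₀ = mean time-zero concentration; k₀ = −slope of ln(mean concentration)
vs. time over time points with positive means, floored at 10⁻⁶; a fixed
fallback k₀ = 0.01 h⁻¹ is tried if the first start fails. The standard error
of k is taken from the fit covariance; percent depletion is
100·(1 − C̄(end)/C̄(0)) over exposure-well means and may legitimately be
negative on noisy null data. Goodness of fit beyond convergence and the
reported residual sum of squares is deliberately not enforced: depletion
curves in this assay are near- but not perfectly first-order, and rejecting
fits on RSS would silently censor slow metabolisers.

Extended incubations (48–72 h, used when nothing depletes by 24 h) are
supported by reading the incubation end from the data rather than assuming
24 h.

## NSD classification

The assay's "no substrate depletion" (NSD) call has no published numeric
criterion, so the package defines one and exposes its alpha (default 0.05):
a compound/fish is NSD when **either** (a) the one-sided Wald test of k > 0
(t = k/SE(k), n−2 df) fails, **or** (b) the exposure-well endpoint
concentrations are not significantly below the cell-free medium-control
endpoint concentrations (one-sided Welch test) — i.e. observed loss does not
exceed abiotic loss. Without medium controls the classifier falls back to
criterion (a) alone and logs a warning. The OR of two tests is deliberately
conservative: its false-depletion rate under a true null is *below* alpha
(measured ≈ 99% NSD on simulated null fish at alpha = 0.05), while the
fallback path alone is a single calibrated test whose type-I error sits
inside the binomial 99% band around alpha at 1000 simulated replicates.
Calibration is therefore asserted on the fallback path, and only a ≥ 90% NSD
rate on the full criterion.

No loss-to-plastic or evaporation correction is applied: plates are sealed
in this design, and medium controls are used only for NSD gating.

## Clearance scaling

Two modes are explicit rather than silently "fixing" the published formula:
`paper_literal` divides k by cell number per well (the formula as published,
dimensionally loose); `volume_corrected` uses the standard k·V/N substrate-
depletion scaling. Their ratio is exactly the well volume in mL (0.075).
Defaults: 500 cells/spheroid × 100 spheroids/well = 50,000 cells/well.
Hepatic extrapolation multiplies by hepatocellularity, a *parameter*, not a
constant: 91×10⁶ cells/g (spheroid-derived, trout) vs. 120×10⁶ cells/g
(human literature); the trout figure *replaces* the human one in the trout
pathway rather than compounding it. Literature conversions: µL min⁻¹ mg⁻¹ S9
× 0.06 × 50 mg/g; µL min⁻¹ (10⁶ cells)⁻¹ × 0.06 × hepatocellularity/10⁶;
all conversions are exactly invertible and round-trip to ≤ 10⁻¹² relative
error. Published trout-spheroid hepatic clearance figures for propranolol
and diclofenac (54.0 and 49.8 mL h⁻¹ g⁻¹) cannot be reconstructed from the
stated mean rate constants under either mode (paper-literal gives ≈ 40.0 for
k = 0.022 h⁻¹); the package documents both modes and leaves that gap as a
property of the source data, not something to be tuned around.

## Cohort statistics

Cohort aggregates are arithmetic means and sample SDs (n−1) over non-NSD
fish; the mean half-life is the mean of per-fish half-lives, not ln 2 over
the mean k (Jensen's inequality makes these differ materially at this
spread). Inter-individual differences are tested on ln(per-well % depletion)
— each endpoint well expressed against its fish's time-zero mean — with
one-way ANOVA and Tukey HSD (Tukey–Kramer on unbalanced data; the design
itself is balanced at 6 wells/fish). Letters are assigned by
insertion–absorption: start from one column holding all fish, split each
column on every significant pair, absorb subset columns, then letter the
columns in decreasing order of group mean (ties broken by fish id). The
resulting columns are exactly the maximal cliques of the non-significance
graph, so two fish share a letter iff their adjusted difference is not
significant — an identity the implementation re-checks on every run and the
tests verify against a brute-force clique oracle over all 4-group
significance patterns.

A note on power: with twelve fish at the observed means ± sds, the slowest
fish's nearest neighbour sits close to the Tukey critical difference, so
although the slowest fish always separates from the fast half of the cohort,
*complete* isolation (no shared letter with any fish) occurs in roughly 70%
of resampled cohorts, not always. The test suite asserts the majority rate
and the always-separated property rather than certainty.

## Synthetic data

The generator reproduces the plate design: per time point
{0, 0.5, 1, 2, 4, 24} h, six exposure wells (spheroids + drug), three
solvent controls (spheroids, no drug — emitted at concentration 0 so real
exports with that layout parse), three medium controls (drug, no spheroids,
decaying at the abiotic loss rate, default 0 for sealed plates). Per-fish k
is lognormal, moment-matched to mean 0.022 and SD 0.010 h⁻¹ — positivity by
construction, matching a cohort reported only as mean ± SD; time-zero
concentration is Normal(98, 4) µg/L; measurement error is multiplicative
lognormal with unit mean and CV 0.10, reflecting signal-proportional LC-MS/MS
error (no noise model is published; this choice also makes negative
concentrations impossible, so no truncation is needed). The acetonitrile
quench is treated as sampling termination, not dilution: concentrations are
on the exposure-medium scale. Reproducibility contract: one root seed;
per-fish substreams keyed by SHA-256 of (seed, fish_id), so fish i's data is
byte-identical regardless of cohort size; identical seed + config gives
byte-identical output.

What the generator does *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: deviations from strict first-order
kinetics (the real curves are only approximately exponential), metabolite
formation, spheroid size/viability heterogeneity, well-position effects, and
non-multiplicative error at the quantification limit.

## Problem sizes and numerical choices

Recovery runs use 200 simulated fish (SEM of mean k ≈ 0.0007 h⁻¹, tight
enough to resolve the 0.022 target); null-calibration runs use 1000
replicates (binomial 99% band ± 0.018 around alpha = 0.05); Tukey resampling
uses 200 cohorts. Reported tables round k to 3 decimals and t½/% to 1
decimal, matching the assay's reporting convention; full precision is kept
internally and in CSVs. CSV floats are re-read with round-trip precision so
write→read is exact. Degenerate inputs: k_sd = 0 collapses the lognormal to
a point mass; CV = 0 gives exact noise-free curves (recovery to numerical
precision); zero-variance endpoint comparisons fall back to a direct mean
comparison in the Welch guard.

## Read-across

A compound's read-across prediction is concordant when its human
extensive-metabolism status (≥ 50% of dose metabolised; all packaged
compounds sit at 6% or ≥ 99%, far from the threshold) equals the observed
trout depletion outcome. The alternative mechanistic reading — predicting
from CYP ortholog presence — is exposed separately as a flag marking
compounds whose major human CYPs are absent in trout (CYP2D6 has no trout
ortholog), rather than conflated with the concordance score.

## Known limitations

Single-compound wells only; no Michaelis–Menten or biphasic models; no
binding correction (fu) or liver blood-flow model, so hepatic intrinsic
clearance is not whole-body clearance; the read-across table covers the
seven packaged compounds and is not a general CYP-abundance model.
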