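# Methods

## Compositions and coordinates

A participant-day is the 960-min window 07:00–23:00. Epoch-level ENMO
(‖a‖ − 1 g, truncated at zero, in mg) is classified into nine bands with
lower-inclusive, half-open intervals: [0, 50), [50, 100), …, [300, 350),
[350, 700), [700, ∞). The lower-inclusive convention is a package decision —
band descriptions like "50–100 mg" do not pin the boundary — chosen so the
closed lower bound of the "≥700 mg" top band is the same rule as every other
band. Band minutes are exact epoch counts × epoch length / 60, never rounded
before reporting. Per-band minutes are averaged over valid wear days and
closed (rescaled) to 960 min; closure also absorbs partial wear, since
non-wear imputation belongs to the upstream device pipeline and is out of
scope.

Wear validity: a day is valid at ≥ 600 worn minutes within the window; a
participant is retained with ≥ 3 valid days and post-calibration error
≤ 10 mg. Screening is applied within the 960-min window (whether a 24-h
protocol should count wear outside it is ambiguous; we standardise on the
window the compositions are built from).

Log-ratio transforms need strict positivity. Zero band durations (possible in
the high-intensity bands) receive a pseudo-duration of 0.5 s (1/120 min)
before closure — far below the 1-min reporting resolution — exposed as a
config knob (`zero_pseudo`), since no canonical zero-replacement rule exists
at this scale.

Pivot coordinates: for D parts ordered with a lead part first,
z_k = √((D−k)/(D−k+1)) · ln(x_(k) / gm(parts after k)). The first coordinate
satisfies z₁ = √(D/(D−1)) · clr_lead and is invariant to the ordering of the
remaining parts; we fix that ordering to original band order (lead moved to
front) purely for reproducibility. The basis rows are orthonormal in clr
space (tested to 1e−12).

## Regression and the pivot scan

OLS of BMI z-score on the eight ILR coordinates plus covariates. Covariate
coding (a package decision; the choice is config-visible and keeps every
design full-rank): girl indicator; school-mean-centred age, continuous; EIMD
decile, continuous 1–10; device model, two indicators against a reference
level; sampling frequency, 30-Hz indicator. CIs and p-values use the t
distribution at residual df. No multiplicity correction is applied across the
nine rotations; the nine tests are views of one fitted surface, and users
should interpret them jointly.

Identities used as oracles: the nine rotations share a column space, so
fitted values agree to numerical precision and Σⱼ β_ILR1⁽ʲ⁾ = 0 exactly. A
published per-band table of first-pivot coefficients therefore must sum to
zero up to rounding when the nine fits use identical rows; a table that does
not is flagged rather than reverse-engineered.

The omnibus F compares the full fit with the covariates-only fit
(df1 = 8, df2 = residual df of the full model) and is rotation-invariant.
Where the sex coefficient is significant at α = 0.05 (configurable), the scan
is rerun within each sex with sex dropped from the covariates. Diagnostics:
VIF = 1/(1−R²) per column (intercept participates in the auxiliary
regressions but is not scored), and a one-way random-effects school ICC,
(MSB − MSW)/(MSB + (n₀−1)MSW) with the ANOVA-harmonised mean group size n₀,
negative estimates truncated to zero; schools with a single member are
dropped from the ICC, carrying no within-school information.

## Isotemporal substitution

One-for-remaining reallocation: band j gains t minutes, each other band loses
t/(D−1); totals are conserved exactly and the operation is inverted by −t.
The baseline is the analysed stratum's geometric-mean composition
(configurable). Predicted differences are computed in coefficient space —
Δ = β·(ilr(new) − ilr(base)) — which provably equals the brute-force
difference of two predictions with identical covariates (tested to 1e−10).
The CI is the delta-method linear-combination interval at the residual-df t
quantile; t-based rather than normal-based is a package decision (the two
differ negligibly at n ≈ 1500, and a 100k-draw parametric simulation from
the coefficient covariance agrees with the interval within 0.005 per bound
in the test suite). The negative arm is bounded by the maximum-reallocation
rule "leave at least 1 min in the band", i.e. t_max = ⌊band time − 1⌋, the
rule consistent with both published anchors (11.1 → 10, 6.3 → 5); the floor
is configurable.

## Synthetic cohorts

The generator emulates a pooled school-based study: n = 1803 roster, 57.5 %
girls, 63 schools with Dirichlet-weighted sizes, two school phases (66.3 %
primary) driving age (primary N(9.0, 1.9), secondary N(13.4, 1.5) years,
giving overall ≈ 10.5 (2.6)), EIMD deciles skewed low (deciles 1–5 carry
67.4 %), three device models (0.7/0.2/0.1) and a 30-Hz share of 20 %
independent of model.

Compositions are independent log-normal per band around sex-specific target
geometric means (the published per-sex nine-band rows), then closed; the
empirical geometric-mean composition converges to the closed target by
construction. The per-band log-SD profile (0.05 … 0.45, increasing with
intensity) is a package choice of plausible spread — the real log-ratio
covariance is not printed in the source tables, so covariance realism is
explicitly not an acceptance dimension.

The outcome is linear in clr coordinates: y = α_sex + a_sex·clr(x) +
γ_SES·decile + ε. Default effect vectors a_sex invert the published per-band
first-pivot coefficients through β_ILR1 = √(9/8)·a, centred to sum to zero;
γ_SES = −0.02 per decile. Intercepts are set analytically so per-sex outcome
means hit 0.53/0.49, and the noise SD is derived in closed form (independent
log-normal parts make var(a·clr x) = Σ aⱼ²sⱼ²) so the marginal outcome SD
hits 1.24; with the defaults this gives noise SD ≈ 0.95. Because Σa = 0,
closure and centring cancel and OLS on any pivot basis is unbiased for
√(9/8)·aⱼ — the foundation of the recovery and coverage tests. Missingness
removes exactly the configured counts (67 outcome, 233 wear, 50 SES) from
disjoint random records, in cascade order.

Epoch streams apportion band minutes to whole 1-s epochs by largest
remainder (preserving the 57,600-epoch day exactly), draw ENMO uniformly
within each band, and shuffle; banding inverts a stream to within 1/60 min
per band. The generator does not emulate device noise, diurnal profiles,
autocalibration drift, or correlated log-ratio structure — so passing tests
certify the statistical machinery, not the realism of any particular cohort.

## Exclusion cascade

Fixed order: missing outcome → failed wear screening → missing deprivation
decile, each stage counting only survivors of the previous one; this is the
only order under which the published stage counts reconcile
(1803 − 67 − 233 − 50 = 1453), and the roster identity
N_roster = N_retained + Σ counts is asserted. BMI z-score and EIMD decile are
consumed as given; growth-reference and postcode machinery are out of scope.

## Problem sizes and numerical choices

Simulation studies in the tests and acceptance script use 200 replicates at
n = 1500 for CI coverage, 1000–2000 replicates at n = 500 for the omnibus
type-I error, and 100,000 coefficient draws for the substitution-interval
check — sizes at which the Monte-Carlo error is well below the asserted
tolerances while the whole suite stays interactive. Round-trip tolerances:
basis orthonormality 1e−12, ilr round trips 1e−9 relative, rotation
invariance 1e−8 absolute on fitted values. All rounding (1–2 dp) happens in
the reporting layer only.

## Known limitations

Fixed-effects covariate adjustment only (no mixed models or cluster-robust
errors — defensible when the school ICC is small, as it is by construction
here); one-for-remaining reallocations only (no pairwise or grouped
substitutions, no 24-h compositions including sleep); no multiple-imputation
machinery; band-boundary and zero-replacement conventions are decisions, not
estimates, and can shift results for data concentrated at band edges or with
many empty high-intensity bands.
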