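# Methods

## The indices

### Carceral Resource Index

A city-year budget is a set of departmental appropriation lines. Each
line is assigned to exactly one of five categories — carceral, health,
support, excluded, other — and

CRI = ((health + support) − carceral) / total,

where *total* sums all five categories. The index is a ratio of
appropriations, so it is dimensionless, bounded in [−1, 1], invariant
under currency rescaling (hence under inflation adjustment), and moving
an amount δ from a carceral line to a health line raises it by exactly
2δ/total.

Classification is deterministic: case-insensitive substring matching of
the normalized department name against an ordered pattern lexicon,
longest pattern first, ties broken by lexicon order. The packaged
default lexicon encodes the category definitions above (public defense
is deliberately carceral: it is situated within court/law-enforcement
spending in city budgets). There is no general rule for departments that
straddle the carceral and health/support systems beyond the four named
exclusions — medical examiners, environmental protection, child and
family services, education — so new ambiguous departments should be
resolved with the per-line `category_override` column, which always wins
over the lexicon and is recorded in the classification audit trail.
"Excluded" and "other" behave identically in the formula (denominator
only) but are logged separately for auditability.

Amounts are exact decimals from ingest through aggregation; division
happens in floating point only inside `compute_cri`, and invariants are
checked at 1e-12. Inflation factors (for cities whose adopted budget is
only available for an adjacent year) are required configuration inputs
with the provenance left to the analyst; no price index is hard-coded.

### Index of Concentration at the Extremes

ICE = (A − P)/T for a privileged count A, deprived count P, and
denominator T. The seven variants map onto census-style tables:
household income (>$100k vs <$25k, denominator all households),
educational attainment of adults ≥25 (≥4 years college vs less than high
school), race/ethnicity (white non-Hispanic vs Black non-Hispanic,
denominator total population), race×income (white non-Hispanic >$100k vs
Black <$25k), race×income with "people of color" deprived (all <$25k
minus white non-Hispanic <$25k), and the two analogous homeownership
variants on occupied housing units. The denominators intentionally
differ across variants — each is the universe of its source table — so
values are comparable within a variant across cities, not across
variants.

Missing tables propagate as missing values, never zeros: a city without
crime data is excluded from crime analyses only (complete-case per
model), and a model whose exposure is entirely missing is skipped with a
logged reason.

Income brackets finer than the three analysis bins may be aggregated at
ingest (`coarsen_income_bins`); only the <$25k and >$100k extremes enter
any statistic.

## Statistical analysis

Bivariate screens correlate each covariate and ICE variant with the CRI.
The method is Pearson's r when both variables pass Shapiro–Wilk at
α = 0.05 and Spearman's ρ otherwise; four variables (age ≥65 share,
property crime rate, ICE-income, ICE-education) are treated as Gaussian
a priori via an override list, which is study configuration, not a data
decision. Degenerate inputs (ties, n < 3 effective) fall back to
Spearman conservatively.

Regression models are ordinary least squares of CRI on the z-scored
exposure (sample SD, divisor n−1, computed within each model's
complete-case rows), optionally its square, and raw-scale covariates.
Raw (non-orthogonal) polynomial terms are used so the linear and
quadratic coefficients are separately interpretable; p-values are
two-sided from the t distribution with residual degrees of freedom, and
no multiple-testing correction is applied. Default adjustment sets:
age ≥65 and non-Hispanic-White shares for the income-ICE model; those
plus the >$100k share for the education-ICE model; age ≥65 only for the
combined race+income models (race and income are already part of those
exposures). All sets are overridable in configuration. Rank-deficient
designs raise an error naming the dependent columns (identified from the
null-space singular vectors).

Diagnostics per fit: (fitted, residual) pairs; normal-probability
quantile pairs of the residuals; and a curvature indicator — the slope
and p-value of residuals regressed on squared fitted values. Note the
indicator has low power when the fitted values are nearly constant
(e.g. a pure quadratic with no linear term under a symmetric exposure);
it supplements, not replaces, refitting with the quadratic term.
Partial residuals for the exposure add the fitted linear (+ quadratic)
exposure contribution back onto the residuals.

The cohort summary splits cities at the median CRI; ties and (for odd n)
the median city go to the "equal or below" stratum. IQRs use linear
interpolation between order statistics by default; the rule is
configurable because at n = 50 reported precision is insensitive to it.

## Synthetic cohorts

The generator emulates the *structure* of a 50-city cross-sectional
study: per city a budget ledger, five count tables, and prior-year crime
counts, with a planted quadratic link from the z-scored white/Black+income
ICE to the CRI. Causality runs demography → budget, matching the
analysis DAG: demographics are drawn first, the realized ICE is z-scored
across the cohort, the target CRI is drawn from

cri = β₀ + β₁·z + β₂·z² + σ·ε,  ε ~ N(0, 1),

and the ledger is back-solved so that classifying and aggregating it
reproduces the target: with a sampled non-numerator share q (other +
excluded), the carceral share of the total is ((1−q)−cri)/2 and
health+support ((1−q)+cri)/2, split across pool-drawn department names
and rounded to cents. Targets beyond min(0.99, 1−q) in magnitude are
clipped and counted; explicitly requested infeasible targets raise. The
truth table records the ICE variants and the realized (post-rounding)
CRI, recomputed inside the generator with inline arithmetic, so
round-trip tests compare two independent code paths.

### Default parameters and calibration

- **Link**: β₀ = −0.59 (a carceral-leaning baseline at the magnitude of
  observed large-city medians), β₁ = 0.47, β₂ = 0.58 (the magnitude of
  adjusted race×income estimates reported for large-city cohorts),
  σ = 0.25. σ was calibrated once so that refitting the quadratic model
  on default cohorts attains adjusted R² ≈ 0.30; with these defaults the
  clipping frequency is ≈ 0.2%.
- **Privilege structure**: each city receives a latent privilege score
  u ∈ [0, 1]; cohorts contain a fixed 30% quota of "deprived-tier"
  cities (u ~ Beta(60, 180), mean 0.25) with the rest "privileged-tier"
  (u ~ Beta(216, 84), mean 0.72). The two-tier mixture reproduces the
  strongly left-skewed, short-right-tailed city ICE distributions seen
  in large-city cohorts (a cluster of deeply segregated cities below a
  privileged majority), and it bounds the variance of the planted
  quadratic signal so that a CRI constrained to [−1, 1] can
  simultaneously carry the default coefficient magnitudes and an
  adjusted R² near 0.3. The quota (rather than independent Bernoulli
  tiers) keeps the exposure's sample moments stable across cohorts;
  independent assignment is available via `tier_assignment="random"`.
- **Tables**: cell probabilities interpolate linearly in u between a
  deprived and a privileged profile (chosen so ICE variants span ranges
  comparable to published large-city interquartile ranges, e.g.
  white/Black+income ICE from ≈ −0.06 in the deprived tier to ≈ 0.14 in
  the privileged tier), then counts are drawn Dirichlet-multinomial with
  concentration 8000 — city-level aggregates are precise, so
  overdispersion is mild. Age bands use fixed base probabilities
  (0.135, 0.648, 0.217); the elderly share is deliberately at the high
  end of published city summaries, whose age denominators are ambiguous,
  and the under-18/≥65 proportions are computed over total population.
  Populations are log-uniform on 390k–4M; households are 0.39 per
  capita; adults ≥25 are 66% of population.
- **Crime**: violent and property rates are lognormal around medians 719
  and 3920 per 100,000 with a mild negative dependence on privilege;
  counts are Poisson at those rates, dated to the year before the budget.
- **Budgets**: totals of roughly $0.8–15B, non-numerator share 2.5–13%
  of the total. Real city budgets devote larger shares to general
  government; the small "other" share here keeps the full CRI range
  feasible and is a deliberate stylization.

A single seed expands into per-city substreams (`SeedSequence.spawn`),
so cohorts are bit-reproducible and a city's draws do not depend on how
many cities precede it.

### What passing tests do and do not show

The generator produces exactly the tabular structures the ingest layer
reads, with a known link; recovery and calibration tests therefore
validate the *estimator and pipeline plumbing* — unbiased coefficient
recovery, nominal CI coverage and test size, exact noiseless round
trips — under the generator's assumptions. Real data differ in ways the
generator does not emulate: free-text department names that defeat the
lexicon (requiring overrides), ACS sampling error and margins of error,
spatial correlation between cities, within-city heterogeneity,
multi-year budget dynamics, and ICE distributions not composed of two
privilege tiers. Passing tests say nothing about those.

## Problem sizes

Monte-Carlo suites use 500 cohorts of 50 cities for parameter-recovery
and coverage checks and 1,000 cohorts for null calibration of the
quadratic test; formula oracles use 1,000 random ledgers/tables. These
sizes give Monte-Carlo standard errors of about 1% on coverage and
rejection rates, sufficient for the ±2% tolerances asserted.

## Known limitations

- The lexicon is a reproducible proxy for expert hand-coding; it cannot
  resolve genuinely ambiguous departments and does not parse budget
  documents (PDFs) — ledgers must already be tabular.
- Municipal appropriations only: county/state/federal flows, and police
  overtime hidden in shared line items, are out of scope.
- The analysis is cross-sectional and associational; no causal claims,
  no spatial-correlation corrections, no ACS margin-of-error handling.
- The quadratic-on-z specification is the only nonlinearity modeled.
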