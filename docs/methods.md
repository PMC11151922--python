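# Methods

## The invariability partition

The package analyses the temporal stability of a metacommunity variable
observed as a dense nonnegative tensor `x[u, k, t]` (unit × site × year).
Stability is temporal invariability, the reciprocal of the coefficient of
variation CV = temporal SD / temporal mean. Four weighted CVs are formed,
one per cell of the organizational-level × spatial-scale grid (see the
README for the formulas); the weighting — component SDs are summed and
divided by the single regional mean μ — makes adjacent CVs differ only in
where the aggregation happens (inside or outside the SD), so each
synchrony index is exactly the ratio of two adjacent CVs. Two conventions
exist in the synchrony literature; we report the CV-ratio (square-root)
scale by default because it is the only scale on which the multiplicative
identities CV_C,R = CV_C,L·Ψ_C,L→R and CV_C,L = CV_S,L·Ψ_S→C,L hold
exactly, and expose the variance scale (the squared ratios) behind
`synchrony_scale="variance"` for comparison with variance-ratio indices.

Temporal SDs use the sample (n − 1) denominator. With only two years —
the minimal design the package must support — the sample SD reduces to
|x₁ − x₂|/√2, and synchrony ratios degenerate gracefully: a spatial
synchrony of 1 simply means all sites moved the same direction between
the two years.

Degenerate cases are handled so that batch runs over four variables never
abort on one: an all-zero tensor or nonpositive regional mean is an
error; a 0/0 synchrony (every component series constant) is reported as 1
with a `degenerate` flag; a zero CV maps to infinite invariability, also
flagged. A nonzero-over-zero synchrony cannot occur because an
aggregate's SD is bounded by the sum of its parts' SDs.

## Aggregation rules

Survey tables are long-format CSVs keyed by year/round/site/subplot (and
species). Duplicate keys are summed, not rejected — field sheets
legitimately split one observation across rows — and the merge count is
logged. Subplots and within-year rounds are collapsed to one value per
unit-site-year; `annualize="sum"` (default) totals the rounds,
`annualize="mean"` divides that total by the number of distinct rounds.
The unit universe is global: a species or plant–pollinator pair absent
from a site-year is a true zero abundance there, which is what makes the
regional sums well defined over a fixed unit set.

Fruit set is the exception: an unmeasured plant-site-year is unknown, not
zero. Those cells are masked, and the partition runs on the complete-case
unit subset (plants observed in every site-year), with the number of
dropped units recorded in the result. Fruit set per population is pooled
(total fruits / total flowers marked) by default; an unweighted mean of
individual proportions is available as `individual_mean`.

Visitation is left as raw visit totals per site-year by default, on the
assumption of constant census effort across rounds and sites; a
per-flower rate (visits divided by the site-year flower total) is
available via `StudyConfig(visits_per_flower=True)` when effort or floral
display varies.

## Taylor's power law

Across the units of a hierarchical level (population series, community
totals, or both pooled for the "region" level), the scaling of temporal
variability with mean abundance is summarized by an OLS fit on log₁₀
axes. The default regresses log SD on log mean, so b = 0.5 is the
variance-linear-in-mean (Poisson-like) benchmark, b = 1 is constant CV,
b = 0 constant SD, and negative b (variance shrinking with abundance) is
allowed and simply reported. The alternative `var_vs_mean` convention
regresses log variance and reports the slope as-is (linearity then reads
as slope 1); outputs record which convention produced them. Series with
zero mean or zero SD have no log-log coordinate and are excluded with a
count; fits need at least three usable units.

## The synthetic metacommunity generator

The generator emulates the sampling design the I/O layer expects — M
sites surveyed over R rounds per year for T years, S plant species, A
pollinator species, counts scattered across subplot bins — with ground
truth known by construction:

- **Fluctuations** are log-scale Gaussians with exchangeable correlation:
  `rho_species` between species within a site, `rho_spatial` between
  sites within a species. They are realized by a four-component factor
  model (common + site + species + residual) whose cross-site
  cross-species correlation is the product of the two, the unique
  separable choice with nonnegative weights for ρ ∈ [0, 1). Large-T
  synchrony targets are closed-form on the log scale —
  Ψ_S→C,L → sqrt((1 + (S−1)ρ)/S) for equal-SD species, the spatial
  analogue with (M, rho_spatial) — and slightly attenuated after
  exponentiation and rounding; recovery tests therefore use moderate
  log-scale SD (0.3) and an absolute tolerance of 0.05.
- **Mean–variance scaling**: species means are log-uniform on
  `mu_range`, and each species' log-scale SD is set so abundance SD ≈
  c·mean^`taylor_b` (exact for small SDs). Counts come from rounding the
  continuous abundances by default, preserving the target exponent;
  `count_mode="poisson"` instead draws each species-site annual count
  i.i.d. Poisson around a constant rate, which pins temporal variance to
  the mean (b = 0.5) by construction and is the mode used for the
  scaling benchmark.
- **Visits** follow pollinator-specific Dirichlet preferences over plants
  (concentration → ∞ gives generalists), scaled by flower counts, a
  per-flower visit rate, and a lognormal yearly activity fluctuation;
  realized visits are Poisson. Summing the visit table over pollinators
  reproduces the plant-level visitation marginal exactly.
- **Fruit set** responds to visits per flower v through a saturating
  (Michaelis–Menten) curve fs = fruitset_max·v/(v + halfsat). This
  parametric form is a modeling choice of the generator, not an
  empirical claim; no field-calibrated visitation→fruit-set curve is
  implied. Individuals get logit-normal noise around the expectation, a
  Poisson number of marked flowers, and binomial fruits — so fruits
  never exceed flowers marked.

All randomness descends from a single integer seed through named
substreams (flowers, visits, fruit set), so each stage is independently
reproducible.

Default parameters mirror a Mediterranean shrubland design: 5 sites, 2
years, 8 rounds, 8 plant species, 12 pollinator species, species mean
annual flower counts 5–200, ρ_species = 0.3, ρ_spatial = 0.5, taylor_b =
0.5, 10 marked individuals per plant-site-year with ~20 flowers each.
Counts are scattered over 20 subplot bins rather than a full 400-cell
grid purely to keep tables compact; site-round sums, and hence every
downstream statistic, are unaffected.

What passing tests do and do not show: the generator has no population
dynamics (no density dependence, competition, or phenology), its spatial
structure is exchangeable rather than distance-based, and its
fruit-set link is an assumed saturating curve. Recovery of the
closed-form synchrony and scaling targets validates the *estimators*
under known conditions; it says nothing about whether real communities
satisfy those conditions.

## Numerical and scope choices

- Recovery benchmarks use T = 200 years, M = 1 site, 20 seeds for
  synchrony (grid S ∈ {2, 5, 10} × ρ ∈ {0, 0.3, 0.8}) and T = 50 years,
  30 units, 10 seeds for the Poisson scaling exponent — sizes at which
  Monte-Carlo error is comfortably inside the stated tolerances while the
  whole suite runs in seconds.
- Oracle equivalence is asserted against a deliberately independent
  brute-force partition (explicit loops, stdlib statistics) on 200 random
  small tensors at 1e-10.
- No confidence intervals are produced: with two years of data a block
  bootstrap of temporal quantities is meaningless, and the partition
  identities are exact rather than estimated.
- Ties and degenerate inputs: label order is sorted lexicographically;
  tensors are dense; years and rounds are treated as labels, not indices.
- The level-ordering report (invariability non-decreasing from population
  to region) is asserted as a *consistency check*: it follows
  algebraically from Ψ ≤ 1, so agreement with the qualitative pattern
  seen in field studies is a property of the decomposition, not an
  empirical finding of the package.
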