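# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, and what the synthetic generator does and does not
emulate.

## Vessel traits

All traits are computed after the exclusion filter. The filter keeps
vessels with lumen area ≥ `min_area` (default 5000 µm²; "smaller than"
excluded, so the boundary value is retained). Cluster membership is taken
from the retained population: a two-vessel cluster that loses one member to
the filter leaves a solitary vessel. This is a convention — the grouping
indices are defined on the vessel population actually analysed.

Single-vessel diameters assume round vessels, `D = 2√(A/π)`. The
theoretical hydraulic conductivity converts diameters to m and the analysed
area (aoi) to m² internally while keeping the viscosity of water at 20 °C
in MPa·s (η = 1.002 × 10⁻⁹ MPa s, ρ = 998.2 kg m⁻³), so the result lands
directly in kg m⁻¹ MPa⁻¹ s⁻¹. The vulnerability index divides the raw-unit
mean diameter (µm) by the raw-unit vessel frequency (mm⁻²), the customary
index convention, with the mean diameter taken over the same filtered
vessel set as every other trait.

Cores A and B of a tree-ring are combined by **pooling** their filtered
vessels and summing their aoi. Pooling is the only convention that keeps
`VFrac ≡ VFreq·LA·10⁻⁶` exact at the combined level; averaging core-level
trait values is available as `combine="mean"`. Group identifiers are
namespaced by core when pooling so clusters never merge across cores. A
core-ring with no vessel above the threshold is skipped with a logged
warning and contributes neither vessels nor aoi to the combined level.

## Chronologies and common signal

Chronologies are built from combined-level records; the site mean ignores
missing tree-years. First differences are defined only between consecutive
calendar years — a gap produces a missing difference rather than a
multi-year jump. r̄ (between) is the mean pairwise Pearson correlation
over tree series, skipping pairs with fewer than three common years;
r̄ (within) is the mean over trees of the A-vs-B core correlation — the
usual within-tree inter-core statistic. EPS uses the standard form
`n·r̄/(1+(n−1)·r̄)`, clipped to [0, 1], with r̄ ≤ 0 mapping to 0.

## Site-type mixed model

Each trait is transformed before modelling (defaults: log for LA, THC, VI;
square root for VFreq; none for VFrac, HWD, GI, SVI — strictly positive,
right-skewed quantities get log, counts-per-area gets the square root, and
bounded indices are left alone). The model is
`value ~ site (+ tree-level covariate)` with random intercepts for tree and
for core nested in tree, fitted by REML (statsmodels `MixedLM`); the REML
fit supplies the variance decomposition and convergence flags.

Inference about site type uses the containment (expected-mean-squares)
stratum: site varies between trees only, so the F-test and the pairwise
contrasts are computed from per-tree means with denominator df =
n_trees − (number of between-tree parameters) — 45 − 3 = 42 at the default
design. For balanced data this is the classical exact mixed-design test; it
is calibrated at the nominal level, and as the random variances go to zero
it coincides *identically* with the fixed-effects ANOVA on tree means. A
Wald test against the REML covariance was rejected during development: at
the zero-variance boundary the REML variance estimates stay small-positive
and deflate the F statistic by tens of percent.

Post-hoc comparisons are tested on the transformed scale with Bonferroni
correction over the three site pairs; marginal means are back-transformed
for reporting; the compact letter display uses insert-and-absorb and, when
the global test is not significant, reports no separation. Variance
homogeneity is checked with the median-centred (Brown–Forsythe) Levene
test.

## Repeated-measures correlation

`rmcorr` centres both variables on subject means and correlates the centred
values; the sign is the common within-subject slope, df = N − k − 1, and p
comes from the t transform. Pairs with missing values are dropped, then
subjects left with fewer than two pairs are removed and N, k adjusted. A
single remaining subject degenerates to an ordinary Pearson correlation
with df = N − 2. The implementation agrees with an independent
sums-of-squares ANCOVA and with the pingouin reference to 10⁻⁸ (test
suite).

## Climate windows

Windows are calendar-anchored: starts on the 1st and 16th of each month
from previous-year May through current-year July, omitting the July-16
start whose span would leave July — 29 windows, each exactly 30 days
(overshooting slightly into the following month after 31-day months and
February, which keeps window length constant and yearly series directly
comparable). Strict 15-day stepping was rejected because it drifts across
month boundaries. Up to 10 % of a window's days may be missing (summaries
then use present days); beyond that the window-year is missing and later
dropped pairwise. The heat-moisture index applies the annual functional
form to window aggregates, `HMI = (T̄+10)/(P/1000)`, and is undefined (NaN)
for rain-free windows.

The climate-correlation surface first-differences each tree's trait series
and each window's yearly climate series, then computes rmcorr (tree as
subject) per trait × window × variable, with `*`, `**`, `***` at 0.05,
0.01, 0.001. **Calibration caveat:** first-differencing independent yearly
values makes consecutive differences MA(1) with lag-1 autocorrelation −0.5
in both series; the variance of the correlation estimate inflates by
1 + 2·(0.5)² = 1.5 over the nominal t reference, so the screen's real
false-positive rate per cell is ≈ 0.07–0.09, not 0.05. The suite pins the
measured rate to that band; published surfaces of this kind should be read
as exploratory, and no multiple-testing correction is applied across the
29-window surface (matching field practice for such figures).

## Synthetic cohort generator

The generator is calibrated entirely to published site-level summary
statistics (means and SDs of the traits per site type) and produces, per
site: 15 trees × 2 cores × 10 ring years (2009–2018), aoi 10 mm² per
core-ring (≈110–140 vessels per ring at the calibrated frequencies —
realistic workload, still desk-scale).

- **Lumen area.** Ring-level log-LA is Gaussian around the site target with
  total SD matched to the published observation-level SD, decomposed into
  tree (0.50), climate-driven shared year (0.15), tree-year (0.20) and core
  (0.15) fractions. Tree effects are drawn sum-to-zero within a site
  (balanced sampling), so a single cohort hits its configured site means to
  ≈1 %. Within a ring, vessel diameters are lognormal with σ = 0.1858 —
  the value that makes the hydraulically weighted diameter consistent with
  the site mean lumen area (`HWD/2√(LA/π) = exp(3.5σ²)`; for lognormal D,
  `HWD = exp(µ+4.5σ²)` while `2√(LA/π) = exp(µ+σ²)`, and the package keeps
  `HWD/E[D] = exp(4σ²)` as a self-consistency test).
- **Space constraint.** Each ring draws a vessel fraction and realises
  `n ~ Poisson(VFrac·aoi/LA)` vessels (minimum 1). This mechanically
  produces the published negative LA–VFreq correlation. Log-VFrac carries a
  positive regression on log-LA (λ = 0.45·σ_F/σ_L, matching the published
  tree-wise LA–VFrac correlation of 0.45); without it the conductivity tail
  is under-produced. The VFrac location is solved so the *realised* vessel
  frequency hits the published site target despite the Jensen term on 1/LA.
- **Clustering.** Vessels are laid down sequentially; a vessel joins the
  open cluster with probability g₁ while it is a singleton and g₂ once it
  holds two or more. (g₁, g₂) are solved numerically at config-build time
  by least squares on the relative GI/SVI errors. The published (GI, SVI)
  pairs are internally infeasible by a fraction of a percent — they imply
  non-solitary clusters with mean size just below 2 — so the solution lands
  within ≈1 % of both targets (park) rather than exactly on them.
- **Climate.** Daily temperature is a two-harmonic seasonal curve solving
  annual mean 6.8 °C, July 21.2 °C and January −9.7 °C, plus AR(1) noise
  (φ = 0.7, innovation SD 2.5 °C); precipitation is Bernoulli–gamma (wet
  probability 0.45, shape 0.65) targeting ≈1000 mm yr⁻¹. One synthetic
  station serves all sites by default; a warm-offset second station is
  available.
- **Climate sensitivities** act on the shared year effects through
  standardized 30-day-window series, in units of the year-effect SD per
  climate SD. Defaults mirror the published qualitative pattern: street
  types load log-LA negatively on current-spring temperature and positively
  on current-summer HMI; the park type loads vessel packing and grouping
  instead. Crucially, the across-tree *shared* part of the year signal is
  exactly the climate-driven component; the rest of the year-variance
  budget is tree-specific. Trees are therefore conditionally independent
  given climate — the condition under which a tree-as-subject correlation
  screen has a well-defined null. With shared non-climate year noise the
  screen's false-positive rate was measured at ≈0.4, which is worth
  remembering when reading real-data surfaces: any synchronous non-climate
  forcing (construction, pests, management) masquerades as climate signal.
- **Contaminants.** A configured 4 % of vessels are drawn below the 5000
  µm² threshold (uniform 1500–4900 µm², solitary), so the exclusion filter
  always has work to do.

Regeneration with the same seed is bit-identical; all randomness flows from
one `SeedSequence`.

**What the generator does not emulate:** within-ring spatial arrangement
beyond cluster membership; latewood vessels; serial correlation of traits
across years (year effects are white given climate); the GI–VFrac
correlation reported for real trees; measurement error in aoi; cross-dating
error. Tests passing on synthetic cohorts therefore demonstrate that the
*machinery* is correct and calibrated, not that real data meet its
assumptions.

## Numerical choices and problem sizes

- Grouping calibration: `scipy.optimize.least_squares` with bounds
  g₁ ∈ (0, 0.999], g₂ ∈ [0, 0.9], two starts; configurations whose best
  joint relative error exceeds ~10 % raise `InvalidConfigError`.
- Correlation pairs with fewer than three overlapping years are skipped in
  r̄; cells with constant climate or insufficient overlap are NaN, never
  imputed.
- The simulation-based checks in the test suite use reduced designs chosen
  to keep the whole suite at desk scale: the climate-surface calibration
  runs 100 seeds of a 2-site × 10-tree cohort with aoi 4 mm²; the
  mixed-model operating characteristics use 200 null and 60 power
  replicates with 5 ring years per core. The headline calibration checks
  use the full default 45-tree cohort.

## Known limitations

- The vulnerability index is reported as the mean of per-ring ratios;
  population summaries of ratio traits exceed the ratio of the summary
  means (≈+10 % for VI at the default dispersions).
- The containment F-test is exact for balanced designs; for strongly
  unbalanced tree counts it is an approximation (tree means enter
  unweighted).
- The first-difference climate screen is anticonservative by construction
  (see above); the package reports unadjusted stars deliberately.
- EPS and r̄ from 10-year series carry large sampling noise; with the
  default calibration, channels without climate sensitivity have r̄ ≈ 0 by
  design.
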