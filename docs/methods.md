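# Methods

## Data model

Observations are plot-level records in long format — genotype, condition
(`normal` = fall sowing, `stress` = late/spring sowing; the aliases
`fall`/`spring` are accepted on input), year, replicate, optional
incomplete-block id, trait code, value. Grain and biological yield are
standardized to g/m² by dividing harvested plot mass by the harvested area
(0.40 m² in the reference layout, i.e. ×2.5). Harvest index is computed per
plot as 100·GY/BY and then averaged; the ratio of condition means is a
different quantity (Jensen gap) and is deliberately not used. Missing
values are handled by complete-case analysis per trait; genotypes missing
an entire condition are excluded from yield summaries and listed in an
exclusion report rather than silently dropped. Reported tables round half
away from zero at the printed precision.

## ANOVA model and error terms

The alpha-lattice layout is analyzed as a randomized complete block design;
incomplete-block effects are assumed negligible and the block column is
ignored by default (the simulator has a block-variance knob for robustness
checks). The combined model is

    y_ijkl = mu_j + g_i + (g·sd)_ij + y_k + (sd·y)_jk + (g·y)_ik
             + (g·sd·y)_ijk + r_l(jk) + e_ijkl

with genotype and sowing date fixed, year and replication-within-SD×year
random. Sums of squares come from the exact mean decomposition of the
balanced layout; the engine refuses unbalanced data rather than silently
switching to a partial-SS approximation. SS and df conservation are
asserted on every run.

Denominators for F-tests are not uniquely determined by the printed
significance patterns, so the package adopts the standard mixed-model
assignment and makes it overridable per source: fixed effects are tested
against their interaction with random year (SD and Y against SD×Y with 1 df
— consistent with a sowing-date effect reaching only p < 0.05 despite a
very large mean-square ratio; G against G×Y; G×SD against G×SD×Y) and
random interactions against the residual. When a denominator mean square is
exactly zero (degenerate noise-free inputs) the F statistic is reported as
infinity with p = 0.

Outliers are screened, never auto-removed: a preliminary RCBD fit
(genotype + replicate) within each condition × year yields externally
studentized residuals, and plots with |r| > 3 are returned for inspection.
Groups the model fits perfectly (zero residual variance) are skipped, since
studentized residuals are then 0/0 noise.

## Variance components and heritability

For a per-condition analysis with y years and r replicates the expected
mean squares give the method-of-moments solution

    sigma2_e  = MS_res
    sigma2_GxY = (MS_GxY − MS_res) / r
    sigma2_G  = (MS_G − MS_GxY) / (r·y)

Negative solutions are truncated to zero and flagged; raw values are kept
for diagnostics. Phenotypic variance is on a genotype-mean basis,
σ²P = σ²G + σ²G×Y/y + σ²e/(r·y), so h²b = σ²G/σ²P (equivalently
1 − MS_G×Y/MS_G when nothing truncates). When σ²G truncates, heritability
is reported as the sentinel `np` (non-predictive) instead of a number.
Fisher's LSD is t(1−α/2, df_err)·√(2·MS_err/n) with no multiplicity
correction, matching common practice for these trials.

## Indices, classification, ranking

The ten indices are computed from per-genotype condition means and the
panel means of the analyzed panel itself (controls included). GMP is the
geometric mean √(YP·YS); sources that print the unrooted product YP·YS are
served by the `gmp_raw` column, which equals STI·XP². HSI is an affine
function of YSI, which forces corr(YSI, HSI) = −1 and corr(HSI, PYR) = +1
on any panel — these identities, together with HM ≤ GMP ≤ MP and
STI = GMP²/XP², are asserted in the test suite on every generated table.

HSI class boundaries default to tolerant ≤ 0.8 < semi-tolerant ≤ 1.3 <
susceptible (an alternative 1.2 susceptibility boundary in circulation is
available through `HsiThresholds`). Composite ranking averages per-index
ranks (1 = best in the index's direction, ties averaged) over HSI (low
good), MP and STI (high good); ties in mean rank break by lower HSI, then
genotype id, making the ordering fully deterministic. The HSI-vs-MP
refinement fits an ordinary least-squares line of HSI on MP and selects
genotypes with above-mean MP whose HSI falls below the line by more than a
small numerical tolerance — an operationalization of "high productivity
with better-than-expected tolerance"; the rule is an interpretation, since
only the regression itself is standard.

## Correlations and PCA

Trait correlations are computed on genotype means within each condition
(one value per genotype per trait, the granularity at which such tables are
reported), index correlations across the whole panel; two-sided p-values
come from the t transform with n−2 df, starred at 0.05/0.01 without
multiple-testing correction. PCA standardizes complete cases to z-scores
and eigen-decomposes the correlation matrix; each component's sign is fixed
so its largest-magnitude loading is positive, making loadings reproducible
across platforms. Both pooled and per-condition PCA are available, as the
appropriate pooling for biplots is analysis-dependent.

## The simulator

All effects are Gaussian: the ANOVA and heritability machinery only uses
second moments, and no distributional claims beyond that are needed. The
stress penalty acts on the condition mean (μ_stress = μ_normal·(1 − p));
genotype-specific sensitivity enters only through the G×SD term. Each model
term draws from its own sub-stream of the master seed, so variance knobs
are independent. The reference-scale configuration uses μ_normal = 899 g/m²
and p = 0.25 (panel means 899/674), residual variance 2358 g²/m⁴ (a ~6.2%
CV at the pooled mean), and genotype-level components (var_G = 6500,
var_G×SD = 3900, var_G×Y = 2100, var_G×SD×Y = 2400) giving a
between-genotype SD of condition means of ~115 g/m². A homoscedastic
component set cannot reproduce different spreads under normal (≈129) and
stress (≈100) conditions simultaneously, so the calibration sits between
the two; year-level variances are set small (50/100/25), consistent with a
non-significant year main effect. Quality traits (PGP, ZSV, GH), when
enabled, use near-zero condition penalties with dominant genotypic
variance, mimicking traits that respond to genotype but not sowing date.

What the simulator does **not** emulate: spatial field trend and
incomplete-block structure (beyond an optional block-variance knob),
non-Gaussian or heteroscedastic errors, genotype-specific multiplicative
stress responses, and correlated multi-trait architecture. Passing tests
therefore demonstrate correctness of the estimators under the assumed
second-moment structure, not robustness to field artifacts.

## Numerical choices and problem sizes

Balanced-design SS are accumulated from cell means in double precision;
conservation is asserted at 1e-9 relative tolerance. Monte-Carlo tests
compare estimator means to truth within 3 empirical standard errors;
recovery runs use 120–200 simulated trials (full 156-genotype scale for the
acceptance-level recovery check, 60–100 genotypes for unit-level checks),
sizes at which the Monte-Carlo error is a few percent of the target
quantities. The zero-genotypic-variance case is genuinely stochastic — with
no genotype signal MS_G < MS_G×Y roughly half the time — so the `np`
sentinel is asserted to fire in a substantial fraction of replicates, and
deterministically on constructed mean squares with MS_G < MS_G×Y.

## Known limitations

- Unbalanced data are rejected, not approximated; users must resolve
  exclusions first. No REML/mixed-model path is provided.
- LSD is offered for any (MS, df, n) the user supplies, but the correct
  error term for cross-condition mean comparisons is design-dependent and
  left to the caller.
- Moisture corrections for kernel-weight and test-weight traits are assumed
  already applied upstream.
- The HSI-vs-MP selection rule and the F-test denominators are documented
  interpretations where the field's reporting conventions are ambiguous;
  both are configurable.
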