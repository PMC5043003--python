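# Methods

`cagestat` implements the statistical backbone of a chronic (1-year)
rodent feeding trial analysed at the cage level: standardized effect
sizes with confidence intervals classified against biological-relevance
limits, a decision-tree battery of classical tests, AR(1) longitudinal
models for growth data, design power calculations, and cross-method
concordance accounting — all exercised against a synthetic trial
generator that reproduces the design's hierarchical structure.

## The experimental unit

Two animals share a cage, and the cage — not the animal — is the unit of
inference throughout. All endpoint values are aggregated to cage means
before any test is run; feed consumption is recorded once per cage and
period as the total amount eaten and is summed, never averaged or halved.
Group sizes in every formula therefore count cages (10 per group and
gender in the default design; 5 at interim months, where only a
subsample of 10 animals per group is bled).

## Standardized effect sizes (SES)

For a treatment-vs-control comparison the SES is
`d = (x̄_T − x̄_C) / s_p` with the pooled SD
`s_p² = ((n_C−1)s_C² + (n_T−1)s_T²)/(n_C+n_T−2)`, and

```
se(d)² = (n_C + n_T)/(n_C n_T) + d² / (2 (n_C + n_T − 2)).
```

The 95 % interval uses the large-sample standard-normal multiplier
(1.959964) by default; a t-based multiplier (df = n_C+n_T−2) is available
via `ci="t"`. No small-sample (Hedges) correction is applied by default —
the SES is defined as the plain mean difference over the pooled SD — but
`hedges=True` applies `J(df) = 1 − 3/(4 df − 1)`. Both options exist
because the literature uses both variants; the defaults are the plainest
reading of the definition.

Each CI is classified jointly by significance (does it cover 0?) and
relevance against symmetric limits ±L (default L = 1.0 SD, the effect the
design was powered to detect):

- **a** — not significant and CI strictly inside (−L, L): clear negative;
- **b** — significant but the CI is not entirely beyond ±L;
- **c** — significant and the CI lies entirely outside ±L: potentially
  relevant;
- **d** — not significant and not inside (−L, L): inconclusive.

Containment is open-interval and "outside" is strict, so a CI touching a
limit falls to the conservative cases b/d. The classification is
exhaustive and mutually exclusive for every finite CI (property-tested).

Zero-variance comparisons are never exceptions in batch runs: equal
means give a flagged degenerate null result; unequal means with zero
pooled SD raise only in the scalar API and are flagged in the batch.

### Power

Design power is the exact power of the pooled two-sample t-test computed
from the noncentral t distribution (df = 2n−2, noncentrality d√(n/2)).
At d = 1.0, α = 0.05 two-sided and n = 20 units per group it is 0.869,
and the smallest n reaching 85 % power is 19 — consistent with a 20-unit
design. A raw-data Monte-Carlo simulation in the test suite agrees with
the noncentral-t values to < 0.005 at 10⁶ replicates.

## The classical decision tree

Per (endpoint, gender, time) cell of the cage table:

1. **Normality** — Kolmogorov–Smirnov with the Lilliefors correction on
   the pooled ANOVA residuals (per-group testing is an option). Because
   mean and SD are estimated, the null distribution of the statistic is
   non-standard; it is simulated (10⁴ seeded draws, cached per sample
   size) and the p-value is `(1 + #{D₀ ≥ D})/(n_sim + 1)`. This matches
   statsmodels' table-based implementation to ~0.03 in p where the tables
   are dense.
2. **Homogeneity** — Levene's test (ANOVA F on absolute deviations from
   the group mean; median-centering, i.e. Brown–Forsythe, via a flag).
3. Both pass at α = 0.05 → **parametric branch**: one-way ANOVA; if the
   omnibus p < α, Dunnett-adjusted comparisons and unadjusted post hoc t
   tests against control. Otherwise (and always for qualitative-ordinal
   endpoints) → **nonparametric branch**: Kruskal–Wallis with tie
   correction; if p < α, pairwise Wilcoxon rank-sum tests vs control.

Post hoc flags are gated on the omnibus test on the decision-tree path.
The three fixed single-method batteries used for cross-method comparison
(`anova_t`, `anova_dunnett`, `kw_wilcoxon`) are **ungated** — the
pairwise test is applied to every comparison — so their null flag rates
sit at (or below, for the multiplicity-adjusted Dunnett) the nominal
level, which is what the concordance accounting assumes. Assumption
tests run per endpoint-time cell, not once per endpoint.

Under a fully null normal simulation the tree takes the parametric path
in ≈ (1−α)² ≈ 90 % of cells — the two gates each spend their α.

### Dunnett's many-to-one p-values

Writing the group means as μ + σZᵢ/√nᵢ and the pooled SD as σU with
νU² ~ χ²_ν, the joint CDF of the comparison statistics factorizes given
(U, Z₀):

```
P(max_i |T_i| ≤ t) = E_{U,Z0} ∏_i [ Φ(c_i + h_i) − Φ(c_i − h_i) ],
c_i = √n_i Z0/√n_0,   h_i = √n_i · t·U·√(1/n_i + 1/n_0).
```

The expectation is evaluated with 80 Gauss–Hermite nodes in Z₀ and 128
Gauss–Legendre nodes in U over its truncated chi density (support cut at
the 10⁻¹⁰ tails). Accuracy is ~10⁻⁶, comfortably inside the 10⁻⁴
target; with one treatment group the quadrature reproduces the central t
CDF to 10⁻⁸, and adjusted p-values match both scipy's QMC implementation
(5·10⁻⁴) and a million-replicate raw-data max-|T| simulation (< 0.005).
A seeded Monte-Carlo fallback covers the (untypical) case of more than
16 treatment groups, where the product over the quadrature grid loses
accuracy.

### Wilcoxon rank-sum

Exact two-sided p by enumeration for n_a + n_b ≤ 20 without ties; the
normal approximation with tie and continuity correction otherwise. The
most central configuration (U equal to its null mean, e.g. two identical
samples) reports p = 1 exactly; the continuity correction would
otherwise leave it just below 1. The exact path equals exhaustive
enumeration over all label arrangements for every group size with
n_a + n_b ≤ 12 (swept in the tests).

Zero within-group variance with unequal means anywhere in the ANOVA
family returns p = 0 with the capped statistic `F_CAP = 1e12` and a
degeneracy flag, never an exception.

## Longitudinal AR(1)-REML

Body weight, feed consumption and feed efficiency per cage are modelled
as `value ~ group + week` (week continuous; a group×week interaction and
a gender fixed factor are flags; the batch driver fits pooled-with-gender
and per-gender models). Residuals within a cage follow a continuous-lag
AR(1) process, corr = ρ^Δweeks, which handles the weekly-then-biweekly
recording grid exactly. "AR covariance" is read as first-order; the
order is the natural default and nothing in the package depends on
higher orders.

Because AR(1) is Markov, each cage series is whitened sequentially
(`e*_j = (e_j − r_j e_{j−1})/√(1−r_j²)`, `r_j = ρ^{t_j − t_{j−1}}`),
turning GLS into OLS and giving log|V| in closed form. The REML
criterion is profiled over ρ by bounded scalar minimization on
(−0.99, 0.99) (xatol 10⁻⁶, deterministic; restricted to [0, 0.99) if the
grid has non-integer gaps, where negative ρ has no continuous-lag
meaning). β̂ and σ̂² have closed forms at each ρ. Contrast p-values use
the t distribution with N − p residual df — an approximation that is
accurate here because the panels are large relative to p. Non-convergence
is reported through the `converged` field with the last iterate.

`lsmeans(fit, at_week)` gives model-predicted group means with
delta-method standard errors and contrasts vs control (averaging the
gender dummy at 0.5 in pooled fits); these feed the SES computation for
least-square-mean body weights. With a single time point per cage the
fit reduces exactly to one-way ANOVA on cage values (verified to 10⁻⁸).

Monte-Carlo checks (500 replicate two-group panels, 10 cages, 13 weekly
points, ρ = 0.6, slope 5 g/week, offset −20 g, σ = 10 g): mean ρ̂ ≈ 0.59
(slight downward REML bias at T = 13 is expected) and 95 % CI coverage of
the offset ≈ 94–95 %.

## The synthetic trial generator

The generator defines the conditions under which everything above is
validated. For a quantitative endpoint,

```
y_animal = μ + δσ + u_cage + ε,
u_cage ~ N(0, (1−w)σ²),   ε ~ N(0, wσ²m),   m = animals/cage,
```

so the **cage mean** has variance σ² exactly and δ is the standardized
effect on the cage-mean SD scale — the scale of the power analysis and
the relevance limits, and hence the directly recoverable quantity.
`w ∈ [0,1)` is the share of cage-mean variance contributed by animal
residuals; no empirical between/within decomposition is available for
this kind of trial data, so the default w = 0.5 is a convention (it
affects only how variance splits below the cage level, not any
cage-level operating characteristic). Lognormal endpoints apply the same
construction on the log scale; ordinal endpoints threshold the latent
normal into ≤ 6 ordered bins.

One global seed drives a splittable per-endpoint stream (CRC-32 of the
endpoint name as the spawn key), so adding endpoints never perturbs
existing ones and identical seeds give byte-identical tables. Early
sacrifice is representable by dropping an animal's records; cage values
fall back to the surviving animal with `n_animals = 1`.

Growth curves are monomolecular, `W(t) = A − (A − W0)e^{−kt}`, with
unit-mean lognormal multiplicative noise (CV 3 %). Defaults — male
W0 = 150 g, A = 600 g, k = 0.08/week; female W0 = 110 g, A = 360 g,
k = 0.09/week — put terminal means near 594 g and 358 g, the magnitudes
typical of 1-year Wistar Han trials. Feed intake ramps linearly to a
plateau (cage totals of 380 g/week male, 260 g/week female). Group
effects on weight enter as asymptote shifts in grams.

The default endpoint panel has 29 haematology/differential/biochemistry
endpoints at months 3/6/12 plus 13 relative organ weights at necropsy:
100 endpoint-time cells per gender, i.e. 600 treatment-vs-control
comparisons in the four-group design — the scale at which the
cross-method concordance is exercised. Which 5 of 10 cages form the
interim subsample is not determined by the design; the generator takes
the first cages in layout order, and the analysis simply uses whatever
units carry data, recording n per comparison.

What the generator does **not** emulate: measurement rounding and
detection limits, seasonal drift, inter-assay batch effects, attrition
beyond simple record removal, tumour incidence, or any pharmacokinetic
coupling between endpoints. Passing tests therefore demonstrate correct
operating characteristics under the assumed hierarchical-normal world,
not robustness to those real-data features.

## Concordance accounting

Agreement between two methods is the percentage of comparisons whose
binary significant/non-significant flags coincide over a shared universe
(degenerate zero-variance comparisons excluded and listed in the run
manifest). SES "significance" for this purpose is CI-excludes-zero
(cases b or c), ignoring relevance. Each comparison is counted once per
method pair. Under the null default trial, SES-vs-decision-tree
agreement lands around 94–96 %: the z-based SES interval flags ~5–6 % of
null comparisons while the gated, Dunnett-adjusted tree flags ~2–3 %, so
discordance is bounded by the sum of the two error rates.

## Numerical and reproducibility choices

- Quartiles for Tukey-fence screening use linear interpolation between
  order statistics (type 7); screening only flags, never removes.
- Significant-figure rounding (diet ratio QC) uses round-half-even on
  decimal representations, reproducing printed 2-figure ratios without
  binary-float artifacts.
- CSV outputs are written at 6 significant digits and are byte-stable;
  the SES panel figure is rendered with a fixed SVG hash salt and no
  timestamps, so re-runs with the same seed hash identically (the run
  manifest records SHA-256 of every output).
- All α default to 0.05, two-sided. Relevance limit L defaults to 1.0 SD.
- Monte-Carlo problem sizes used by the validation suite (2000 replicate
  trials for calibration/coverage, 10⁶ draws for power and Dunnett
  cross-checks, 500 panels for REML recovery) were chosen to make
  Monte-Carlo error small relative to the tolerances being asserted.

## Known limitations

- No FDR/Bonferroni family corrections beyond Dunnett; no
  repeated-measures ANOVA, random-slope models or spline growth curves.
- The contrast df in the GLS fit is the residual df, not a
  Satterthwaite/Kenward–Roger adjustment; with small panels the
  contrast tests can be mildly liberal.
- Ordinal endpoints are supported by the generator and the nonparametric
  branch but excluded from default comparison counting.
- No unit conversion: units are metadata strings carried through
  unchanged.
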