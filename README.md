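# cagestat

Cage-level statistics for repeated-dose rodent feeding trials: the
standardized-effect-size (SES) analysis framework used in chronic
whole-food toxicity studies, together with the classical decision-tree
testing it is compared against.

In guideline feeding trials (OECD TG 452-style designs) two rats share a
cage and the **cage is the experimental unit**. Dozens of haematology,
clinical-biochemistry and organ-weight endpoints are measured at several
time points in four diet groups, producing hundreds of
treatment-vs-control comparisons. `cagestat` is for biostatisticians and
study designers who need to run — or audit — that analysis:

- **SES with confidence intervals.** For each comparison,
  `d = (x̄_T − x̄_C)/s_p` with
  `se(d)² = (n_C+n_T)/(n_C n_T) + d²/(2(n_C+n_T−2))`, and a 95 % CI
  classified jointly by statistical significance (CI vs 0) and biological
  relevance (CI vs ±L, default L = 1.0 SD) into cases **a** (clear
  negative), **b** (significant, relevance unclear), **c** (potentially
  relevant) and **d** (inconclusive), plus the all-endpoints-at-a-glance
  panel graphic.
- **Decision-tree classical analysis.** Lilliefors-corrected
  Kolmogorov–Smirnov normality (Monte-Carlo null) and Levene homogeneity
  gates choosing between ANOVA + Dunnett + post hoc t and
  Kruskal–Wallis + pairwise Wilcoxon; Dunnett's many-to-one p-values by
  control-variate quadrature over the multivariate-t representation.
- **Longitudinal models.** REML-estimated GLS with continuous-lag AR(1)
  within-cage correlation for body weight / feed consumption / feed
  efficiency, with least-square means and contrasts vs control.
- **Design power.** Noncentral-t power and sample size on the SES scale.
- **Synthetic trials.** A hierarchical generator (group effects in
  cage-mean SD units, cage random effects, animal residuals, growth
  curves, 3/6/12-month panels) so the whole pipeline is testable without
  any animal data.
- **Concordance.** Pairwise agreement of significance flags between the
  SES approach, the decision tree, and three fixed single-method
  batteries.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from cagestat import ses_estimate, ses_power, required_n, dose_ratio

# One endpoint cell: control 1.85 ± 0.52 vs treated 3.65 ± 0.96,
# 10 cages per group.
r = ses_estimate(1.85, 0.52, 10, 3.65, 0.96, 10)
print(f"d = {r.d:.3f}, 95% CI ({r.ci_lo:.2f}, {r.ci_hi:.2f}), case {r.case}")
# -> d = 2.332, 95% CI (1.17, 3.49), case c

print(ses_power(1.0, 20).power)   # -> 0.86895  (design power at d = 1 SD)
print(required_n(1.0, 0.85))      # -> 19       (smallest n/group for 85 %)
print(dose_ratio(31.3, 10.4))     # -> 3.0      (diet content ratio QC)
```

`d = 2.33` says the treated group mean sits 2.3 pooled SDs above
control; the CI excludes 0 (significant) and lies entirely beyond +1 SD,
so the comparison is case **c** — potentially biologically relevant. A
20-cage design detects a 1 SD shift with 86.9 % power at α = 0.05
two-sided.

The full pipeline on a synthetic trial:

```sh
cagestat report --seed 5 --out report/
```

prints, for the default null trial,

```json
{
  "n_comparisons": 600,
  "significant_counts": {"ses": 38, "decision_tree": 12, "anova_t": 36,
                         "anova_dunnett": 18, "kw_wilcoxon": 26},
  "agreement_ses_vs_tree": 95.33
}
```

(counts vary with the seed: under the null each method flags at roughly
its nominal error rate) and writes cage tables, SES results with cases,
decision-tree paths, the SES panel SVG, agreement matrices and a
manifest with SHA-256 hashes of every output — rerunning with the same
seed reproduces the hashes byte for byte. The other subcommands
(`simulate`, `aggregate`, `analyze-ses`, `analyze-classical`,
`analyze-longitudinal`, `compare`, `power`) expose the individual
stages; measurement input is a tidy CSV with columns
`animal_id,cage_id,gender,group,endpoint,time,value[,kind,unit]`.

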