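# comorbnet

Comorbidity-network analysis of **early aging** in matched COPD/control
EMR-style cohorts.

People with a COPD diagnosis accumulate chronic comorbidities — and in
particular the diseases characteristic of old age — earlier than age- and
sex-matched controls. `comorbnet` implements the full analysis pipeline
behind that observation for anyone working with person-level cohorts of
binary chronic-condition indicators (epidemiologists, health-services
researchers, methods developers), together with a synthetic cohort
generator that reproduces the statistical structure of such data, so every
stage is testable without access to protected medical records.

## What it computes

**Disease co-occurrence networks.** For a stratum of *n* people and a
catalog of *D* chronic conditions, every disease with at least one case is
a node, and an edge joins diseases *i, j* whose phi coefficient

φᵢⱼ = (ad − bc) / √((a+b)(c+d)(a+c)(b+d))

(the Pearson correlation of the two binary indicators, computed from the
2×2 co-occurrence table) is significant at α = 0.01 via the χ²₁ statistic
n·φ². Edges are signed; negative associations are retained with polarity
recorded (a positive-only flag, Fisher-exact edge tests and
Benjamini–Hochberg correction are available).

**Network statistics.** Density 2E/(N(N−1)); degree median and IQR
(nearest-rank quartiles); the degree histogram with heavy-tail diagnostics
(discrete power-law vs geometric likelihood); **hubs** = nodes at or above
the 75th percentile of degree; and percentile bootstrap confidence
intervals obtained by resampling *persons* and rebuilding the network
(B = 1000 by default).

**Early-aging comparison.** Both groups are split into five age brackets
(40–55, 56–65, 66–75, 76–85, >85); a network is built per (group, bracket)
cell. Cells are compared by one-way ANOVA on node degrees (after
size-matching the cells' person counts), and each COPD bracket is assigned
the closest control bracket that is statistically indistinguishable — the
bracket-midpoint difference is the **aging lag**. Elder-disease prevalence
trajectories (13 conditions characteristic of the elderly) are compared per
bracket with Fisher exact tests.

**Mortality.** A logistic model of 3-year death on age (per decade),
comorbidity count, and the COPD indicator, with Wald 95% CIs on the odds
ratios; plus a smokers-subgroup replication with seeded 1:1 age/sex
matching.

**Synthetic cohorts.** A Gaussian latent-factor threshold model: person
factors u ~ N(0, I_K), disease d present with probability
Φ(λ_d·u + b_d + s_d(age_eff − 40)), where age_eff = age + Δ for the COPD
group. The age shift Δ (default 15 years) *is* the early-aging hypothesis;
the factor loadings create the correlated co-occurrence and hub structure;
mortality is drawn at odds ratios 2.75 / 1.09 / 1.65 with the intercept
calibrated to an 11% control death fraction.

## Worked example

```python
import comorbnet as cn

cfg = cn.GeneratorConfig(n_per_group=27617, seed=1)
records, catalog = cn.simulate_cohort(cfg)

copd = [r for r in records if r.group == "copd"]
ctrl = [r for r in records if r.group == "control"]
for label, group in (("copd", copd), ("control", ctrl)):
    st = cn.network_stats(cn.build_network(group, catalog, alpha=0.01))
    print(label, st.n_nodes, st.n_edges, round(st.density, 3),
          st.degree_median, len(st.hubs))

model = cn.fit_mortality_model(records, catalog)
print({k: round(v, 2) for k, v in model.odds_ratios.items()})

grid = cn.build_grid(records, catalog, alpha=0.01)
lag = {e.copd_bracket: e for e in cn.estimate_aging_lag(grid, "degree")}
print(lag["56-65"].matched_control_brackets, lag["56-65"].lag_years)
```

prints

```
copd 119 1993 0.284 34.0 31
control 118 1760 0.255 30.0 30
{'age_per_10y': 2.81, 'n_comorbidities': 1.09, 'copd': 1.67}
['56-65', '66-75'] 0.0
```

The COPD network is larger and denser (119 nodes / 1993 links vs 118 /
1760 — the COPD condition itself never occurs among controls, hence the
missing node), the refit recovers the generating mortality odds ratios,
and the 56–65 COPD cell is indistinguishable from older control cells.
The single-cohort lag estimate is noisy at the bracket resolution (this
seed is a borderline same-bracket match); its median across replicate
cohorts is 10–20 years, the early-aging signature.

A command-line interface wraps the same stages:

```sh
comorbnet simulate --n-per-group 27617 --seed 1 --outdir out
comorbnet report-all --cohort out/cohort.csv --catalog out/catalog.csv --outdir out
```

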