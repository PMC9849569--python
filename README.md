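# symptomnet

Longitudinal symptom-network analysis of ordinal questionnaire panels, built
for 4-wave PHQ-9 / GAD-7 cohorts (e.g. women followed across an IVF-ET
treatment cycle) but generic over any 16-item, 0–3-scored, two-community
panel.

Psychometric network analysis treats depression and anxiety not as two
latent diseases but as a system of interacting symptoms. The core object is
a Gaussian graphical model: nodes are the 9 depression and 7 anxiety items,
and an edge between items *i* and *j* carries their partial correlation
`w_ij = -K_ij / sqrt(K_ii K_jj)` given all other items, where `K` is the
precision matrix. `K` is estimated by the graphical lasso
(L1-penalized Gaussian likelihood) with the penalty chosen by the extended
BIC, `EBIC = -2 l(K) + E log n + 4 E gamma log p`. On top of the per-wave
networks the package computes:

* **strength** and **bridge centrality** (bridge strength / betweenness /
  closeness over the depression–anxiety partition);
* **bootstrap stability** — edge percentile intervals, case-drop Spearman
  curves, and the CS coefficient;
* the paired permutation **network comparison test** between waves
  (structure statistic *M* = max absolute edge difference, global-strength
  statistic *S*), with Holm-corrected edge-level tests and Bonferroni
  correction across wave pairs;
* the **change-trajectory network**: a GGM over per-participant OLS slopes
  of each item across the four waves;
* simulation-based **sample-size planning** for GGM edge recovery;
* a **synthetic cohort generator** with known network ground truth, wave
  drift, and age-dependent dropout, so every stage is testable without
  clinical data.

See `docs/methods.md` for the model conventions and design choices.

## Worked example

```python
import symptomnet as sn

# A study-shaped synthetic cohort: 343/269/261/212 complete cases per wave,
# 210 participants observed at all four waves, older participants more
# likely to drop out.
spec = sn.CohortSpec(seed=7)
panel = sn.generate_cohort(spec)
print(sn.complete_case_counts(panel))
#> {'T1': 343, 'T2': 269, 'T3': 261, 'T4': 212}

# Baseline network: Pearson correlations -> graphical lasso -> EBIC choice.
X, ids = sn.complete_cases(panel, "T1")
net = sn.estimate_network(X)
print(net.n, round(net.lambda_selected, 4), net.edge_count,
      round(sn.global_strength(net), 3))
#> 343 0.175 13 1.021

# Node centrality, including the bridge indices.
cent = sn.bridge_centrality(net)
print(cent["strength"].sort_values(ascending=False).head(3).round(3))
#> App    0.278
#> Enr    0.263
#> Scd    0.241

# Paired network comparison between waves T1 and T2 (common completers).
comp = sn.compare_waves(panel, pairs=(("T1", "T2"),), n_perm=200, seed=0)
print(comp.summary[["n_pairs", "M", "p_M", "S", "p_S"]].round(3))
#>    n_pairs      M    p_M      S    p_S
#> 0      269  0.205  0.149  0.118  0.900

# Change-trajectory network over the 210 completers' item slopes.
slopes = sn.ols_slopes(panel)
slope_net = sn.slope_network(slopes)
print(slopes.n, slope_net.edge_count)
#> 210 0
```

The numbers mean: at baseline the EBIC-selected penalty 0.175 keeps 13
partial-correlation edges whose absolute weights sum to 1.02; appetite,
energy and suicidal-ideation problems carry the largest strength in this
particular synthetic truth; the T1–T2 comparison over the 269 shared
completers finds no significant structure change (M = 0.205, permutation
p = 0.149) nor global-strength change (S = 0.118, p = 0.90) — as expected,
since the generator holds the true network fixed across waves and only
shifts symptom means. The slope network is empty because the default
generator has no within-person dependence across waves, so true slope
correlations are zero.

The same steps are available from the shell:

```
symptomnet simulate --seed 7 --out cohort.csv
symptomnet estimate cohort.csv --wave T1
symptomnet compare cohort.csv --n-perm 1000
symptomnet power --nodes 16 --density 0.2
symptomnet run-study config.yaml
```

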