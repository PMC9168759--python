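# sextme

Sex-difference analysis of the tumor microenvironment (TME) from bulk
tumor molecular profiles: a tested, reusable implementation of the
pan-cancer workflow that asks whether male and female patients differ in
tumor mutational burden, immune infiltration, checkpoint-gene expression,
immune pathways, mutation spectra, prognosis and immunotherapy response —
and, on synthetic cohorts with planted ground truth, whether each stage
actually recovers what was planted.

It is written for computational oncologists and methodologists who have a
MAF-like somatic mutation table, an FPKM expression matrix, a clinical
table and marker gene sets (GMT), and who want every statistic of this
workflow behind one consistent, scriptable surface.

## What it computes

**Per-sample TME features.** TMB = *N*<sub>non-silent</sub> / 38 Mb from
the nine non-silent MAF classes; per-cell infiltration by single-sample
GSEA — for each sample, genes are ranked by expression and the score
integrates the running difference between the weighted in-set rank ECDF
(weight α = 0.25) and the uniform out-of-set ECDF; immune and stromal
compartment scores by the same statistic, with tumor purity from the
cosine calibration cos(0.6049872018 + 0.0001467884·(immune+stromal)).

**Sex-bias statistics.** Wilcoxon rank-sum tests for the four summary
scores; Welch *t* (female − male) per cell and per checkpoint gene with
Benjamini–Hochberg adjustment within each family; a cancer is "strong
sex-biased" when ≥ 4 of 7 feature flags are significant.

**Differential correlation.** Spearman ρ of TMB with each TME feature
within each sex, compared by the Fisher transformation
*Z* = atanh(*r*), *z* = (*Z*<sub>m</sub> − *Z*<sub>f</sub>) /
√(1/(n₁−3) + 1/(n₂−3)), with the upper-tail standard-normal probability
of |*z*| (a two-sided option is exposed).

**Pathway GSEA.** Weighted Kolmogorov–Smirnov enrichment on the
female-vs-male *t*-score ranking with sex-label permutations: per-pathway
P, NES and tail-ratio FDR.

**Mutations, survival, immunotherapy.** Per-gene mutated-by-sex
chi-square (Yates when expected counts < 5, FDR < 0.25); multivariate
logistic regression of mutation status on standardized cell scores;
per-sex univariate Cox screens feeding the risk score
Σ<sub>k∈S</sub> β<sub>k</sub>·a<sub>k</sub> with median-split
Kaplan–Meier / log-rank stratification and multivariable adjustment; and
per-sex ROC/AUC of TMB for checkpoint-blockade response.

**Synthetic cohorts.** `sextme.synthetic` generates all four input files
with planted sex effects (cell shifts, mutation-rate differences, a
Gaussian-copula TMB–immune correlation, hazards, response slopes) plus a
truth record and a recovery scorer.

## Worked example

```python
from sextme import synthetic, preprocess, scores, sex_bias, diff_corr

cfg = synthetic.SimulationConfig(seed=11, sex_cell_effects={"cell_01": 1.0},
                                 tmb_tme_corr={"male": 0.5, "female": 0.0})
cohort = synthetic.simulate_cohort(cfg)
expr = preprocess.filter_genes(cohort.expression)        # log2(FPKM+1)
table = scores.compute_sample_scores(
    expr, cohort.mutations, cohort.signatures,
    cohort.estimate_sets["STROMAL"], cohort.estimate_sets["IMMUNE"])
print(table.iloc[:3, :5].round(3))
```

```
         tmb  immune_score  stromal_score  estimate_score  purity
S0001  0.605        42.010         41.571          83.581   0.815
S0002  0.421       141.419       -142.889          -1.469   0.823
S0003  0.079       -11.728        163.192         151.464   0.810
```

The planted +1 female shift on `cell_01` is the top sex-biased cell
(Welch t = 7.11, FDR ≈ 0 — the next best cell sits at FDR 0.09), and the
male-only TMB–immune coupling shows up as a differential correlation:

```python
res = sex_bias.sex_bias_scan(table, expr, cohort.clinical)
print(res["cells"].sort_values("fdr").head(1).round(4))
dc = diff_corr.diffcorr_scan(table, cohort.clinical)
print(dc.loc[["immune_score"]].round(4))
```

```
         t_score    p    fdr      direction
cell_01   7.1138  0.0  0.000  female_biased

              r_male  p_male  r_female  ...  z_score  p_diff  significant
immune_score  0.5092     0.0    0.1899  ...   2.5727   0.005         True
```

Here `r_male = 0.51` against `r_female = 0.19` recovers the planted
male-specific correlation (`p_diff = 0.005`).  The same comparison run on
two published coefficients — male r = 0.04 (n = 83) vs female r = −0.36
(n = 29) — gives z = 1.847, P = 0.032:

```python
cmp = diff_corr.compare_correlations(0.04, 83, -0.36, 29)
# z = 1.847, p = 0.0324
```

The `sextme` console script exposes every stage
(`simulate`, `preprocess`, `score`, `sexdiff`, `diffcorr`, `gsea`,
`mutations`, `survival`, `icb-auc`) and `sextme run --config config.yaml`
wires them end to end with a JSON manifest.

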