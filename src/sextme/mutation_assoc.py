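"""Sex-biased mutation genes and their association with immune cells.

A binary mutation matrix (non-silent records only) keeps genes mutated in
strictly more than 5% of cohort samples.  Per gene, a 2x2 mutated-by-sex
Pearson chi-square (Yates continuity correction when any expected cell is
below 5) with Benjamini-Hochberg adjustment flags sex-biased genes at
FDR < 0.25.  For each flagged gene, a multivariate logistic regression of
mutation status on all standardized cell-enrichment scores estimates
per-cell associations (Wald P, direction from the coefficient sign).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import expected_freq

from .readwrite import NON_SILENT_CLASSES
from .sex_bias import bh_fdr

logger = logging.getLogger(__name__)

MIN_MUTATION_FREQ = 0.05


def mutation_matrix(mutations: pd.DataFrame, samples: Sequence[str],
                    min_freq: float = MIN_MUTATION_FREQ) -> pd.DataFrame:
    """Binary genes x samples mutation indicator over the cohort.

    An entry is 1 iff the sample has at least one non-silent record for the
    gene.  Genes with mutation frequency strictly above ``min_freq`` are
    retained (the boundary is dropped).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample list is empty")
    nonsilent = mutations[
        mutations["variant_classification"].isin(NON_SILENT_CLASSES)
        & mutations["sample"].isin(set(samples))]
    if len(nonsilent) == 0:
        logger.warning("no non-silent mutation records for the cohort")
        return pd.DataFrame(index=pd.Index([], name="gene"), columns=samples, dtype=int)
    matrix = (pd.crosstab(nonsilent["gene"], nonsilent["sample"]) > 0).astype(int)
    matrix = matrix.reindex(columns=samples, fill_value=0)
    freq = matrix.mean(axis=1)
    kept = matrix.loc[freq > min_freq]
    if len(kept) == 0:
        logger.warning("no gene exceeds the %.0f%% mutation-frequency filter",
                       100 * min_freq)
    return kept


def chi_square_2x2(table: np.ndarray, correction: bool) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected."""
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def sex_biased_mutations(matrix: pd.DataFrame, clinical: pd.DataFrame,
                         fdr_cut: float = 0.25) -> pd.DataFrame:
    """Per-gene mutated-by-sex chi-square with BH adjustment.

    Yates continuity correction is applied when any expected cell count is
    below 5 (logged per gene).  Genes mutated in all or none of the samples
    are skipped.  Direction is called at FDR < ``fdr_cut``.
    """
    common = [s for s in matrix.columns if s in clinical.index]
    sex = clinical.loc[common, "sex"]
    male = sex == "male"
    if male.all() or (~male).all():
        raise ValueError("both sexes must be present")
    sub = matrix[common]

    rows = []
    for gene, indicator in sub.iterrows():
        mut = indicator.to_numpy(dtype=bool)
        if mut.all() or not mut.any():
            logger.warning("gene %s mutated in all or no samples; skipped", gene)
            continue
        table = np.array([
            [int((mut & male).sum()), int((mut & ~male).sum())],
            [int((~mut & male).sum()), int((~mut & ~male).sum())],
        ])
        corrected = bool(expected_freq(table).min() < 5)
        chi2, p = chi_square_2x2(table, correction=corrected)
        freq_m = table[0, 0] / male.sum()
        freq_f = table[0, 1] / (~male).sum()
        rows.append({"gene": gene, "freq_male": freq_m, "freq_female": freq_f,
                     "chi2": chi2, "corrected": corrected, "p": p})
    result = pd.DataFrame(rows)
    if len(result) == 0:
        return result
    result = result.set_index("gene")
    result["fdr"] = bh_fdr(result["p"])
    result["direction"] = np.where(
        result["fdr"] >= fdr_cut, "none",
        np.where(result["freq_male"] > result["freq_female"],
                 "male_biased", "female_biased"))
    return result


def mutation_cell_association(matrix: pd.DataFrame, cell_scores: pd.DataFrame,
                              biased_genes: Iterable[str],
                              p_cut: float = 0.05) -> pd.DataFrame:
    """Joint logistic regression of mutation status on standardized cells.

    Per gene, the binary mutation indicator is the outcome and all cell
    enrichment scores (standardized to zero mean, unit variance) enter as
    joint predictors; per-cell Wald P-values and coefficient signs give the
    up/down call in mutated patients.  Non-converged fits (e.g. perfect
    separation) are excluded with a warning.
    """
    biased_genes = list(biased_genes)
    missing = [g for g in biased_genes if g not in matrix.index]
    if missing:
        raise ValueError(f"genes absent from the mutation matrix: {missing}")
    common = [s for s in matrix.columns if s in cell_scores.index]
    cells = cell_scores.loc[common]
    std = cells.std(ddof=0)
    z = (cells - cells.mean()) / std.replace(0, np.nan)
    z = z.dropna(axis=1)
    design = sm.add_constant(z.to_numpy())

    rows = []
    for gene in biased_genes:
        y = matrix.loc[gene, common].to_numpy(dtype=float)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False):
                raise RuntimeError("did not converge")
            if not np.all(np.isfinite(fit.bse)):
                raise RuntimeError("unstable standard errors")
        except Exception as err:  # separation, singular Hessian, ...
            logger.warning("gene %s logistic fit excluded: %s", gene, err)
            continue
        for k, cell in enumerate(z.columns, start=1):
            coef = float(fit.params[k])
            rows.append({
                "gene": gene, "cell": cell, "coefficient": coef,
                "p": float(fit.pvalues[k]),
                "significant": float(fit.pvalues[k]) < p_cut,
                "direction": "up" if coef > 0 else "down",
            })
    return pd.DataFrame(rows)
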