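"""Male-vs-female comparisons of TME features and the strong/weak call.

Summary scores (TMB, immune, stromal, purity) are compared by the Wilcoxon
rank-sum test; per-cell enrichment and immune-checkpoint-gene expression by
Welch's t-test with Benjamini-Hochberg adjustment within each family.  A
cancer is called "strong sex-biased" when at least four of seven feature
flags are significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_CUT = 0.05
FDR_CUT = 0.25


def wrs_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Exact enumeration when both groups have fewer than 8 values and the data
    are tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U statistic of ``x``, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    small = min(x.size, y.size) < 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def welch_t(female: Sequence[float], male: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, female minus male.

    Positive t means the feature is higher in females.  Degenerate inputs:
    zero variance in both groups with equal means gives (0, 1); zero variance
    with unequal means gives a signed infinite t with P = 0 and a warning.
    """
    f = np.asarray(female, dtype=float)
    m = np.asarray(male, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("each group needs at least 2 values")
    if f.var(ddof=1) == 0 and m.var(ddof=1) == 0:
        if f.mean() == m.mean():
            return 0.0, 1.0
        logger.warning("zero variance with unequal means: degenerate t-test")
        return math.copysign(math.inf, f.mean() - m.mean()), 0.0
    res = stats.ttest_ind(f, m, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(effect: float, significant: bool) -> str:
    if not significant:
        return "none"
    return "female_biased" if effect > 0 else "male_biased"


def sex_bias_scan(scores: pd.DataFrame, expression: pd.DataFrame,
                  clinical: pd.DataFrame, icg_list: Iterable[str] = (),
                  p_cut: float = P_CUT, fdr_cut: float = FDR_CUT) -> dict[str, pd.DataFrame]:
    """Run every male-vs-female feature comparison for one cohort.

    Returns a dict with keys ``summary`` (WRS on tmb / immune_score /
    stromal_score / purity), ``cells`` (Welch t per enrichment column, BH
    within the family) and, when ``icg_list`` is given, ``icgs`` (Welch t
    per checkpoint gene, BH within the family).
    """
    from .scores import cell_columns

    common = clinical.index.intersection(scores.index)
    clin = clinical.loc[common]
    sc = scores.loc[common]
    female = clin.index[clin["sex"] == "female"]
    male = clin.index[clin["sex"] == "male"]
    if min(len(female), len(male)) < 10:
        logger.warning("fewer than 10 samples in one sex stratum; "
                       "sex-bias tests are low-powered")

    rows = []
    for feature in ["tmb", "immune_score", "stromal_score", "purity"]:
        stat, p = wrs_test(sc.loc[female, feature], sc.loc[male, feature])
        diff = float(sc.loc[female, feature].median() - sc.loc[male, feature].median())
        rows.append({"feature": feature, "statistic": stat, "p": p,
                     "direction": _direction(diff, p < p_cut)})
    summary = pd.DataFrame(rows).set_index("feature")

    cell_rows = []
    for cell in cell_columns(sc):
        t, p = welch_t(sc.loc[female, cell], sc.loc[male, cell])
        cell_rows.append({"feature": cell, "t_score": t, "p": p})
    cells = pd.DataFrame(cell_rows).set_index("feature")
    cells["fdr"] = bh_fdr(cells["p"])
    cells["direction"] = [_direction(t, f < fdr_cut)
                          for t, f in zip(cells["t_score"], cells["fdr"])]

    result = {"summary": summary, "cells": cells}

    icg_list = list(icg_list)
    if icg_list:
        present = [g for g in icg_list if g in expression.index]
        missing = sorted(set(icg_list) - set(present))
        if missing:
            logger.warning("%d checkpoint gene(s) absent from the matrix, "
                           "skipped: %s", len(missing), missing[:10])
        icg_rows = []
        for gene in present:
            t, p = welch_t(expression.loc[gene, female], expression.loc[gene, male])
            icg_rows.append({"feature": gene, "t_score": t, "p": p})
        icgs = pd.DataFrame(icg_rows)
        if len(icgs):
            icgs = icgs.set_index("feature")
            icgs["fdr"] = bh_fdr(icgs["p"])
            icgs["direction"] = [_direction(t, f < fdr_cut)
                                 for t, f in zip(icgs["t_score"], icgs["fdr"])]
        result["icgs"] = icgs
    return result


@dataclass
class CancerFeatureSummary:
    """The seven sex-bias feature flags and the strong/weak call for a cohort."""

    cancer_label: str
    tmb_sig: bool
    immune_sig: bool
    stromal_sig: bool
    purity_sig: bool
    cells_fraction: float
    icg_fraction: float
    pathways_fraction: float
    cells_sig: bool
    icg_sig: bool
    pathways_sig: bool
    group: str

    @property
    def n_significant(self) -> int:
        return sum([self.tmb_sig, self.immune_sig, self.stromal_sig,
                    self.purity_sig, self.cells_sig, self.icg_sig,
                    self.pathways_sig])


def classify_cancer(tmb_p: float, immune_p: float, stromal_p: float,
                    purity_p: float, cell_fdrs: Sequence[float],
                    icg_fdrs: Sequence[float], pathway_fdrs: Sequence[float],
                    p_cut: float = P_CUT, fdr_cut: float = FDR_CUT,
                    cancer_label: str = "cohort") -> CancerFeatureSummary:
    """Classify a cancer as strong or weak sex-biased.

    Seven flags: the four summary-score WRS P-values at ``p_cut``, and the
    three feature-family fractions (cells, checkpoint genes, pathways) which
    count as significant when at least one member passes ``fdr_cut``.
    Strong means at least four of the seven flags are true.
    """
    for name, p in [("tmb", tmb_p), ("immune", immune_p),
                    ("stromal", stromal_p), ("purity", purity_p)]:
        if p is None or not np.isfinite(p):
            raise ValueError(f"missing {name} P-value")

    def fraction(fdrs):
        fdrs = np.asarray(list(fdrs), dtype=float)
        if fdrs.size == 0:
            return 0.0
        return float(np.mean(fdrs < fdr_cut))

    cells_frac = fraction(cell_fdrs)
    icg_frac = fraction(icg_fdrs)
    path_frac = fraction(pathway_fdrs)
    flags = [tmb_p < p_cut, immune_p < p_cut, stromal_p < p_cut,
             purity_p < p_cut, cells_frac > 0, icg_frac > 0, path_frac > 0]
    group = "strong" if sum(flags) >= 4 else "weak"
    return CancerFeatureSummary(
        cancer_label=cancer_label,
        tmb_sig=flags[0], immune_sig=flags[1], stromal_sig=flags[2],
        purity_sig=flags[3],
        cells_fraction=cells_frac, icg_fraction=icg_frac,
        pathways_fraction=path_frac,
        cells_sig=flags[4], icg_sig=flags[5], pathways_sig=flags[6],
        group=group,
    )
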