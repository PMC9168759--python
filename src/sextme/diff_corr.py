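"""Sex-differential correlation of TMB with TME features.

Within each sex, TMB is correlated with every TME feature by Spearman's
rank correlation.  The male and female coefficients are then compared by
the Fisher z-transformation: each r is mapped through atanh, the difference
is scaled by sqrt(1/(n1-3) + 1/(n2-3)), and the resulting score is referred
to the standard normal.  The reported difference P-value is the upper-tail
probability of |z| (see :func:`compare_correlations`); a two-sided option
is exposed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Spearman correlation is undefined (constant input vector)."""


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Significance defaults to the t approximation
    ``t = r * sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom
    (two-sided).  With ``exact=True`` (n <= 8) the P-value is the exact
    permutation probability of ``|rho| >= |rho_observed|`` over all n!
    orderings of one vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    r = float(stats.spearmanr(x, y).statistic)
    if not exact:
        return r, spearman_p(r, x.size)
    if x.size > 8:
        raise ValueError("exact mode supported only for n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    tol = 1e-12
    r_obs = abs(_rank_corr(rx, ry))
    for perm in itertools.permutations(range(x.size)):
        total += 1
        if abs(_rank_corr(rx, ry[list(perm)])) >= r_obs - tol:
            count += 1
    return r, count / total


def spearman_p(r: float, n: int) -> float:
    """Two-sided t-approximation significance of a Spearman coefficient:
    ``t = r * sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom."""
    if n < 4:
        raise ValueError("need at least 4 observations")
    if abs(r) >= 1.0:
        return 2.0 / math.factorial(n) if n <= 12 else 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def fisher_z(r: float) -> float:
    """Fisher z-transform ``0.5 * ln((1+r)/(1-r))`` of a correlation."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation {r} outside (-1, 1)")
    return float(np.arctanh(r))


@dataclass
class CorrelationComparison:
    """Male-vs-female comparison of one feature's correlation with TMB."""

    feature: str
    r_male: float
    r_female: float
    n1: int
    n2: int
    z_male: float
    z_female: float
    z_score: float
    p_diff: float
    p_male: float = float("nan")
    p_female: float = float("nan")


def compare_correlations(r_male: float, n1: int, r_female: float, n2: int,
                         two_sided: bool = False,
                         feature: str = "") -> CorrelationComparison:
    """Compare two independent correlations via the Fisher z-transformation.

    ``z_score = (atanh(r_male) - atanh(r_female)) / sqrt(1/(n1-3) + 1/(n2-3))``.
    By default ``p_diff = 1 - Phi(|z_score|)``, the upper-tail standard-normal
    probability of the absolute score — the convention under which the
    module's reference worked example reproduces its published value; pass
    ``two_sided=True`` for ``2 * (1 - Phi(|z|))``.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each group needs more than 3 observations")
    z_m = fisher_z(r_male)
    z_f = fisher_z(r_female)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z_m - z_f) / se
    p = stats.norm.sf(abs(z))
    if two_sided:
        p = 2.0 * p
    return CorrelationComparison(
        feature=feature, r_male=r_male, r_female=r_female, n1=n1, n2=n2,
        z_male=z_m, z_female=z_f, z_score=float(z), p_diff=float(p))


def diffcorr_scan(scores: pd.DataFrame, clinical: pd.DataFrame,
                  two_sided: bool = False,
                  p_cut: float = 0.05) -> pd.DataFrame:
    """Per-feature Spearman (TMB vs feature) within each sex plus the
    Fisher-z comparison of the two coefficients.

    Features are the immune score, stromal score, purity and every cell
    enrichment column.  Failures on individual features (constant input,
    |r| = 1) drop that row with a warning.
    """
    from .scores import cell_columns

    common = clinical.index.intersection(scores.index)
    clin = clinical.loc[common]
    sc = scores.loc[common]
    male = clin.index[clin["sex"] == "male"]
    female = clin.index[clin["sex"] == "female"]
    if min(len(male), len(female)) < 4:
        raise ValueError("need at least 4 patients per sex")

    features = ["immune_score", "stromal_score", "purity"] + cell_columns(sc)
    rows = []
    for feature in features:
        try:
            r_m, p_m = spearman(sc.loc[male, "tmb"], sc.loc[male, feature])
            r_f, p_f = spearman(sc.loc[female, "tmb"], sc.loc[female, feature])
            cmp = compare_correlations(r_m, len(male), r_f, len(female),
                                       two_sided=two_sided, feature=feature)
        except ValueError as err:
            logger.warning("feature %s skipped: %s", feature, err)
            continue
        rows.append({
            "feature": feature, "r_male": r_m, "p_male": p_m,
            "r_female": r_f, "p_female": p_f,
            "n1": len(male), "n2": len(female),
            "z_score": cmp.z_score, "p_diff": cmp.p_diff,
            "significant": cmp.p_diff < p_cut,
        })
    return pd.DataFrame(rows).set_index("feature")
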