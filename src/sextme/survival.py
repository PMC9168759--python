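"""Sex-specific immune-cell prognostic models.

Within a sex stratum, each cell-enrichment score is screened by a
univariate Cox proportional-hazards model (partial likelihood with Efron
tie handling).  Cells with Wald P < 0.05 form the stratum's prognostic
signature; each patient's risk score is the sum of univariate coefficients
times infiltration levels.  A median split on the risk score defines
high/low-risk groups compared by Kaplan-Meier curves and the log-rank
test, and a multivariable Cox fit adjusts the risk score for age and
ordinal tumor stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


class NoEventsError(ValueError):
    """No observed events in the stratum."""


class CollinearityError(ValueError):
    """Rank-deficient covariate design."""


@dataclass
class CoxResult:
    covariate: str
    beta: float
    hr: float
    se: float
    wald_p: float
    n: int
    n_events: int
    converged: bool = True


@dataclass
class PrognosticSignature:
    """Sex-specific prognostic cell set with univariate Cox coefficients."""

    sex: str
    betas: dict[str, float] = field(default_factory=dict)
    all_results: pd.DataFrame = None

    @property
    def cells(self) -> list[str]:
        return list(self.betas)


def _check_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size != event.size:
        raise ValueError("time and event must have equal length")
    if np.any(time < 0) or np.any(~np.isfinite(time)):
        raise ValueError("times must be finite and non-negative")
    if not set(np.unique(event)) <= {0.0, 1.0}:
        raise ValueError("event indicators must be 0/1")
    if event.sum() == 0:
        raise NoEventsError("no observed events")
    return time, event


def cox_univariate(time, event, covariate, name: str = "covariate") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Newton solver)."""
    time, event = _check_survival(time, event)
    x = np.asarray(covariate, dtype=float)
    if np.unique(x).size == 1:
        raise ValueError(f"constant covariate {name!r}")
    frame = pd.DataFrame({"time": time, "event": event, name: x})
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as err:
        logger.warning("Cox fit for %s failed: %s", name, err)
        return CoxResult(name, np.nan, np.nan, np.nan, np.nan,
                         len(time), int(event.sum()), converged=False)
    summary = fitter.summary.loc[name]
    return CoxResult(
        covariate=name,
        beta=float(summary["coef"]),
        hr=float(np.exp(summary["coef"])),
        se=float(summary["se(coef)"]),
        wald_p=float(summary["p"]),
        n=len(time), n_events=int(event.sum()),
    )


def build_signature(cell_scores: pd.DataFrame, clinical: pd.DataFrame,
                    sex: str, p_cut: float = 0.05) -> PrognosticSignature:
    """Univariate Cox screen of every cell within one sex stratum.

    Cells with Wald P < ``p_cut`` enter the signature with their univariate
    coefficients.  An empty signature is allowed (warned); downstream
    stratification is then refused.
    """
    from .scores import cell_columns

    stratum = clinical.index[clinical["sex"] == sex]
    stratum = stratum.intersection(cell_scores.index)
    clin = clinical.loc[stratum]
    usable = clin["os_time"].notna() & clin["os_event"].notna()
    clin = clin.loc[usable]
    if len(clin) < 10 or float(clin["os_event"].sum()) < 5:
        logger.warning("%s stratum has <10 patients or <5 events; "
                       "Cox screen is low-powered", sex)
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=float)
    _check_survival(time, event)

    rows = []
    betas = {}
    for cell in cell_columns(cell_scores):
        try:
            res = cox_univariate(time, event, cell_scores.loc[clin.index, cell],
                                 name=cell)
        except ValueError as err:
            logger.warning("cell %s skipped in Cox screen: %s", cell, err)
            continue
        rows.append({"covariate": cell, "beta": res.beta, "hr": res.hr,
                     "se": res.se, "wald_p": res.wald_p, "n": res.n,
                     "n_events": res.n_events, "converged": res.converged})
        if res.converged and res.wald_p < p_cut:
            betas[cell] = res.beta
    if not betas:
        logger.warning("no prognostic cell at P < %.2f in the %s stratum",
                       p_cut, sex)
    return PrognosticSignature(sex=sex, betas=betas,
                               all_results=pd.DataFrame(rows).set_index("covariate"))


def risk_score(signature: PrognosticSignature,
               cell_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-patient risk score ``sum_k beta_k * a_k`` and the median split.

    Scores strictly above the median are high-risk; ties at the median go
    to the low-risk group.  An empty signature refuses stratification.
    """
    if not signature.betas:
        raise ValueError("empty signature: stratification refused")
    missing = [c for c in signature.cells if c not in cell_scores.columns]
    if missing:
        raise ValueError(f"cell column(s) missing from scores: {missing}")
    beta = pd.Series(signature.betas)
    score = cell_scores[beta.index].to_numpy() @ beta.to_numpy()
    result = pd.DataFrame({"risk_score": score}, index=cell_scores.index)
    median = float(np.median(score))
    result["group"] = np.where(score > median, "high", "low")
    return result


def km_curves(time, event, groups) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves per group (long format)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.asarray(groups)
    frames = []
    for label in np.unique(groups):
        mask = groups == label
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask], label=str(label))
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curve.insert(0, "group", str(label))
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def logrank_chi2(time, event, mask_a) -> float:
    """Two-group log-rank chi-square from observed-minus-expected events
    over risk sets, with the hypergeometric variance (1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    observed = expected = variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & mask_a).sum()
        deaths = ((time == t) & (event == 1)).sum()
        deaths_a = ((time == t) & (event == 1) & mask_a).sum()
        observed += deaths_a
        expected += deaths * n_a / n
        if n > 1:
            variance += deaths * (n_a / n) * (1 - n_a / n) * (n - deaths) / (n - 1)
    if variance == 0:
        return 0.0
    return float((observed - expected) ** 2 / variance)


def km_logrank(time, event, groups,
               exact: bool = False) -> tuple[pd.DataFrame, float, float]:
    """Two-group log-rank test plus the per-group Kaplan-Meier curves.

    The default P-value is the 1-df chi-square approximation.  With
    ``exact=True`` (total n <= 12) the P-value is the complete relabeling
    permutation probability of a chi-square at least as large as observed.
    """
    time, event = _check_survival(time, event)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2 or any((groups == g).sum() == 0 for g in labels):
        raise ValueError("exactly two non-empty groups required")
    curves = km_curves(time, event, groups)
    a = groups == labels[0]
    res = logrank_test(time[a], time[~a], event[a], event[~a])
    chi2 = float(res.test_statistic)
    if not exact:
        return curves, chi2, float(res.p_value)
    if len(time) > 12:
        raise ValueError("exact mode supported only for total n <= 12")
    import itertools

    observed = logrank_chi2(time, event, a)
    n_a = int(a.sum())
    hits = total = 0
    for combo in itertools.combinations(range(len(time)), n_a):
        mask = np.zeros(len(time), dtype=bool)
        mask[list(combo)] = True
        total += 1
        if logrank_chi2(time, event, mask) >= observed - 1e-9:
            hits += 1
    return curves, chi2, hits / total


_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def stage_to_ordinal(stage) -> float:
    """Ordinal tumor-stage encoding: I -> 1 ... IV -> 4.

    Accepts tokens like 'II', 'Stage IIIA', '3'; unrecognized values are
    missing.
    """
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return np.nan
    token = str(stage).strip().lower()
    token = re.sub(r"^stage\s*", "", token)
    token = re.sub(r"[abc]$", "", token)
    if token in _ROMAN:
        return float(_ROMAN[token])
    if token in {"1", "2", "3", "4"}:
        return float(token)
    return np.nan


def cox_multivariable(time, event, covariates: pd.DataFrame) -> pd.DataFrame:
    """Joint Efron partial-likelihood Cox fit of named covariates.

    Rank-deficient designs raise :class:`CollinearityError` naming the
    offending column(s).  Returns one row per covariate (beta, HR, se,
    Wald P).
    """
    time, event = _check_survival(time, event)
    X = covariates.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; drop those rows first")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        # identify columns that do not increase rank when added in order
        offending = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            candidate = centered[:, kept + [j]]
            if np.linalg.matrix_rank(candidate) == len(kept):
                offending.append(covariates.columns[j])
            else:
                kept.append(j)
        raise CollinearityError(f"collinear covariate column(s): {offending}")
    frame = covariates.copy()
    frame["time"] = time
    frame["event"] = event
    fitter = CoxPHFitter()
    fitter.fit(frame, duration_col="time", event_col="event")
    summary = fitter.summary
    return pd.DataFrame({
        "beta": summary["coef"],
        "hr": np.exp(summary["coef"]),
        "se": summary["se(coef)"],
        "wald_p": summary["p"],
        "n": len(time),
        "n_events": int(event.sum()),
    })
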