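"""Sex-stratified ROC/AUC of TMB as a predictor of immunotherapy response.

The AUC is the Mann-Whitney probability that a responder's TMB exceeds a
non-responder's, with half-credit for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)


@dataclass
class AucResult:
    sex: str
    n_responders: int
    n_nonresponders: int
    auc: float
    roc_points: pd.DataFrame = field(default=None, repr=False)


def auc_score(scores, labels) -> float:
    """Rank-based AUC of ``scores`` for binary ``labels`` (1 = positive)."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("need at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def tmb_auc(tmb: pd.Series, clinical: pd.DataFrame) -> list[AucResult]:
    """Per-sex AUC of TMB for responder vs non-responder.

    Strata missing either class (or response labels entirely) are skipped
    with a warning.
    """
    common = clinical.index.intersection(tmb.index)
    clin = clinical.loc[common]
    results = []
    for sex in ("male", "female"):
        stratum = clin.index[(clin["sex"] == sex) & clin["response"].notna()]
        if len(stratum) == 0:
            logger.warning("%s stratum has no response labels; skipped", sex)
            continue
        labels = (clin.loc[stratum, "response"] == "responder").astype(int).to_numpy()
        values = tmb.loc[stratum].to_numpy(dtype=float)
        if labels.sum() == 0 or labels.sum() == labels.size:
            logger.warning("%s stratum lacks a response class; skipped", sex)
            continue
        fpr, tpr, thresholds = roc_curve(labels, values)
        results.append(AucResult(
            sex=sex,
            n_responders=int(labels.sum()),
            n_nonresponders=int(labels.size - labels.sum()),
            auc=auc_score(values, labels),
            roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr,
                                     "threshold": thresholds}),
        ))
    return results
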