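"""Cohort assembly filters and expression normalization.

Samples are retained when aged 18-85 inclusive, with known sex and at least
moderate immune infiltration (an upstream deconvolution call supplied as a
boolean flag).  Genes whose zero-expression fraction exceeds 90% of samples
are removed, and the surviving FPKM values are log2(x+1)-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """Every sample was removed by the cohort filters."""


class EmptyMatrixError(ValueError):
    """Every gene was removed by the zero-expression filter."""


@dataclass
class Cohort:
    """A filtered cancer cohort ready for scoring.

    ``expression`` is genes x samples; every expression sample appears in
    ``clinical``; ``mutations`` is restricted to cohort samples.
    """

    expression: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    cancer_label: str = "cohort"
    filter_report: pd.DataFrame = field(default=None, repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def n_by_sex(self) -> dict[str, int]:
        counts = self.clinical["sex"].value_counts()
        return {"male": int(counts.get("male", 0)), "female": int(counts.get("female", 0))}


def filter_samples(clinical: pd.DataFrame, expression: pd.DataFrame,
                   mutations: pd.DataFrame, *, min_age: float = 18,
                   max_age: float = 85, cancer_label: str = "cohort") -> Cohort:
    """Apply the cohort inclusion filters and assemble a :class:`Cohort`.

    Retains samples with ``min_age <= age <= max_age`` (missing age is
    excluded), known sex and ``immune_infiltrated`` true, intersected with
    the expression columns.  Mutation records for non-cohort samples are
    dropped.  Per-reason drop counts are attached as ``filter_report``.
    """
    clin = clinical.copy()
    in_expr = clin.index.isin(expression.columns)
    age = pd.to_numeric(clin["age"], errors="coerce")
    age_ok = (age >= min_age) & (age <= max_age)
    sex_ok = clin["sex"].isin(["male", "female"])
    infiltrated = clin["immune_infiltrated"].astype(bool)

    keep = in_expr & age_ok.to_numpy() & sex_ok.to_numpy() & infiltrated.to_numpy()
    report = pd.DataFrame({
        "reason": ["no_expression", "age_out_of_range", "missing_sex",
                   "not_immune_infiltrated", "retained"],
        "n": [int((~in_expr).sum()),
              int((in_expr & ~age_ok.to_numpy()).sum()),
              int((in_expr & age_ok.to_numpy() & ~sex_ok.to_numpy()).sum()),
              int((in_expr & age_ok.to_numpy() & sex_ok.to_numpy()
                   & ~infiltrated.to_numpy()).sum()),
              int(keep.sum())],
    })
    if not keep.any():
        raise EmptyCohortError("no samples pass the cohort filters")
    retained = clin.index[keep]
    counts = clin.loc[retained, "sex"].value_counts()
    if min(int(counts.get("male", 0)), int(counts.get("female", 0))) < 10:
        logger.warning("cohort %s has < 10 samples in one sex stratum; "
                       "downstream sex-bias calls will be low-powered", cancer_label)
    cohort = Cohort(
        expression=expression.loc[:, retained].copy(),
        mutations=mutations[mutations["sample"].isin(set(retained))].reset_index(drop=True),
        clinical=clin.loc[retained].copy(),
        cancer_label=cancer_label,
        filter_report=report,
    )
    return cohort


def filter_genes(expression: pd.DataFrame, zero_fraction_threshold: float = 0.9,
                 log_transform: bool = True) -> pd.DataFrame:
    """Remove genes with > ``zero_fraction_threshold`` zero-value samples,
    then log2(x+1)-transform the remaining raw FPKM values.

    The boundary is strict: a gene at exactly the threshold is kept.
    """
    values = expression.to_numpy(dtype=float)
    zero_frac = (values == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        raise EmptyMatrixError("all genes removed by the zero-expression filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zero-expression filter removed %d of %d genes",
                    n_dropped, len(keep))
    out = expression.loc[keep]
    if log_transform:
        out = np.log2(out + 1.0)
    return out
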