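"""Per-sample tumor-microenvironment feature scores.

Four score families make up the per-sample TME feature vector:

* **TMB** — non-silent somatic mutation count divided by 38 Mb of coding
  genome (the usual whole-exome estimate).
* **Immune-cell enrichment** — a single-sample GSEA (ssGSEA) enrichment
  score per cell-type marker signature: genes are ranked within each
  sample, and the score integrates the running difference between the
  weighted in-set rank ECDF (weight exponent ``alpha = 0.25``) and the
  uniform out-of-set ECDF.  Being rank-based, the score is invariant under
  any strictly monotone transform of a sample's expression vector.
* **Immune / stromal scores** — the same ssGSEA statistic applied to an
  immune and a stromal compartment signature; their sum is the combined
  (ESTIMATE-style) score.
* **Tumor purity** — the published non-linear calibration
  ``cos(0.6049872018 + 0.0001467884 * combined_score)``, clamped to [0, 1].
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .readwrite import NON_SILENT_CLASSES, GeneSetCollection

logger = logging.getLogger(__name__)

#: Exome coding length (Mb) used as the TMB denominator.
TMB_LENGTH_MB = 38.0

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


class DegenerateSetError(ValueError):
    """The gene set covers the whole expression matrix."""


class EmptyOverlapError(ValueError):
    """No gene-set member is present in the expression matrix."""


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def compute_tmb(mutations: pd.DataFrame, samples: Iterable[str],
                length_mb: float = TMB_LENGTH_MB) -> pd.DataFrame:
    """Tumor mutational burden per sample: non-silent count / ``length_mb``.

    Samples without mutation records get TMB 0 (with a warning).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("compute_tmb requires a non-empty sample list")
    nonsilent = mutations[mutations["variant_classification"].isin(NON_SILENT_CLASSES)]
    counts = nonsilent.groupby("sample").size()
    missing = [s for s in samples if s not in counts.index]
    if missing:
        logger.warning("%d sample(s) have no mutation records; TMB set to 0",
                       len(missing))
    n_mut = np.array([int(counts.get(s, 0)) for s in samples], dtype=float)
    return pd.DataFrame({
        "sample": samples,
        "n_mutation": n_mut.astype(int),
        "length_mb": length_mb,
        "tmb": n_mut / length_mb,
    }).set_index("sample")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _sample_order(values: np.ndarray, gene_keys: np.ndarray) -> np.ndarray:
    """Indices ordering genes by expression descending, ties by gene token
    ascending (bit-reproducible)."""
    # lexsort: last key is primary
    return np.lexsort((gene_keys, -values))


def _es_from_order(in_set_ordered: np.ndarray, ranks_alpha: np.ndarray,
                   n_out: int) -> float:
    """Integrated running-sum ES given the in-set mask in list order and the
    rank weights (already in list order)."""
    weights = np.where(in_set_ordered, ranks_alpha, 0.0)
    total = weights.sum()
    step_in = weights / total
    step_out = np.where(in_set_ordered, 0.0, 1.0 / n_out)
    running = np.cumsum(step_in - step_out)
    return float(running.sum())


def ssgsea_score(expression: pd.DataFrame, gene_set: Iterable[str],
                 alpha: float = 0.25) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` for every sample.

    Per sample, genes are ranked by expression descending (ties broken by
    gene token ascending); the gene at list position ``p`` carries rank
    ``N - p + 1``.  In-set steps are ``rank**alpha`` normalized to the
    in-set total; out-of-set steps are uniform; the score is the sum of the
    running in-minus-out difference over all positions.
    """
    genes = expression.index.to_numpy()
    members = set(gene_set) & set(genes)
    if not members:
        raise EmptyOverlapError("no gene-set member present in the expression matrix")
    if len(members) == len(genes):
        raise DegenerateSetError("gene set covers every gene in the matrix")
    n = len(genes)
    in_set = np.isin(genes, sorted(members))
    gene_keys = np.argsort(np.argsort(genes))  # token order as integer keys
    ranks = np.arange(n, 0, -1, dtype=float)   # rank N at the top position
    ranks_alpha = ranks ** alpha
    n_out = n - len(members)

    values = expression.to_numpy(dtype=float)
    scores = np.empty(expression.shape[1])
    for j in range(expression.shape[1]):
        order = _sample_order(values[:, j], gene_keys)
        scores[j] = _es_from_order(in_set[order], ranks_alpha, n_out)
    return pd.Series(scores, index=expression.columns, name="es")


def cell_infiltration(expression: pd.DataFrame,
                      signatures: GeneSetCollection,
                      alpha: float = 0.25) -> pd.DataFrame:
    """ssGSEA enrichment of every cell signature; samples x cells.

    Signatures with no gene in the matrix are skipped with a warning.
    Shares the per-sample ranking across signatures for speed.
    """
    if len(signatures) == 0:
        raise ValueError("signature collection is empty")
    genes = expression.index.to_numpy()
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    gene_keys = np.argsort(np.argsort(genes))
    ranks_alpha = (np.arange(n, 0, -1, dtype=float)) ** alpha

    masks, names = [], []
    for name, members in signatures.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        if not idx:
            logger.warning("signature %s has no genes in the matrix; column absent", name)
            continue
        if len(idx) == n:
            logger.warning("signature %s covers every gene; column absent", name)
            continue
        overlap = len(idx)
        logger.debug("signature %s: %d/%d genes in matrix", name, overlap, len(members))
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        masks.append(mask)
        names.append(name)
    if not masks:
        raise EmptyOverlapError("no signature overlaps the expression matrix")

    mask_matrix = np.stack(masks, axis=1)           # n_genes x n_sets
    n_out = n - mask_matrix.sum(axis=0)             # per set
    values = expression.to_numpy(dtype=float)
    out = np.empty((expression.shape[1], len(names)))
    for j in range(expression.shape[1]):
        order = _sample_order(values[:, j], gene_keys)
        ordered = mask_matrix[order]                # n_genes x n_sets
        weights = ranks_alpha[:, None] * ordered
        step_in = weights / weights.sum(axis=0, keepdims=True)
        step_out = (~ordered) / n_out[None, :]
        out[j] = np.cumsum(step_in - step_out, axis=0).sum(axis=0)
    return pd.DataFrame(out, index=expression.columns, columns=names)


# ---------------------------------------------------------------------------
# Immune / stromal / purity
# ---------------------------------------------------------------------------

def estimate_scores(expression: pd.DataFrame, stromal_set: Iterable[str],
                    immune_set: Iterable[str], alpha: float = 0.25) -> pd.DataFrame:
    """Immune and stromal ssGSEA scores and their sum, per sample."""
    immune = ssgsea_score(expression, immune_set, alpha=alpha)
    stromal = ssgsea_score(expression, stromal_set, alpha=alpha)
    return pd.DataFrame({
        "immune_score": immune,
        "stromal_score": stromal,
        "estimate_score": immune + stromal,
    })


def tumor_purity(estimate_score) -> np.ndarray:
    """Tumor purity from the combined immune+stromal score via the cosine
    calibration, clamped to [0, 1]."""
    score = np.asarray(estimate_score, dtype=float)
    raw = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * score)
    clipped = (raw < 0) | (raw > 1)
    if np.any(clipped):
        logger.warning("%d purity value(s) outside [0, 1] before clamping",
                       int(np.sum(clipped)))
    return np.clip(raw, 0.0, 1.0)


def compute_sample_scores(expression: pd.DataFrame, mutations: pd.DataFrame,
                          signatures: GeneSetCollection,
                          stromal_set: Iterable[str], immune_set: Iterable[str],
                          length_mb: float = TMB_LENGTH_MB) -> pd.DataFrame:
    """Assemble the full per-sample TME feature table.

    Columns: tmb, immune_score, stromal_score, estimate_score, purity,
    then one enrichment column per cell signature.
    """
    tmb = compute_tmb(mutations, expression.columns, length_mb=length_mb)
    est = estimate_scores(expression, stromal_set, immune_set)
    cells = cell_infiltration(expression, signatures)
    table = pd.concat([tmb[["tmb"]], est, cells], axis=1)
    table["purity"] = tumor_purity(table["estimate_score"])
    cols = ["tmb", "immune_score", "stromal_score", "estimate_score", "purity"]
    return table[cols + [c for c in table.columns if c not in cols]]


def cell_columns(scores: pd.DataFrame) -> list[str]:
    """Names of the per-cell enrichment columns in a sample-score table."""
    summary = {"tmb", "immune_score", "stromal_score", "estimate_score", "purity"}
    return [c for c in scores.columns if c not in summary]
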