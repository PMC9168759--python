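"""Two-group GSEA on the sex-difference t-score ranking.

Genes are ranked by the Welch t-score of female-minus-male expression; each
pathway's enrichment score (ES) is the signed maximal deviation of the
weighted Kolmogorov-Smirnov running sum over that ranking (hit steps
``|t|^weight`` normalized to the in-set total, miss steps uniform).
Significance comes from sex-label permutations that recompute the full
ranking: per-pathway P against the same-sign null ES pool (with a +1
pseudocount), NES as ES over the mean same-sign null magnitude, and FDR by
the sign-pooled ratio-of-tails construction, capped at 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .readwrite import GeneSetCollection

logger = logging.getLogger(__name__)


class DegenerateSetError(ValueError):
    """Pathway overlaps nothing, or everything, in the matrix."""


def _welch_t_vector(values: np.ndarray, female_mask: np.ndarray) -> np.ndarray:
    """Welch t (female - male) for every row of ``values`` at once.

    Rows with zero variance in both groups get t = 0.
    """
    f = values[:, female_mask]
    m = values[:, ~female_mask]
    nf, nm = f.shape[1], m.shape[1]
    mf, mm = f.mean(axis=1), m.mean(axis=1)
    vf = f.var(axis=1, ddof=1)
    vm = m.var(axis=1, ddof=1)
    denom = np.sqrt(vf / nf + vm / nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mf - mm) / denom, 0.0)
    return t


def rank_genes_by_t(expression: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the female-minus-male Welch t-score, descending.

    Ties are broken by gene token ascending, so the ranking is
    deterministic.  Zero-variance genes carry t = 0 and are flagged.
    """
    common = clinical.index.intersection(expression.columns)
    clin = clinical.loc[common]
    female_mask = (clin["sex"] == "female").to_numpy()
    if female_mask.sum() < 2 or (~female_mask).sum() < 2:
        raise ValueError("need at least 2 samples per sex")
    values = expression.loc[:, common].to_numpy(dtype=float)
    t = _welch_t_vector(values, female_mask)
    zero_var = (values.var(axis=1) == 0)
    if zero_var.any():
        logger.warning("%d zero-variance gene(s) ranked with t = 0",
                       int(zero_var.sum()))
    genes = expression.index.to_numpy()
    order = np.lexsort((genes, -t))
    return pd.DataFrame({"gene": genes[order], "t_score": t[order],
                         "zero_variance": zero_var[order]}).set_index("gene")


def gsea_es(ranked_genes: pd.DataFrame, gene_set, weight: float = 1.0) -> float:
    """Signed maximal-deviation enrichment score on a ranked gene list."""
    genes = ranked_genes.index.to_numpy()
    t = ranked_genes["t_score"].to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    return _es_core(hit, t, weight)


def _es_core(hit: np.ndarray, t: np.ndarray, weight: float) -> float:
    n_hit = int(hit.sum())
    n = hit.size
    if n_hit == 0 or n_hit == n:
        raise DegenerateSetError("gene set is empty or covers the whole list "
                                 "after intersection")
    w = np.where(hit, np.abs(t) ** weight, 0.0)
    total = w.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal steps
        w = hit.astype(float)
        total = float(n_hit)
    running = np.cumsum(w / total - (~hit) / (n - n_hit))
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation(expression: pd.DataFrame, clinical: pd.DataFrame,
                     pathways: GeneSetCollection, n_perm: int = 1000,
                     seed: int | None = 0, weight: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA of every pathway against the sex-difference ranking.

    Sex labels are permuted ``n_perm`` times (the t-ranking is recomputed
    per permutation, preserving gene-gene correlation).  Per pathway:
    ``p = (1 + #{same-sign |ES_null| >= |ES|}) / (1 + #same-sign)``;
    ``nes = ES / mean(|ES_null same-sign|)``; FDR is the sign-pooled
    tail-ratio over normalized null and observed scores, capped at 1.
    Fully reproducible for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    common = clinical.index.intersection(expression.columns)
    clin = clinical.loc[common]
    female_mask = (clin["sex"] == "female").to_numpy()
    if female_mask.sum() < 2 or (~female_mask).sum() < 2:
        raise ValueError("need at least 2 samples per sex")
    values = expression.loc[:, common].to_numpy(dtype=float)
    genes = expression.index.to_numpy()
    token_keys = np.argsort(np.argsort(genes))

    names, masks = [], []
    for name, members in pathways.items():
        hit = np.isin(genes, members)
        if hit.sum() == 0 or hit.sum() == len(genes):
            logger.warning("pathway %s degenerate after intersection; skipped", name)
            continue
        names.append(name)
        masks.append(hit)
    if not names:
        raise DegenerateSetError("no usable pathway after intersection")
    mask_matrix = np.stack(masks, axis=0)  # n_path x n_genes

    def all_es(fmask: np.ndarray) -> np.ndarray:
        t = _welch_t_vector(values, fmask)
        order = np.lexsort((token_keys, -t))
        t_ord = t[order]
        hits_ord = mask_matrix[:, order]
        out = np.empty(len(names))
        for i in range(len(names)):
            out[i] = _es_core(hits_ord[i], t_ord, weight)
        return out

    es_obs = all_es(female_mask)

    rng = np.random.default_rng(seed)
    null_es = np.empty((n_perm, len(names)))
    labels = female_mask.copy()
    for b in range(n_perm):
        null_es[b] = all_es(rng.permutation(labels))

    p = np.empty(len(names))
    nes = np.empty(len(names))
    null_nes = np.full_like(null_es, np.nan)
    for i, es in enumerate(es_obs):
        same = null_es[:, i] >= 0 if es >= 0 else null_es[:, i] < 0
        pool = np.abs(null_es[same, i])
        n_same = pool.size
        p[i] = (1.0 + np.sum(pool >= abs(es))) / (1.0 + n_same)
        mean_mag = pool.mean() if n_same else np.nan
        nes[i] = es / mean_mag if n_same and mean_mag > 0 else np.sign(es)
        # normalize this pathway's nulls by their own sign-matched means
        pos = null_es[:, i] >= 0
        pos_mean = np.abs(null_es[pos, i]).mean() if pos.any() else np.nan
        neg_mean = np.abs(null_es[~pos, i]).mean() if (~pos).any() else np.nan
        null_nes[pos, i] = null_es[pos, i] / pos_mean if pos.any() else np.nan
        null_nes[~pos, i] = null_es[~pos, i] / neg_mean if (~pos).any() else np.nan

    flat_null = null_nes[np.isfinite(null_nes)]
    fdr = np.empty(len(names))
    for i, score in enumerate(nes):
        if score >= 0:
            null_tail = np.mean(flat_null[flat_null >= 0] >= score) \
                if np.any(flat_null >= 0) else 0.0
            obs_tail = np.mean(nes[nes >= 0] >= score)
        else:
            null_tail = np.mean(flat_null[flat_null < 0] <= score) \
                if np.any(flat_null < 0) else 0.0
            obs_tail = np.mean(nes[nes < 0] <= score)
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0

    return pd.DataFrame({
        "pathway": names, "es": es_obs, "nes": nes, "p": p, "fdr": fdr,
        "direction": np.where(es_obs > 0, "female_biased", "male_biased"),
    }).set_index("pathway")
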