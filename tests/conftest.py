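import numpy as np
import pandas as pd
import pytest

from sextme import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A modest null cohort shared by read-only tests."""
    cfg = synthetic.SimulationConfig(
        seed=7, n_male=40, n_female=40, n_genes=400, n_cells=6,
        genes_per_signature=10, n_stromal_genes=20, n_mutation_genes=60)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(11)
    genes = [f"g{i:02d}" for i in range(20)]
    samples = [f"s{i}" for i in range(6)]
    return pd.DataFrame(rng.exponential(5.0, size=(20, 6)),
                        index=pd.Index(genes, name="gene"), columns=samples)


def brute_force_ssgsea(values: np.ndarray, genes: np.ndarray, members: set,
                       alpha: float) -> float:
    """Independent ssGSEA oracle: materialize both ECDFs explicitly.

    Positions are walked one by one; the in-set ECDF accumulates
    rank**alpha weights, the out-of-set ECDF accumulates uniform mass, and
    the score is the sum of their pointwise differences.
    """
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    n = len(genes)
    in_flags = [genes[i] in members for i in order]
    ranks = [n - p for p in range(n)]  # rank N at the top position
    weights = [(r ** alpha) if f else 0.0 for r, f in zip(ranks, in_flags)]
    total_in = sum(weights)
    n_out = n - sum(in_flags)
    es = 0.0
    ecdf_in = 0.0
    ecdf_out = 0.0
    for p in range(n):
        ecdf_in += weights[p] / total_in
        if not in_flags[p]:
            ecdf_out += 1.0 / n_out
        es += ecdf_in - ecdf_out
    return es
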