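import numpy as np
import pandas as pd
import pytest

from sextme import scores
from sextme.readwrite import GeneSetCollection

from conftest import brute_force_ssgsea


def ladder_expression():
    return pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]},
                        index=["g1", "g2", "g3", "g4", "g5"])


class TestTmb:
    def test_non_silent_count_over_38(self):
        records = pd.DataFrame({
            "sample": ["A"] * 42,
            "gene": [f"G{i}" for i in range(42)],
            "variant_classification": ["Missense_Mutation"] * 38 + ["Silent"] * 4,
        })
        tmb = scores.compute_tmb(records, ["A"])
        assert tmb.loc["A", "n_mutation"] == 38
        assert tmb.loc["A", "tmb"] == pytest.approx(1.0)

    def test_sample_without_records_gets_zero(self):
        records = pd.DataFrame({"sample": ["A"], "gene": ["G"],
                                "variant_classification": ["Missense_Mutation"]})
        tmb = scores.compute_tmb(records, ["A", "B"])
        assert tmb.loc["B", "tmb"] == 0.0

    def test_frameshift_indels_count(self):
        records = pd.DataFrame({
            "sample": ["A"] * 19, "gene": [f"G{i}" for i in range(19)],
            "variant_classification": ["Frame_Shift_Del"] * 19})
        assert scores.compute_tmb(records, ["A"]).loc["A", "tmb"] == pytest.approx(0.5)

    def test_count_conservation(self, small_cohort):
        muts = small_cohort.mutations
        samples = list(small_cohort.clinical.index)
        tmb = scores.compute_tmb(muts, samples)
        nonsilent = muts[muts["variant_classification"]
                         .isin(scores.NON_SILENT_CLASSES)]
        assert tmb["n_mutation"].sum() == len(nonsilent)


class TestSsgsea:
    def test_hand_computed_weighted_es(self):
        es = scores.ssgsea_score(ladder_expression(), {"g1", "g2"}, alpha=0.25)
        assert es.iloc[0] == pytest.approx(2.5139, abs=1e-4)

    def test_hand_computed_unweighted_es(self):
        es = scores.ssgsea_score(ladder_expression(), {"g1", "g2"}, alpha=0.0)
        assert es.iloc[0] == pytest.approx(2.5)

    def test_bottom_gene_negative_es(self):
        # running sums -0.25, -0.5, -0.75, -1.0, 0 integrate to -2.5
        es = scores.ssgsea_score(ladder_expression(), {"g5"}, alpha=0.0)
        assert es.iloc[0] == pytest.approx(-2.5)

    def test_degenerate_and_empty_sets_raise(self):
        expr = ladder_expression()
        with pytest.raises(scores.DegenerateSetError):
            scores.ssgsea_score(expr, {"g1", "g2", "g3", "g4", "g5"})
        with pytest.raises(scores.EmptyOverlapError):
            scores.ssgsea_score(expr, {"absent"})

    def test_monotone_transform_invariance(self, tiny_expression):
        gene_set = set(tiny_expression.index[:5])
        base = scores.ssgsea_score(tiny_expression, gene_set)
        doubled = scores.ssgsea_score(tiny_expression * 2 + 1, gene_set)
        pd.testing.assert_series_equal(base, doubled)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            genes = np.array([f"g{i:03d}" for i in range(n)])
            values = rng.normal(size=(n, 2))
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(genes, size=k, replace=False))
            expr = pd.DataFrame(values, index=genes, columns=["a", "b"])
            got = scores.ssgsea_score(expr, members, alpha=alpha)
            for j, col in enumerate(["a", "b"]):
                want = brute_force_ssgsea(values[:, j], genes, members, alpha)
                assert got[col] == pytest.approx(want, abs=1e-9)

    def test_sample_permutation_equivariance(self, tiny_expression):
        gene_set = set(tiny_expression.index[:4])
        base = scores.ssgsea_score(tiny_expression, gene_set)
        shuffled = tiny_expression[list(tiny_expression.columns)[::-1]]
        flipped = scores.ssgsea_score(shuffled, gene_set)
        pd.testing.assert_series_equal(base[flipped.index], flipped)


class TestCellInfiltration:
    def test_all_signatures_scored(self, small_cohort):
        expr = np.log2(small_cohort.expression + 1)
        table = scores.cell_infiltration(expr, small_cohort.signatures)
        assert table.shape[1] == len(small_cohort.signatures)

    def test_missing_signature_column_absent(self, tiny_expression):
        sigs = GeneSetCollection()
        sigs.add("present", list(tiny_expression.index[:3]))
        sigs.add("absent", ["nope1", "nope2"])
        table = scores.cell_infiltration(tiny_expression, sigs)
        assert list(table.columns) == ["present"]

    def test_matches_single_set_scorer(self, tiny_expression):
        sigs = GeneSetCollection()
        sigs.add("setA", list(tiny_expression.index[:4]))
        table = scores.cell_infiltration(tiny_expression, sigs)
        single = scores.ssgsea_score(tiny_expression, tiny_expression.index[:4])
        np.testing.assert_allclose(table["setA"], single, atol=1e-12)


class TestEstimateAndPurity:
    def test_estimate_is_sum(self, tiny_expression):
        stromal = set(tiny_expression.index[:4])
        immune = set(tiny_expression.index[4:9])
        est = scores.estimate_scores(tiny_expression, stromal, immune)
        np.testing.assert_allclose(
            est["estimate_score"], est["immune_score"] + est["stromal_score"])

    def test_raising_immune_genes_raises_immune_score(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:02d}" for i in range(50)]
        expr = pd.DataFrame(rng.normal(5, 1, size=(50, 2)),
                            index=genes, columns=["base", "boosted"])
        immune = genes[:10]
        expr.loc[immune, "boosted"] = expr.loc[immune, "base"] + 5.0
        expr.loc[genes[10:], "boosted"] = expr.loc[genes[10:], "base"]
        est = scores.estimate_scores(expr, set(genes[40:]), set(immune))
        assert est.loc["boosted", "immune_score"] > est.loc["base", "immune_score"]

    def test_purity_at_zero(self):
        assert scores.tumor_purity(0.0) == pytest.approx(0.8224, abs=1e-3)

    def test_purity_near_boundary(self):
        arg_pi_half = (np.pi / 2 - scores.PURITY_INTERCEPT) / scores.PURITY_SLOPE
        assert scores.tumor_purity(arg_pi_half) == pytest.approx(0.0, abs=1e-9)

    def test_purity_monotone_decreasing(self):
        grid = np.linspace(-3000, 6000, 50)
        purity = scores.tumor_purity(grid)
        assert np.all(np.diff(purity) <= 0)
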