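import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sextme import mutation_assoc


def chi2_closed_form(a, b, c, d, yates=False):
    """2x2 chi-square n(ad-bc)^2 / (row/col products), optional Yates."""
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0)
    return n * diff ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def make_records(sample_gene_pairs):
    return pd.DataFrame({
        "sample": [s for s, _ in sample_gene_pairs],
        "gene": [g for _, g in sample_gene_pairs],
        "variant_classification": "Missense_Mutation",
    })


class TestMutationMatrix:
    def test_frequency_boundary_strict(self):
        samples = [f"S{i}" for i in range(100)]
        pairs = [(f"S{i}", "keep") for i in range(6)] + \
                [(f"S{i}", "drop") for i in range(5)]
        matrix = mutation_assoc.mutation_matrix(make_records(pairs), samples)
        assert list(matrix.index) == ["keep"]

    def test_repeated_records_binarize(self):
        samples = [f"S{i}" for i in range(10)]
        pairs = [("S0", "G"), ("S0", "G"), ("S1", "G")]
        matrix = mutation_assoc.mutation_matrix(make_records(pairs), samples,
                                                min_freq=0.0)
        assert matrix.loc["G", "S0"] == 1
        assert matrix.loc["G"].sum() == 2

    def test_silent_records_ignored(self):
        samples = [f"S{i}" for i in range(10)]
        records = make_records([(f"S{i}", "G") for i in range(3)])
        records.loc[0, "variant_classification"] = "Silent"
        matrix = mutation_assoc.mutation_matrix(records, samples, min_freq=0.0)
        assert matrix.loc["G"].sum() == 2

    def test_frequency_count_conservation(self, small_cohort):
        samples = list(small_cohort.clinical.index)
        matrix = mutation_assoc.mutation_matrix(small_cohort.mutations, samples,
                                                min_freq=0.0)
        freqs = matrix.mean(axis=1)
        counts = freqs * len(samples)
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)


class TestSexBiasedMutations:
    def make_clinical(self, n_male, n_female):
        idx = [f"S{i}" for i in range(n_male + n_female)]
        return pd.DataFrame({"sex": ["male"] * n_male + ["female"] * n_female},
                            index=pd.Index(idx, name="sample"))

    def matrix_from_flags(self, flags):
        samples = [f"S{i}" for i in range(len(flags))]
        return pd.DataFrame([flags], index=pd.Index(["G"], name="gene"),
                            columns=samples)

    def test_uncorrected_chi2_matches_closed_form(self):
        # mutated x sex table [[8, 2], [2, 8]] -> chi2 = 7.2
        flags = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        clinical = self.make_clinical(10, 10)
        result = mutation_assoc.sex_biased_mutations(
            self.matrix_from_flags(flags), clinical)
        # expected counts are all 5, so no continuity correction applies
        assert not result.loc["G", "corrected"]
        assert result.loc["G", "chi2"] == pytest.approx(7.2)
        assert result.loc["G", "chi2"] == pytest.approx(
            chi2_closed_form(8, 2, 2, 8))

    def test_yates_closed_form(self):
        assert chi2_closed_form(8, 2, 2, 8, yates=True) == pytest.approx(5.0)
        got, _ = mutation_assoc.chi_square_2x2(
            np.array([[8, 2], [2, 8]]), correction=True)
        assert got == pytest.approx(5.0)

    def test_equal_frequencies_not_called(self):
        flags = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        result = mutation_assoc.sex_biased_mutations(
            self.matrix_from_flags(flags), self.make_clinical(10, 10))
        assert result.loc["G", "p"] == pytest.approx(1.0, abs=0.05)
        assert result.loc["G", "direction"] == "none"

    def test_uncorrected_p_matches_sf_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            table = rng.integers(1, 40, size=(2, 2))
            chi2, p = mutation_assoc.chi_square_2x2(table, correction=False)
            want = chi2_closed_form(*table.ravel())
            assert chi2 == pytest.approx(want, abs=1e-9)
            assert p == pytest.approx(stats.chi2.sf(want, df=1), abs=1e-9)

    def test_sample_order_invariance(self):
        flags = [1, 0, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0]
        clinical = self.make_clinical(10, 10)
        matrix = self.matrix_from_flags(flags)
        shuffled = matrix[matrix.columns[::-1]]
        a = mutation_assoc.sex_biased_mutations(matrix, clinical)
        b = mutation_assoc.sex_biased_mutations(shuffled, clinical)
        pd.testing.assert_frame_equal(a, b)


class TestCellAssociation:
    def test_single_binary_predictor_log_odds(self):
        # counts [[8,2],[2,8]]: fitted coefficient on the standardized
        # predictor corresponds to log OR = ln(16) on the raw 0/1 scale
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        x = np.array([1.0] * 10 + [0.0] * 10)
        samples = [f"S{i}" for i in range(20)]
        matrix = pd.DataFrame([y], index=pd.Index(["G"], name="gene"),
                              columns=samples)
        cells = pd.DataFrame({"cellA": x}, index=samples)
        result = mutation_assoc.mutation_cell_association(matrix, cells, ["G"])
        coef = result.loc[result["cell"] == "cellA", "coefficient"].iloc[0]
        # undo the standardization (sd = 0.5) to recover the raw log OR
        assert coef / x.std() == pytest.approx(np.log(16), abs=1e-3)
        assert result["direction"].iloc[0] == "up"

    def test_planted_association_detected(self):
        rng = np.random.default_rng(8)
        n = 200
        samples = [f"S{i}" for i in range(n)]
        mutated = np.zeros(n, dtype=int)
        mutated[:60] = 1
        cells = pd.DataFrame(rng.normal(size=(n, 3)),
                             index=samples, columns=["a", "b", "c"])
        cells.loc[mutated == 1, "a"] += 1.0
        matrix = pd.DataFrame([mutated], index=pd.Index(["G"], name="gene"),
                              columns=samples)
        result = mutation_assoc.mutation_cell_association(matrix, cells, ["G"])
        row = result[result["cell"] == "a"].iloc[0]
        assert row["coefficient"] > 0
        assert row["p"] < 0.05

    def test_null_coefficients_small(self):
        rng = np.random.default_rng(9)
        n = 300
        samples = [f"S{i}" for i in range(n)]
        mutated = (rng.random(n) < 0.3).astype(int)
        cells = pd.DataFrame(rng.normal(size=(n, 4)), index=samples,
                             columns=list("abcd"))
        matrix = pd.DataFrame([mutated], index=pd.Index(["G"], name="gene"),
                              columns=samples)
        result = mutation_assoc.mutation_cell_association(matrix, cells, ["G"])
        assert (result["coefficient"].abs() < 0.5).all()

    def test_perfect_separation_excluded(self):
        n = 30
        samples = [f"S{i}" for i in range(n)]
        mutated = np.array([1] * 15 + [0] * 15)
        cells = pd.DataFrame({"a": np.linspace(-1, 1, n) * mutated * 2 + mutated * 5},
                             index=samples)
        matrix = pd.DataFrame([mutated], index=pd.Index(["G"], name="gene"),
                              columns=samples)
        result = mutation_assoc.mutation_cell_association(matrix, cells, ["G"])
        assert len(result) == 0
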