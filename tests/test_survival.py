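import itertools

import numpy as np
import pandas as pd
import pytest

from sextme import survival, synthetic


def cox_grid_oracle(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    """Grid-search maximizer of the (Breslow, tie-free) partial likelihood."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    x = np.asarray(x, dtype=float)
    betas = np.arange(lo, hi + step, step)
    loglik = np.zeros_like(betas)
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    for i in np.nonzero(event == 1)[0]:
        risk = time >= time[i]
        ex = np.exp(betas[:, None] * x[None, risk])
        loglik += betas * x[i] - np.log(ex.sum(axis=1))
    return betas[np.argmax(loglik)]


def logrank_permutation_oracle(time, event, groups):
    """Exact relabeling distribution of the log-rank statistic."""
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups)
    n_a = int((groups == groups[0]).sum())
    observed = logrank_test(time[groups == groups[0]], time[groups != groups[0]],
                            event[groups == groups[0]],
                            event[groups != groups[0]]).test_statistic
    hits = total = 0
    idx = np.arange(len(groups))
    for combo in itertools.combinations(idx, n_a):
        mask = np.zeros(len(groups), dtype=bool)
        mask[list(combo)] = True
        stat = logrank_test(time[mask], time[~mask],
                            event[mask], event[~mask]).test_statistic
        total += 1
        if stat >= observed - 1e-9:
            hits += 1
    return hits / total


class TestCoxUnivariate:
    def test_matches_grid_oracle_small(self):
        # early deaths carry x=1, so beta is positive; alternating the
        # covariate keeps the partial likelihood bounded (no separation)
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = survival.cox_univariate(time, event, x)
        beta_grid = cox_grid_oracle(time, event, x, step=1e-3)
        assert res.beta > 0
        assert res.beta == pytest.approx(beta_grid, abs=2e-3)

    def test_random_small_datasets_match_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(15):
            n = int(rng.integers(5, 9))
            time = rng.permutation(np.arange(1.0, n + 1))  # no ties
            event = np.ones(n)
            x = rng.normal(size=n)
            res = survival.cox_univariate(time, event, x)
            if not res.converged or abs(res.beta) > 4:
                continue
            want = cox_grid_oracle(time, event, x, step=1e-3)
            assert res.beta == pytest.approx(want, abs=2e-3)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            survival.cox_univariate([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 1, 1])

    def test_no_events_raises(self):
        with pytest.raises(survival.NoEventsError):
            survival.cox_univariate([1, 2, 3], [0, 0, 0], [1, 2, 3])

    def test_hr_is_exp_beta_and_recovery(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        true_beta = 0.7
        t = rng.exponential(1.0 / (0.01 * np.exp(true_beta * x)))
        c = rng.uniform(0, np.quantile(t, 0.9), size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        res = survival.cox_univariate(time, event, x)
        assert res.hr == pytest.approx(np.exp(res.beta))
        assert res.beta == pytest.approx(true_beta, rel=0.2)


class TestSignatureAndRisk:
    def test_risk_score_arithmetic(self):
        sig = survival.PrognosticSignature(
            sex="male", betas={"A": 0.5, "B": -1.0})
        cells = pd.DataFrame({"A": [2.0], "B": [1.0]}, index=["S1"])
        out = survival.risk_score(sig, cells)
        assert out.loc["S1", "risk_score"] == pytest.approx(0.0)

    def test_empty_signature_refused(self):
        sig = survival.PrognosticSignature(sex="male", betas={})
        with pytest.raises(ValueError):
            survival.risk_score(sig, pd.DataFrame({"A": [1.0]}))

    def test_median_split_ties_to_low(self):
        sig = survival.PrognosticSignature(sex="male", betas={"A": 1.0})
        cells = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0]},
                             index=["a", "b", "c", "d"])
        out = survival.risk_score(sig, cells)
        assert list(out["group"]) == ["low", "low", "high", "high"]

    def test_planted_hazard_cells_recovered(self):
        cfg = synthetic.SimulationConfig(
            seed=13, n_male=150, n_female=10, n_genes=260, n_cells=6,
            genes_per_signature=10, n_stromal_genes=20, n_mutation_genes=40,
            hazard_gammas={"cell_01": 0.9, "cell_02": -0.9})
        cohort = synthetic.simulate_cohort(cfg)
        cells = cohort.truth.latent  # latent abundances as infiltration levels
        cells.columns = list(cells.columns)
        scores = cells.copy()
        scores["tmb"] = 0.0
        sig = survival.build_signature(scores, cohort.clinical, "male")
        assert "cell_01" in sig.betas and sig.betas["cell_01"] > 0
        assert "cell_02" in sig.betas and sig.betas["cell_02"] < 0


class TestKmLogrank:
    def test_hand_computed_logrank(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        curves, chi2, p = survival.km_logrank(time, event, groups)
        assert chi2 == pytest.approx(2.882, abs=5e-3)
        assert p == pytest.approx(0.090, abs=2e-3)

    def test_identical_groups_null(self):
        time = np.array([1.0, 2.0, 1.0, 2.0])
        event = np.array([1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        _, chi2, p = survival.km_logrank(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_km_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(14)
        time = rng.exponential(10, 40)
        event = (rng.random(40) < 0.7).astype(int)
        event[0] = 1
        groups = np.array(["A"] * 20 + ["B"] * 20)
        curves, _, _ = survival.km_logrank(time, event, groups)
        for _, sub in curves.groupby("group"):
            s = sub.sort_values("time")["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_exact_mode_matches_permutation_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            n = 8
            time = rng.permutation(np.arange(1.0, n + 1))
            event = np.ones(n)
            groups = np.array(["A"] * 4 + ["B"] * 4)
            _, _, p = survival.km_logrank(time, event, groups, exact=True)
            want = logrank_permutation_oracle(time, event, groups)
            assert p == pytest.approx(want, abs=0.02)

    def test_hand_statistic_matches_reference(self):
        rng = np.random.default_rng(19)
        time = rng.exponential(10, 20)
        event = (rng.random(20) < 0.7).astype(int)
        event[:2] = 1
        groups = np.array(["A"] * 10 + ["B"] * 10)
        _, chi2, _ = survival.km_logrank(time, event, groups)
        assert survival.logrank_chi2(time, event, groups == "A") == \
            pytest.approx(chi2, abs=1e-8)


class TestCoxMultivariable:
    def test_duplicated_column_collinearity(self):
        rng = np.random.default_rng(16)
        n = 50
        x = rng.normal(size=n)
        covs = pd.DataFrame({"risk_score": x, "dup": x})
        with pytest.raises(survival.CollinearityError, match="dup"):
            survival.cox_multivariable(rng.exponential(5, n),
                                       np.ones(n), covs)

    def test_single_covariate_reduces_to_univariate(self):
        rng = np.random.default_rng(17)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x)))
        event = np.ones(n)
        uni = survival.cox_univariate(t, event, x, name="x")
        multi = survival.cox_multivariable(t, event, pd.DataFrame({"x": x}))
        assert multi.loc["x", "beta"] == pytest.approx(uni.beta, abs=1e-8)

    def test_joint_planted_effects_detected(self):
        rng = np.random.default_rng(18)
        n = 300
        score = rng.normal(size=n)
        age = rng.uniform(40, 80, n)
        hazard = 0.002 * np.exp(0.8 * score + 0.04 * (age - 60))
        t = rng.exponential(1.0 / hazard)
        c = rng.uniform(0, np.quantile(t, 0.9), n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        covs = pd.DataFrame({"risk_score": score, "age": age})
        result = survival.cox_multivariable(time, event, covs)
        assert (result["wald_p"] < 0.05).all()

    def test_stage_encoding(self):
        assert survival.stage_to_ordinal("Stage IIIA") == 3
        assert survival.stage_to_ordinal("iv") == 4
        assert survival.stage_to_ordinal("2") == 2
        assert np.isnan(survival.stage_to_ordinal("x"))
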