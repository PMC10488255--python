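"""GEE logit estimation, aggregate fits, relative risks, pairwise contrasts.

statsmodels serves as the independent maximum-likelihood / GEE oracle; the
estimators under test are implemented from first principles in
``bactvolt.stats``.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bactvolt.stats import (
    CompleteSeparationError,
    cells_to_gee_data,
    fit_from_aggregates,
    fit_gee_logit,
    pairwise_comparisons,
    reconstruct_counts,
    relative_risk,
)
from bactvolt.synthgen import generate_dose_response_table


def simulate_binary(seed, n=300, n_clusters=5, beta=(0.3, 0.8)):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    cl = rng.integers(0, n_clusters, size=n)
    p = expit(beta[0] + beta[1] * x)
    y = (rng.random(n) < p).astype(float)
    return y, x, cl


class TestGEEIndependenceOracle:
    def test_matches_pooled_ml_logistic(self):
        # independence GEE solves the logistic score equations: point
        # estimates must equal pooled maximum likelihood
        import statsmodels.api as sm

        worst = 0.0
        for seed in range(20):
            y, x, cl = simulate_binary(seed, n=150)
            fit = fit_gee_logit(y, x, cl, working_correlation="independence")
            ml = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            worst = max(worst, float(np.abs(fit.beta - np.asarray(ml.params)).max()))
        assert worst <= 1e-6

    def test_single_cluster_equals_ml_with_model_se(self):
        import statsmodels.api as sm

        y, x, _ = simulate_binary(3, n=200)
        cl = np.zeros(len(y), dtype=int)
        with pytest.warns(RuntimeWarning, match="single cluster"):
            fit = fit_gee_logit(y, x, cl, working_correlation="independence")
        ml = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, np.asarray(ml.params), atol=1e-7)
        assert fit.se_type == "model"


class TestGEEExchangeable:
    def test_matches_statsmodels_gee(self):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable
        from statsmodels.genmod.families import Binomial
        from statsmodels.genmod.generalized_estimating_equations import GEE

        df = generate_dose_response_table(
            [0, 15, 60, 300], -1.0, 0.003, 3, 400, 0.15, seed=7
        )
        y, x, cl = df.y.to_numpy(float), df.x.to_numpy(float), df.replicate.to_numpy()
        mine = fit_gee_logit(y, x, cl, working_correlation="exchangeable")
        ref = GEE(
            y, sm.add_constant(x), groups=cl, family=Binomial(),
            cov_struct=Exchangeable(),
        ).fit()
        np.testing.assert_allclose(mine.beta, np.asarray(ref.params), atol=1e-6)
        np.testing.assert_allclose(mine.robust_se, np.asarray(ref.bse), rtol=1e-4)
        assert mine.alpha == pytest.approx(float(ref.cov_struct.dep_params), abs=1e-6)

    def test_flat_dose_response_gives_zero_slope(self):
        # identical depolarization proportion at every dose
        x = np.repeat([0.0, 15.0, 60.0, 300.0], 40)
        y = np.tile([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0] * 5, 4)
        cl = np.tile(np.arange(4), len(x) // 4)
        fit = fit_gee_logit(y, x, cl, working_correlation="exchangeable")
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_covariate_shift_moves_only_intercept(self):
        y, x, cl = simulate_binary(11, n=400)
        a = fit_gee_logit(y, x, cl, working_correlation="exchangeable")
        b = fit_gee_logit(y, x + 10.0, cl, working_correlation="exchangeable")
        assert abs(a.beta[1] - b.beta[1]) <= 1e-8
        assert a.beta[0] == pytest.approx(b.beta[0] + 10.0 * b.beta[1], abs=1e-6)

    def test_sandwich_matches_model_se_without_clustering(self):
        # replicate_sd = 0, many clusters: robust and model-based standard
        # errors estimate the same quantity
        df = generate_dose_response_table(
            [0, 15, 60, 300], -1.0, 0.003, 30, 100, 0.0, seed=13
        )
        fit = fit_gee_logit(
            df.y.to_numpy(float), df.x.to_numpy(float), df.replicate.to_numpy(),
            working_correlation="exchangeable",
        )
        np.testing.assert_allclose(fit.robust_se, fit.model_se, rtol=0.25)

    def test_complete_separation_raises(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        cl = np.tile(np.arange(4), 10)
        with pytest.raises(CompleteSeparationError):
            fit_gee_logit(y, x, cl)

    def test_parameter_recovery_small(self):
        # scaled-down recovery check (the full 200-run version lives in the
        # acceptance suite): mean slope over 25 sims within 3 MC SEs of truth
        beta1 = 0.00325
        est = []
        for seed in range(25):
            df = generate_dose_response_table(
                [0, 15, 60, 300], -1.02, beta1, 3, 250, 0.1, seed=seed
            )
            est.append(
                fit_gee_logit(
                    df.y.to_numpy(float), df.x.to_numpy(float),
                    df.replicate.to_numpy(), "exchangeable",
                ).beta[1]
            )
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - beta1) <= 3 * mc_se


class TestAggregateFits:
    def test_aggregate_equals_expanded_individual_fit(self):
        agg = pd.DataFrame(
            {"x": [0.0, 15.0, 60.0, 300.0],
             "n_total": [50, 60, 55, 40],
             "n_depolarized": [9, 17, 21, 19]}
        )
        from_agg = fit_from_aggregates(agg)
        y, x, cl = [], [], []
        for i, row in agg.iterrows():
            k, n = int(row.n_depolarized), int(row.n_total)
            y += [1.0] * k + [0.0] * (n - k)
            x += [row.x] * n
            cl += [i] * n
        expanded = fit_gee_logit(
            np.array(y), np.array(x), np.array(cl),
            working_correlation="independence",
        )
        np.testing.assert_allclose(from_agg.beta, expanded.beta, atol=1e-10)

    def test_two_equal_proportions_give_zero_slope(self):
        agg = pd.DataFrame(
            {"x": [0.0, 1.0], "n_total": [100, 200], "n_depolarized": [25, 50]}
        )
        assert fit_from_aggregates(agg).beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_slope_robust_to_one_count_perturbation(self):
        # half-up rounding can move any reconstructed count by 1; the fitted
        # slope must not move at the printed precision
        base = reconstruct_counts(
            [21.03, 26.13, 37.59, 47.38], [2808, 3243, 3438, 3101], x=[0, 15, 60, 300]
        )
        slope = fit_from_aggregates(base).beta[1]
        for i in range(4):
            for delta in (-1, 1):
                bumped = base.copy()
                bumped.loc[i, "n_depolarized"] += delta
                s = fit_from_aggregates(bumped).beta[1]
                assert abs(s - slope) < 5e-6

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fit_from_aggregates(pd.DataFrame({"x": [0, 1]}))


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "pct,total,expected",
        [(50.0, 10, 5), (21.03, 2808, 591), (0.0, 1000, 0), (100.0, 7, 7)],
    )
    def test_half_up_rounding(self, pct, total, expected):
        out = reconstruct_counts([pct], [total])
        assert int(out["n_depolarized"].iloc[0]) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            reconstruct_counts([50.0], [10, 20])

    def test_covariate_column_attached(self):
        out = reconstruct_counts([10.0, 20.0], [100, 100], x=[0, 15])
        assert list(out.columns) == ["x", "n_total", "n_depolarized"]


class TestRelativeRisk:
    def test_equal_probabilities_give_unity(self):
        assert relative_risk(0.3, 0.3).rr == pytest.approx(1.0)

    def test_neurotransmitter_style_decline(self):
        # control 48.95% vs glutamate 28.46%: crude ratio 0.5814
        assert relative_risk(0.4895, 0.2846).rr == pytest.approx(0.5814, abs=5e-4)

    def test_growth_style_increase(self):
        assert relative_risk(0.3815, 0.4104).rr == pytest.approx(1.0758, abs=5e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(0.0, 0.5)


class TestPairwiseComparisons:
    @staticmethod
    def build(groups_fracs, n_per=400, n_reps=3, sd=0.05, seed=0):
        rng = np.random.default_rng(seed)
        from scipy.special import logit as _logit

        rows = []
        for g, f in groups_fracs.items():
            for r in range(n_reps):
                p = expit(_logit(f) + rng.normal(0, sd))
                rows.append(
                    pd.DataFrame(
                        {"y": (rng.random(n_per) < p).astype(int),
                         "condition": g, "cluster": f"{g}/R{r}"}
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_identical_groups_give_rr_one_p_large(self):
        data = self.build({"A": 0.4, "B": 0.4}, seed=21)
        (res,) = pairwise_comparisons(data)
        assert res.rr == pytest.approx(1.0, abs=0.15)
        assert res.p_value > 0.05

    def test_three_groups_give_three_contrasts(self):
        data = self.build({"A": 0.2, "B": 0.4, "C": 0.5}, seed=22)
        results = pairwise_comparisons(data)
        assert len(results) == 3
        assert {(r.group_a, r.group_b) for r in results} == {
            ("A", "B"), ("A", "C"), ("B", "C")
        }

    def test_detects_a_large_difference(self):
        data = self.build({"Control": 0.2, "KCl300": 0.5}, n_per=2000, seed=23)
        (res,) = pairwise_comparisons(data)
        assert res.p_value < 0.001
        assert res.rr == pytest.approx(2.5, rel=0.2)

    def test_bonferroni_inflates_p(self):
        data = self.build({"A": 0.35, "B": 0.4, "C": 0.45}, seed=24)
        raw = pairwise_comparisons(data)
        adj = pairwise_comparisons(data, bonferroni=True)
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, 3 * r.p_value))


class TestCellsToGEEData:
    def test_binary_outcome_and_cluster_labels(self):
        from conftest import make_cell_table

        table = pd.concat(
            [make_cell_table([10.0, 20.0], condition="A", replicate="R1"),
             make_cell_table([30.0], condition="B", replicate="R1")],
            ignore_index=True,
        )
        data = cells_to_gee_data(table, 15.0)
        assert list(data["y"]) == [0, 1, 1]
        # replicates of different conditions are distinct panels
        assert set(data["cluster"]) == {"A/R1", "B/R1"}
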