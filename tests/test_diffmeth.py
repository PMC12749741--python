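"""Group linear models, empirical-Bayes moderation, BH and DMC calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from crcmeth.core import MValueMatrix
from crcmeth.diffmeth import (
    EBayesParams,
    bh_adjust,
    call_dmcs,
    dmc_union,
    estimate_ebayes_params,
    fit_group_model,
    moderate_and_test,
    posterior_variance,
    run_dmc_analysis,
)


def _mv(values: np.ndarray, groups: list[str]) -> MValueMatrix:
    frame = pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(values.shape[0])],
        columns=[f"S{i}" for i in range(values.shape[1])],
    )
    return MValueMatrix(values=frame, groups=pd.Series(groups, index=frame.columns))


class TestFitGroupModel:
    def test_hand_ols_oracle(self):
        # probe with g1: (1, 3), g2: (5, 7): means (2, 6), pooled s2 = 2, df = 2
        mv = _mv(np.array([[1.0, 3.0, 5.0, 7.0]]), ["NONTUMOR"] * 2 + ["ADK"] * 2)
        fit = fit_group_model(mv)
        assert fit.means.loc["p0", "NONTUMOR"] == 2.0
        assert fit.means.loc["p0", "ADK"] == 6.0
        assert fit.s2.loc["p0"] == pytest.approx(2.0)
        assert fit.df.loc["p0"] == 2.0

    def test_zero_within_group_variance(self):
        mv = _mv(np.array([[1.0, 1.0, 5.0, 5.0]]), ["NONTUMOR"] * 2 + ["ADK"] * 2)
        fit = fit_group_model(mv)
        assert fit.s2.loc["p0"] == 0.0

    def test_equal_groups_zero_delta(self):
        mv = _mv(
            np.array([[2.0, 4.0, 2.0, 4.0]]), ["NONTUMOR"] * 2 + ["ADK"] * 2
        )
        fit = fit_group_model(mv)
        assert fit.means.loc["p0", "ADK"] - fit.means.loc["p0", "NONTUMOR"] == 0.0

    def test_missing_values_adjust_df(self):
        vals = np.array([[1.0, 3.0, np.nan, 5.0, 7.0, 9.0]])
        mv = _mv(vals, ["NONTUMOR"] * 3 + ["ADK"] * 3)
        fit = fit_group_model(mv)
        assert fit.df.loc["p0"] == 3.0  # 5 observations - 2 groups
        assert fit.n_obs.loc["p0", "NONTUMOR"] == 2

    def test_four_group_fit_matches_anova_residuals(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 12))
        groups = ["NONTUMOR"] * 3 + ["LGA"] * 3 + ["HGA"] * 3 + ["ADK"] * 3
        fit = fit_group_model(_mv(vals, groups))
        # oracle: residual mean square of the one-way ANOVA per probe
        for i in range(5):
            parts = [vals[i, 0:3], vals[i, 3:6], vals[i, 6:9], vals[i, 9:12]]
            ss = sum(((p - p.mean()) ** 2).sum() for p in parts)
            assert fit.s2.iloc[i] == pytest.approx(ss / 8)
            assert fit.df.iloc[i] == 8.0


class TestEstimateEbayes:
    def test_recovers_generative_parameters(self):
        # s2 ~ s02 * F(d, d0): inverse-chisq prior scaled by chisq sampling
        rng = np.random.default_rng(5)
        d0, s02, d, n = 4.0, 1.0, 6, 200_000
        s2 = (s02 * d0 / rng.chisquare(d0, n)) * rng.chisquare(d, n) / d
        p = estimate_ebayes_params(s2, d)
        assert 3.5 <= p.d0 <= 4.5
        assert 0.95 <= p.s02 <= 1.05

    def test_constant_variances_give_infinite_d0(self):
        p = estimate_ebayes_params(np.full(500, 2.0), 6)
        assert np.isinf(p.d0)
        assert p.s02 == pytest.approx(2.0, rel=1e-6)

    def test_bisection_satisfies_trigamma_equation(self):
        rng = np.random.default_rng(6)
        d0, s02, d, n = 3.0, 2.0, 4, 50_000
        s2 = (s02 * d0 / rng.chisquare(d0, n)) * rng.chisquare(d, n) / d
        p = estimate_ebayes_params(s2, d)
        z = np.log(s2)
        target = np.var(z, ddof=1) - special.polygamma(1, d / 2.0)
        assert abs(special.polygamma(1, p.d0 / 2.0) - target) < 1e-6

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            estimate_ebayes_params(np.ones(10), 4)


class TestModerateAndTest:
    def test_posterior_variance_example(self):
        # (d0*s02 + d*s2)/(d0+d) = (4*1 + 4*3)/8 = 2
        out = posterior_variance(np.array([3.0]), np.array([4.0]), EBayesParams(4, 1))
        assert out[0] == pytest.approx(2.0)

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(20, 8))
        mv = _mv(vals, ["NONTUMOR"] * 4 + ["ADK"] * 4)
        fit = fit_group_model(mv)
        rec = moderate_and_test(fit, EBayesParams(0.0, 1.0), ("NONTUMOR", "ADK"))
        for i in range(20):
            res = stats.ttest_ind(vals[i, 4:], vals[i, :4], equal_var=True)
            assert rec["t"].iloc[i] == pytest.approx(res.statistic, abs=1e-10)
            assert rec["p"].iloc[i] == pytest.approx(res.pvalue, abs=1e-10)

    def test_matches_independent_formula_evaluation(self):
        """Moderated t, df and p agree with a brute-force evaluation of the
        posterior-variance and t-CDF formulas on 20 fixture probes."""
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(20, 10))
        mv = _mv(vals, ["NONTUMOR"] * 5 + ["ADK"] * 5)
        fit = fit_group_model(mv)
        params = EBayesParams(d0=4.0, s02=0.8)
        rec = moderate_and_test(fit, params, ("NONTUMOR", "ADK"))
        for i in range(20):
            a, b = vals[i, :5], vals[i, 5:]
            s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 8
            s2_post = (4.0 * 0.8 + 8 * s2) / (4.0 + 8)
            t_expect = (b.mean() - a.mean()) / np.sqrt(s2_post * (1 / 5 + 1 / 5))
            p_expect = 2 * (1 - stats.t.cdf(abs(t_expect), 12))
            assert rec["t"].iloc[i] == pytest.approx(t_expect, abs=1e-8)
            assert rec["df_total"].iloc[i] == pytest.approx(12.0)
            assert rec["p"].iloc[i] == pytest.approx(p_expect, abs=1e-8)

    def test_infinite_d0_gives_z_statistic(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(50, 8))
        mv = _mv(vals, ["NONTUMOR"] * 4 + ["ADK"] * 4)
        fit = fit_group_model(mv)
        s02 = 1.3
        rec = moderate_and_test(fit, EBayesParams(np.inf, s02), ("NONTUMOR", "ADK"))
        delta = (fit.means["ADK"] - fit.means["NONTUMOR"]).to_numpy()
        z = delta / np.sqrt(s02 * (1 / 4 + 1 / 4))
        assert np.allclose(rec["t"].to_numpy(), z)
        assert np.allclose(rec["p"], 2 * stats.norm.sf(np.abs(z)))

    def test_huge_d0_approaches_infinite_limit(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(30, 8))
        mv = _mv(vals, ["NONTUMOR"] * 4 + ["ADK"] * 4)
        fit = fit_group_model(mv)
        rec_big = moderate_and_test(fit, EBayesParams(1e8, 1.0), ("NONTUMOR", "ADK"))
        rec_inf = moderate_and_test(fit, EBayesParams(np.inf, 1.0), ("NONTUMOR", "ADK"))
        assert np.allclose(rec_big["t"], rec_inf["t"], atol=1e-4)

    def test_zero_variance_probe_rescued_by_moderation(self):
        mv = _mv(np.array([[1.0, 1.0, 5.0, 5.0]]), ["NONTUMOR"] * 2 + ["ADK"] * 2)
        fit = fit_group_model(mv)
        rec = moderate_and_test(fit, EBayesParams(4.0, 1.0), ("NONTUMOR", "ADK"))
        assert np.isfinite(rec["t"].iloc[0])


class TestBhAdjust:
    def test_hand_step_up(self):
        # q_(3) = 0.03; q_(2) = min(0.03, 0.02*3/2)=0.03; q_(1) = min(0.03, 0.01*3)=0.03
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_second_hand_fixture(self):
        p = [0.005, 0.04, 0.2, 0.9]
        expected = [0.02, 0.08, 0.8 / 3, 0.9]
        assert np.allclose(bh_adjust(p), expected)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDmcs:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["probe_id", "contrast", "delta_m", "t", "df_total", "p"]
        )

    def test_dual_threshold(self):
        rec = self._records(
            [
                ("a", "NONTUMOR->ADK", 3.1, 10.0, 10, 1e-9),
                ("b", "NONTUMOR->ADK", 1.5, 9.0, 10, 1e-9),
                ("c", "NONTUMOR->ADK", 4.0, 2.0, 10, 0.01),
            ]
        )
        out = call_dmcs(rec)
        by = out.set_index("probe_id")
        assert bool(by.loc["a", "is_dmc"]) is True
        assert by.loc["a", "direction"] == "gain"
        assert bool(by.loc["b", "is_dmc"]) is False  # effect below 2 M
        assert bool(by.loc["c", "is_dmc"]) is False  # q above threshold

    def test_bh_within_contrast(self):
        rec = self._records(
            [
                ("a", "c1", 3.0, 5.0, 10, 0.01),
                ("b", "c1", 3.0, 5.0, 10, 0.02),
                ("a", "c2", 3.0, 5.0, 10, 0.5),
            ]
        )
        out = call_dmcs(rec)
        q_c1 = out.loc[out["contrast"] == "c1", "q"].to_numpy()
        assert np.allclose(sorted(q_c1), [0.02, 0.02])
        assert out.loc[out["contrast"] == "c2", "q"].iloc[0] == pytest.approx(0.5)


class TestNullAndPower:
    def test_null_data_produce_no_dmcs(self):
        rng = np.random.default_rng(12)
        groups = (
            ["NONTUMOR"] * 20 + ["LGA"] * 12 + ["HGA"] * 19 + ["ADK"] * 22
        )
        mv = _mv(rng.normal(size=(2000, 73)), groups)
        _, _, _, summary = run_dmc_analysis(mv)
        assert summary["dmc_union"] == 0

    def test_planted_shifts_recovered(self):
        rng = np.random.default_rng(13)
        groups = (
            ["NONTUMOR"] * 20 + ["LGA"] * 12 + ["HGA"] * 19 + ["ADK"] * 22
        )
        vals = rng.normal(size=(2000, 73))
        vals[:100, 20:] += 4.0  # |delta M| = 4 from NONTUMOR onward
        records, _, _, _ = run_dmc_analysis(_mv(vals, groups))
        union = dmc_union(records)
        planted = {f"p{i}" for i in range(100)}
        recall = len(planted & set(union)) / 100
        assert recall >= 0.95
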