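"""Two-sample MR estimators, heterogeneity handling and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from pqtlmr.mr import (
    InsufficientInstrumentsError,
    diagnostics_tables,
    egger,
    ivw,
    leave_one_out,
    ratio_estimates,
    weighted_median,
)
from pqtlmr.simulate import InstrumentScenario, simulate_instruments
from pqtlmr.sumstats import HarmonizedSet


def est_frame(bx, by, se_out, se_exp=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_out = np.broadcast_to(np.asarray(se_out, float), bx.shape)
    se_exp = np.broadcast_to(
        np.asarray(se_exp if se_exp is not None else 0.01, float), bx.shape
    )
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(bx))],
            "b_ratio": by / bx,
            "se_ratio": se_out / np.abs(bx),
            "weight": (np.abs(bx) / se_out) ** 2,
            "beta_exp": bx,
            "se_exp": se_exp,
            "beta_out": by,
            "se_out": se_out,
        }
    )


class TestRatioEstimates:
    def test_unit_exposure(self):
        hs = HarmonizedSet(
            "p",
            pd.DataFrame(
                {
                    "variant_id": ["v1"],
                    "beta_exp": [1.0],
                    "se_exp": [0.1],
                    "beta_out": [0.2],
                    "se_out": [0.05],
                }
            ),
        )
        est = ratio_estimates(hs)
        assert est.loc[0, "b_ratio"] == pytest.approx(0.2)
        assert est.loc[0, "se_ratio"] == pytest.approx(0.05)
        assert est.loc[0, "weight"] == pytest.approx(400.0)

    def test_negative_exposure(self):
        hs = HarmonizedSet(
            "p",
            pd.DataFrame(
                {
                    "variant_id": ["v1"],
                    "beta_exp": [-0.5],
                    "se_exp": [0.1],
                    "beta_out": [0.2],
                    "se_out": [0.05],
                }
            ),
        )
        est = ratio_estimates(hs)
        assert est.loc[0, "b_ratio"] == pytest.approx(-0.4)
        assert est.loc[0, "se_ratio"] == pytest.approx(0.1)

    def test_null_exposure_dropped(self):
        hs = HarmonizedSet(
            "p",
            pd.DataFrame(
                {
                    "variant_id": ["v1", "v2"],
                    "beta_exp": [0.0, 0.3],
                    "se_exp": [0.1, 0.1],
                    "beta_out": [0.2, 0.06],
                    "se_out": [0.05, 0.05],
                }
            ),
        )
        assert ratio_estimates(hs)["variant_id"].tolist() == ["v2"]


class TestIvw:
    def test_singleton(self):
        est = est_frame([1.0], [0.3], 0.1)
        res, het = ivw(est)
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert het.df == 0
        assert het.model_selected == "fixed"

    def test_two_identical_estimates(self):
        est = est_frame([1.0, 1.0], [0.3, 0.3], 0.1)
        res, het = ivw(est)
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.0707, abs=5e-5)
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.model_selected == "fixed"

    def test_random_effects_inflates_se_when_q_large(self, rng):
        b = np.concatenate([np.full(10, 0.5), np.full(10, -0.5)])
        est = est_frame(np.ones(20), b, 0.05)
        res_f, _ = ivw(est, model="fixed")
        res_a, het = ivw(est, model="auto")
        assert het.model_selected == "random"
        assert res_a.se > res_f.se
        assert res_a.se == pytest.approx(res_f.se * np.sqrt(het.q_stat / het.df), rel=1e-9)

    def test_empty_estimates_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(est_frame([], [], []))

    def test_parameter_recovery(self):
        means = []
        for seed in range(100):
            hs, _ = simulate_instruments(InstrumentScenario(theta=0.2, seed=seed))
            res, _ = ivw(ratio_estimates(hs))
            means.append(res.beta)
        assert np.mean(means) == pytest.approx(0.2, abs=0.02)


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(est_frame(bx, 0.5 * bx, 0.05))
        assert res.beta == pytest.approx(0.5, abs=1e-9)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-9)

    def test_matches_weighted_least_squares_oracle(self, rng):
        bx = rng.uniform(0.05, 0.4, 12)
        by = 0.05 + 0.3 * bx + rng.normal(0, 0.02, 12)
        se_out = rng.uniform(0.01, 0.05, 12)
        est = est_frame(bx, by, se_out)
        res = egger(est)
        # oracle: closed-form weighted normal equations
        w = 1.0 / se_out**2
        x = np.column_stack([np.ones_like(bx), bx])
        beta_hat = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (w * by))
        assert res.egger_intercept == pytest.approx(beta_hat[0], rel=1e-9)
        assert res.beta == pytest.approx(beta_hat[1], rel=1e-9)

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.05, 0.4, 10)
        by = 0.02 + 0.3 * bx + rng.normal(0, 0.02, 10)
        est1 = est_frame(bx, by, 0.03)
        flip = rng.random(10) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        est2 = est_frame(bx * sgn, by * sgn, 0.03)
        r1, r2 = egger(est1), egger(est2)
        assert r2.beta == pytest.approx(r1.beta, rel=1e-9)
        assert r2.egger_intercept == pytest.approx(r1.egger_intercept, rel=1e-9)

    def test_intercept_recovery_under_directional_pleiotropy(self):
        intercepts = []
        for seed in range(100):
            hs, _ = simulate_instruments(
                InstrumentScenario(
                    theta=0.2, pleiotropy_mode="directional", pleiotropy_scale=0.05,
                    seed=seed,
                )
            )
            intercepts.append(egger(ratio_estimates(hs)).egger_intercept)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(est_frame([0.1, 0.2], [0.05, 0.1], 0.05))


class TestWeightedMedian:
    def test_three_equal_weights(self):
        est = est_frame([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], 0.1)
        assert weighted_median(est, seed=0).beta == pytest.approx(2.0)

    def test_dominant_weight_wins(self):
        est = est_frame([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.001, 1.0, 1.0])
        assert weighted_median(est, seed=0).beta == pytest.approx(1.0, abs=0.01)

    def test_bootstrap_se_reproducible(self):
        est = est_frame([1.0, 0.8, 1.2, 0.9], [0.2, 0.18, 0.25, 0.15], 0.05)
        r1 = weighted_median(est, seed=42)
        r2 = weighted_median(est, seed=42)
        assert r1.se == r2.se

    def test_robust_to_forty_percent_invalid(self):
        wins = 0
        for seed in range(60):
            hs, _ = simulate_instruments(
                InstrumentScenario(
                    theta=0.2, pleiotropy_mode="directional", pleiotropy_scale=0.3,
                    prop_invalid=0.4, seed=seed,
                )
            )
            est = ratio_estimates(hs)
            r_ivw, _ = ivw(est)
            r_wm = weighted_median(est, seed=seed)
            wins += abs(r_wm.beta - 0.2) < abs(r_ivw.beta - 0.2)
        assert wins >= 54  # >= 90%


class TestLeaveOneOut:
    def test_identical_estimates_give_identical_refits(self):
        est = est_frame(np.ones(5), np.full(5, 0.3), 0.1)
        loo = leave_one_out(est)
        np.testing.assert_allclose(loo["ivw_beta"], 0.3)
        assert not loo["flagged"].any()

    def test_two_instruments_each_refit_is_the_other(self):
        est = est_frame([1.0, 1.0], [0.2, 0.4], 0.1)
        loo = leave_one_out(est).set_index("left_out_variant")
        assert loo.loc["v0", "ivw_beta"] == pytest.approx(0.4)
        assert loo.loc["v1", "ivw_beta"] == pytest.approx(0.2)

    def test_gross_outlier_produces_largest_shift(self):
        by = np.full(10, 0.2)
        by[3] = 2.0
        est = est_frame(np.ones(10), by, 0.1)
        loo = leave_one_out(est)
        biggest = loo.loc[loo["shift"].abs().idxmax(), "left_out_variant"]
        assert biggest == "v3"
        assert loo.set_index("left_out_variant").loc["v3", "flagged"]


def test_sign_equivariance_of_all_estimators(rng):
    hs, _ = simulate_instruments(InstrumentScenario(theta=0.25, seed=9))
    est = ratio_estimates(hs)
    neg = est.copy()
    neg["beta_out"] = -neg["beta_out"]
    neg["b_ratio"] = -neg["b_ratio"]
    for fit in (
        lambda e: ivw(e)[0],
        egger,
        lambda e: weighted_median(e, seed=1),
    ):
        r_pos, r_neg = fit(est), fit(neg)
        assert r_neg.beta == pytest.approx(-r_pos.beta, rel=1e-6)
        assert r_neg.pvalue == pytest.approx(r_pos.pvalue, rel=1e-6)


def test_all_estimators_agree_on_identical_ratios():
    bx = np.array([0.1, 0.15, 0.2, 0.3])
    est = est_frame(bx, 0.4 * bx, 0.05 * bx)  # identical ratios & proportional SEs
    r_ivw, _ = ivw(est)
    r_wm = weighted_median(est, seed=0)
    r_eg = egger(est)
    assert r_ivw.beta == pytest.approx(0.4, abs=1e-9)
    assert r_wm.beta == pytest.approx(0.4, abs=1e-9)
    assert r_eg.beta == pytest.approx(0.4, abs=1e-6)


def test_ivw_null_calibration_and_q_distribution():
    rejections = 0
    qs = []
    n_reps = 400
    for seed in range(n_reps):
        hs, _ = simulate_instruments(InstrumentScenario(theta=0.0, seed=seed))
        res, het = ivw(ratio_estimates(hs))
        rejections += res.pvalue < 0.05
        qs.append(het.q_stat)
    assert 0.02 <= rejections / n_reps <= 0.08
    assert np.mean(qs) == pytest.approx(49.0, rel=0.06)  # chi-square mean = J - 1


def test_diagnostics_tables_shapes(rng):
    hs, _ = simulate_instruments(InstrumentScenario(theta=0.2, seed=3, j_instruments=10))
    est = ratio_estimates(hs)
    r_ivw, _ = ivw(est)
    r_eg = egger(est)
    tabs = diagnostics_tables(est, r_ivw, r_eg)
    assert all(len(t) == 10 for t in tabs.values())
    np.testing.assert_allclose(tabs["funnel"]["precision"], 1 / est["se_ratio"])
    np.testing.assert_allclose(tabs["funnel"]["b_ratio"], est["b_ratio"])
    assert {"ivw_fit", "egger_fit"} <= set(tabs["scatter"].columns)
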