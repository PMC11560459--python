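"""Metrics, the CV harness, and the three component-selection rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leafspec as ls
from leafspec.errors import ConfigError, DomainError, StateError
from leafspec.selection import (
    press,
    r2,
    report_table,
    rmse,
    rmse_percent,
    rpd,
    sign_flip_pvalue,
)
from leafspec.synthetic import planted_rank_config

from _helpers import make_curve, random_curve_with_residuals


class TestMetrics:
    def test_perfect_predictions(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert press(obs - obs) == 0.0
        assert r2(obs, obs) == 1.0

    def test_hand_computed_example(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 4.0])
        assert press(obs - pred) == 1.0
        assert rmse(1.0, 3) == pytest.approx(np.sqrt(1.0 / 3.0))
        assert r2(obs, pred) == pytest.approx(0.5)

    def test_rmse_percent_uses_full_dataset_mean(self):
        assert rmse_percent(4.0, 4, trait_mean=5.0) == pytest.approx(20.0)
        with pytest.raises(DomainError):
            rmse_percent(4.0, 4, trait_mean=0.0)

    def test_rpd_r2_identity_with_matched_conventions(self):
        # with SD and RMSE over the same set and n-denominators,
        # RPD = 1/sqrt(1 - R2); R2 = 0.84 gives exactly 2.5
        rng = np.random.default_rng(0)
        obs = rng.standard_normal(200)
        resid = obs - obs.mean()
        pred = obs - np.sqrt(0.16) * resid / np.sqrt(np.mean(resid**2)) * np.std(obs)
        val_r2 = r2(obs, pred)
        sd_n = np.sqrt(np.mean((obs - obs.mean()) ** 2))
        rmse_n = np.sqrt(np.mean((obs - pred) ** 2))
        assert rpd(sd_n, rmse_n) == pytest.approx(1.0 / np.sqrt(1.0 - val_r2))
        assert val_r2 == pytest.approx(0.84)
        assert rpd(sd_n, rmse_n) == pytest.approx(2.5)

    @given(st.floats(0.01, 0.99))
    def test_rpd_identity_property(self, target_r2):
        rng = np.random.default_rng(1)
        obs = rng.standard_normal(50)
        sd_n = np.std(obs)
        pred = obs - np.sqrt(1 - target_r2) * (obs - obs.mean())
        rmse_n = np.sqrt(np.mean((obs - pred) ** 2))
        assert rpd(sd_n, rmse_n) == pytest.approx(
            1.0 / np.sqrt(1.0 - r2(obs, pred)), rel=1e-9
        )

    @pytest.mark.parametrize(
        "value,expected",
        [(2.45, "excellent"), (2.46, "excellent"), (2.01, "excellent"),
         (2.0, "fair"), (1.71, "fair"), (1.40, "fair"),
         (1.39, "non-reliable"), (1.28, "non-reliable")],
    )
    def test_rpd_reliability_classes(self, value, expected):
        assert ls.classify_rpd(value) == expected

    def test_rpd_domain_errors(self):
        with pytest.raises(DomainError):
            ls.classify_rpd(0.0)
        with pytest.raises(DomainError):
            rpd(1.0, 0.0)


class TestSelectPressMin:
    def test_convex_curve_minimum(self):
        a = np.arange(1, 31)
        curve = make_curve(0.2 + 0.001 * (a - 19.0) ** 2)
        assert ls.select_press_min(curve).n_components == 19

    def test_monotone_decreasing_picks_max_with_warning(self):
        curve = make_curve(np.linspace(1.0, 0.1, 10))
        with pytest.warns(UserWarning, match="max_components"):
            assert ls.select_press_min(curve).n_components == 10

    def test_ties_break_toward_fewer_components(self):
        vp = np.linspace(1.0, 0.5, 10)
        vp[4] = vp[8] = 0.1
        assert ls.select_press_min(make_curve(vp)).n_components == 5


class TestBackwardPenalty:
    def test_flat_curve_reduces_to_one(self):
        curve = make_curve(np.ones(12))
        assert ls.select_backward_penalty(curve).n_components == 1

    def test_steep_curve_keeps_press_min_choice(self):
        # every reduction below the minimum costs far more than tau
        vp = np.array([1.0, 0.7, 0.4, 0.1, 0.4, 0.7])
        res = ls.select_backward_penalty(make_curve(vp))
        assert res.n_components == ls.select_press_min(make_curve(vp)).n_components

    def test_nitrogen_like_reduction_from_19_to_14(self):
        # plateau within tau-steps over 14..19, a >tau jump at 13->14
        vp = np.empty(30)
        vp[:13] = np.linspace(1.0, 0.30, 13)          # A=1..13
        vp[13] = 0.20                                 # A=14: jump of 0.10 > tau
        vp[14:19] = [0.19, 0.18, 0.17, 0.165, 0.16]   # A=15..19 gentle slope
        vp[19:] = np.linspace(0.17, 0.25, 11)         # rising overfit tail
        curve = make_curve(vp)
        assert ls.select_press_min(curve).n_components == 19
        res = ls.select_backward_penalty(curve, penalty_percent=1.5)
        assert res.n_components == 14
        assert res.method == "press_adj"


class TestVoet:
    def test_identical_residuals_give_p_one_and_smaller_model(self):
        rng = np.random.default_rng(0)
        sq = rng.exponential(size=(3, 50))
        sq[0] = 5.0 * sq[2]  # A=1 uniformly worse than the reference
        sq[1] = sq[2]        # A=2 predicts exactly as well as the reference A=3
        curve = make_curve(sq.sum(axis=1) * [1.0, 1.0 + 1e-9, 1.0],
                           val_sq_residuals=sq)
        res = ls.select_voet(curve, seed=1)
        assert res.n_components == 2

    def test_uniformly_worse_small_model_is_rejected(self):
        rng = np.random.default_rng(0)
        ref = rng.exponential(size=50)
        sq = np.vstack([10.0 * ref, ref])
        curve = make_curve(sq.sum(axis=1), val_sq_residuals=sq)
        res = ls.select_voet(curve, alpha=0.01, seed=2)
        assert res.n_components == 2

    def test_missing_residuals_raise_state_error(self):
        curve = make_curve(np.linspace(1.0, 0.2, 5))
        with pytest.raises(StateError):
            ls.select_voet(curve)

    def test_sign_flip_pvalue_bounds(self):
        rng = np.random.default_rng(3)
        p = sign_flip_pvalue(rng.standard_normal(30), 199, rng)
        assert 1.0 / 200 <= p <= 1.0
        assert sign_flip_pvalue(np.zeros(10), 199, rng) == 1.0


@pytest.fixture(scope="module")
def small_xy():
    cfg = planted_rank_config(3, n_samples=80, seed=21)
    spectra, traits, _ = ls.generate_dataset(cfg)
    spectra = ls.trim_spectra(spectra)
    return spectra.reflectance, traits.trait("Y").to_numpy()


class TestRunCV:
    def test_same_seed_reproduces_curve(self, small_xy):
        X, y = small_xy
        cfg = ls.CVConfig(n_iterations=2, max_components=6, seed=5)
        c1 = ls.run_cv(X, y, cfg)
        c2 = ls.run_cv(X, y, cfg)
        np.testing.assert_array_equal(c1.val_press, c2.val_press)
        np.testing.assert_array_equal(c1.val_sq_residuals, c2.val_sq_residuals)

    def test_noiseless_rank3_signal_collapses_press_at_three_components(self):
        cfg = planted_rank_config(3, n_samples=80, seed=8,
                                  trait_noise_sd=0.0, spectral_noise_sd=0.0)
        spectra, traits, _ = ls.generate_dataset(cfg)
        X = ls.trim_spectra(spectra).reflectance
        y = traits.trait("Y").to_numpy()
        curve = ls.run_cv(X, y, ls.CVConfig(n_iterations=5, max_components=5, seed=1))
        assert curve.val_press[2] < 1e-6 * curve.val_press[0]

    def test_pure_noise_response_has_no_validation_skill(self):
        rng = np.random.default_rng(6)
        cfg = planted_rank_config(3, n_samples=300, seed=31)
        spectra, _, _ = ls.generate_dataset(cfg)
        X = ls.trim_spectra(spectra).reflectance
        y = 10.0 + rng.standard_normal(300)
        curve = ls.run_cv(X, y, ls.CVConfig(n_iterations=5, max_components=8, seed=2))
        assert np.all(curve.val_r2 <= 0.05)

    def test_normalized_press_max_is_exactly_one(self, small_xy):
        X, y = small_xy
        curve = ls.run_cv(X, y, ls.CVConfig(n_iterations=3, max_components=6, seed=9))
        for which in ("cal", "val"):
            norm = curve.normalized_press(which)
            assert norm.max() == 1.0 and np.all(norm > 0.0)

    def test_rank_cap_lowered_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="lowered"):
            curve = ls.run_cv(
                X, y, ls.CVConfig(n_iterations=1, max_components=30, seed=0)
            )
        assert curve.components[-1] < 30

    def test_selection_rules_respect_ordering(self, small_xy):
        X, y = small_xy
        curve = ls.run_cv(X, y, ls.CVConfig(n_iterations=5, max_components=8, seed=3))
        a_min = ls.select_press_min(curve).n_components
        assert ls.select_backward_penalty(curve).n_components <= a_min
        assert ls.select_voet(curve, seed=4).n_components <= a_min


class TestReportTable:
    def test_two_traits_three_methods_give_six_rows(self):
        rng = np.random.default_rng(0)
        rows = {}
        for trait in ("A", "B"):
            curve = random_curve_with_residuals(rng, n_components=8)
            rows[trait] = [
                ls.select_press_min(curve),
                ls.select_backward_penalty(curve),
                ls.select_voet(curve, seed=1),
            ]
        table = report_table(rows)
        assert len(table) == 6
        assert set(table["method"]) == {"press_min", "press_adj", "voet"}

    def test_rpd_class_column_consistent(self):
        rng = np.random.default_rng(1)
        curve = random_curve_with_residuals(rng, n_components=6)
        table = report_table({"T": [ls.select_press_min(curve)]})
        for _, row in table.iterrows():
            assert row["rpd_class"] == ls.classify_rpd(row["val_rpd"])

    def test_normalized_press_within_unit_interval(self):
        rng = np.random.default_rng(2)
        curve = random_curve_with_residuals(rng, n_components=9)
        table = report_table({"T": [ls.select_backward_penalty(curve)]})
        for col in ("cal_press_norm", "val_press_norm"):
            assert ((table[col] > 0) & (table[col] <= 1)).all()


def test_cv_config_validation():
    with pytest.raises(ConfigError):
        ls.CVConfig(calibration_fraction=1.0)
    with pytest.raises(ConfigError):
        ls.CVConfig(k_folds=1)
    with pytest.raises(ConfigError):
        ls.CVConfig(max_components=0)
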