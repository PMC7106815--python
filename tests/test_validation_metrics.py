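"""Quality-of-fit, internal and external validation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavqsar.validation_metrics import (
    ValidationReport,
    adjusted_r2,
    f_statistic,
    kfold_external,
    loo_cv,
    r2_pred,
    r_squared,
    rm2_metrics,
    rmsep,
    std_error,
)


def linear_fit_fn(x, y):
    """Refit callback: ordinary least squares with intercept."""
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return lambda rows: np.column_stack([np.ones(len(rows)), rows]) @ coef


def mean_fit_fn(x, y):
    mu = float(np.mean(y))
    return lambda rows: np.full(len(rows), mu)


class TestRSquared:
    def test_hand_value(self):
        # RSS = 1, TSS = 2
        assert r_squared([1, 2, 3], [1, 2, 2]) == pytest.approx(0.5)

    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 4.0]) == pytest.approx(1.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_translation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=8)
        pred = obs + 0.3 * rng.normal(size=8)
        assert r_squared(obs + shift, pred + shift) == pytest.approx(
            r_squared(obs, pred), abs=1e-8
        )


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,n,p,expected",
        [
            (1.0, 10, 3, 1.0),
            (0.5, 10, 2, (4.5 - 2) / 7),
            (0.3182, 20, 3, (19 * 0.3182 - 3) / 16),
        ],
    )
    def test_values(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected)

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, 4, 3)


class TestFStatistic:
    def test_mean_prediction_is_zero(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        assert f_statistic(obs, np.full(4, obs.mean()), p=1) == 0.0

    def test_hand_value(self):
        # explained SS = 4.64, RSS = 0.04, df = (1, 2) -> F = 232
        obs = [0.0, 1.0, 2.0, 3.0]
        pred = [0.1, 0.9, 2.1, 2.9]
        assert f_statistic(obs, pred, p=1) == pytest.approx(232.0)

    def test_noise_free_fit_returns_inf(self):
        assert f_statistic([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0], p=1) == math.inf


class TestStdError:
    def test_hand_value(self):
        # residuals (0.2, -0.2, 0.2, -0.2), df = N - p = 3
        obs = np.zeros(4)
        pred = np.array([0.2, -0.2, 0.2, -0.2])
        s = std_error(obs, pred, p=1, df_convention="n_minus_p")
        assert s == pytest.approx(math.sqrt(0.16 / 3))

    def test_zero_residuals(self):
        assert std_error([1.0, 2.0], [1.0, 2.0], p=1, df_convention="n_minus_p") == 0.0

    def test_df_conventions_differ(self):
        obs = np.arange(10.0)
        pred = obs + 0.5
        s1 = std_error(obs, pred, p=2, df_convention="n_minus_p_minus_1")
        s2 = std_error(obs, pred, p=2, df_convention="n_minus_p")
        assert s1 == pytest.approx(math.sqrt(2.5 / 7))
        assert s2 == pytest.approx(math.sqrt(2.5 / 8))

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            std_error([1.0, 2.0], [1.0, 2.0], p=1, df_convention="bogus")


class TestLooCv:
    def test_collinear_data_perfect(self):
        x = np.arange(6.0)[:, None]
        y = 3.0 * np.arange(6.0) + 1.0
        press, sdep, q2, _ = loo_cv(linear_fit_fn, x, y)
        assert press == pytest.approx(0.0, abs=1e-18)
        assert q2 == pytest.approx(1.0)

    def test_mean_model_hand_values(self):
        # three holdouts: 1.5^2 + 0 + 1.5^2 = 4.5
        x = np.zeros((3, 1))
        y = np.array([0.0, 1.0, 2.0])
        press, sdep, q2, preds = loo_cv(mean_fit_fn, x, y)
        assert press == pytest.approx(4.5)
        assert sdep == pytest.approx(math.sqrt(1.5))
        assert q2 == pytest.approx(-1.25)
        np.testing.assert_allclose(preds, [1.5, 1.0, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_refits_and_press_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        x = rng.normal(size=(n, 3))
        y = x @ np.array([1.0, -0.5, 0.2]) + 0.3 * rng.normal(size=n)
        press, _, _, preds = loo_cv(linear_fit_fn, x, y)
        # oracle: n independent refits
        expected = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            expected[i] = linear_fit_fn(x[keep], y[keep])(x[i : i + 1])[0]
        np.testing.assert_allclose(preds, expected, atol=1e-10)
        rss = float(np.sum((y - linear_fit_fn(x, y)(x)) ** 2))
        assert press >= rss - 1e-12

    def test_failing_fold_is_named(self):
        def broken(x, y):
            raise np.linalg.LinAlgError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            loo_cv(broken, np.zeros((3, 1)), np.arange(3.0))


class TestRm2Metrics:
    def test_identity_predictions(self):
        obs = np.array([0.1, 0.5, 0.9, 0.3])
        res = rm2_metrics(obs, obs)
        assert res.rm2 == pytest.approx(1.0)
        assert res.delta_rm2 == pytest.approx(0.0)
        assert not res.radicand_clamped

    def test_formula_arithmetic(self):
        # rm2 = r2 (1 - sqrt(r2 - r0^2)) at r2 = 0.9, r0^2 = 0.8
        assert 0.9 * (1 - math.sqrt(0.1)) == pytest.approx(0.615395, abs=1e-6)

    def test_average_and_delta(self, rng):
        obs = rng.normal(size=10)
        pred = obs + 0.4 * rng.normal(size=10)
        res = rm2_metrics(obs, pred)
        assert res.rm2_avg == pytest.approx((res.rm2 + res.rm2_prime) / 2)
        assert res.delta_rm2 == pytest.approx(abs(res.rm2 - res.rm2_prime))

    def test_rm2_bounded_by_r2(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            obs = r.normal(size=8)
            pred = obs + r.normal(size=8)
            res = rm2_metrics(obs, pred)
            r2 = (np.corrcoef(obs, pred)[0, 1]) ** 2
            assert res.rm2 <= r2 + 1e-12
            assert res.delta_rm2 >= 0

    def test_radicand_never_negative_with_origin_regressions(self):
        # the origin-constrained RSS cannot beat the best affine fit, so
        # r0^2 <= Pearson r^2 and the sqrt radicand stays non-negative;
        # the clamp branch is defensive only.  Anticorrelated predictions
        # drive rm2 negative without tripping it.
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 10))
            obs = r.normal(r.uniform(-5, 5), r.uniform(0.1, 3), size=n)
            pred = r.normal(r.uniform(-5, 5), r.uniform(0.1, 3), size=n)
            assert not rm2_metrics(obs, pred).radicand_clamped
        anticorr = rm2_metrics([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
        assert anticorr.rm2 < 0 and not anticorr.radicand_clamped

    def test_scaled_variant(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        res = rm2_metrics(obs, pred, scale=True)
        assert 0 <= res.rm2 <= 1


class TestExternalMetrics:
    def test_r2_pred_hand_value(self):
        assert r2_pred([1.0, 2.0], [1.0, 1.0], train_mean=0.0) == pytest.approx(0.8)

    def test_r2_pred_perfect(self):
        assert r2_pred([1.0, 2.0], [1.0, 2.0], train_mean=0.5) == pytest.approx(1.0)

    def test_r2_pred_zero_denominator(self):
        with pytest.raises(ValueError):
            r2_pred([1.0, 1.0], [0.9, 1.1], train_mean=1.0)

    def test_rmsep_values(self):
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmsep([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)


class TestKfoldExternal:
    def test_six_by_four_partition(self, rng):
        n = 24
        x = rng.normal(size=(n, 2))
        y = x @ np.array([1.0, 0.5]) + 0.1 * rng.normal(size=n)
        reports = kfold_external(linear_fit_fn, x, y, "6x4", seed=0)
        assert len(reports) == 6
        held_out = np.concatenate([r.test_indices for r in reports])
        assert sorted(held_out.tolist()) == list(range(n))

    def test_leave_one_out_equivalence(self, rng):
        n = 10
        x = rng.normal(size=(n, 2))
        y = x @ np.array([0.8, -0.3]) + 0.2 * rng.normal(size=n)
        press, *_ = loo_cv(linear_fit_fn, x, y)
        reports = kfold_external(
            linear_fit_fn, x, y, [[i] for i in range(n)], seed=0
        )
        total = sum(r.rmsep**2 for r in reports)
        assert total == pytest.approx(press, abs=1e-10)

    def test_noise_free_folds_perfect(self, rng):
        n = 24
        x = rng.normal(size=(n, 2))
        y = 2.0 * x[:, 0] - x[:, 1] + 0.5
        for r in kfold_external(linear_fit_fn, x, y, "6x4", seed=1):
            assert r.r2_pred == pytest.approx(1.0)

    def test_uneven_partition_rejected(self, rng):
        with pytest.raises(ValueError, match="cover"):
            kfold_external(linear_fit_fn, rng.normal(size=(10, 2)),
                           rng.normal(size=10), "3x4", seed=0)

    def test_deterministic_partition(self, rng):
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        a = kfold_external(linear_fit_fn, x, y, "3x4", seed=7)
        b = kfold_external(linear_fit_fn, x, y, "3x4", seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.test_indices, rb.test_indices)


class TestValidationReport:
    def test_delta_rm2_consistency_enforced(self):
        with pytest.raises(ValueError, match="delta_rm2"):
            ValidationReport(rm2=0.6, rm2_prime=0.5, delta_rm2=0.3)

    def test_delta_rm2_autofilled(self):
        rep = ValidationReport(rm2=0.6, rm2_prime=0.5)
        assert rep.delta_rm2 == pytest.approx(0.1)
        assert rep.rm2_avg is None  # not derived implicitly

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ValidationReport(r2=1.5)
        with pytest.raises(ValueError):
            ValidationReport(press=-0.1)

    def test_serialization_drops_absent_fields(self):
        rep = ValidationReport(n=20, p=3, r2=0.5)
        d = rep.to_dict()
        assert d["r2"] == 0.5 and "q2" not in d
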