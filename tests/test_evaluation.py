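import math

import numpy as np
import pytest

from rgbphen.evaluation import (
    anova_tukey,
    error_percent,
    fit_metrics,
    fit_yield_cubic,
    paired_t_test,
    pearson_r,
    validation_stats,
)


class TestErrorPercent:
    def test_hand_arithmetic(self):
        assert error_percent(2.0, 1.8) == pytest.approx(10.0)

    def test_identity(self):
        assert error_percent(3.7, 3.7) == 0.0

    def test_signed(self):
        assert error_percent(2.0, 2.2) == pytest.approx(-10.0)

    def test_zero_manual(self):
        with pytest.raises(ZeroDivisionError):
            error_percent(0.0, 1.0)


class TestFitMetrics:
    def test_perfect_fit(self, rng):
        y = rng.normal(size=20)
        fm = fit_metrics(y, y, p=2)
        assert fm.r2 == 1.0 and fm.rmse == 0.0 and fm.ase == 0.0

    def test_null_model(self, rng):
        y = rng.normal(size=20)
        fm = fit_metrics(y, np.full_like(y, y.mean()), p=1)
        assert fm.r2 == pytest.approx(0.0, abs=1e-12)

    def test_press_matches_brute_force_loo(self, rng):
        # oracle: explicit refit leaving each row out
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(0, 0.3, size=n)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fm = fit_metrics(y, X @ coef, p=3, design=X)
        press_oracle = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            c_i, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            press_oracle += (y[i] - X[i] @ c_i) ** 2
        assert fm.press == pytest.approx(press_oracle, abs=1e-9)

    def test_press_dominates_sse(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.5, 1.5] + rng.normal(0, 1.0, size=n)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ coef
        fm = fit_metrics(y, yhat, p=2, design=X)
        sse = np.sum((y - yhat) ** 2)
        assert fm.press >= sse

    def test_r2_affine_invariance(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(0, 0.5, size=30)
        r2 = fit_metrics(y, yhat, p=2).r2
        r2_scaled = fit_metrics(10 * y + 3, 10 * yhat + 3, p=2).r2
        assert r2_scaled == pytest.approx(r2, rel=1e-12)

    def test_n_le_p_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fit_metrics([1.0, 2.0], [1.0, 2.0], p=2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_metrics([1.0, 1.0, 1.0], [1.0, 1.1, 0.9], p=1)

    def test_aic_bic_formulas(self, rng):
        y = rng.normal(size=25)
        yhat = y + rng.normal(0, 0.5, size=25)
        sse = float(np.sum((y - yhat) ** 2))
        fm = fit_metrics(y, yhat, p=3)
        assert fm.aic == pytest.approx(25 * math.log(sse / 25) + 6)
        assert fm.bic == pytest.approx(25 * math.log(sse / 25) + 3 * math.log(25))


class TestValidationStats:
    def test_constant_shift(self, rng):
        y = rng.normal(size=10)
        vs = validation_stats(y, y + 1.0)
        assert vs.mean_error == pytest.approx(1.0)
        assert vs.sd_error == pytest.approx(0.0, abs=1e-12)

    def test_identity(self, rng):
        y = rng.normal(size=10)
        vs = validation_stats(y, y)
        assert (vs.mean_error, vs.sd_error, vs.r2) == (0.0, 0.0, 1.0)

    def test_matches_manual_recomputation(self, rng):
        obs = rng.normal(2.0, 1.0, size=40)
        pred = obs + rng.normal(0.3, 0.4, size=40)
        vs = validation_stats(obs, pred)
        err = pred - obs
        mu = err.sum() / len(err)
        sigma = math.sqrt(((err - mu) ** 2).sum() / (len(err) - 1))
        sx, sy = obs - obs.mean(), pred - pred.mean()
        r = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert vs.mean_error == pytest.approx(mu, abs=1e-9)
        assert vs.sd_error == pytest.approx(sigma, abs=1e-9)
        assert vs.r2 == pytest.approx(r**2, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            validation_stats([1.0, 2.0, 3.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_null_behaviour(self, rng):
        a = rng.normal(size=200)
        b = a + rng.normal(0.0, 0.5, size=200)
        _, p = paired_t_test(a, b)
        assert p > 0.05

    def test_zero_variance_differences(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_hand_computed_t(self):
        a = np.array([2.1, 3.4, 1.9, 4.2, 3.3])
        b = np.array([1.8, 3.1, 2.2, 3.6, 3.0])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        t, _ = paired_t_test(a, b)
        assert t == pytest.approx(t_expected, abs=1e-9)


class TestAnovaTukey:
    def test_null_shares_letter(self, rng):
        groups = {f"g{i}": rng.normal(5.0, 1.0, size=12) for i in range(4)}
        _, p, grouping = anova_tukey(groups)
        assert p > 0.05
        assert len(set(grouping.letters)) == 1

    def test_strong_effect_distinct_letters(self, rng):
        groups = {
            "lo": rng.normal(0.0, 1.0, size=10),
            "hi": rng.normal(10.0, 1.0, size=10),
        }
        f, p, grouping = anova_tukey(groups)
        assert p < 1e-6
        letters = grouping.as_dict()
        assert letters["lo"][1] != letters["hi"][1]

    def test_relabeling_symmetry(self, rng):
        data = {g: rng.normal(i, 1.0, size=8) for i, g in enumerate("abc")}
        _, _, g1 = anova_tukey(data)
        renamed = {f"x_{k}": v for k, v in data.items()}
        _, _, g2 = anova_tukey(renamed)
        d1, d2 = g1.as_dict(), g2.as_dict()
        for k in data:
            assert d1[k][1] == d2[f"x_{k}"][1]

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            anova_tukey({"only": rng.normal(size=5)})

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestYieldCubic:
    def test_exact_cubic(self):
        x = np.linspace(0.5, 3.0, 12)
        y = 5.0 + 2.0 * x - 0.3 * x**2 + 0.05 * x**3
        fit = fit_yield_cubic(x, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx((5.0, 2.0, -0.3, 0.05), abs=1e-8)
        assert fit.significant

    def test_constant_yield(self):
        x = np.linspace(0.5, 3.0, 10)
        fit = fit_yield_cubic(x, np.full_like(x, 7.0))
        assert fit.r2 == 0.0

    def test_r2_matches_residual_recomputation(self, rng):
        x = rng.uniform(0.5, 3.0, size=30)
        y = 4.0 + x + 0.2 * x**3 + rng.normal(0, 0.5, size=30)
        fit = fit_yield_cubic(x, y)
        X = np.column_stack([np.ones_like(x), x, x**2, x**3])
        yhat = X @ np.asarray(fit.coefficients)
        r2_oracle = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(r2_oracle, abs=1e-9)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant trait"):
            fit_yield_cubic(np.ones(10), np.arange(10.0))
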