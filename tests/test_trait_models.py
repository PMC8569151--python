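import numpy as np
import pandas as pd
import pytest

from rgbphen.synthetic_data import generate_vi_table
from rgbphen.trait_models import (
    FROZEN_MODEL_IDS,
    LinearTraitModel,
    MLPConfig,
    fit_linear_trait_model,
    frozen_model,
    predict_mlp,
    stepwise_select,
    train_mlp,
)
from rgbphen.vegindices import VI_NAMES

REG1_PREDICTORS = ("bgi", "ppr", "ngrdi", "ncpi", "nppr")
REG3_PREDICTORS = ("nppr", "ncpi", "ngrdi", "ppr")


class TestFrozenModels:
    def test_reg1_coefficients(self):
        m = frozen_model("reg1")
        assert m.trait == "LAI" and m.mode == "sum"
        assert dict(zip(m.predictor_names, m.coefficients)) == {
            "bgi": 28.82, "ppr": 13.77, "ngrdi": -7.91, "ncpi": 14.88, "nppr": 25.86,
        }
        assert m.intercept == -39.74

    def test_reg2(self):
        m = frozen_model("reg2")
        assert m.mode == "product"
        assert m.coefficients == (505.84,)
        assert m.intercept == 0.134
        assert set(m.predictor_names) == {"bgi", "ppr", "nppr", "ngrdi", "ncpi"}

    def test_reg3(self):
        m = frozen_model("reg3")
        assert m.trait == "LG"
        assert m.intercept == -144.24
        assert dict(zip(m.predictor_names, m.coefficients))["nppr"] == 254.26

    def test_reg4(self):
        m = frozen_model("reg4")
        assert m.coefficients == (3372.55,)
        assert m.intercept == 19.96
        assert set(m.predictor_names) == {"ppr", "nppr", "ngrdi", "ncpi"}

    def test_unknown_id(self):
        with pytest.raises(KeyError, match="reg9"):
            frozen_model("reg9")


class TestEstimateTrait:
    def test_all_zero_vis_reg1(self):
        est = frozen_model("reg1").predict_one({n: 0.0 for n in VI_NAMES})
        assert est.value == pytest.approx(-39.74)
        assert est.below_zero

    def test_all_zero_vis_reg4(self):
        est = frozen_model("reg4").predict_one({n: 0.0 for n in VI_NAMES})
        assert est.value == pytest.approx(19.96)
        assert not est.below_zero

    def test_hand_evaluation_reg1(self):
        vi = {"bgi": 0.25, "ppr": 0.6, "ngrdi": 1 / 3, "ncpi": 1 / 3, "nppr": 4 / 3}
        expected = (
            28.82 * 0.25 + 13.77 * 0.6 - 7.91 / 3 + 14.88 / 3 + 25.86 * 4 / 3 - 39.74
        )
        est = frozen_model("reg1").predict_one(vi)
        assert est.value == pytest.approx(expected)
        assert est.value == pytest.approx(12.53, abs=0.01)

    def test_missing_predictor(self):
        with pytest.raises(KeyError, match="missing"):
            frozen_model("reg1").predict_one({"bgi": 0.5})

    @pytest.mark.parametrize("model_id", ["reg1", "reg3"])
    def test_affine_slope_equals_coefficient(self, model_id):
        model = frozen_model(model_id)
        base = {n: 0.4 for n in VI_NAMES}
        f0 = model.predict_one(base).value
        for name, coef in zip(model.predictor_names, model.coefficients):
            bumped = dict(base)
            bumped[name] = base[name] + 1.0
            assert model.predict_one(bumped).value - f0 == pytest.approx(coef)

    def test_json_round_trip(self, tmp_path):
        m = frozen_model("reg2")
        path = tmp_path / "m.json"
        m.save(path)
        assert LinearTraitModel.load(path) == m


class TestOLSRefit:
    @pytest.mark.parametrize("model_id", FROZEN_MODEL_IDS)
    def test_noiseless_recovery(self, model_id):
        model = frozen_model(model_id)
        table = generate_vi_table(200, model_id, seed=11)
        refit = fit_linear_trait_model(
            table, model.predictor_names, model.trait, mode=model.mode
        )
        np.testing.assert_allclose(refit.coefficients, model.coefficients, atol=1e-6)
        assert refit.intercept == pytest.approx(model.intercept, abs=1e-6)

    def test_duplicated_rows_identical_fit(self):
        table = generate_vi_table(100, "reg1", noise_sd=0.2, seed=3)
        doubled = pd.concat([table, table], ignore_index=True)
        f1 = fit_linear_trait_model(table, REG1_PREDICTORS, "LAI")
        f2 = fit_linear_trait_model(doubled, REG1_PREDICTORS, "LAI")
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-9)

    def test_collinear_predictors_rejected(self):
        table = generate_vi_table(50, "reg1", seed=4)
        table["bgi2"] = 2 * table["bgi"]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_linear_trait_model(table, ("bgi", "bgi2"), "LAI")

    def test_insufficient_rows(self):
        table = generate_vi_table(4, "reg1", seed=5)
        with pytest.raises(ValueError, match="insufficient"):
            fit_linear_trait_model(table, REG1_PREDICTORS, "LAI")

    def test_unbiased_and_root_n_shrinkage(self):
        # coefficient estimates across 200 replicates: unbiased, RMSE ~ 1/sqrt(n)
        model = frozen_model("reg1")
        rmse_by_n = {}
        biases = []
        for n in (50, 800):
            errs = []
            for rep in range(200):
                table = generate_vi_table(n, "reg1", noise_sd=0.5, seed=1000 * n + rep)
                refit = fit_linear_trait_model(table, model.predictor_names, "LAI")
                errs.append(np.subtract(refit.coefficients, model.coefficients))
            errs = np.asarray(errs)
            biases.append(np.abs(errs.mean(axis=0)))
            rmse_by_n[n] = np.sqrt((errs**2).mean(axis=0))
            se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
            assert np.all(np.abs(errs.mean(axis=0)) < 4 * se)
        ratio = rmse_by_n[50] / rmse_by_n[800]
        expected = np.sqrt(800 / 50)
        assert np.all(ratio > expected * 0.6)
        assert np.all(ratio < expected * 1.6)


class TestStepwise:
    def test_recovers_reg1_support(self):
        table = generate_vi_table(300, "reg1", seed=21)
        result = stepwise_select(table, "LAI")
        assert set(result.selected) == {"bgi", "ppr", "nppr", "ngrdi", "ncpi"}
        assert "rgr" not in result.selected

    def test_recovers_reg3_support(self):
        table = generate_vi_table(300, "reg3", seed=22)
        result = stepwise_select(table, "LG")
        assert set(result.selected) == {"ppr", "nppr", "ngrdi", "ncpi"}

    def test_independent_trait_selects_nothing(self):
        # typical null behaviour at this seed; AIC can admit a spurious
        # predictor on other draws, which is expected of the criterion
        table = generate_vi_table(200, "reg1", seed=23)
        table["LAI"] = np.random.default_rng(1).normal(0.0, 1.0, size=len(table))
        result = stepwise_select(table, "LAI")
        assert result.selected == ()

    def test_criterion_path_non_increasing(self):
        table = generate_vi_table(300, "reg1", noise_sd=0.3, seed=24)
        result = stepwise_select(table, "LAI")
        assert all(b < a for a, b in zip(result.criterion_path, result.criterion_path[1:]))


@pytest.fixture(scope="module")
def reg1_table():
    return generate_vi_table(300, "reg1", seed=0)


@pytest.fixture(scope="module")
def trained(reg1_table):
    return train_mlp(reg1_table, REG1_PREDICTORS, "LAI", MLPConfig(seed=42))


class TestMLP:
    def test_training_r2(self, reg1_table, trained):
        y = reg1_table["LAI"].to_numpy()
        pred = trained.predict(reg1_table)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.95

    def test_loss_decreases(self, trained):
        assert trained.loss_history[-1] <= trained.loss_history[100]

    def test_deterministic_given_seed(self, reg1_table):
        cfg = MLPConfig(epochs=200, seed=9)
        m1 = train_mlp(reg1_table, REG1_PREDICTORS, "LAI", cfg)
        m2 = train_mlp(reg1_table, REG1_PREDICTORS, "LAI", cfg)
        np.testing.assert_array_equal(m1.predict(reg1_table), m2.predict(reg1_table))

    def test_zero_epochs_returns_initialization(self, reg1_table):
        m = train_mlp(reg1_table, REG1_PREDICTORS, "LAI", MLPConfig(epochs=0, seed=1))
        y = reg1_table["LAI"].to_numpy()
        pred = m.predict(reg1_table)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 < 0.5  # untrained network explains essentially nothing

    def test_identical_rows_identical_outputs(self, trained, reg1_table):
        row = reg1_table.iloc[[0]]
        two = pd.concat([row, row], ignore_index=True)
        out = trained.predict(two)
        assert out[0] == out[1]

    def test_permutation_equivariance(self, trained, reg1_table):
        perm = np.random.default_rng(5).permutation(len(reg1_table))
        out = trained.predict(reg1_table)
        out_perm = trained.predict(reg1_table.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(out_perm, out[perm])

    def test_feature_mismatch_rejected(self, trained):
        with pytest.raises(ValueError, match="features"):
            trained.predict(np.zeros((3, 2)))

    def test_missing_column_rejected(self, trained):
        with pytest.raises(KeyError, match="missing feature"):
            trained.predict(pd.DataFrame({"bgi": [0.5]}))

    def test_residuals_below_generating_noise(self):
        # noise large enough to dominate the network's approximation error
        noise_sd = 2.0
        table = generate_vi_table(300, "reg1", noise_sd=noise_sd, seed=6)
        m = train_mlp(table, REG1_PREDICTORS, "LAI", MLPConfig(seed=7))
        resid = table["LAI"].to_numpy() - predict_mlp(table, m)
        assert resid.std() < noise_sd

    def test_too_few_rows(self):
        table = generate_vi_table(5, "reg1", seed=8)
        with pytest.raises(ValueError, match="at least 10"):
            train_mlp(table, REG1_PREDICTORS, "LAI")

    def test_json_round_trip(self, trained, reg1_table, tmp_path):
        path = tmp_path / "mlp.json"
        trained.save(path)
        from rgbphen.trait_models import MLPModel

        back = MLPModel.load(path)
        np.testing.assert_allclose(
            back.predict(reg1_table), trained.predict(reg1_table), atol=1e-12
        )
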