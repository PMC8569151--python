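"""Trait estimators: frozen published models, OLS refitting, stepwise
selection, and a small deterministic multilayer perceptron.

Linear models come in two modes.  "sum" mode is an ordinary affine model
over named vegetation indices; "product" mode regresses the trait on the
single product of the named indices.  Four frozen models ship with the
package (reg1/reg2 for LAI, reg3/reg4 for lateral growth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .vegindices import VI_NAMES, VIVector

__all__ = [
    "LinearTraitModel",
    "TraitEstimate",
    "MLPConfig",
    "MLPModel",
    "StepwiseResult",
    "FROZEN_MODEL_IDS",
    "frozen_model",
    "estimate_trait",
    "fit_linear_trait_model",
    "stepwise_select",
    "train_mlp",
    "predict_mlp",
]


class TraitEstimate(NamedTuple):
    value: float
    below_zero: bool


@dataclass(frozen=True)
class LinearTraitModel:
    """Affine trait model over named VIs, in "sum" or "product" mode."""

    trait: str
    mode: str
    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "product"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sum" and len(self.coefficients) != len(self.predictor_names):
            raise ValueError("sum mode: one coefficient per predictor required")
        if self.mode == "product":
            if len(self.coefficients) != 1:
                raise ValueError("product mode: exactly one weight required")
            if len(self.predictor_names) < 1:
                raise ValueError("product mode: at least one predictor required")

    def _design_vector(self, vi: dict[str, float]) -> float:
        missing = [n for n in self.predictor_names if n not in vi]
        if missing:
            raise KeyError(f"missing predictor(s): {missing}")
        if self.mode == "sum":
            return float(
                sum(c * vi[n] for c, n in zip(self.coefficients, self.predictor_names))
            )
        prod = 1.0
        for n in self.predictor_names:
            prod *= vi[n]
        return float(self.coefficients[0] * prod)

    def predict_one(self, vi: VIVector | dict[str, float]) -> TraitEstimate:
        d = vi.as_dict() if isinstance(vi, VIVector) else dict(vi)
        value = self.intercept + self._design_vector(d)
        return TraitEstimate(value=value, below_zero=value < 0)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.predictor_names if n not in table.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        if self.mode == "sum":
            X = table[list(self.predictor_names)].to_numpy(dtype=float)
            return self.intercept + X @ np.asarray(self.coefficients)
        prod = np.prod(table[list(self.predictor_names)].to_numpy(dtype=float), axis=1)
        return self.intercept + self.coefficients[0] * prod

    # JSON round trip -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "mode": self.mode,
            "predictor_names": list(self.predictor_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearTraitModel":
        return cls(
            trait=d["trait"],
            mode=d["mode"],
            predictor_names=tuple(d["predictor_names"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            intercept=float(d["intercept"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LinearTraitModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Published frozen estimators.  Predictor order follows the printed equations.
_FROZEN: dict[str, LinearTraitModel] = {
    "reg1": LinearTraitModel(
        trait="LAI",
        mode="sum",
        predictor_names=("bgi", "ppr", "ngrdi", "ncpi", "nppr"),
        coefficients=(28.82, 13.77, -7.91, 14.88, 25.86),
        intercept=-39.74,
    ),
    "reg2": LinearTraitModel(
        trait="LAI",
        mode="product",
        predictor_names=("bgi", "ppr", "nppr", "ngrdi", "ncpi"),
        coefficients=(505.84,),
        intercept=0.134,
    ),
    "reg3": LinearTraitModel(
        trait="LG",
        mode="sum",
        predictor_names=("nppr", "ncpi", "ngrdi", "ppr"),
        coefficients=(254.26, 136.76, -92.73, -82.78),
        intercept=-144.24,
    ),
    "reg4": LinearTraitModel(
        trait="LG",
        mode="product",
        predictor_names=("ppr", "nppr", "ngrdi", "ncpi"),
        coefficients=(3372.55,),
        intercept=19.96,
    ),
}

FROZEN_MODEL_IDS = tuple(_FROZEN)


def frozen_model(model_id: str) -> LinearTraitModel:
    """One of the published estimators: reg1 | reg2 | reg3 | reg4."""
    try:
        return _FROZEN[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {sorted(_FROZEN)}"
        ) from None


def estimate_trait(
    vi: VIVector | dict[str, float], model: LinearTraitModel
) -> TraitEstimate:
    return model.predict_one(vi)


# ---------------------------------------------------------------------------
# OLS refitting


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, k = X.shape
    if n <= k:
        raise ValueError(f"insufficient rows: n={n} <= parameters={k}")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_linear_trait_model(
    table: pd.DataFrame,
    predictors: Sequence[str],
    trait: str,
    mode: str = "sum",
    trait_name: str | None = None,
) -> LinearTraitModel:
    """OLS fit of a sum- or product-mode model.

    ``trait`` names the response column in ``table``; in product mode the
    single regressor is the rowwise product of the named predictor columns.
    """
    predictors = tuple(predictors)
    y = table[trait].to_numpy(dtype=float)
    if mode == "sum":
        X = table[list(predictors)].to_numpy(dtype=float)
    elif mode == "product":
        X = np.prod(table[list(predictors)].to_numpy(dtype=float), axis=1)[:, None]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    design = np.column_stack([np.ones(len(y)), X])
    coef = _ols(design, y)
    return LinearTraitModel(
        trait=trait_name or trait,
        mode=mode,
        predictor_names=predictors,
        coefficients=tuple(float(c) for c in coef[1:]),
        intercept=float(coef[0]),
    )


# ---------------------------------------------------------------------------
# stepwise selection


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    criterion_path: tuple[float, ...]


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    # Floor the SSE so numerically perfect fits do not drive the criterion to
    # -inf and reward junk predictors that shave machine-epsilon residuals.
    floor = max(sst, 1.0) * 1e-12
    return n * np.log(max(sse, floor) / n) + 2 * k


def stepwise_select(
    table: pd.DataFrame,
    trait: str,
    candidates: Sequence[str] = VI_NAMES,
) -> StepwiseResult:
    """Forward-backward stepwise OLS minimizing AIC.

    Adds the best-improving candidate, then drops any member whose removal
    improves the criterion; stops when neither move improves.
    """
    candidates = list(candidates)
    y = table[trait].to_numpy(dtype=float)
    cols = {c: table[c].to_numpy(dtype=float) for c in candidates}
    n = len(y)

    def aic_for(subset: list[str]) -> float:
        X = np.column_stack([np.ones(n)] + [cols[c] for c in subset])
        return _aic(y, X)

    selected: list[str] = []
    current = aic_for(selected)
    path = [current]
    while True:
        improved = False
        # forward step
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            trials = [(aic_for(selected + [c]), c) for c in remaining]
            best_aic, best_c = min(trials, key=lambda t: t[0])
            if best_aic < current - 1e-9:
                selected.append(best_c)
                current = best_aic
                path.append(current)
                improved = True
        # backward sweep
        dropped = True
        while dropped and len(selected) > 0:
            dropped = False
            trials = [
                (aic_for([s for s in selected if s != c]), c) for c in selected
            ]
            best_aic, best_c = min(trials, key=lambda t: t[0])
            if best_aic < current - 1e-9:
                selected.remove(best_c)
                current = best_aic
                path.append(current)
                improved = dropped = True
        if not improved:
            break
    return StepwiseResult(selected=tuple(selected), criterion_path=tuple(path))


# ---------------------------------------------------------------------------
# multilayer perceptron


@dataclass(frozen=True)
class MLPConfig:
    hidden_layers: tuple[int, ...] = (5, 4, 3)
    learning_rate: float = 0.001
    momentum: float = 0.99
    epochs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class MLPDivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPModel:
    """Fully-connected sigmoid network with a linear output node.

    Inputs and the response are standardized during training; the scaler
    parameters are stored so prediction works on raw features.
    """

    feature_names: tuple[str, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    config: MLPConfig = field(default_factory=MLPConfig)
    loss_history: np.ndarray | None = None

    def _forward(self, Xs: np.ndarray) -> list[np.ndarray]:
        activations = [Xs]
        a = Xs
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == len(self.weights) - 1 else _sigmoid(z)
            activations.append(a)
        return activations

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in table.columns]
            if missing:
                raise KeyError(f"missing feature column(s): {missing}")
            X = table[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got shape {X.shape}"
                )
        Xs = (X - self.x_mean) / self.x_sd
        out = self._forward(Xs)[-1][:, 0]
        return out * self.y_sd + self.y_mean

    # JSON round trip -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "config": {
                "hidden_layers": list(self.config.hidden_layers),
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        cfg = d["config"]
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            config=MLPConfig(
                hidden_layers=tuple(cfg["hidden_layers"]),
                learning_rate=cfg["learning_rate"],
                momentum=cfg["momentum"],
                epochs=cfg["epochs"],
                seed=cfg["seed"],
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_mlp(
    table: pd.DataFrame,
    features: Sequence[str],
    trait: str,
    config: MLPConfig | None = None,
) -> MLPModel:
    """Full-batch gradient descent with momentum from seeded uniform init.

    Architecture: n_features -> hidden layers -> 1, sigmoid hidden units,
    linear output; loss is mean squared error on the standardized response.
    Deterministic given ``config.seed``.
    """
    config = config or MLPConfig()
    features = tuple(features)
    X = table[list(features)].to_numpy(dtype=float)
    y = table[trait].to_numpy(dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 rows to train")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0)) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    sizes = [len(features), *config.hidden_layers, 1]
    rng = np.random.default_rng(config.seed)
    weights = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1])
              for i in range(len(sizes) - 1)]
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    model = MLPModel(
        feature_names=features,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        config=config,
    )

    n_layers = len(weights)
    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        acts = model._forward(Xs)
        resid = acts[-1][:, 0] - ys
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise MLPDivergenceError(epoch)
        losses[epoch] = loss
        # backprop: dL/d(output) for MSE = 2*resid/n
        delta = (2.0 * resid / n)[:, None]
        for i in range(n_layers - 1, -1, -1):
            grad_w = acts[i].T @ delta
            grad_b = delta.sum(axis=0)
            if i > 0:
                a = acts[i]  # sigmoid activation of layer i
                delta = (delta @ weights[i].T) * a * (1.0 - a)
            vel_w[i] = config.momentum * vel_w[i] - config.learning_rate * grad_w
            vel_b[i] = config.momentum * vel_b[i] - config.learning_rate * grad_b
            weights[i] += vel_w[i]
            biases[i] += vel_b[i]
    model.loss_history = losses
    return model


def predict_mlp(table: pd.DataFrame | np.ndarray, model: MLPModel) -> np.ndarray:
    return model.predict(table)
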