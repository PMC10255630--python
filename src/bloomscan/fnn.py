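"""Small feedforward regression network (1 hidden layer).

This is the unit the scanning stage trains thousands of times, so the
design optimizes for determinism and small-data robustness rather than
throughput on large data: tanh hidden layer, linear output, full-batch
L-BFGS on the joint mean-squared error of all outputs, and weight
initialization drawn uniformly from the replicate seed.  Identical
(condition, data, hyperparameters) reproduce bit-identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .dataset import Normalizer, WindowedDataset
from .errors import ConfigError, DataError, FactorOrderError, TrainingDivergedError

__all__ = [
    "ModelCondition",
    "TrainConfig",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
]

MIN_TRAINING_SAMPLES = 10


@dataclass(frozen=True)
class ModelCondition:
    """One point of the scan grid: factor subset x width x replicate."""

    subset: tuple[str, ...]
    n_hidden: int
    replicate_seed: int

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Full-batch optimizer settings (all deterministic)."""

    max_iter: int = 200
    gtol: float = 1e-7
    ftol: float = 1e-12
    l2: float = 0.0
    init_scale: float = 0.5


@dataclass
class TrainedModel:
    """Weights plus the metadata needed to refuse mismatched inputs."""

    condition: ModelCondition
    w1: np.ndarray  # (d_in, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, d_out)
    b2: np.ndarray
    input_factors: tuple[str, ...]
    target_factors: tuple[str, ...]
    layout: tuple[tuple[int, str], ...]
    train_log: dict = field(default_factory=dict)
    normalizer: Normalizer | None = None

    @property
    def n_outputs(self) -> int:
        return self.w2.shape[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        hidden = np.tanh(x @ self.w1 + self.b1)
        return hidden @ self.w2 + self.b2


def _init_params(
    rng: np.random.Generator, d_in: int, n_hidden: int, d_out: int, scale: float
) -> np.ndarray:
    n = d_in * n_hidden + n_hidden + n_hidden * d_out + d_out
    return rng.uniform(-scale, scale, size=n)


def _unpack(theta, d_in, n_hidden, d_out):
    a = d_in * n_hidden
    b = a + n_hidden
    c = b + n_hidden * d_out
    w1 = theta[:a].reshape(d_in, n_hidden)
    b1 = theta[a:b]
    w2 = theta[b:c].reshape(n_hidden, d_out)
    b2 = theta[c:]
    return w1, b1, w2, b2


def train(
    condition: ModelCondition,
    windows: WindowedDataset,
    hyper: TrainConfig | None = None,
    normalizer: Normalizer | None = None,
) -> TrainedModel:
    """Fit one network on (normalized) window samples.

    Minimizes the mean squared error pooled over every output factor
    jointly, full batch, so the result is a pure function of
    (replicate seed, data, hyperparameters).
    """
    hyper = hyper or TrainConfig()
    x, y = windows.x, windows.y
    if len(x) < MIN_TRAINING_SAMPLES:
        raise DataError(
            f"need >= {MIN_TRAINING_SAMPLES} training samples, have {len(x)}"
        )
    d_in, d_out = x.shape[1], y.shape[1]
    n_hidden = condition.n_hidden
    rng = np.random.default_rng(condition.replicate_seed)
    theta0 = _init_params(rng, d_in, n_hidden, d_out, hyper.init_scale)
    denom = x.shape[0] * d_out

    def loss_grad(theta):
        # overflow here just signals divergence, caught after the solve
        with np.errstate(over="ignore", invalid="ignore"):
            w1, b1, w2, b2 = _unpack(theta, d_in, n_hidden, d_out)
            hidden = np.tanh(x @ w1 + b1)
            pred = hidden @ w2 + b2
            err = pred - y
            loss = float(np.sum(err * err)) / denom
            if hyper.l2:
                loss += hyper.l2 * (
                    float(np.sum(w1 * w1)) + float(np.sum(w2 * w2))
                )
            d_pred = (2.0 / denom) * err
            g_w2 = hidden.T @ d_pred
            g_b2 = d_pred.sum(axis=0)
            d_hidden = (d_pred @ w2.T) * (1.0 - hidden * hidden)
            g_w1 = x.T @ d_hidden
            g_b1 = d_hidden.sum(axis=0)
            if hyper.l2:
                g_w1 = g_w1 + 2.0 * hyper.l2 * w1
                g_w2 = g_w2 + 2.0 * hyper.l2 * w2
            grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
        return loss, grad

    result = minimize(
        loss_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": hyper.max_iter,
            "gtol": hyper.gtol,
            "ftol": hyper.ftol,
        },
    )
    if not np.isfinite(result.fun):
        raise TrainingDivergedError(
            f"training diverged (loss={result.fun})", iteration=int(result.nit)
        )
    w1, b1, w2, b2 = _unpack(result.x, d_in, n_hidden, d_out)
    return TrainedModel(
        condition=condition,
        w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=b2.copy(),
        input_factors=windows.input_factors,
        target_factors=windows.target_factors,
        layout=windows.layout,
        train_log={
            "iterations": int(result.nit),
            "final_loss": float(result.fun),
            "converged": bool(result.success),
            "message": str(result.message),
        },
        normalizer=normalizer,
    )


def predict(model: TrainedModel, windows: WindowedDataset) -> np.ndarray:
    """Predictions (normalized space), one output row per sample.

    Refuses mismatched window layouts — inputs are never silently
    reordered to fit the model.
    """
    if windows.layout != model.layout or windows.input_factors != model.input_factors:
        raise FactorOrderError(
            "window factor layout does not match the model's training layout"
        )
    if windows.x.shape[1] != model.w1.shape[0]:
        raise FactorOrderError(
            f"input width {windows.x.shape[1]} != model width {model.w1.shape[0]}"
        )
    return model.forward(windows.x)


# -- serialization ----------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "condition": {
            "subset": list(model.condition.subset),
            "n_hidden": model.condition.n_hidden,
            "replicate_seed": model.condition.replicate_seed,
        },
        "weights": {
            "w1": model.w1.tolist(),
            "b1": model.b1.tolist(),
            "w2": model.w2.tolist(),
            "b2": model.b2.tolist(),
        },
        "input_factors": list(model.input_factors),
        "target_factors": list(model.target_factors),
        "layout": [[lag, f] for lag, f in model.layout],
        "train_log": model.train_log,
        "normalizer": model.normalizer.to_dict() if model.normalizer else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    cond = payload["condition"]
    normalizer = payload.get("normalizer")
    return TrainedModel(
        condition=ModelCondition(
            tuple(cond["subset"]), int(cond["n_hidden"]),
            int(cond["replicate_seed"]),
        ),
        w1=np.asarray(payload["weights"]["w1"]),
        b1=np.asarray(payload["weights"]["b1"]),
        w2=np.asarray(payload["weights"]["w2"]),
        b2=np.asarray(payload["weights"]["b2"]),
        input_factors=tuple(payload["input_factors"]),
        target_factors=tuple(payload["target_factors"]),
        layout=tuple((int(l), f) for l, f in payload["layout"]),
        train_log=payload.get("train_log", {}),
        normalizer=Normalizer.from_dict(normalizer) if normalizer else None,
    )
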