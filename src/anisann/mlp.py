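"""Single-hidden-layer perceptron regression trained by BFGS with restarts.

The model is the matrix composition

    Y = f1(W2 · f2(W1 · X + B1) + B2)

with ``f2`` the hidden-layer and ``f1`` the output-layer transfer function,
each drawn from {identity, logistic, tanh, exponential}.  Training minimizes
the sum-of-squares (SOS) error over all rows and outputs with an analytic
gradient (backpropagation) fed to a quasi-Newton BFGS optimizer with
strong-Wolfe line search.  Because the SOS surface is multimodal, training is
restarted from multiple random initializations (weights uniform in
[−0.5, 0.5]) and the restart with the smallest *validation* SOS is retained.
An architecture search scans a grid of hidden-layer sizes and activation
pairs and keeps the grid point with minimal validation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .io import DesignMatrix, ResponseScaler, SplitIndices

__all__ = [
    "ACTIVATIONS",
    "MLPParams",
    "TrainingConfig",
    "TrainedModel",
    "MLPRegressor",
    "forward",
    "sos_loss",
    "loss_gradient",
    "train_mlp",
    "search_architectures",
    "overall_performance",
    "save_params_text",
    "load_params_text",
]


def _identity(z):
    return z


def _d_identity(z):
    return np.ones_like(z)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _d_logistic(z):
    s = _logistic(z)
    return s * (1.0 - s)


def _d_tanh(z):
    return 1.0 - np.tanh(z) ** 2


#: name -> (f, f') on the pre-activation.
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "identity": (_identity, _d_identity),
    "logistic": (_logistic, _d_logistic),
    "tanh": (np.tanh, _d_tanh),
    "exponential": (np.exp, np.exp),
}


class ShapeError(ValueError):
    """Dimension mismatch between parameters and data."""


class TrainingError(RuntimeError):
    """All optimizer restarts diverged."""


@dataclass
class MLPParams:
    """Weights, biases and transfer-function identifiers of the network.

    ``W1`` is inputs × hidden, ``W2`` hidden × outputs; ``B1``/``B2`` are the
    hidden/output bias vectors.
    """

    W1: np.ndarray
    B1: np.ndarray
    W2: np.ndarray
    B2: np.ndarray
    hidden_activation: str = "exponential"
    output_activation: str = "exponential"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.B1 = np.asarray(self.B1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.B2 = np.asarray(self.B2, dtype=float)
        for act in (self.hidden_activation, self.output_activation):
            if act not in ACTIVATIONS:
                raise ValueError(
                    f"unknown activation {act!r}; choose from {sorted(ACTIVATIONS)}"
                )
        i, h = self.W1.shape
        h2, o = self.W2.shape
        if h != h2 or self.B1.shape != (h,) or self.B2.shape != (o,):
            raise ShapeError(
                f"inconsistent shapes: W1 {self.W1.shape}, B1 {self.B1.shape}, "
                f"W2 {self.W2.shape}, B2 {self.B2.shape}"
            )

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[1]

    @property
    def n_parameters(self) -> int:
        """Total weight + bias count: I·H + H + H·O + O."""
        i, h, o = self.n_inputs, self.n_hidden, self.n_outputs
        return i * h + h + h * o + o

    def to_vector(self) -> np.ndarray:
        """Flatten as W1 (row-major), B1, W2 (row-major), B2."""
        return np.concatenate(
            [self.W1.ravel(), self.B1, self.W2.ravel(), self.B2]
        )

    @classmethod
    def from_vector(
        cls,
        vec: np.ndarray,
        n_inputs: int,
        n_hidden: int,
        n_outputs: int,
        hidden_activation: str = "exponential",
        output_activation: str = "exponential",
    ) -> "MLPParams":
        i, h, o = n_inputs, n_hidden, n_outputs
        expected = i * h + h + h * o + o
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (expected,):
            raise ShapeError(f"expected vector of length {expected}, got {vec.shape}")
        pos = 0
        W1 = vec[pos : pos + i * h].reshape(i, h); pos += i * h
        B1 = vec[pos : pos + h]; pos += h
        W2 = vec[pos : pos + h * o].reshape(h, o); pos += h * o
        B2 = vec[pos:]
        return cls(W1, B1, W2, B2, hidden_activation, output_activation)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def forward(params: MLPParams, X) -> np.ndarray:
    """Evaluate the network row-wise: ``f1(f2(X·W1 + B1)·W2 + B2)``."""
    X = _as_matrix(X)
    if X.shape[1] != params.n_inputs:
        raise ShapeError(
            f"input width {X.shape[1]} does not match W1 input dimension "
            f"{params.n_inputs}"
        )
    f1 = ACTIVATIONS[params.output_activation][0]
    f2 = ACTIVATIONS[params.hidden_activation][0]
    with np.errstate(over="ignore", invalid="ignore"):
        A1 = f2(X @ params.W1 + params.B1)
        return f1(A1 @ params.W2 + params.B2)


def sos_loss(params: MLPParams, X, Y_target) -> float:
    """Sum over all rows and outputs of squared prediction error."""
    Y_target = np.asarray(Y_target, dtype=float)
    pred = forward(params, X)
    if Y_target.ndim == 1:
        Y_target = Y_target[:, None]
    if pred.shape != Y_target.shape:
        raise ShapeError(f"prediction {pred.shape} vs target {Y_target.shape}")
    with np.errstate(over="ignore", invalid="ignore"):
        loss = float(np.sum((pred - Y_target) ** 2))
    return loss if np.isfinite(loss) else float("inf")


def loss_gradient(params: MLPParams, X, Y_target) -> np.ndarray:
    """Analytic gradient of :func:`sos_loss`, flattened as ``to_vector``.

    Standard backpropagation of the squared error through the two affine
    layers and their transfer functions.
    """
    X = _as_matrix(X)
    Y = np.asarray(Y_target, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    f1, df1 = ACTIVATIONS[params.output_activation]
    f2, df2 = ACTIVATIONS[params.hidden_activation]
    with np.errstate(over="ignore", invalid="ignore"):
        Z1 = X @ params.W1 + params.B1
        A1 = f2(Z1)
        Z2 = A1 @ params.W2 + params.B2
        Yhat = f1(Z2)
        dZ2 = 2.0 * (Yhat - Y) * df1(Z2)
        gW2 = A1.T @ dZ2
        gB2 = dZ2.sum(axis=0)
        dZ1 = (dZ2 @ params.W2.T) * df2(Z1)
        gW1 = X.T @ dZ1
        gB1 = dZ1.sum(axis=0)
    return np.concatenate([gW1.ravel(), gB1, gW2.ravel(), gB2])


def overall_performance(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean over outputs of the squared Pearson correlation r².

    Zero-variance columns (in either vector) carry no correlation information
    and are excluded from the mean.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.ndim == 1:
        y_true, y_pred = y_true[:, None], y_pred[:, None]
    r2 = np.full(y_true.shape[1], np.nan)
    for j in range(y_true.shape[1]):
        a, b = y_true[:, j], y_pred[:, j]
        if np.std(a) == 0 or np.std(b) == 0 or not np.all(np.isfinite(b)):
            continue
        r2[j] = np.corrcoef(a, b)[0, 1] ** 2
    return float(np.nanmean(r2)) if np.any(np.isfinite(r2)) else float("nan")


@dataclass
class TrainingConfig:
    """Knobs of the training protocol and architecture search."""

    hidden_sizes: tuple[int, ...] = tuple(range(5, 21))
    activations: tuple[tuple[str, str], ...] = (("exponential", "exponential"),)
    restarts: int = 50
    max_iterations: int = 1000
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not all(1 <= h <= 1000 for h in self.hidden_sizes):
            raise ValueError(f"hidden sizes must lie in 1..1000: {self.hidden_sizes}")
        if self.restarts < 1:
            raise ValueError("restarts must be ≥ 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")
        self.activations = tuple(
            (str(h), str(o)) for h, o in self.activations
        )
        for pair in self.activations:
            for act in pair:
                if act not in ACTIVATIONS:
                    raise ValueError(f"unknown activation {act!r}")


class MLPRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator around the BFGS-trained perceptron.

    Parameters
    ----------
    hidden_units : int
        Hidden-layer width.
    hidden_activation, output_activation : str
        Transfer functions, from {identity, logistic, tanh, exponential}.
    restarts : int
        Independent optimizer runs from random initializations.
    max_iter : int
        BFGS iteration cap per run.
    tol : float
        Gradient-norm convergence tolerance passed to the optimizer.
    init_scale : float
        Initial weights drawn uniformly from [−init_scale, init_scale].
    random_state : int or None
        Seeds initialization; identical seeds give identical fits.

    Attributes
    ----------
    params_ : MLPParams
        Weights of the selected restart.
    train_sos_, val_sos_ : float
        Final SOS of the selected restart (``val_sos_`` is NaN when no
        validation set was supplied and selection used the training SOS).
    restart_log_ : list of dict
        Per-restart initial/final losses, iteration counts and discards.
    loss_trajectory_ : ndarray
        Best-so-far training SOS per accepted iteration of the winning run.
    """

    def __init__(
        self,
        hidden_units: int = 10,
        hidden_activation: str = "exponential",
        output_activation: str = "exponential",
        restarts: int = 50,
        max_iter: int = 1000,
        tol: float = 1e-10,
        init_scale: float = 0.5,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.init_scale = init_scale
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) == 0:
            raise TrainingError("training partition is empty")
        has_val = X_val is not None and y_val is not None and len(_as_matrix(X_val)) > 0
        if has_val:
            X_val = _as_matrix(X_val)
            y_val = np.asarray(y_val, dtype=float)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        n_in, n_out, n_hid = X.shape[1], y.shape[1], int(self.hidden_units)
        rng = np.random.default_rng(self.random_state)

        def unpack(vec):
            return MLPParams.from_vector(
                vec, n_in, n_hid, n_out,
                self.hidden_activation, self.output_activation,
            )

        f1, df1 = ACTIVATIONS[self.output_activation]
        f2, df2 = ACTIVATIONS[self.hidden_activation]

        def loss_and_grad(vec, evals):
            # fused forward + backward pass; one line-search evaluation each
            p = unpack(vec)
            with np.errstate(over="ignore", invalid="ignore"):
                Z1 = X @ p.W1 + p.B1
                A1 = f2(Z1)
                Z2 = A1 @ p.W2 + p.B2
                Yhat = f1(Z2)
                R = Yhat - y
                loss = float(np.sum(R * R))
                dZ2 = 2.0 * R * df1(Z2)
                gW2 = A1.T @ dZ2
                gB2 = dZ2.sum(axis=0)
                dZ1 = (dZ2 @ p.W2.T) * df2(Z1)
                gW1 = X.T @ dZ1
                gB1 = dZ1.sum(axis=0)
            g = np.concatenate([gW1.ravel(), gB1, gW2.ravel(), gB2])
            if not np.isfinite(loss):
                loss = float("inf")
            g = np.where(np.isfinite(g), g, 0.0)
            evals.append(min(loss, evals[-1]) if evals else loss)
            return loss, g

        n_params = n_in * n_hid + n_hid + n_hid * n_out + n_out
        best = None
        self.restart_log_ = []
        for run in range(int(self.restarts)):
            x0 = rng.uniform(-self.init_scale, self.init_scale, size=n_params)
            trajectory: list[float] = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    loss_and_grad, x0, jac=True, method="BFGS",
                    args=(trajectory,),
                    options={"maxiter": int(self.max_iter), "gtol": self.tol},
                )
            f0 = trajectory[0]
            final = float(res.fun)
            entry = {
                "restart": run,
                "initial_sos": float(f0),
                "final_sos": final,
                "n_iter": int(res.nit),
                "discarded": not np.isfinite(final),
            }
            if entry["discarded"]:
                self.restart_log_.append(entry)
                continue
            params = unpack(res.x)
            val = sos_loss(params, X_val, y_val) if has_val else final
            entry["val_sos"] = float(val)
            self.restart_log_.append(entry)
            key = val if np.isfinite(val) else np.inf
            if best is None or key < best[0]:
                best = (key, params, final, val, np.asarray(trajectory), int(res.nit))
        if best is None:
            raise TrainingError("all optimizer restarts diverged to non-finite loss")
        (_, self.params_, self.train_sos_, val_sos,
         self.loss_trajectory_, self.n_iter_) = best
        self.val_sos_ = float(val_sos) if has_val else float("nan")
        self.n_parameters_ = self.params_.n_parameters
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise TrainingError("MLPRegressor is not fitted")
        return forward(self.params_, X)

    def score(self, X, y):
        """Overall performance: mean r² across outputs."""
        return overall_performance(np.asarray(y, dtype=float), self.predict(X))


@dataclass
class TrainedModel:
    """A fitted network plus the preprocessing needed to apply it.

    Predictions pass the raw 10-column encoding through the network and
    inverse-transform the outputs back to original response units.
    """

    params: MLPParams
    scaler: ResponseScaler
    split: SplitIndices
    output_names: list[str]
    sos: dict[str, float]                    # per-partition, normalized units
    sos_original: dict[str, float]           # per-partition, original units
    performance: dict[str, float]            # per-partition mean r²
    loss_trajectory: np.ndarray
    restart_log: list[dict]
    n_iterations: int

    @property
    def n_parameters(self) -> int:
        return self.params.n_parameters

    @property
    def net_name(self) -> str:
        p = self.params
        return f"MLP {p.n_inputs}-{p.n_hidden}-{p.n_outputs}"

    def predict(self, X) -> np.ndarray:
        """Predict responses in original units for encoded inputs."""
        return self.scaler.inverse_transform(forward(self.params, X))

    def predict_normalized(self, X) -> np.ndarray:
        return forward(self.params, X)


def _partition_metrics(
    params: MLPParams,
    scaler: ResponseScaler,
    X: np.ndarray,
    Y: np.ndarray,
    Yn: np.ndarray,
    split: SplitIndices,
) -> tuple[dict, dict, dict]:
    sos_n, sos_o, perf = {}, {}, {}
    for name, idx in (
        ("train", split.train), ("validation", split.validation), ("test", split.test)
    ):
        if len(idx) == 0:
            sos_n[name] = sos_o[name] = perf[name] = float("nan")
            continue
        pred_n = forward(params, X[idx])
        pred_o = scaler.inverse_transform(pred_n)
        sos_n[name] = float(np.sum((pred_n - Yn[idx]) ** 2))
        sos_o[name] = float(np.sum((pred_o - Y[idx]) ** 2))
        perf[name] = overall_performance(Y[idx], pred_o)
    return sos_n, sos_o, perf


def train_mlp(
    X,
    Y,
    split: SplitIndices,
    config: TrainingConfig,
    hidden: int,
    activations: tuple[str, str] = ("exponential", "exponential"),
    output_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one architecture with the full protocol.

    Scales responses to [0, 1] on the training partition, runs
    ``config.restarts`` BFGS minimizations from random starts and keeps the
    restart with the smallest validation SOS.
    """
    X = _as_matrix(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    scaler = ResponseScaler().fit(Y[split.train])
    Yn = scaler.transform(Y)
    est = MLPRegressor(
        hidden_units=hidden,
        hidden_activation=activations[0],
        output_activation=activations[1],
        restarts=config.restarts,
        max_iter=config.max_iterations,
        tol=config.tol,
        random_state=config.seed,
    )
    est.fit(
        X[split.train], Yn[split.train],
        X_val=X[split.validation] if len(split.validation) else None,
        y_val=Yn[split.validation] if len(split.validation) else None,
    )
    sos_n, sos_o, perf = _partition_metrics(est.params_, scaler, X, Y, Yn, split)
    names = (
        list(output_names)
        if output_names is not None
        else [f"output_{j}" for j in range(Y.shape[1])]
    )
    return TrainedModel(
        params=est.params_,
        scaler=scaler,
        split=split,
        output_names=names,
        sos=sos_n,
        sos_original=sos_o,
        performance=perf,
        loss_trajectory=est.loss_trajectory_,
        restart_log=est.restart_log_,
        n_iterations=est.n_iter_,
    )


def search_architectures(
    X,
    Y,
    split: SplitIndices,
    config: TrainingConfig,
    output_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, TrainedModel]:
    """Scan the hidden-size × activation-pair grid; keep the minimal
    validation-error model.

    Returns a one-row-per-combination summary (network name, per-partition
    performance and SOS error in normalized and original units, optimizer
    iteration count) and the winning :class:`TrainedModel`.
    """
    if not config.hidden_sizes or not config.activations:
        raise ValueError("architecture grid is empty")
    rows = []
    best_model, best_err = None, np.inf
    for gi, hidden in enumerate(config.hidden_sizes):
        for gj, acts in enumerate(config.activations):
            sub = TrainingConfig(
                hidden_sizes=(hidden,),
                activations=(acts,),
                restarts=config.restarts,
                max_iterations=config.max_iterations,
                tol=config.tol,
                seed=config.seed + 1000 * gi + 100 * gj,
            )
            model = train_mlp(
                X, Y, split, sub, hidden, acts, output_names=output_names
            )
            rows.append(
                {
                    "net_name": model.net_name,
                    "hidden_units": hidden,
                    "hidden_activation": acts[0],
                    "output_activation": acts[1],
                    "performance_train": model.performance["train"],
                    "performance_test": model.performance["test"],
                    "performance_validation": model.performance["validation"],
                    "error_train": model.sos["train"],
                    "error_test": model.sos["test"],
                    "error_validation": model.sos["validation"],
                    "error_train_original": model.sos_original["train"],
                    "error_test_original": model.sos_original["test"],
                    "error_validation_original": model.sos_original["validation"],
                    "training_algorithm": f"BFGS {model.n_iterations}",
                    "error_function": "SOS",
                    "n_parameters": model.n_parameters,
                }
            )
            err = model.sos["validation"]
            if np.isfinite(err) and err < best_err:
                best_err, best_model = err, model
    if best_model is None:
        raise TrainingError("no architecture achieved a finite validation error")
    return pd.DataFrame(rows), best_model


def save_params_text(params: MLPParams, path: str | Path) -> None:
    """Serialize weights as labelled full-precision text blocks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# MLP {params.n_inputs}-{params.n_hidden}-{params.n_outputs}\n"
            f"# hidden_activation {params.hidden_activation}\n"
            f"# output_activation {params.output_activation}\n"
        )
        for label, arr in (
            ("W1", params.W1), ("B1", params.B1[None, :]),
            ("W2", params.W2), ("B2", params.B2[None, :]),
        ):
            fh.write(f"[{label}] {arr.shape[0]} {arr.shape[1]}\n")
            for row in arr:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_params_text(path: str | Path) -> MLPParams:
    blocks: dict[str, np.ndarray] = {}
    hidden_act = output_act = "exponential"
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("# hidden_activation"):
            hidden_act = line.split()[-1]
        elif line.startswith("# output_activation"):
            output_act = line.split()[-1]
        elif line.startswith("["):
            header = line.split()
            label = header[0].strip("[]")
            nr, nc = int(header[1]), int(header[2])
            data = [
                [float(v) for v in lines[i + 1 + r].split()] for r in range(nr)
            ]
            blocks[label] = np.asarray(data)
            i += nr
        i += 1
    return MLPParams(
        W1=blocks["W1"], B1=blocks["B1"][0],
        W2=blocks["W2"], B2=blocks["B2"][0],
        hidden_activation=hidden_act, output_activation=output_act,
    )
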