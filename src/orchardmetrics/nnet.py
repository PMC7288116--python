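"""Back-propagation neural network for per-tree yield prediction.

A three-layer perceptron: m inputs -> h tanh ("tansig") hidden units ->
one linear ("purelin") output, trained to minimize mean squared error
with the Levenberg-Marquardt algorithm (an `adam` backend is available as
a fallback).  The hidden width follows the empirical rule
h = ceil(sqrt(m + n)) + a with the adjustment constant a in 1..10, either
fixed or selected on the validation split.  Data are split 60/15/25 into
training/validation/test; inputs and the target are z-scored on the
training split only (tanh saturates on raw 0-255 moment features), and
training stops early when validation MSE has not improved for ``patience``
epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_SPLIT = (0.60, 0.15, 0.25)


def hidden_nodes(m: int, n: int = 1, a: int = 1) -> int:
    """Hidden-layer width rule h = ceil(sqrt(m + n)) + a."""
    if not 1 <= a <= 10:
        raise ValueError("adjustment constant a must be in 1..10")
    return math.ceil(math.sqrt(m + n)) + a


def split_data(
    n_samples: int,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint shuffled train/validation/test index sets.

    Sizes use largest-remainder rounding so they always sum to
    ``n_samples``.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    raw = np.array(fractions) * n_samples
    sizes = np.floor(raw).astype(int)
    remainder = n_samples - sizes.sum()
    order = np.argsort(-(raw - sizes))
    for k in range(remainder):
        sizes[order[k]] += 1
    perm = np.random.default_rng(seed).permutation(n_samples)
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return perm[:i1], perm[i1:i2], perm[i2:]


@dataclass
class ModelConfig:
    n_inputs: int
    n_outputs: int = 1
    hidden_a: int | str = "auto"
    hidden_nodes: int | None = None
    optimizer: str = "levenberg_marquardt"
    max_epochs: int = 500
    patience: int = 6
    split: tuple[float, float, float] = DEFAULT_SPLIT
    seed: int = 0

    def resolve_hidden(self, a: int) -> int:
        if self.hidden_nodes is not None:
            return self.hidden_nodes
        return hidden_nodes(self.n_inputs, self.n_outputs, a)


class BPANN:
    """m -> h -> 1 network with tanh hidden layer and linear output.

    Prediction is deterministic given the stored weights and the input
    standardization parameters frozen at fit time.
    """

    def __init__(
        self,
        n_hidden: int,
        optimizer: str = "levenberg_marquardt",
        max_epochs: int = 500,
        patience: int = 6,
        seed: int = 0,
    ):
        if optimizer not in ("levenberg_marquardt", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        self.n_hidden = int(n_hidden)
        self.optimizer = optimizer
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.seed = int(seed)
        self.W1 = self.b1 = self.w2 = None
        self.b2 = 0.0
        self.x_mean = self.x_sd = None
        self.y_mean = 0.0
        self.y_sd = 1.0
        self.training_log: list[dict] = []

    # -- parameter vector helpers -------------------------------------
    def _init_params(self, m: int, rng: np.random.Generator) -> np.ndarray:
        h = self.n_hidden
        W1 = rng.normal(0.0, 1.0 / math.sqrt(m), (h, m))
        b1 = np.zeros(h)
        w2 = rng.normal(0.0, 1.0 / math.sqrt(h), h)
        b2 = np.zeros(1)
        return np.concatenate([W1.ravel(), b1, w2, b2])

    def _unpack(self, params: np.ndarray, m: int):
        h = self.n_hidden
        k = h * m
        W1 = params[:k].reshape(h, m)
        b1 = params[k:k + h]
        w2 = params[k + h:k + 2 * h]
        b2 = params[k + 2 * h]
        return W1, b1, w2, b2

    @staticmethod
    def _forward(params_unpacked, X: np.ndarray):
        W1, b1, w2, b2 = params_unpacked
        A1 = np.tanh(X @ W1.T + b1)
        yhat = A1 @ w2 + b2
        return yhat, A1

    def _residual_jacobian(self, params: np.ndarray, X: np.ndarray, y: np.ndarray):
        m = X.shape[1]
        W1, b1, w2, b2 = self._unpack(params, m)
        yhat, A1 = self._forward((W1, b1, w2, b2), X)
        r = yhat - y
        # d yhat / d params, one row per sample.
        dA = (1.0 - A1**2) * w2  # (n, h)
        J = np.concatenate(
            [
                (dA[:, :, None] * X[:, None, :]).reshape(len(X), -1),  # W1
                dA,                                                    # b1
                A1,                                                    # w2
                np.ones((len(X), 1)),                                  # b2
            ],
            axis=1,
        )
        return r, J

    # -- training backends --------------------------------------------
    def _val_mse(self, params: np.ndarray, Xv: np.ndarray, yv: np.ndarray) -> float:
        yhat, _ = self._forward(self._unpack(params, Xv.shape[1]), Xv)
        return float(np.mean((yhat - yv) ** 2))

    def _train_lm(self, params, X, y, Xv, yv):
        # Large initial damping keeps early steps short so the validation
        # snapshot has fine granularity; x10 / /10 multiplicative schedule.
        lam = 1e2
        r, J = self._residual_jacobian(params, X, y)
        sse = float(r @ r)
        best = params.copy()
        best_val = self._val_mse(params, Xv, yv)
        stall = 0
        eye = np.eye(len(params))
        for epoch in range(self.max_epochs):
            g = J.T @ r
            A = J.T @ J
            accepted = False
            for _ in range(8):
                try:
                    delta = np.linalg.solve(A + lam * eye, g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                trial = params - delta
                r_t, J_t = self._residual_jacobian(trial, X, y)
                sse_t = float(r_t @ r_t)
                if not np.isfinite(sse_t):
                    raise RuntimeError("non-finite training loss in LM step")
                if sse_t < sse:
                    params, r, J, sse = trial, r_t, J_t, sse_t
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            val = self._val_mse(params, Xv, yv)
            self.training_log.append(
                {"epoch": epoch, "train_mse": sse / len(X), "val_mse": val, "lambda": lam}
            )
            if val < best_val - 1e-12:
                best_val, best = val, params.copy()
                stall = 0
            else:
                stall += 1
            if stall >= self.patience or not accepted:
                break
        return best

    def _train_adam(self, params, X, y, Xv, yv, lr=0.01):
        m1 = np.zeros_like(params)
        m2 = np.zeros_like(params)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best = params.copy()
        best_val = self._val_mse(params, Xv, yv)
        stall = 0
        for epoch in range(self.max_epochs):
            r, J = self._residual_jacobian(params, X, y)
            g = 2.0 * (J.T @ r) / len(X)
            m1 = beta1 * m1 + (1 - beta1) * g
            m2 = beta2 * m2 + (1 - beta2) * g**2
            mhat = m1 / (1 - beta1 ** (epoch + 1))
            vhat = m2 / (1 - beta2 ** (epoch + 1))
            params = params - lr * mhat / (np.sqrt(vhat) + eps)
            if not np.all(np.isfinite(params)):
                raise RuntimeError("non-finite parameters in adam step")
            val = self._val_mse(params, Xv, yv)
            self.training_log.append(
                {"epoch": epoch, "train_mse": float(r @ r) / len(X), "val_mse": val}
            )
            if val < best_val - 1e-12:
                best_val, best = val, params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        return best

    # -- public API -----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, validation: tuple[np.ndarray, np.ndarray] | None = None):
        """Train on (X, y), early-stopping on the validation pair.

        Standardization parameters are computed from X and y here (the
        training split) and frozen; validation data are standardized with
        them, never refit.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("training data contain missing values")
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd = np.where(sd > 0, sd, 1.0)
        self.y_mean = float(y.mean())
        ysd = float(y.std())
        self.y_sd = ysd if ysd > 0 else 1.0
        Xs = (X - self.x_mean) / self.x_sd
        ys = (y - self.y_mean) / self.y_sd
        if validation is not None:
            Xv = (np.asarray(validation[0], dtype=np.float64) - self.x_mean) / self.x_sd
            yv = (np.asarray(validation[1], dtype=np.float64).ravel() - self.y_mean) / self.y_sd
        else:
            Xv, yv = Xs, ys
        rng = np.random.default_rng(self.seed)
        params = self._init_params(Xs.shape[1], rng)
        self.training_log = []
        if self.optimizer == "levenberg_marquardt":
            params = self._train_lm(params, Xs, ys, Xv, yv)
        else:
            params = self._train_adam(params, Xs, ys, Xv, yv)
        self.W1, self.b1, self.w2, self.b2 = self._unpack(params, Xs.shape[1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass with the stored standardization."""
        if self.W1 is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"feature length {X.shape[1]} != model input size {self.W1.shape[1]}"
            )
        Xs = (X - self.x_mean) / self.x_sd
        yhat, _ = self._forward((self.W1, self.b1, self.w2, self.b2), Xs)
        return yhat * self.y_sd + self.y_mean


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """R^2, RMSE, and relative-average-deviation statistics.

    RAD_i = |pred_i - true_i| / true_i * 100, aggregated as mean/max/min
    over entries with true > 0.  Zero variance in y_true leaves R^2
    undefined (nan, flagged).
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need at least 2 samples")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2_defined = ss_tot > 0
    r2 = 1.0 - ss_res / ss_tot if r2_defined else float("nan")
    rmse = math.sqrt(np.mean((y_true - y_pred) ** 2))
    pos = y_true > 0
    if pos.any():
        rad = np.abs(y_pred[pos] - y_true[pos]) / y_true[pos] * 100.0
        rad_avg, rad_max, rad_min = float(rad.mean()), float(rad.max()), float(rad.min())
    else:
        rad_avg = rad_max = rad_min = float("nan")
    return {
        "R2": r2,
        "R2_defined": r2_defined,
        "RMSE": rmse,
        "RAD_avg": rad_avg,
        "RAD_max": rad_max,
        "RAD_min": rad_min,
        "n": len(y_true),
    }


@dataclass
class YieldModelResult:
    """Trained model plus per-split predictions and metrics."""

    model: BPANN
    config: ModelConfig
    chosen_a: int | None
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    predictions: np.ndarray = field(repr=False, default=None)
    metrics: dict = field(default_factory=dict)

    @property
    def test_r2(self) -> float:
        return self.metrics["test"]["R2"]


def fit_yield_model(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    **config_overrides,
) -> YieldModelResult:
    """Split, (optionally) select the hidden-width constant, train, score.

    With ``hidden_a='auto'`` each a in 1..10 is trained on the training
    split and the one with the lowest validation RMSE wins (test data play
    no role in selection).  Metrics are reported per split and for the
    whole dataset, each labelled.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if config is None:
        config = ModelConfig(n_inputs=X.shape[1], **config_overrides)
    if config.n_inputs != X.shape[1]:
        raise ValueError("config.n_inputs disagrees with X")
    idx_tr, idx_va, idx_te = split_data(len(X), config.split, seed=config.seed)
    Xtr, ytr = X[idx_tr], y[idx_tr]
    Xva, yva = X[idx_va], y[idx_va]

    def _fit(a: int) -> BPANN:
        net = BPANN(
            n_hidden=config.resolve_hidden(a),
            optimizer=config.optimizer,
            max_epochs=config.max_epochs,
            patience=config.patience,
            seed=config.seed + 1000 * a,
        )
        return net.fit(Xtr, ytr, validation=(Xva, yva))

    if config.hidden_a == "auto" and config.hidden_nodes is None:
        best_net, best_a, best_rmse = None, None, np.inf
        for a in range(1, 11):
            net = _fit(a)
            rmse = evaluate(yva, net.predict(Xva))["RMSE"]
            if rmse < best_rmse:
                best_net, best_a, best_rmse = net, a, rmse
        net, chosen_a = best_net, best_a
    else:
        a = 1 if config.hidden_a == "auto" else int(config.hidden_a)
        net, chosen_a = _fit(a), a
    preds = net.predict(X)
    metrics = {
        "train": evaluate(ytr, preds[idx_tr]),
        "val": evaluate(yva, preds[idx_va]),
        "test": evaluate(y[idx_te], preds[idx_te]),
        "all": evaluate(y, preds),
    }
    return YieldModelResult(
        model=net,
        config=config,
        chosen_a=chosen_a,
        idx_train=idx_tr,
        idx_val=idx_va,
        idx_test=idx_te,
        predictions=preds,
        metrics=metrics,
    )
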