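"""The three estimators behind a common fit/predict contract.

* :func:`fit_plsr` — partial least squares regression; the number of
  latent variables is chosen by leave-one-out cross-validation, taking
  the candidate with the minimum PRESS (predicted residual error sum of
  squares) and, on ties, the fewest latent variables.
* :func:`fit_rf` — random-forest regression (bootstrap ensemble of
  depth-limited trees, mean aggregation).
* :func:`fit_bpnn` — a classic backpropagation network: sigmoid hidden
  units, linear output, full-batch gradient descent with momentum and a
  variable learning rate (grown on improvement, cut — with the step
  undone — when the training loss spikes), and early stopping on a
  caller-supplied stop set: training halts once the stop-set loss has
  failed to decrease for ``patience`` consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor


# ---------------------------------------------------------------------------
# PLSR

@dataclass
class PLSRModel:
    """Fitted PLSR with its PRESS curve.

    ``press[r]`` is the leave-one-out PRESS for r latent variables;
    ``n_components`` is the argmin (smallest r on ties).
    """
    n_components: int
    press: dict
    _pls: PLSRegression = field(repr=False)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self._pls.predict(np.asarray(X, float))).ravel()


def _press_loocv(X, y, r: int) -> float:
    n = X.shape[0]
    press = 0.0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        pls = PLSRegression(n_components=r, scale=False)
        pls.fit(X[keep], y[keep])
        pred = float(np.asarray(pls.predict(X[i:i + 1])).ravel()[0])
        press += (y[i] - pred) ** 2
    return press


def fit_plsr(X_cal, y_cal, max_r: int = 15) -> PLSRModel:
    """Fit PLSR, selecting latent variables by minimum LOOCV PRESS.

    X and y are centered internally with calibration statistics (no
    per-feature scaling). ``max_r`` caps the candidate count at
    min(n-1, p, max_r).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < 1:
        raise ValueError("X is rank-deficient beyond r=0; PLSR undefined")
    r_max = max(1, min(max_r, n - 1, p, rank))
    press = {r: _press_loocv(X, y, r) for r in range(1, r_max + 1)}
    r_best = min(press, key=lambda r: (press[r], r))
    pls = PLSRegression(n_components=r_best, scale=False)
    pls.fit(X, y)
    return PLSRModel(n_components=r_best, press=press, _pls=pls)


# ---------------------------------------------------------------------------
# Random forest

@dataclass
class RFConfig:
    """Random-forest hyperparameters (defaults are the tuned values:
    200 trees, depth 10, sqrt(p) features per split)."""
    n_trees: int = 200
    max_depth: int = 10
    max_features: str = "sqrt"  # "sqrt" or "third" (p/3)
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features not in ("sqrt", "third"):
            raise ValueError("max_features must be 'sqrt' or 'third'")


def fit_rf(X_cal, y_cal, cfg: RFConfig = RFConfig()) -> RandomForestRegressor:
    """Seeded random-forest regression on the calibration set."""
    X = np.asarray(X_cal, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 calibration samples")
    mf = "sqrt" if cfg.max_features == "sqrt" else 1.0 / 3.0
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees, max_depth=cfg.max_depth, max_features=mf,
        bootstrap=True, random_state=int(cfg.seed))
    rf.fit(X, np.asarray(y_cal, dtype=float))
    return rf


def feature_importance(model: RandomForestRegressor, bands=None) -> pd.DataFrame:
    """Impurity-based feature importances, sorted descending.

    Returns a DataFrame with columns ``band`` and ``importance``
    (non-negative, summing to 1).
    """
    if not hasattr(model, "estimators_"):
        raise ValueError("model is not fitted")
    imp = model.feature_importances_
    if bands is None:
        bands = list(range(imp.size))
    df = pd.DataFrame({"band": list(bands), "importance": imp})
    return df.sort_values("importance", ascending=False, kind="stable",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# BPNN

@dataclass
class BPNNConfig:
    """Backpropagation-network settings (defaults: one hidden layer of
    10 nodes, learning rate 0.01, 500 epochs, patience 5)."""
    hidden: tuple = (10,)
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: int = 5
    momentum: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class BPNNModel:
    """Trained network with the calibration standardization frozen in."""
    weights: list
    biases: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    epochs_run: int
    stop_losses: list = field(repr=False, default_factory=list)

    def _forward(self, Z):
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            Z = _sigmoid(Z @ W + b)
        return (Z @ self.weights[-1] + self.biases[-1]).ravel()

    def predict(self, X) -> np.ndarray:
        Z = (np.asarray(X, float) - self.x_mean) / self.x_sd
        return self._forward(Z) * self.y_sd + self.y_mean


def fit_bpnn(X_cal, y_cal, cfg: BPNNConfig = BPNNConfig(),
             X_stop=None, y_stop=None) -> BPNNModel:
    """Train the network by full-batch gradient descent with momentum.

    Inputs and the target are z-scored with calibration statistics.
    Training stops at ``max_epochs`` or as soon as the stop-set loss has
    failed to improve on its best value for ``patience`` consecutive
    epochs (the best-so-far weights are kept). The stop set must be
    disjoint from calibration and non-empty.
    """
    if X_stop is None or y_stop is None or len(np.atleast_1d(y_stop)) == 0:
        raise ValueError("early stopping requires a non-empty stop set")
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
    Z = (X - x_mean) / x_sd
    t = (y - y_mean) / y_sd
    Zs = (np.asarray(X_stop, float) - x_mean) / x_sd
    ts = (np.asarray(y_stop, float) - y_mean) / y_sd

    rng = np.random.default_rng(int(cfg.seed))
    sizes = [Z.shape[1], *cfg.hidden, 1]
    # small initial weights keep hidden units in their near-linear
    # regime; the output layer is warm-started by a least-squares solve
    # on the initial hidden activations
    W = [rng.normal(0.0, 0.3 / np.sqrt(sizes[i]), (sizes[i], sizes[i + 1]))
         for i in range(len(sizes) - 1)]
    b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    H0 = Z
    for i in range(len(W) - 1):
        H0 = _sigmoid(H0 @ W[i] + b[i])
    A = np.column_stack([np.ones(H0.shape[0]), H0])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    b[-1][:] = coef[0]
    W[-1][:, 0] = coef[1:]
    vW = [np.zeros_like(w) for w in W]
    vb = [np.zeros_like(x) for x in b]

    def forward(A0):
        acts = [A0]
        for i in range(len(W) - 1):
            acts.append(_sigmoid(acts[-1] @ W[i] + b[i]))
        acts.append(acts[-1] @ W[-1] + b[-1])
        return acts

    n = Z.shape[0]
    best = (np.inf, None, 0)
    stall = 0
    stop_losses = []
    epochs_run = 0
    lr = cfg.learning_rate
    prev_train = np.inf
    prev_stop = np.inf
    for epoch in range(1, cfg.max_epochs + 1):
        acts = forward(Z)
        pred = acts[-1].ravel()
        train_loss = float(np.mean((pred - t) ** 2))
        # adaptive learning rate (classic variable-rate backprop): if the
        # training loss spiked, undo the step, cut the rate, and reset
        # momentum; on improvement, grow the rate gently.
        if train_loss > 1.04 * prev_train:
            for i in range(len(W)):
                W[i] -= vW[i]
                b[i] -= vb[i]
                vW[i][:] = 0.0
                vb[i][:] = 0.0
            lr *= 0.7
            acts = forward(Z)
            pred = acts[-1].ravel()
            train_loss = float(np.mean((pred - t) ** 2))
        elif train_loss < prev_train:
            lr = min(lr * 1.05, 100.0 * cfg.learning_rate)
        prev_train = train_loss
        # backprop of 0.5*mean squared error
        delta = (pred - t)[:, None] / n
        for i in range(len(W) - 1, -1, -1):
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ W[i].T) * acts[i] * (1.0 - acts[i])
            vW[i] = cfg.momentum * vW[i] - lr * gW
            vb[i] = cfg.momentum * vb[i] - lr * gb
            W[i] += vW[i]
            b[i] += vb[i]
        # stop-set loss with updated weights
        Zp = Zs
        for i in range(len(W) - 1):
            Zp = _sigmoid(Zp @ W[i] + b[i])
        loss = float(np.mean(((Zp @ W[-1] + b[-1]).ravel() - ts) ** 2))
        stop_losses.append(loss)
        epochs_run = epoch
        if loss < best[0]:
            best = (loss, ([w.copy() for w in W], [x.copy() for x in b]), epoch)
        # the stop rule is literal: halt after `patience` consecutive
        # epochs in which the stop-set loss failed to decrease
        if loss < prev_stop - 1e-12:
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
        prev_stop = loss
    W_best, b_best = best[1] if best[1] is not None else (W, b)
    return BPNNModel(weights=W_best, biases=b_best, x_mean=x_mean, x_sd=x_sd,
                     y_mean=y_mean, y_sd=y_sd, epochs_run=epochs_run,
                     stop_losses=stop_losses)
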