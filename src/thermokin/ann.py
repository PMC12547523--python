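"""Feed-forward neural-network surrogate for TGA mass loss.

Maps (temperature, heating rate) to fractional mass loss α ∈ [0, 1] with a
small fully connected network (default: one hidden layer of 4 sigmoid-family
units). Training minimizes mean squared error with an L2 weight penalty,

    J(w) = MSE + λ·‖W‖² / n_train        (biases unpenalized),

by full-batch L-BFGS with analytic gradients; λ is selected on the validation
split from a small grid. The data are split 60/20/20 into training, test and
validation sets by seeded random row assignment, and the best-validation
iterate is retained (``best_epoch``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.preprocessing import StandardScaler

from .thermogram import ConversionCurve

__all__ = [
    "AnnSpec",
    "AnnMetrics",
    "AnnModel",
    "Dataset",
    "build_dataset",
    "split_indices",
    "train_ann",
    "predict",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda h: 1.0 - h**2),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda h: h * (1.0 - h),
    ),
}


@dataclass(frozen=True)
class AnnSpec:
    """Architecture, split fractions, regularization grid and seed."""

    hidden_layers: tuple = (4,)
    activation: str = "tanh"
    split: tuple = (0.60, 0.20, 0.20)  # train, test, validation
    max_epochs: int = 2000
    seed: int = 0
    l2_grid: tuple = (1e-4, 1e-3, 1e-2)

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")

    def n_weights(self, n_features: int = 2) -> int:
        sizes = (n_features, *self.hidden_layers, 1)
        return sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass(frozen=True)
class AnnMetrics:
    mse_train: float
    mse_val: float
    mse_test: float
    r_train: float
    r_val: float
    r_test: float
    best_epoch: int
    l2: float
    converged: bool


@dataclass
class Dataset:
    """Supervised (T, β) → mass-loss-fraction table with stored scaler."""

    X: np.ndarray  # raw features (n, 2): temperature K, beta K/min
    y: np.ndarray  # fractional mass loss in [0, 1]
    scaler: StandardScaler
    feature_names: tuple = ("temperature_K", "beta_K_per_min")

    @property
    def X_std(self) -> np.ndarray:
        return self.scaler.transform(self.X)

    def __len__(self):
        return len(self.y)


def build_dataset(curves: list[ConversionCurve], n_points: int) -> Dataset:
    """Sample each curve on an even temperature grid over the common window.

    ``n_points`` is the total row count; each curve contributes
    n_points // n_curves rows (a remainder is dropped with a warning).
    """
    if not curves:
        raise ValueError("no curves supplied")
    lo = max(c.temperature[0] for c in curves)
    hi = min(c.temperature[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves do not span a common temperature window")
    per_curve, rem = divmod(n_points, len(curves))
    if per_curve < 2:
        raise ValueError("n_points too small for the number of curves")
    if rem:
        warnings.warn(
            f"n_points={n_points} not divisible by {len(curves)} curves; "
            f"using {per_curve * len(curves)} rows"
        )
    grid = np.linspace(lo, hi, per_curve)
    rows_X, rows_y = [], []
    for c in curves:
        alpha = np.interp(grid, c.temperature, c.alpha)
        rows_X.append(np.column_stack([grid, np.full(per_curve, c.beta)]))
        rows_y.append(np.clip(alpha, 0.0, 1.0))
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    scaler = StandardScaler().fit(X)
    return Dataset(X=X, y=y, scaler=scaler)


def split_indices(n: int, split: tuple, rng: np.random.Generator):
    """Disjoint (train, test, val) index arrays with exact rounded proportions."""
    perm = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_test = int(round(split[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_test], perm[n_train + n_test :]


# ---------------------------------------------------------------- MLP internals


def _shapes(n_features: int, hidden: tuple) -> list[tuple[int, int]]:
    sizes = (n_features, *hidden, 1)
    return list(zip(sizes[:-1], sizes[1:]))


def _unflatten(theta: np.ndarray, shapes):
    layers, pos = [], 0
    for a, b in shapes:
        W = theta[pos : pos + a * b].reshape(a, b)
        pos += a * b
        bias = theta[pos : pos + b]
        pos += b
        layers.append((W, bias))
    return layers


def _flatten(layers) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in layers])


def _forward(layers, X, act):
    phi = _ACTIVATIONS[act][0]
    a = X
    for W, b in layers[:-1]:
        a = phi(a @ W + b)
    W, b = layers[-1]
    return (a @ W + b).ravel()


def _loss_grad(theta, shapes, X, y, lam, act):
    phi, dphi = _ACTIVATIONS[act]
    layers = _unflatten(theta, shapes)
    n = len(y)
    # forward, caching activations
    acts = [X]
    for W, b in layers[:-1]:
        acts.append(phi(acts[-1] @ W + b))
    W_out, b_out = layers[-1]
    pred = (acts[-1] @ W_out + b_out).ravel()
    resid = pred - y
    loss = float(resid @ resid) / n
    loss += lam / n * sum(float(np.sum(W**2)) for W, _ in layers)
    # backward
    delta = (2.0 / n) * resid[:, None]
    grads = [None] * len(layers)
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        gW = acts[li].T @ delta + (2.0 * lam / n) * W
        gb = delta.sum(axis=0)
        grads[li] = (gW, gb)
        if li > 0:
            delta = (delta @ W.T) * dphi(acts[li])
    return loss, _flatten(grads)


def _init_layers(shapes, rng):
    layers = []
    for a, b in shapes:
        bound = np.sqrt(6.0 / (a + b))
        layers.append((rng.uniform(-bound, bound, size=(a, b)), np.zeros(b)))
    return layers


@dataclass
class AnnModel:
    """Trained surrogate: weights, feature scaler and training metadata."""

    layers: list
    activation: str
    scaler: StandardScaler
    spec: AnnSpec
    l2: float
    T_range: tuple
    beta_range: tuple

    def predict(self, T, beta):
        return predict(self, T, beta)

    def _raw(self, X_std: np.ndarray) -> np.ndarray:
        return _forward(self.layers, X_std, self.activation)

    def to_json(self) -> str:
        """Flat-text serialization of weights, scaler and spec."""
        return json.dumps({
            "activation": self.activation,
            "l2": self.l2,
            "T_range": list(self.T_range),
            "beta_range": list(self.beta_range),
            "spec": {
                "hidden_layers": list(self.spec.hidden_layers),
                "activation": self.spec.activation,
                "split": list(self.spec.split),
                "max_epochs": self.spec.max_epochs,
                "seed": self.spec.seed,
                "l2_grid": list(self.spec.l2_grid),
            },
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "layers": [[W.tolist(), b.tolist()] for W, b in self.layers],
        })

    @classmethod
    def from_json(cls, text: str) -> "AnnModel":
        d = json.loads(text)
        spec = AnnSpec(
            hidden_layers=tuple(d["spec"]["hidden_layers"]),
            activation=d["spec"]["activation"],
            split=tuple(d["spec"]["split"]),
            max_epochs=d["spec"]["max_epochs"],
            seed=d["spec"]["seed"],
            l2_grid=tuple(d["spec"]["l2_grid"]),
        )
        scaler = StandardScaler()
        scaler.mean_ = np.array(d["scaler_mean"])
        scaler.scale_ = np.array(d["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = len(scaler.mean_)
        layers = [(np.array(W), np.array(b)) for W, b in d["layers"]]
        return cls(layers=layers, activation=d["activation"], scaler=scaler,
                   spec=spec, l2=d["l2"], T_range=tuple(d["T_range"]),
                   beta_range=tuple(d["beta_range"]))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train_ann(data: Dataset, spec: AnnSpec) -> tuple[AnnModel, AnnMetrics]:
    """Train the surrogate; deterministic under a fixed spec seed.

    For each λ on the grid the network is trained from the same seeded
    initialization; the λ (and iterate) with the lowest validation MSE wins.
    If the optimizer hits ``max_epochs`` without converging, the best-so-far
    weights are returned with ``converged=False``.
    """
    n = len(data)
    if n < 10 * spec.n_weights(data.X.shape[1]):
        warnings.warn(
            f"{n} rows for {spec.n_weights(data.X.shape[1])} weights: "
            "fewer than 10 rows per weight, the fit may be underdetermined"
        )
    rng = np.random.default_rng(spec.seed)
    itr, ite, iva = split_indices(n, spec.split, rng)
    Xs = data.X_std
    Xtr, ytr = Xs[itr], data.y[itr]
    Xva, yva = Xs[iva], data.y[iva]
    Xte, yte = Xs[ite], data.y[ite]
    shapes = _shapes(data.X.shape[1], spec.hidden_layers)
    theta0 = _flatten(_init_layers(shapes, rng))

    best = None  # (val_mse, theta, epoch, lam, converged)
    for lam in spec.l2_grid:
        tracker = {"epoch": 0, "best_val": np.inf, "best_theta": theta0.copy(),
                   "best_epoch": 0}

        def callback(theta, tracker=tracker, lam=lam):
            tracker["epoch"] += 1
            pred = _forward(_unflatten(theta, shapes), Xva, spec.activation)
            val = float(np.mean((pred - yva) ** 2))
            if val < tracker["best_val"]:
                tracker["best_val"] = val
                tracker["best_theta"] = theta.copy()
                tracker["best_epoch"] = tracker["epoch"]

        res = minimize(
            _loss_grad, theta0, args=(shapes, Xtr, ytr, lam, spec.activation),
            jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": spec.max_epochs, "ftol": 1e-14, "gtol": 1e-12},
        )
        callback(res.x)  # include the final iterate
        cand = (tracker["best_val"], tracker["best_theta"], tracker["best_epoch"],
                lam, bool(res.success))
        if best is None or cand[0] < best[0]:
            best = cand

    val_mse, theta, best_epoch, lam, converged = best
    layers = _unflatten(theta, shapes)
    model = AnnModel(
        layers=layers, activation=spec.activation, scaler=data.scaler, spec=spec,
        l2=lam, T_range=(float(data.X[:, 0].min()), float(data.X[:, 0].max())),
        beta_range=(float(data.X[:, 1].min()), float(data.X[:, 1].max())),
    )
    preds = {k: _forward(layers, X, spec.activation)
             for k, X in (("train", Xtr), ("val", Xva), ("test", Xte))}
    metrics = AnnMetrics(
        mse_train=float(np.mean((preds["train"] - ytr) ** 2)),
        mse_val=val_mse,
        mse_test=float(np.mean((preds["test"] - yte) ** 2)),
        r_train=_pearson(preds["train"], ytr),
        r_val=_pearson(preds["val"], yva),
        r_test=_pearson(preds["test"], yte),
        best_epoch=best_epoch,
        l2=lam,
        converged=converged,
    )
    return model, metrics


def predict(model: AnnModel, T, beta):
    """Predict mass-loss fraction, clamped to [0, 1].

    Warns when the query temperature lies outside the training range
    (extrapolation). Monotonicity in T is not enforced.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), T.shape)
    lo, hi = model.T_range
    if np.any((T < lo) | (T > hi)):
        warnings.warn(
            f"query temperature outside the training range [{lo:.1f}, {hi:.1f}] K; "
            "extrapolating"
        )
    X = np.column_stack([T, beta])
    out = np.clip(model._raw(model.scaler.transform(X)), 0.0, 1.0)
    return float(out[0]) if out.size == 1 else out
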