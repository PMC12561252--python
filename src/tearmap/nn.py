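"""Wear-time -> regional-map regression: a small MLP trained by Levenberg-Marquardt.

The model maps a single input (lens wear duration in days) to 121
regional tear-quality outputs.  Inputs and outputs are min-max scaled to
[-1, 1] (fitted over the whole supplied dataset, the MATLAB ``mapminmax``
convention); hidden layers use tanh, the output layer is linear.

Training is damped Gauss-Newton on the full batch:

    dw = -(J'J + mu I)^-1 J' e

with ``e`` the scaled-space residual vector over the training partition
and ``J`` its analytic Jacobian with respect to all weights and biases.
``mu`` is multiplied by 10 after a rejected step (cost not reduced) and
divided by 10 after an accepted one.  When the parameter count exceeds
the residual count the update is computed in residual space,
``dw = -J'(JJ' + mu I)^-1 e``, which is algebraically identical but
avoids forming a huge normal matrix.  Early stopping keeps the weights
of the best-validation epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .core import PolarGrid, TearFilmMap
from .mapping import PivotLayout
from .stats import spearman_r

__all__ = [
    "MinMaxScaler",
    "MLPModel",
    "TrainOptions",
    "TrainRecord",
    "SplitIndices",
    "GridSearchResult",
    "fit_scaler",
    "split_data",
    "init_model",
    "forward",
    "train_lm",
    "grid_search",
    "predict_map",
    "evaluate",
]


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinMaxScaler:
    """Per-variable affine map [min, max] -> [-1, 1]; constant variables map to 0."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def span(self) -> np.ndarray:
        return self.maxs - self.mins

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        span = np.where(self.span == 0, 1.0, self.span)
        out = 2.0 * (x - self.mins) / span - 1.0
        return np.where(self.span == 0, 0.0, out)

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return np.where(
            self.span == 0, self.mins, (y + 1.0) * self.span / 2.0 + self.mins
        )


def fit_scaler(samples) -> MinMaxScaler:
    """Fit per-column min/max; ``samples`` is (n,) or (n, d)."""
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] == 1 and np.asarray(samples).ndim == 1:
        x = x.T
    if x.shape[0] < 1:
        raise ValueError("need at least one sample")
    return MinMaxScaler(mins=x.min(axis=0), maxs=x.max(axis=0))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        parts = [set(self.train.tolist()), set(self.val.tolist()), set(self.test.tolist())]
        n = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != n:
            raise ValueError("split partitions must be disjoint")

    @property
    def n(self) -> int:
        return self.train.size + self.val.size + self.test.size


def split_data(n_samples: int, fractions=(0.70, 0.15, 0.15), rng=None) -> SplitIndices:
    """Seeded shuffle, then contiguous train/val/test assignment.

    Validation and test sizes are ``round(f * n)``; the training part
    takes the remainder (so n = 92 gives 64/14/14).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(round(fractions[1] * n_samples))
    n_test = int(round(fractions[2] * n_samples))
    n_train = n_samples - n_val - n_test
    if n_samples < 7 or min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n_samples} too small for a {fractions} split")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n_samples)
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train:n_train + n_val]),
        test=np.sort(perm[n_train + n_val:]),
    )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class MLPModel:
    """Feedforward regressor: tanh hidden layers, linear output, [-1,1] scaling."""

    layer_sizes: tuple
    weights: list        # weights[l]: (n_out, n_in)
    biases: list         # biases[l]: (n_out,)
    input_scaler: MinMaxScaler | None = None
    output_scaler: MinMaxScaler | None = None
    seed: int = 0

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    def unpack(self, vector: np.ndarray) -> None:
        pos = 0
        for l, (n_in, n_out) in enumerate(zip(self.layer_sizes[:-1], self.layer_sizes[1:])):
            self.weights[l] = vector[pos:pos + n_in * n_out].reshape(n_out, n_in)
            pos += n_in * n_out
            self.biases[l] = vector[pos:pos + n_out].copy()
            pos += n_out

    def copy(self) -> "MLPModel":
        return MLPModel(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            input_scaler=self.input_scaler,
            output_scaler=self.output_scaler,
            seed=self.seed,
        )

    def to_json_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "input_scaler": None if self.input_scaler is None else
                {"mins": self.input_scaler.mins.tolist(),
                 "maxs": self.input_scaler.maxs.tolist()},
            "output_scaler": None if self.output_scaler is None else
                {"mins": self.output_scaler.mins.tolist(),
                 "maxs": self.output_scaler.maxs.tolist()},
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MLPModel":
        mk = lambda s: None if s is None else MinMaxScaler(
            mins=np.asarray(s["mins"], dtype=float),
            maxs=np.asarray(s["maxs"], dtype=float))
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            input_scaler=mk(d["input_scaler"]),
            output_scaler=mk(d["output_scaler"]),
            seed=int(d["seed"]),
        )


def init_model(layer_sizes, seed: int = 0) -> MLPModel:
    """Seeded uniform init, scale 1/sqrt(fan_in) per layer."""
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if any(s < 1 for s in layer_sizes) or len(layer_sizes) < 2:
        raise ValueError(f"invalid layer sizes {layer_sizes}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        a = 1.0 / math.sqrt(n_in)
        weights.append(rng.uniform(-a, a, size=(n_out, n_in)))
        biases.append(rng.uniform(-a, a, size=n_out))
    return MLPModel(layer_sizes=layer_sizes, weights=weights, biases=biases, seed=seed)


def _forward_scaled(model: MLPModel, xs: np.ndarray,
                    keep_activations: bool = False):
    """Forward pass in scaled space; xs is (n, n_in)."""
    a = xs
    activations = [a]
    n_layers = len(model.weights)
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w.T + b
        a = z if l == n_layers - 1 else np.tanh(z)
        activations.append(a)
    return (a, activations) if keep_activations else a


def forward(model: MLPModel, wear_days) -> np.ndarray:
    """Predict pivot vectors in original tear-quality units; returns (n, n_out)."""
    x = np.asarray(wear_days, dtype=float).reshape(-1, 1)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    xs = model.input_scaler.apply(x) if model.input_scaler is not None else x
    ys = _forward_scaled(model, xs)
    return model.output_scaler.invert(ys) if model.output_scaler is not None else ys


def _jacobian_scaled(model: MLPModel, xs: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobian of scaled outputs w.r.t. the packed parameter vector.

    Returns (ys, J) with ys (n, K) and J ((n*K), P), rows ordered
    sample-major then output, columns in ``pack`` order.
    """
    ys, acts = _forward_scaled(model, xs, keep_activations=True)
    n = xs.shape[0]
    K = model.layer_sizes[-1]
    L = len(model.weights)
    # G[l]: d y_k / d z_l, shape (n, K, units_l)
    G = np.broadcast_to(np.eye(K), (n, K, K)).copy()
    blocks: list[np.ndarray] = []
    for l in range(L - 1, -1, -1):
        a_prev = acts[l]                      # (n, units_{l-1})
        w_block = np.einsum("nko,ni->nkoi", G, a_prev).reshape(n * K, -1)
        b_block = G.reshape(n * K, -1)
        blocks.append(np.concatenate([w_block, b_block], axis=1))
        if l > 0:
            G = np.einsum("nko,oi->nki", G, model.weights[l])
            G = G * (1.0 - acts[l] ** 2)[:, None, :]
    blocks.reverse()
    return ys, np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training
# ---------------------------------------------------------------------------

@dataclass
class TrainOptions:
    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_factor: float = 10.0
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    patience: int = 6


@dataclass
class TrainRecord:
    epochs: int
    stop_reason: str
    train_rmse: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    test_rmse: list = field(default_factory=list)
    mu_trajectory: list = field(default_factory=list)
    cost_trajectory: list = field(default_factory=list)
    best_epoch: int = -1


def _solve_lm_step(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    m, p = J.shape
    if p <= m:
        A = J.T @ J
        A[np.diag_indices_from(A)] += mu
        rhs = J.T @ e
        c = cho_factor(A, lower=True, check_finite=False)
        return -cho_solve(c, rhs, check_finite=False)
    B = J @ J.T
    B[np.diag_indices_from(B)] += mu
    c = cho_factor(B, lower=True, check_finite=False)
    return -(J.T @ cho_solve(c, e, check_finite=False))


def _rmse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def train_lm(model: MLPModel, X, Y, split: SplitIndices,
             opts: TrainOptions | None = None) -> tuple[MLPModel, TrainRecord]:
    """Full-batch Levenberg-Marquardt fit with validation-based early stopping.

    Scalers are fitted on the whole (X, Y) and attached to the model.
    RMSE trajectories are recorded in original (inverse-scaled) units;
    the returned model carries the weights of the best-validation epoch.
    """
    opts = opts or TrainOptions()
    X = np.asarray(X, dtype=float).reshape(-1, 1)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if split.train.size == 0:
        raise ValueError("empty training partition")
    if not np.all(np.isfinite(Y)):
        raise ValueError("targets must be complete; drop or impute upstream")

    model = model.copy()
    model.input_scaler = fit_scaler(X)
    model.output_scaler = fit_scaler(Y)
    xs = model.input_scaler.apply(X)
    ys_t = model.output_scaler.apply(Y)

    def partition_rmse(idx):
        if idx.size == 0:
            return float("nan")
        return _rmse(forward(model, X[idx, 0]), Y[idx])

    record = TrainRecord(epochs=0, stop_reason="max_epochs")
    mu = opts.mu0
    xt, yt = xs[split.train], ys_t[split.train]
    ys_pred = _forward_scaled(model, xt)
    cost = float(np.mean((ys_pred - yt) ** 2))
    best_val = np.inf
    best_w = model.pack()
    best_epoch = -1
    since_best = 0
    w = model.pack()

    for epoch in range(opts.max_epochs):
        ys_pred, J = _jacobian_scaled(model, xt)
        e = (ys_pred - yt).ravel()
        grad = J.T @ e
        if np.max(np.abs(grad)) < opts.grad_tol:
            record.stop_reason = "grad_tol"
            break
        accepted = False
        while True:
            try:
                step = _solve_lm_step(J, e, mu)
            except LinAlgError:
                step = None
            if step is not None:
                w_new = w + step
                model.unpack(w_new)
                cost_new = float(np.mean((_forward_scaled(model, xt) - yt) ** 2))
                if np.isfinite(cost_new) and cost_new < cost:
                    w, cost = w_new, cost_new
                    mu = max(mu / opts.mu_factor, 1e-20)
                    accepted = True
                    break
            mu *= opts.mu_factor
            if mu > opts.mu_max:
                break
        if not accepted:
            model.unpack(w)
            if mu > opts.mu_max:
                record.stop_reason = "mu_overflow"
            else:
                raise LinAlgError("LM normal equations singular after mu escalation")
            break

        record.epochs = epoch + 1
        record.mu_trajectory.append(mu)
        record.cost_trajectory.append(cost)
        record.train_rmse.append(partition_rmse(split.train))
        record.val_rmse.append(partition_rmse(split.val))
        record.test_rmse.append(partition_rmse(split.test))

        if split.val.size:
            val = record.val_rmse[-1]
            if val < best_val - 1e-15:
                best_val, best_w, best_epoch = val, w.copy(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= opts.patience:
                    record.stop_reason = "val_patience"
                    break
        else:
            best_w, best_epoch = w.copy(), epoch

    model.unpack(best_w)
    record.best_epoch = best_epoch
    return model, record


# ---------------------------------------------------------------------------
# architecture grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    records: list                 # dicts: depth, width, n_params, val_rmse, seed
    selected: dict

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def grid_search(X, Y, split: SplitIndices, depths=range(1, 11),
                widths=(8, 16, 32, 64), seed: int = 0,
                opts: TrainOptions | None = None) -> GridSearchResult:
    """Evaluate every (depth, uniform width) architecture on one shared split.

    Selection is the validation-RMSE argmin; ties prefer fewer
    parameters, then lower depth.
    """
    X = np.asarray(X, dtype=float).reshape(-1)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_out = Y.shape[1]
    records = []
    for i, depth in enumerate(depths):
        for j, width in enumerate(widths):
            sizes = (1,) + (int(width),) * int(depth) + (n_out,)
            cfg_seed = int((seed * 100003 + i * 101 + j) % (2**31))
            model = init_model(sizes, seed=cfg_seed)
            trained, rec = train_lm(model, X, Y, split, opts)
            val = rec.val_rmse[rec.best_epoch] if rec.best_epoch >= 0 else float("inf")
            records.append({
                "depth": int(depth), "width": int(width),
                "n_params": trained.n_params, "val_rmse": float(val),
                "seed": cfg_seed,
            })
    selected = min(records,
                   key=lambda r: (r["val_rmse"], r["n_params"], r["depth"]))
    return GridSearchResult(records=records, selected=selected)


# ---------------------------------------------------------------------------
# dense-map prediction and evaluation
# ---------------------------------------------------------------------------

def predict_map(model: MLPModel, wear_days: float, layout: PivotLayout,
                grid: PolarGrid) -> TearFilmMap:
    """Forward pass at one wear time, thin-plate-spline scattered to a dense grid.

    Cells beyond the layout's outermost ring are masked (no extrapolation).
    """
    if model.layer_sizes[-1] != layout.n_points:
        raise ValueError("model output dimension must equal layout size")
    pivots = forward(model, [float(wear_days)])[0]
    px, py = layout.cartesian()
    interp = RBFInterpolator(np.column_stack([px, py]), pivots,
                             kernel="thin_plate_spline")
    gx, gy = grid.cartesian_mesh()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = interp(pts).reshape(grid.shape)
    r, _ = grid.mesh()
    vals = np.where(r <= layout.max_radius * (1 + 1e-9),
                    np.maximum(vals, 0.0), np.nan)
    return TearFilmMap(grid=grid, values=vals, modality="tear_quality",
                       session="post")


def evaluate(model: MLPModel, X, Y, split: SplitIndices) -> dict:
    """Per-partition pooled Spearman R and RMSE in original units."""
    X = np.asarray(X, dtype=float).reshape(-1)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    out = {}
    for name, idx in (("train", split.train), ("val", split.val),
                      ("test", split.test)):
        if idx.size == 0:
            raise ValueError(f"empty partition {name}")
        pred = forward(model, X[idx])
        obs = Y[idx]
        out[name] = {
            "spearman_r": spearman_r(pred.ravel(), obs.ravel()),
            "rmse": _rmse(pred, obs),
            "n_samples": int(idx.size),
        }
    return out
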