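"""Multilayer-perceptron surrogate trained by online backpropagation.

The surrogate is deliberately small and faithful to a classical training
recipe: sigmoid hidden units (default one hidden layer of two nodes), an
unthresholded linear output, inputs (and by default the target) min-max
scaled to the unit interval on the training set, stochastic per-row
gradient-descent updates with momentum

    dw(t) = -lr * dE/dw + momentum * dw(t-1),   E = (error)^2 / 2,

a fixed number of epochs with per-epoch reshuffling, and no early
stopping.  Because each trained network is a seed-dependent local optimum,
an ensemble of seeds is trained and the network with the lowest training
RMSE is kept.

The per-row update loop is compiled with numba; `loss_and_gradients`
provides an independent pure-numpy forward/backward pass used for
gradient verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .core import InvalidInputError

def _maybe_file(source) -> str:
    s = str(source)
    if "\n" not in s and len(s) < 4000:
        try:
            p = Path(s)
            if p.exists():
                return p.read_text()
        except OSError:
            pass
    return s


__all__ = [
    "MLPHyperparams",
    "ScalingParams",
    "MLPModel",
    "SeedEnsembleResult",
    "fit_scaling",
    "apply_scaling",
    "invert_target",
    "loss_and_gradients",
    "train_mlp",
    "predict",
    "train_seed_ensemble",
]


@dataclass(frozen=True)
class MLPHyperparams:
    hidden_layout: tuple[int, ...] = (2,)
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 1000
    n_seeds: int = 100
    scale_target: bool = True
    online: bool = True  # per-row updates; False = full-batch gradient steps

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise InvalidInputError("momentum must lie in [0, 1)")
        if self.epochs < 1 or self.n_seeds < 1:
            raise InvalidInputError("epochs and n_seeds must be at least 1")
        if len(self.hidden_layout) not in (1, 2) or any(
            h < 1 for h in self.hidden_layout
        ):
            raise InvalidInputError("hidden_layout must be one or two positive ints")


@dataclass(frozen=True)
class ScalingParams:
    """Training-set min-max scaling; constant columns map to 0.5."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float | None = None  # None: target left unscaled
    y_max: float | None = None


def fit_scaling(X: np.ndarray, y: np.ndarray, scale_target: bool = True) -> ScalingParams:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) == 0:
        raise InvalidInputError("empty training set")
    if scale_target:
        return ScalingParams(X.min(axis=0), X.max(axis=0), float(y.min()), float(y.max()))
    return ScalingParams(X.min(axis=0), X.max(axis=0))


def apply_scaling(X: np.ndarray, sp: ScalingParams) -> np.ndarray:
    """Map each input by (x - min)/(max - min); NOT clipped outside [0,1]."""
    X = np.asarray(X, float)
    rng = sp.x_max - sp.x_min
    out = np.empty_like(X, dtype=float)
    const = rng == 0
    out[:, const] = 0.5
    out[:, ~const] = (X[:, ~const] - sp.x_min[~const]) / rng[~const]
    return out


def scale_target(y: np.ndarray, sp: ScalingParams) -> np.ndarray:
    if sp.y_min is None:
        return np.asarray(y, float)
    rng = sp.y_max - sp.y_min
    if rng == 0:
        return np.full_like(np.asarray(y, float), 0.5)
    return (np.asarray(y, float) - sp.y_min) / rng


def invert_target(y_scaled: np.ndarray, sp: ScalingParams) -> np.ndarray:
    if sp.y_min is None:
        return np.asarray(y_scaled, float)
    rng = sp.y_max - sp.y_min
    if rng == 0:
        return np.full_like(np.asarray(y_scaled, float), sp.y_min)
    return np.asarray(y_scaled, float) * rng + sp.y_min


# ---------------------------------------------------------------------------
# network forward / backward (reference implementation)
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def forward(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass on scaled inputs; returns scaled outputs."""
    a = np.asarray(X, float)
    L = len(weights)
    for layer in range(L - 1):
        a = _sigmoid(a @ weights[layer].T + biases[layer])
    return (a @ weights[-1].T + biases[-1])[:, 0]


def loss_and_gradients(
    weights: Sequence[np.ndarray],
    biases: Sequence[np.ndarray],
    x: np.ndarray,
    y: float,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Single-sample loss E = err^2/2 and analytic gradients.

    Pure-numpy backward pass, independent of the compiled training kernel;
    used to verify the kernel's gradient arithmetic against finite
    differences.
    """
    acts = [np.asarray(x, float)]
    L = len(weights)
    for layer in range(L - 1):
        acts.append(_sigmoid(weights[layer] @ acts[-1] + biases[layer]))
    out = float((weights[-1] @ acts[-1] + biases[-1])[0])
    err = out - y
    loss = 0.5 * err * err
    gw: list[np.ndarray] = [np.zeros_like(w) for w in weights]
    gb: list[np.ndarray] = [np.zeros_like(b) for b in biases]
    delta = np.array([err])
    gw[-1] = np.outer(delta, acts[-1])
    gb[-1] = delta.copy()
    for layer in range(L - 2, -1, -1):
        a = acts[layer + 1]
        delta = (weights[layer + 1].T @ delta) * a * (1 - a)
        gw[layer] = np.outer(delta, acts[layer])
        gb[layer] = delta.copy()
    return loss, gw, gb


# ---------------------------------------------------------------------------
# compiled online-training kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _train_kernel_1h(X, y, perms, W1, b1, W2, b2, lr, mom):  # pragma: no cover
    n, d = X.shape
    h = W1.shape[0]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    a1 = np.empty(h)
    epochs = perms.shape[0]
    for e in range(epochs):
        for ii in range(n):
            i = perms[e, ii]
            # forward
            for j in range(h):
                s = b1[j]
                for c in range(d):
                    s += W1[j, c] * X[i, c]
                a1[j] = 1.0 / (1.0 + np.exp(-s))
            out = b2[0]
            for j in range(h):
                out += W2[0, j] * a1[j]
            err = out - y[i]
            # backward + momentum update
            vb2[0] = -lr * err + mom * vb2[0]
            b2[0] += vb2[0]
            for j in range(h):
                g = err * a1[j]
                vW2[0, j] = -lr * g + mom * vW2[0, j]
                delta = err * W2[0, j] * a1[j] * (1.0 - a1[j])
                # note: delta uses the pre-update W2, as in joint gradient
                W2[0, j] += vW2[0, j]
                vb1[j] = -lr * delta + mom * vb1[j]
                b1[j] += vb1[j]
                for c in range(d):
                    vW1[j, c] = -lr * delta * X[i, c] + mom * vW1[j, c]
                    W1[j, c] += vW1[j, c]


@njit(cache=True)
def _train_kernel_2h(X, y, perms, W1, b1, W2, b2, W3, b3, lr, mom):  # pragma: no cover
    n, d = X.shape
    h1 = W1.shape[0]
    h2 = W2.shape[0]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    vW3 = np.zeros_like(W3)
    vb3 = np.zeros_like(b3)
    a1 = np.empty(h1)
    a2 = np.empty(h2)
    d2 = np.empty(h2)
    d1 = np.empty(h1)
    epochs = perms.shape[0]
    for e in range(epochs):
        for ii in range(n):
            i = perms[e, ii]
            for j in range(h1):
                s = b1[j]
                for c in range(d):
                    s += W1[j, c] * X[i, c]
                a1[j] = 1.0 / (1.0 + np.exp(-s))
            for j in range(h2):
                s = b2[j]
                for c in range(h1):
                    s += W2[j, c] * a1[c]
                a2[j] = 1.0 / (1.0 + np.exp(-s))
            out = b3[0]
            for j in range(h2):
                out += W3[0, j] * a2[j]
            err = out - y[i]
            for j in range(h2):
                d2[j] = err * W3[0, j] * a2[j] * (1.0 - a2[j])
            for j in range(h1):
                s = 0.0
                for c in range(h2):
                    s += W2[c, j] * d2[c]
                d1[j] = s * a1[j] * (1.0 - a1[j])
            vb3[0] = -lr * err + mom * vb3[0]
            b3[0] += vb3[0]
            for j in range(h2):
                g = err * a2[j]
                vW3[0, j] = -lr * g + mom * vW3[0, j]
                W3[0, j] += vW3[0, j]
                vb2[j] = -lr * d2[j] + mom * vb2[j]
                b2[j] += vb2[j]
                for c in range(h1):
                    vW2[j, c] = -lr * d2[j] * a1[c] + mom * vW2[j, c]
                    W2[j, c] += vW2[j, c]
            for j in range(h1):
                vb1[j] = -lr * d1[j] + mom * vb1[j]
                b1[j] += vb1[j]
                for c in range(d):
                    vW1[j, c] = -lr * d1[j] * X[i, c] + mom * vW1[j, c]
                    W1[j, c] += vW1[j, c]


def _train_numpy(X, y, perms, weights, biases, lr, mom):
    """Reference per-row training loop (same arithmetic as the kernels)."""
    vels_w = [np.zeros_like(w) for w in weights]
    vels_b = [np.zeros_like(b) for b in biases]
    for e in range(perms.shape[0]):
        for i in perms[e]:
            _, gw, gb = loss_and_gradients(weights, biases, X[i], y[i])
            for layer in range(len(weights)):
                vels_w[layer] = -lr * gw[layer] + mom * vels_w[layer]
                vels_b[layer] = -lr * gb[layer] + mom * vels_b[layer]
                weights[layer] += vels_w[layer]
                biases[layer] += vels_b[layer]


# ---------------------------------------------------------------------------
# model container and training entry points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLPModel:
    feature_names: tuple[str, ...]
    hidden_layout: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    scaling: ScalingParams
    seed: int
    train_rmse: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "hidden_layout": list(self.hidden_layout),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaling": {
                "x_min": self.scaling.x_min.tolist(),
                "x_max": self.scaling.x_max.tolist(),
                "y_min": self.scaling.y_min,
                "y_max": self.scaling.y_max,
            },
            "seed": self.seed,
            "train_rmse": self.train_rmse,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "MLPModel":
        d = json.loads(_maybe_file(source))
        sc = d["scaling"]
        return MLPModel(
            tuple(d["feature_names"]),
            tuple(d["hidden_layout"]),
            tuple(np.array(w) for w in d["weights"]),
            tuple(np.array(b) for b in d["biases"]),
            ScalingParams(
                np.array(sc["x_min"]), np.array(sc["x_max"]), sc["y_min"], sc["y_max"]
            ),
            d["seed"],
            d["train_rmse"],
        )


def _init_network(
    layout: Sequence[int], d: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    sizes = [d, *layout, 1]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(b, a)))
        biases.append(rng.uniform(-0.5, 0.5, size=b))
    return weights, biases


def train_mlp(
    X_scaled: np.ndarray,
    y_scaled: np.ndarray,
    hp: MLPHyperparams,
    seed: int,
    use_kernel: bool = True,
) -> tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...]]:
    """Train one network on pre-scaled data; returns (weights, biases).

    Weights start uniform(-0.5, 0.5) drawn from ``seed``; each epoch
    reshuffles the row order from the same seed stream; exactly
    ``hp.epochs`` epochs are run.  Deterministic given ``seed``.
    """
    X = np.ascontiguousarray(X_scaled, dtype=float)
    y = np.ascontiguousarray(y_scaled, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise InvalidInputError("need at least 2 training rows")
    rng = np.random.default_rng(seed)
    weights, biases = _init_network(hp.hidden_layout, X.shape[1], rng)
    if hp.online:
        perms = np.argsort(rng.random((hp.epochs, len(X))), axis=1).astype(np.int64)
    else:
        # batch mode: identity 'order', gradients accumulated per epoch
        perms = np.tile(np.arange(len(X), dtype=np.int64), (hp.epochs, 1))
    if not hp.online:
        _train_batch(X, y, hp, weights, biases)
    elif use_kernel and len(hp.hidden_layout) == 1:
        _train_kernel_1h(
            X, y, perms, weights[0], biases[0], weights[1], biases[1],
            hp.learning_rate, hp.momentum,
        )
    elif use_kernel and len(hp.hidden_layout) == 2:
        _train_kernel_2h(
            X, y, perms, weights[0], biases[0], weights[1], biases[1],
            weights[2], biases[2], hp.learning_rate, hp.momentum,
        )
    else:
        _train_numpy(X, y, perms, weights, biases, hp.learning_rate, hp.momentum)
    for w in weights + biases:
        if not np.all(np.isfinite(w)):
            raise InvalidInputError("training diverged to non-finite weights")
    return tuple(weights), tuple(biases)


def _train_batch(X, y, hp, weights, biases):
    vels_w = [np.zeros_like(w) for w in weights]
    vels_b = [np.zeros_like(b) for b in biases]
    for _ in range(hp.epochs):
        gw_sum = [np.zeros_like(w) for w in weights]
        gb_sum = [np.zeros_like(b) for b in biases]
        for i in range(len(X)):
            _, gw, gb = loss_and_gradients(weights, biases, X[i], y[i])
            for layer in range(len(weights)):
                gw_sum[layer] += gw[layer]
                gb_sum[layer] += gb[layer]
        for layer in range(len(weights)):
            vels_w[layer] = -hp.learning_rate * gw_sum[layer] + hp.momentum * vels_w[layer]
            vels_b[layer] = -hp.learning_rate * gb_sum[layer] + hp.momentum * vels_b[layer]
            weights[layer] += vels_w[layer]
            biases[layer] += vels_b[layer]


def _fit_one(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    feature_names: Sequence[str],
    hp: MLPHyperparams,
    seed: int,
    sp: ScalingParams,
) -> MLPModel:
    Xs = apply_scaling(X_raw, sp)
    ys = scale_target(y_raw, sp)
    weights, biases = train_mlp(Xs, ys, hp, seed)
    preds = invert_target(forward(weights, biases, Xs), sp)
    rmse = float(np.sqrt(np.mean((preds - y_raw) ** 2)))
    return MLPModel(
        tuple(feature_names), hp.hidden_layout, weights, biases, sp, seed, rmse
    )


def predict(model: MLPModel, X_raw: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Forward pass on raw inputs (scaled internally, output inverse-scaled).

    When ``feature_names`` is given, columns are re-ordered by name to the
    training order; missing features raise by name.
    """
    X = np.asarray(X_raw, float)
    if feature_names is not None:
        names = list(feature_names)
        try:
            idx = [names.index(n) for n in model.feature_names]
        except ValueError:
            missing = [n for n in model.feature_names if n not in names]
            raise InvalidInputError(f"missing feature column(s): {missing}") from None
        X = X[:, idx]
    if X.shape[1] != len(model.feature_names):
        raise InvalidInputError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    Xs = apply_scaling(X, model.scaling)
    return invert_target(forward(model.weights, model.biases, Xs), model.scaling)


@dataclass(frozen=True)
class SeedEnsembleResult:
    best_model: MLPModel
    per_seed_rmse: tuple[tuple[int, float], ...]


def train_seed_ensemble(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    feature_names: Sequence[str],
    hp: MLPHyperparams,
    seed_offset: int = 0,
) -> SeedEnsembleResult:
    """Train ``hp.n_seeds`` networks (seeds offset..offset+n-1) and keep the
    one with the lowest training RMSE; ties break toward the lowest seed."""
    sp = fit_scaling(X_raw, y_raw, hp.scale_target)
    best: MLPModel | None = None
    rmses: list[tuple[int, float]] = []
    for s in range(seed_offset, seed_offset + hp.n_seeds):
        try:
            m = _fit_one(X_raw, y_raw, feature_names, hp, s, sp)
        except InvalidInputError as exc:
            raise InvalidInputError(f"seed {s}: {exc}") from exc
        rmses.append((s, m.train_rmse))
        if best is None or m.train_rmse < best.train_rmse:
            best = m
    return SeedEnsembleResult(best, tuple(rmses))
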