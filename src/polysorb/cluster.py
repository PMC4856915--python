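"""Gaussian-mixture (EM) discretization of the target into ordered classes.

A K-component Gaussian mixture is fitted to the property values —
univariate for equilibrium water uptake, bivariate (time, WU) for the
all-points target — and its components, ordered by mean water uptake,
define the low/medium/high classes used by the tree-based descriptor
ranking and by the class-accuracy metric.

EM is restart-sensitive on small samples, so the fit runs a configurable
number of k-means++-seeded restarts and keeps the best log-likelihood.
Variances are floored at a small fraction of the data variance to keep the
likelihood bounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .core import InvalidInputError

__all__ = ["EMSettings", "ClusterModel", "fit_em", "assign_class"]

_CLASS_NAMES_3 = ("low", "medium", "high")


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


@dataclass(frozen=True)
class EMSettings:
    n_restarts: int = 25
    tol: float = 1e-8
    max_iter: int = 500
    variance_floor_frac: float = 1e-6
    standardize_bivariate: bool = True
    # univariate only: also start EM from contiguous partitions of the
    # sorted data.  The global optimum frequently is a spiky small-weight
    # component that k-means++ seeding practically never proposes; the
    # partition family contains it by construction.
    partition_inits: bool = True
    max_partition_inits: int = 400


@dataclass(frozen=True)
class ClusterModel:
    """Fitted K-component Gaussian mixture with ordered class labels.

    ``means``/``covariances`` are stored in component order; ``class_order``
    is the permutation sorting components by ascending mean water uptake
    (the last coordinate for bivariate fits).  ``scale_mean``/``scale_sd``
    record the per-coordinate standardization applied before fitting (all
    zeros/ones when none was applied).
    """

    K: int
    weights: np.ndarray
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    class_order: tuple[int, ...]
    loglik: float
    n_restarts_used: int
    n_degenerate_restarts: int = 0
    scale_mean: np.ndarray = field(default_factory=lambda: np.zeros(1))
    scale_sd: np.ndarray = field(default_factory=lambda: np.ones(1))
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise InvalidInputError("mixture weights must be non-negative and sum to 1")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def class_names(self) -> tuple[str, ...]:
        if self.K == 3:
            return _CLASS_NAMES_3
        return tuple(f"class_{i}" for i in range(self.K))

    # -- posteriors and labels -------------------------------------------

    def _standardize(self, points: np.ndarray) -> np.ndarray:
        return (points - self.scale_mean) / self.scale_sd

    def log_responsibilities(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.shape[1] != self.dim:
            raise InvalidInputError(
                f"point dimension {pts.shape[1]} does not match model dim {self.dim}"
            )
        z = self._standardize(pts)
        logp = _log_gauss_mixture_components(z, self.weights, self.means, self.covariances)
        return logp  # (n, K), unnormalized log w_k N_k

    def posterior(self, point) -> np.ndarray:
        logp = self.log_responsibilities(np.atleast_2d(point))[0]
        logp = logp - logp.max()
        p = np.exp(logp)
        return p / p.sum()

    def boundaries(self) -> tuple[float, ...]:
        """Posterior-equality crossings between adjacent (mean-ordered)
        components, on the original univariate scale."""
        if self.dim != 1:
            raise InvalidInputError("boundaries are defined for univariate models only")
        order = list(self.class_order)
        cuts = []
        for a, b in zip(order[:-1], order[1:]):
            mu_a = float(self.means[a, 0])
            mu_b = float(self.means[b, 0])

            def f(x: float, a=a, b=b) -> float:
                lp = self.log_responsibilities([[x]])[0]
                return lp[a] - lp[b]

            lo, hi = mu_a, mu_b
            if lo == hi or f(lo) * f(hi) > 0:
                cut = 0.5 * (lo + hi)
            else:
                cut = brentq(f, lo, hi, xtol=1e-10)
            cuts.append(cut * float(self.scale_sd[-1]) + float(self.scale_mean[-1]))
        return tuple(cuts)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "class_order": list(self.class_order),
            "loglik": self.loglik,
            "n_restarts_used": self.n_restarts_used,
            "n_degenerate_restarts": self.n_degenerate_restarts,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "boundaries": list(self.boundaries()) if self.dim == 1 else None,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "ClusterModel":
        d = json.loads(_maybe_file(source))
        return ClusterModel(
            K=d["K"],
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            class_order=tuple(d["class_order"]),
            loglik=d["loglik"],
            n_restarts_used=d["n_restarts_used"],
            n_degenerate_restarts=d.get("n_degenerate_restarts", 0),
            scale_mean=np.array(d["scale_mean"]),
            scale_sd=np.array(d["scale_sd"]),
        )


def _log_gauss_mixture_components(
    z: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """log(w_k) + log N(z | mu_k, Sigma_k), shape (n, K)."""
    n, d = z.shape
    K = len(weights)
    out = np.empty((n, K))
    for k in range(K):
        diff = z - means[k]
        if d == 1:
            var = covs[k, 0, 0]
            out[:, k] = -0.5 * (np.log(2 * np.pi * var) + diff[:, 0] ** 2 / var)
        else:
            L = np.linalg.cholesky(covs[k])
            sol = np.linalg.solve(L, diff.T)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0))
        with np.errstate(divide="ignore"):
            out[:, k] += np.log(weights[k])
    return out


def _total_loglik(z, weights, means, covs) -> float:
    logp = _log_gauss_mixture_components(z, weights, means, covs)
    m = logp.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))).sum())


def _kmeanspp_init(z: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = len(z)
    centers = [z[rng.integers(n)]]
    for _ in range(K - 1):
        d2 = np.min(
            [((z - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(z[rng.integers(n)])
            continue
        centers.append(z[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _em_run(
    z: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    settings: EMSettings,
    floor: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float]] | None:
    """EM from the given parameters; None when a component degenerates."""
    n, d = z.shape
    K = len(weights)
    weights = weights.copy()
    means = means.copy()
    covs = _apply_floor(covs.copy(), floor)
    prev = -np.inf
    trace: list[float] = []
    for _ in range(settings.max_iter):
        logp = _log_gauss_mixture_components(z, weights, means, covs)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 0.1):  # component weight below 1/(10 n)
            return None
        weights = nk / n
        means = (resp.T @ z) / nk[:, None]
        for k in range(K):
            diff = z - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
        covs = _apply_floor(covs, floor)
        if prev > -np.inf and abs(ll - prev) <= settings.tol * max(1.0, abs(prev)):
            break
        prev = ll
    ll = _total_loglik(z, weights, means, covs)
    trace.append(ll)
    return ll, weights, means, covs, trace


def _apply_floor(covs: np.ndarray, floor: np.ndarray) -> np.ndarray:
    K, d, _ = covs.shape
    out = covs.copy()
    for k in range(K):
        if d == 1:
            out[k, 0, 0] = max(out[k, 0, 0], floor[0])
        else:
            vals, vecs = np.linalg.eigh(out[k])
            vals = np.maximum(vals, floor.min())
            out[k] = (vecs * vals) @ vecs.T
    return out


def fit_em(
    points,
    K: int = 3,
    seed: int = 0,
    settings: EMSettings | None = None,
) -> ClusterModel:
    """Fit a K-component Gaussian mixture by EM, best of several restarts.

    ``points`` is (n,) or (n, d) with d in {1, 2}; bivariate data is
    standardized per coordinate before fitting (configurable).  The
    per-iteration log-likelihood is non-decreasing; restarts whose
    components degenerate (weight below ``1/(10n)``) are discarded and
    counted.  Deterministic given ``seed``.
    """
    settings = settings or EMSettings()
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    if d not in (1, 2):
        raise InvalidInputError("fit_em supports 1- or 2-dimensional points")
    if K > n:
        raise InvalidInputError(f"K={K} exceeds number of points n={n}")

    if d == 2 and settings.standardize_bivariate:
        mu = pts.mean(axis=0)
        sd = pts.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mu = np.zeros(d)
        sd = np.ones(d)
    z = (pts - mu) / sd

    data_var = z.var(axis=0)
    floor = np.maximum(settings.variance_floor_frac * np.where(data_var > 0, data_var, 1.0), 1e-300)

    rng = np.random.default_rng(seed)
    best = None
    n_degenerate = 0
    n_done = 0

    def consider(init) -> None:
        nonlocal best, n_degenerate, n_done
        res = _em_run(z, *init, settings, floor)
        if res is None:
            n_degenerate += 1
            return
        n_done += 1
        if best is None or res[0] > best[0]:
            best = res

    base = np.cov(z.T, ddof=0).reshape(d, d) if n > 1 else np.eye(d)
    attempts = 0
    while n_done < settings.n_restarts and attempts < 4 * settings.n_restarts:
        attempts += 1
        centers = _kmeanspp_init(z, K, rng)
        for _ in range(10):  # short Lloyd refinement of the seeding
            lab = np.argmin(((z[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
            for k in range(K):
                if np.any(lab == k):
                    centers[k] = z[lab == k].mean(axis=0)
        covs0 = np.array([base.copy() for _ in range(K)])
        consider((np.full(K, 1.0 / K), centers.copy(), covs0))

    if d == 1 and settings.partition_inits:
        from itertools import combinations
        from math import comb

        order = np.argsort(z[:, 0], kind="stable")
        zs = z[order]
        all_cuts = list(combinations(range(1, n), K - 1))
        if comb(n - 1, K - 1) > settings.max_partition_inits:
            pick = rng.choice(
                len(all_cuts), size=settings.max_partition_inits, replace=False
            )
            all_cuts = [all_cuts[i] for i in sorted(pick)]
        for cuts in all_cuts:
            bounds = (0, *cuts, n)
            parts = [zs[bounds[i] : bounds[i + 1]] for i in range(K)]
            w0 = np.array([len(p) / n for p in parts])
            m0 = np.array([[p.mean()] for p in parts])
            c0 = np.array([[[max(p.var(), floor[0])]] for p in parts])
            consider((w0, m0, c0))

    if best is None:
        raise InvalidInputError("all EM restarts degenerated")
    ll, weights, means, covs, trace = best
    order = tuple(int(i) for i in np.argsort(means[:, -1], kind="stable"))
    return ClusterModel(
        K=K,
        weights=weights,
        means=means,
        covariances=covs,
        class_order=order,
        loglik=ll,
        n_restarts_used=n_done,
        n_degenerate_restarts=n_degenerate,
        scale_mean=mu,
        scale_sd=sd,
        loglik_trace=tuple(trace),
    )


def assign_class(model: ClusterModel, point) -> tuple[str, np.ndarray]:
    """Class label and posterior vector for one point.

    The label is the argmax-posterior component mapped through the
    mean-ordering; exact posterior ties break toward the lower-mean
    component.
    """
    post = model.posterior(point)
    order = list(model.class_order)
    # iterate in ascending-mean order so ties resolve to the lower class
    best_rank = max(
        range(model.K), key=lambda r: (post[order[r]], -r)
    )
    return model.class_names()[best_rank], post
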