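"""Descriptor-selection cascade: CFS merit + genetic search, tree ranking,
regression top-weight.

The cascade reduces a wide descriptor matrix to a handful of inputs for
the surrogate:

1. correlation-based feature selection (CFS) scored by Hall's merit,
   searched with a bitstring genetic algorithm;
2. a C4.5-style decision tree (gain-ratio splits, pessimistic pruning)
   grown against the mixture-model classes, ranking the CFS subset by
   where descriptors appear in the tree;
3. one additional descriptor from an ordinary least-squares fit on the
   standardized CFS subset — the largest absolute coefficient not already
   ranked by the tree.

Hall's merit for a subset S of size k is

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

with r_cf the mean absolute feature-target correlation over S and r_ff
the mean absolute pairwise correlation within S.  It rewards relevance
and penalizes redundancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cluster import ClusterModel, assign_class
from .core import (
    TIME_FEATURE,
    DescriptorTable,
    InvalidInputError,
    ModelingDataset,
)

__all__ = [
    "SubsetMerit",
    "GASettings",
    "TreeSettings",
    "TreeNode",
    "TreeModel",
    "SelectionConfig",
    "SelectionResult",
    "CorrelationCache",
    "cfs_merit",
    "genetic_search",
    "build_tree",
    "tree_descriptor_ranking",
    "regression_top_descriptor",
    "select_descriptors",
]


# ---------------------------------------------------------------------------
# CFS merit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubsetMerit:
    descriptor_names: frozenset[str]
    merit: float


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0  # constant columns carry no correlation
    r = float(np.corrcoef(x, y)[0, 1])
    return abs(r)


def _symmetric_uncertainty(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """SU = 2 I(X;Y) / (H(X) + H(Y)) on equal-frequency discretizations."""

    def disc(v: np.ndarray) -> np.ndarray:
        qs = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
        return np.searchsorted(qs, v, side="right")

    a, b = disc(x), disc(y)
    n = len(a)
    joint: dict[tuple[int, int], int] = {}
    for u, v in zip(a, b):
        joint[(u, v)] = joint.get((u, v), 0) + 1

    def entropy(labels: np.ndarray) -> float:
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return float(-(p * np.log2(p)).sum())

    hx, hy = entropy(a), entropy(b)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    mi = 0.0
    pa = {u: np.count_nonzero(a == u) / n for u in set(a)}
    pb = {v: np.count_nonzero(b == v) / n for v in set(b)}
    for (u, v), c in joint.items():
        pj = c / n
        mi += pj * math.log2(pj / (pa[u] * pb[v]))
    return 2.0 * mi / (hx + hy)


class CorrelationCache:
    """Precomputed |correlation| structure for fast merit evaluation.

    ``measure`` is ``"pearson"`` (default) or ``"symmetric_uncertainty"``
    (discretized, the WEKA-style alternative).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        names: Sequence[str],
        measure: str = "pearson",
    ) -> None:
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.names = tuple(names)
        self.index = {n: j for j, n in enumerate(self.names)}
        n, p = X.shape
        if measure == "pearson":
            sx = X.std(axis=0)
            sy = y.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                Xc = (X - X.mean(axis=0)) / np.where(sx == 0, 1.0, sx)
                Xc[:, sx == 0] = 0.0
                yc = (y - y.mean()) / (sy if sy > 0 else 1.0)
                if sy == 0:
                    yc = np.zeros_like(y)
                self.r_fy = np.abs(Xc.T @ yc) / n
                self.r_ff = np.abs(Xc.T @ Xc) / n
            np.fill_diagonal(self.r_ff, 1.0)
        elif measure == "symmetric_uncertainty":
            bins = max(2, min(10, n // 3))
            self.r_fy = np.array(
                [_symmetric_uncertainty(X[:, j], y, bins) for j in range(p)]
            )
            self.r_ff = np.eye(p)
            for j in range(p):
                for k in range(j + 1, p):
                    su = _symmetric_uncertainty(X[:, j], X[:, k], bins)
                    self.r_ff[j, k] = self.r_ff[k, j] = su
        else:
            raise InvalidInputError(f"unknown correlation measure {measure!r}")
        self.non_constant = X.std(axis=0) > 0

    def merit_idx(self, idx: np.ndarray) -> float:
        k = len(idx)
        if k == 0:
            return 0.0
        r_cf = float(self.r_fy[idx].mean())
        if k == 1:
            return r_cf
        sub = self.r_ff[np.ix_(idx, idx)]
        r_ff = float((sub.sum() - k) / (k * (k - 1)))
        return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


def cfs_merit(
    subset: Sequence[str],
    X: DescriptorTable | np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    measure: str = "pearson",
) -> float:
    """Hall's CFS merit of a named descriptor subset against target ``y``."""
    if isinstance(X, DescriptorTable):
        names = X.descriptor_names
        X = X.values
    if names is None:
        raise InvalidInputError("names required when X is a bare matrix")
    subset = list(subset)
    if not subset:
        raise InvalidInputError("subset must be non-empty")
    cache = CorrelationCache(X, np.asarray(y, float), names, measure)
    try:
        idx = np.array([cache.index[s] for s in subset])
    except KeyError as exc:
        raise InvalidInputError(f"unknown descriptor name {exc.args[0]!r}") from None
    return cache.merit_idx(idx)


# ---------------------------------------------------------------------------
# Genetic search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GASettings:
    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.6
    mutation_prob: float | None = None  # default 1 / n_descriptors
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise InvalidInputError("population must be at least 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not (0.0 <= p <= 1.0):
                raise InvalidInputError("probabilities must lie in [0, 1]")


def genetic_search(
    X: DescriptorTable | np.ndarray,
    y: np.ndarray,
    ga: GASettings | None = None,
    names: Sequence[str] | None = None,
    measure: str = "pearson",
    cache: CorrelationCache | None = None,
    progress: list | None = None,
    initial_population: np.ndarray | None = None,
) -> SubsetMerit:
    """Bitstring GA maximizing CFS merit over descriptor subsets.

    Tournament selection of size 2, uniform crossover, per-bit mutation,
    elitism; returns the best-ever subset.  Deterministic given the seed.
    Descriptors are indexed in sorted-name order internally, so the result
    does not depend on column order.  ``progress`` (if a list) receives one
    ``(generation, best_merit)`` pair per generation; the best-ever merit
    is non-decreasing.  ``initial_population`` (rows = bitstrings over the
    sorted names) overrides the random initial population.
    """
    ga = ga or GASettings()
    if isinstance(X, DescriptorTable):
        names = X.descriptor_names
        X = X.values
    if names is None:
        raise InvalidInputError("names required when X is a bare matrix")
    y = np.asarray(y, float)
    if cache is None:
        order = np.argsort(np.asarray(names, dtype=object), kind="stable")
        names = [names[j] for j in order]
        cache = CorrelationCache(np.asarray(X, float)[:, order], y, names, measure)
    if not cache.non_constant.any():
        raise InvalidInputError("all descriptor columns are constant")
    p = len(cache.names)
    mut = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / p
    rng = np.random.default_rng(ga.seed)

    if initial_population is not None:
        pop = np.array(initial_population, dtype=bool)
        if pop.shape != (ga.population, p):
            raise InvalidInputError("initial_population shape mismatch")
    else:
        # small expected subsets on wide tables, denser on narrow ones
        p_init = min(0.5, 10.0 / p)
        pop = rng.random((ga.population, p)) < p_init
        for i in range(ga.population):  # guarantee non-empty individuals
            if not pop[i].any():
                pop[i, rng.integers(p)] = True

    def fitness(bits: np.ndarray) -> float:
        return cache.merit_idx(np.flatnonzero(bits))

    fits = np.array([fitness(ind) for ind in pop])
    best_bits = pop[int(np.argmax(fits))].copy()
    best_fit = float(fits.max())

    for gen in range(ga.generations):
        order = np.argsort(-fits, kind="stable")
        elite = pop[order[: ga.elitism]].copy()
        children = [e for e in elite]
        while len(children) < ga.population:
            idx = rng.integers(0, ga.population, size=4)
            pa = pop[idx[0]] if fits[idx[0]] >= fits[idx[1]] else pop[idx[1]]
            pb = pop[idx[2]] if fits[idx[2]] >= fits[idx[3]] else pop[idx[3]]
            c1, c2 = pa.copy(), pb.copy()
            if rng.random() < ga.crossover_prob:
                mask = rng.random(p) < 0.5
                c1[mask], c2[mask] = pb[mask], pa[mask]
            for c in (c1, c2):
                flip = rng.random(p) < mut
                c[flip] = ~c[flip]
                if len(children) < ga.population:
                    children.append(c)
        pop = np.array(children)
        fits = np.array([fitness(ind) for ind in pop])
        g_best = int(np.argmax(fits))
        if fits[g_best] > best_fit:
            best_fit = float(fits[g_best])
            best_bits = pop[g_best].copy()
        if progress is not None:
            progress.append((gen, best_fit))

    chosen = frozenset(cache.names[j] for j in np.flatnonzero(best_bits))
    return SubsetMerit(chosen, best_fit)


# ---------------------------------------------------------------------------
# C4.5-style decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSettings:
    min_leaf: int = 2
    prune: bool = True
    confidence: float = 0.25


@dataclass
class TreeNode:
    n: int
    counts: dict[str, int]
    label: str
    descriptor: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.descriptor is None


@dataclass(frozen=True)
class TreeModel:
    root: TreeNode
    feature_names: tuple[str, ...]
    settings: TreeSettings

    def predict_one(self, row: dict[str, float]) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if row[node.descriptor] <= node.threshold else node.right
        return node.label

    def training_accuracy(self, X: np.ndarray, labels: Sequence[str]) -> float:
        hits = 0
        for i, lab in enumerate(labels):
            row = {n: X[i, j] for j, n in enumerate(self.feature_names)}
            hits += self.predict_one(row) == lab
        return hits / len(labels)


def entropy(counts: Sequence[int]) -> float:
    """Shannon entropy in bits of a class-count vector."""
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def _majority(counts: dict[str, int]) -> str:
    # ties break by name for determinism
    return max(sorted(counts), key=lambda c: counts[c])


def _best_split(
    X: np.ndarray, labels: np.ndarray, names: Sequence[str], min_leaf: int
) -> tuple[float, str, float] | None:
    """Maximize gain ratio over every (descriptor, midpoint threshold)."""
    n = len(labels)
    classes, y = np.unique(labels, return_inverse=True)
    base = entropy(np.bincount(y, minlength=len(classes)))
    best: tuple[float, float, str, float] | None = None  # (gr, -thr ...) keyed below
    for j, name in enumerate(names):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        left = np.zeros(len(classes), dtype=int)
        right = np.bincount(ys, minlength=len(classes)).astype(int)
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = base - (nl * entropy(left) + nr * entropy(right)) / n
            if gain <= 1e-12:
                continue
            split_info = entropy([nl, nr])
            if split_info <= 0:
                continue
            gr = gain / split_info
            thr = 0.5 * (xs[i] + xs[i + 1])
            # ties: higher gain ratio, then lower threshold, then name
            if (
                best is None
                or gr > best[0] + 1e-15
                or (
                    abs(gr - best[0]) <= 1e-15
                    and (thr, name) < (best[3], best[2])
                )
            ):
                best = (gr, -thr, name, thr)
    if best is None:
        return None
    return best[0], best[2], best[3]


def _grow(
    X: np.ndarray, labels: np.ndarray, names: Sequence[str], settings: TreeSettings
) -> TreeNode:
    vals, cnts = np.unique(labels, return_counts=True)
    counts = {str(v): int(c) for v, c in zip(vals, cnts)}
    node = TreeNode(n=len(labels), counts=counts, label=_majority(counts))
    if len(vals) == 1 or len(labels) < 2 * settings.min_leaf:
        return node
    split = _best_split(X, labels, names, settings.min_leaf)
    if split is None:
        return node
    _, name, thr = split
    j = list(names).index(name)
    mask = X[:, j] <= thr
    node.descriptor = name
    node.threshold = thr
    node.left = _grow(X[mask], labels[mask], names, settings)
    node.right = _grow(X[~mask], labels[~mask], names, settings)
    if node.left.is_leaf and node.right.is_leaf and node.left.label == node.right.label:
        node.descriptor = node.threshold = node.left = node.right = None
    return node


def _pessimistic_errors(node: TreeNode, z: float) -> float:
    """Upper-confidence error count (C4.5 pessimistic estimate)."""
    if node.is_leaf:
        e = node.n - node.counts.get(node.label, 0)
        return node.n * _ucb_error_rate(e, node.n, z)
    return _pessimistic_errors(node.left, z) + _pessimistic_errors(node.right, z)


def _ucb_error_rate(errors: int, n: int, z: float) -> float:
    if n == 0:
        return 0.0
    f = errors / n
    z2 = z * z
    num = f + z2 / (2 * n) + z * math.sqrt(f * (1 - f) / n + z2 / (4 * n * n))
    return num / (1 + z2 / n)


def _prune(node: TreeNode, z: float) -> TreeNode:
    if node.is_leaf:
        return node
    node.left = _prune(node.left, z)
    node.right = _prune(node.right, z)
    subtree_err = _pessimistic_errors(node, z)
    as_leaf_err = node.n * _ucb_error_rate(
        node.n - node.counts.get(node.label, 0), node.n, z
    )
    if as_leaf_err <= subtree_err:
        node.descriptor = node.threshold = node.left = node.right = None
    return node


def build_tree(
    X: np.ndarray | DescriptorTable,
    labels: Sequence[str],
    names: Sequence[str] | None = None,
    settings: TreeSettings | None = None,
) -> TreeModel:
    """Grow (and pessimistically prune) a gain-ratio decision tree.

    Splits are binary on midpoints of adjacent observed values; a node with
    a single class becomes a leaf.  A single-class sample yields a
    single-leaf tree.
    """
    settings = settings or TreeSettings()
    if isinstance(X, DescriptorTable):
        names = X.descriptor_names
        X = X.values
    if names is None:
        raise InvalidInputError("names required when X is a bare matrix")
    labels_arr = np.asarray([str(v) for v in labels])
    root = _grow(np.asarray(X, float), labels_arr, names, settings)
    if settings.prune:
        z = float(norm.ppf(1.0 - settings.confidence))
        root = _prune(root, z)
    return TreeModel(root, tuple(names), settings)


def tree_descriptor_ranking(tree: TreeModel) -> list[str]:
    """Unique split descriptors in breadth-first (root-first) order.

    Ties within a level break by training-instance count at the node
    (descending), then by name.
    """
    out: list[str] = []
    level = [tree.root]
    while level:
        internal = [n for n in level if not n.is_leaf]
        for node in sorted(internal, key=lambda nd: (-nd.n, nd.descriptor)):
            if node.descriptor not in out:
                out.append(node.descriptor)
        level = [c for n in internal for c in (n.left, n.right)]
    return out


# ---------------------------------------------------------------------------
# Regression top-weight
# ---------------------------------------------------------------------------


class SingularDesignError(InvalidInputError):
    """OLS design matrix is rank-deficient and no fallback was enabled."""


def regression_top_descriptor(
    X: np.ndarray | DescriptorTable,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
    ridge_fallback: bool = False,
    return_coefs: bool = False,
):
    """Largest-|coefficient| descriptor of OLS on the standardized subset.

    Columns are standardized to zero mean / unit variance (constant columns
    contribute zero).  A rank-deficient design raises
    :class:`SingularDesignError` unless ``ridge_fallback`` substitutes a
    tiny-ridge solve.  Names in ``exclude`` are skipped at the argmax.
    """
    if isinstance(X, DescriptorTable):
        names = X.descriptor_names
        X = X.values
    if names is None:
        raise InvalidInputError("names required when X is a bare matrix")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    sd = X.std(axis=0)
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - X[:, nz].mean(axis=0)) / sd[nz]
    yc = y - y.mean()
    rank = np.linalg.matrix_rank(Z[:, nz]) if nz.any() else 0
    if rank < nz.sum() or n < p + 1:
        if not ridge_fallback:
            raise SingularDesignError(
                "rank-deficient regression design; enable ridge_fallback to proceed"
            )
        lam = 1e-6 * n
        beta_nz = np.linalg.solve(Z[:, nz].T @ Z[:, nz] + lam * np.eye(int(nz.sum())), Z[:, nz].T @ yc)
    else:
        beta_nz, *_ = np.linalg.lstsq(Z[:, nz], yc, rcond=None)
    beta = np.zeros(p)
    beta[nz] = beta_nz
    candidates = [
        (abs(beta[j]), names[j], j) for j in range(p) if names[j] not in set(exclude)
    ]
    if not candidates:
        raise InvalidInputError("exclusion list removed every candidate descriptor")
    # largest |coef|; ties break by name ascending
    name = min(candidates, key=lambda c: (-c[0], c[1]))[1]
    if return_coefs:
        return name, dict(zip(names, beta))
    return name


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionConfig:
    n_final: int | None = None  # default: 3 equilibrium / 6 all_points
    ga: GASettings = field(default_factory=GASettings)
    tree: TreeSettings = field(default_factory=TreeSettings)
    measure: str = "pearson"
    exclude_tree_picks_in_regression: bool = True
    ridge_fallback: bool = True


@dataclass(frozen=True)
class SelectionResult:
    cfs_subset: frozenset[str]
    cfs_merit: float
    tree_descriptors: tuple[str, ...]
    regression_descriptor: str | None
    final_descriptors: tuple[str, ...]
    included_time: bool
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "cfs_subset": sorted(self.cfs_subset),
            "cfs_merit": self.cfs_merit,
            "tree_descriptors": list(self.tree_descriptors),
            "regression_descriptor": self.regression_descriptor,
            "final_descriptors": list(self.final_descriptors),
            "included_time": self.included_time,
            "warning": self.warning,
        }


def select_descriptors(
    dataset: ModelingDataset,
    cluster: ClusterModel,
    cfg: SelectionConfig | None = None,
    ga_progress: list | None = None,
) -> SelectionResult:
    """Run the full cascade on a modelling dataset.

    The final list is the first ``n_final - 1`` tree-ranked descriptors
    plus the regression top-weight descriptor; for the all-points target,
    incubation time is appended afterwards and never dropped.  When fewer
    unique candidates exist than requested, everything found is returned
    with a warning.
    """
    cfg = cfg or SelectionConfig()
    X, y, names = dataset.design_matrix()
    n_final = cfg.n_final or (6 if dataset.target_kind == "all_points" else 3)

    best = genetic_search(
        X, y, cfg.ga, names=names, measure=cfg.measure, progress=ga_progress
    )
    subset = sorted(best.descriptor_names - {TIME_FEATURE})
    name_idx = {n: j for j, n in enumerate(names)}
    Xs = X[:, [name_idx[s] for s in subset]]

    if dataset.target_kind == "all_points":
        pts = np.column_stack([X[:, name_idx[TIME_FEATURE]], y])
        labels = [assign_class(cluster, p)[0] for p in pts]
    else:
        labels = [assign_class(cluster, [v])[0] for v in y]

    tree = build_tree(Xs, labels, names=subset, settings=cfg.tree)
    ranking = tree_descriptor_ranking(tree)

    exclude = list(ranking[: n_final - 1]) if cfg.exclude_tree_picks_in_regression else []
    reg_name: str | None = None
    if subset:
        try:
            reg_name = regression_top_descriptor(
                Xs, y, names=subset, exclude=exclude, ridge_fallback=cfg.ridge_fallback
            )
        except InvalidInputError:
            reg_name = None

    final: list[str] = []
    for nm in ranking:
        if len(final) >= n_final - 1:
            break
        final.append(nm)
    if reg_name is not None and reg_name not in final:
        final.append(reg_name)
    # top up from the CFS subset (merit-ordered singletons) when short
    warning = None
    if len(final) < n_final:
        leftovers = [s for s in subset if s not in final]
        cache = CorrelationCache(Xs, y, subset, cfg.measure)
        leftovers.sort(key=lambda s: -cache.r_fy[cache.index[s]])
        for nm in leftovers:
            if len(final) >= n_final:
                break
            final.append(nm)
    if len(final) < n_final:
        warning = (
            f"only {len(final)} unique candidate descriptors available, "
            f"{n_final} requested"
        )

    included_time = dataset.target_kind == "all_points"
    if included_time and TIME_FEATURE not in final:
        final.append(TIME_FEATURE)

    return SelectionResult(
        cfs_subset=best.descriptor_names,
        cfs_merit=best.merit,
        tree_descriptors=tuple(ranking),
        regression_descriptor=reg_name,
        final_descriptors=tuple(final),
        included_time=included_time,
        warning=warning,
    )
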