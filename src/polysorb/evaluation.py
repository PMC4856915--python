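"""Exhaustive hold-out validation, the three headline metrics, and
library-wide prediction with uncertainty banding.

Validation enumerates every way of holding out 10 % of the units (for 18
polymers: all C(18,2) = 153 leave-two-out splits), trains a seed ensemble
on each training side and scores the held-out side.  Three metrics are
pooled over the union of test-side predictions (averaged per unit first):

* R^2 — squared Pearson correlation between predictions and observations
  (the 1 - SSE/SST variant is reported alongside);
* within-experimental-variability fraction — a prediction counts as
  correct when |pred - obs| does not exceed that polymer's experimental SD;
* class accuracy — agreement of mixture-model class labels assigned to
  prediction and observation.

Library prediction applies every split's model to the not-yet-measured
polymers and reports mean +/- SD across splits with a low/medium/high/
very-high band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from .cluster import ClusterModel, assign_class
from .core import (
    TIME_FEATURE,
    DescriptorTable,
    EquilibriumProperty,
    InvalidInputError,
    ModelingDataset,
)
from .mlp import MLPHyperparams, MLPModel, predict, train_seed_ensemble
from .selection import SelectionConfig, SelectionResult, select_descriptors

__all__ = [
    "SplitScheme",
    "enumerate_splits",
    "within_variability_fraction",
    "r_squared",
    "pearson",
    "class_accuracy",
    "CVConfig",
    "EvaluationReport",
    "crossvalidate_pipeline",
    "BandRules",
    "LibraryPrediction",
    "predict_library",
]


@dataclass(frozen=True)
class SplitScheme:
    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test)
    test_size: int
    exhaustive: bool

    def __len__(self) -> int:
        return len(self.splits)


def enumerate_splits(
    ids: Sequence[str],
    test_fraction: float = 0.10,
    max_splits: int | None = None,
    seed: int = 0,
) -> SplitScheme:
    """All train/test splits holding out ``round(test_fraction * n)`` units.

    Exhaustive enumeration in lexicographic order of the (sorted) id
    tuples.  When the exhaustive count exceeds ``max_splits``, a
    deterministic random sample of that many distinct test sets is drawn
    instead and the scheme is marked non-exhaustive.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise InvalidInputError("need at least 3 units to split")
    test_size = max(1, round(test_fraction * n))
    if test_size >= n:
        raise InvalidInputError(f"test size {test_size} must be smaller than n={n}")
    total = comb(n, test_size)
    id_set = set(ids)
    if max_splits is None or total <= max_splits:
        splits = tuple(
            (tuple(i for i in ids if i not in set(test)), tuple(test))
            for test in combinations(ids, test_size)
        )
        return SplitScheme(splits, test_size, True)
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < max_splits:
        pick = tuple(sorted(rng.choice(n, size=test_size, replace=False).tolist()))
        chosen.add(pick)
    splits = tuple(
        (
            tuple(ids[i] for i in range(n) if i not in set(pick)),
            tuple(ids[i] for i in pick),
        )
        for pick in sorted(chosen)
    )
    return SplitScheme(splits, test_size, False)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def within_variability_fraction(
    preds: Mapping[str, float], eq: Sequence[EquilibriumProperty]
) -> tuple[float, dict[str, bool]]:
    """Fraction of predictions with |pred - obs| <= experimental SD."""
    by_id = {e.polymer_id: e for e in eq}
    flags: dict[str, bool] = {}
    for pid, p in preds.items():
        if pid not in by_id:
            raise InvalidInputError(f"no experimental record for polymer {pid!r}")
        e = by_id[pid]
        flags[pid] = abs(p - e.wu_eq) <= e.sd_exp
    if not flags:
        raise InvalidInputError("no predictions supplied")
    return sum(flags.values()) / len(flags), flags


def pearson(preds: Sequence[float], obs: Sequence[float]) -> float:
    p = np.asarray(preds, float)
    o = np.asarray(obs, float)
    if len(p) < 2:
        raise InvalidInputError("need at least 2 pairs")
    if p.std() == 0 or o.std() == 0:
        raise InvalidInputError("correlation undefined for a constant vector")
    return float(pearsonr(p, o).statistic)


def r_squared(preds: Sequence[float], obs: Sequence[float]) -> float:
    """Squared Pearson correlation between predictions and observations."""
    return pearson(preds, obs) ** 2


def r_squared_sse(preds: Sequence[float], obs: Sequence[float]) -> float:
    """The 1 - SSE/SST variant (differs off the 45-degree line)."""
    p = np.asarray(preds, float)
    o = np.asarray(obs, float)
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0:
        raise InvalidInputError("R^2 undefined for constant observations")
    return 1.0 - float(((o - p) ** 2).sum()) / sst


def class_accuracy(
    preds: Mapping[str, float],
    obs: Mapping[str, float],
    cluster: ClusterModel,
    times: Mapping[str, float] | None = None,
) -> float:
    """Fraction of units whose predicted and observed class labels agree.

    For a bivariate (time, WU) cluster model, ``times`` supplies each
    unit's time coordinate.
    """
    if not preds:
        raise InvalidInputError("no predictions supplied")
    hits = 0
    for uid, p in preds.items():
        o = obs[uid]
        if cluster.dim == 2:
            t = times[uid]
            lab_p = assign_class(cluster, [t, p])[0]
            lab_o = assign_class(cluster, [t, o])[0]
        else:
            lab_p = assign_class(cluster, [p])[0]
            lab_o = assign_class(cluster, [o])[0]
        hits += lab_p == lab_o
    return hits / len(preds)


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    test_fraction: float = 0.10
    mlp: MLPHyperparams = field(default_factory=MLPHyperparams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    group_by_polymer: bool = False  # all-points only: hold out whole polymers
    max_splits: int | None = None
    split_seed: int = 0
    nested_selection: bool = False  # re-select per split (honest variant)


@dataclass
class EvaluationReport:
    target_kind: str
    n_splits: int
    exhaustive: bool
    grouped: bool
    r2_train: float
    r2_cv: float
    r2_cv_sse: float
    r2_cv_per_split_mean: float | None
    frac_within_train: float
    frac_within_test: float
    class_accuracy_cv: float
    features: tuple[str, ...]
    pooled_predictions: dict[str, float]
    pooled_observations: dict[str, float]
    per_split: list[dict] = field(default_factory=list)
    split_models: list[MLPModel] = field(default_factory=list, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("split_models", "per_split")
        }
        payload["features"] = list(self.features)
        payload["per_split"] = self.per_split
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "EvaluationReport":
        from .mlp import _maybe_file

        d = json.loads(_maybe_file(source))
        d["features"] = tuple(d["features"])
        return EvaluationReport(**d)


def _unit_frame(dataset: ModelingDataset):
    """Rows: (unit_id, polymer_id, time-or-None, observed, sd)."""
    if dataset.target_kind == "equilibrium":
        return [
            (e.polymer_id, e.polymer_id, None, e.wu_eq, e.sd_exp)
            for e in dataset.equilibrium
        ]
    return [
        (uid, pid, float(t), float(w), float(s))
        for uid, pid, t, w, s in zip(
            dataset.unit_ids,
            dataset.point_polymer_ids,
            dataset.point_times,
            dataset.point_wu,
            dataset.point_sd,
        )
    ]


def crossvalidate_pipeline(
    dataset: ModelingDataset,
    cluster: ClusterModel,
    cfg: CVConfig | None = None,
    features: Sequence[str] | None = None,
    selection: SelectionResult | None = None,
) -> EvaluationReport:
    """Exhaustive-split cross-validation of the full surrogate pipeline.

    Descriptor selection runs once on the full training data (the default
    protocol; ``cfg.nested_selection`` re-selects inside every split).
    Pooled CV metrics are computed on per-unit averages of all test-side
    predictions.
    """
    cfg = cfg or CVConfig()
    X, y, names = dataset.design_matrix()
    units = _unit_frame(dataset)
    unit_ids = [u[0] for u in units]
    row_of = {u[0]: i for i, u in enumerate(units)}

    if features is None:
        if selection is None:
            selection = select_descriptors(dataset, cluster, cfg.selection)
        features = selection.final_descriptors
    features = tuple(features)
    fidx = [list(names).index(f) for f in features]
    Xf = X[:, fidx]

    if cfg.group_by_polymer and dataset.target_kind == "all_points":
        group_ids = list(dict.fromkeys(dataset.point_polymer_ids))
        scheme = enumerate_splits(
            group_ids, cfg.test_fraction, cfg.max_splits, cfg.split_seed
        )
        grouped = True

        def unit_split(train_g, test_g):
            tr = [u[0] for u in units if u[1] in set(train_g)]
            te = [u[0] for u in units if u[1] in set(test_g)]
            return tr, te

        split_units = [unit_split(tr, te) for tr, te in scheme.splits]
    else:
        scheme = enumerate_splits(
            unit_ids, cfg.test_fraction, cfg.max_splits, cfg.split_seed
        )
        grouped = False
        split_units = list(scheme.splits)

    obs = {u[0]: u[3] for u in units}
    sds = {u[0]: u[4] for u in units}
    times = {u[0]: u[2] for u in units}
    test_preds: dict[str, list[float]] = {uid: [] for uid in unit_ids}
    per_split: list[dict] = []
    models: list[MLPModel] = []
    r2_tr_list: list[float] = []
    fw_tr_list: list[float] = []
    r2_cv_split: list[float] = []

    for s_idx, (train_u, test_u) in enumerate(split_units):
        tr_rows = [row_of[u] for u in train_u]
        te_rows = [row_of[u] for u in test_u]
        try:
            if cfg.nested_selection:
                sub = _restrict(dataset, train_u)
                sel = select_descriptors(sub, cluster, cfg.selection)
                feats = sel.final_descriptors
                f_i = [list(names).index(f) for f in feats]
            else:
                feats, f_i = features, fidx
            ens = train_seed_ensemble(X[np.ix_(tr_rows, f_i)], y[tr_rows], feats, cfg.mlp)
            model = ens.best_model
            p_tr = predict(model, X[np.ix_(tr_rows, f_i)])
            p_te = predict(model, X[np.ix_(te_rows, f_i)])
        except InvalidInputError as exc:
            raise InvalidInputError(f"split {s_idx}: {exc}") from exc
        models.append(model)
        r2_tr = r_squared(p_tr, y[tr_rows])
        r2_tr_list.append(r2_tr)
        fw_tr = np.mean(
            [abs(p - obs[u]) <= sds[u] for p, u in zip(p_tr, train_u)]
        )
        fw_tr_list.append(float(fw_tr))
        for p, u in zip(p_te, test_u):
            test_preds[u].append(float(p))
        if len(test_u) >= 2 and np.std(y[te_rows]) > 0 and np.std(p_te) > 0:
            r2_cv_split.append(r_squared(p_te, y[te_rows]))
        per_split.append(
            {
                "split": s_idx,
                "test_ids": list(test_u),
                "r2_train": r2_tr,
                "train_rmse": model.train_rmse,
                "test_predictions": {u: float(p) for u, p in zip(test_u, p_te)},
            }
        )

    pooled = {u: float(np.mean(v)) for u, v in test_preds.items() if v}
    pooled_ids = list(pooled)
    pv = [pooled[u] for u in pooled_ids]
    ov = [obs[u] for u in pooled_ids]
    fw_test = float(
        np.mean([abs(pooled[u] - obs[u]) <= sds[u] for u in pooled_ids])
    )
    acc = class_accuracy(pooled, obs, cluster, times if cluster.dim == 2 else None)

    return EvaluationReport(
        target_kind=dataset.target_kind,
        n_splits=len(scheme),
        exhaustive=scheme.exhaustive,
        grouped=grouped,
        r2_train=float(np.mean(r2_tr_list)),
        r2_cv=r_squared(pv, ov),
        r2_cv_sse=r_squared_sse(pv, ov),
        r2_cv_per_split_mean=float(np.mean(r2_cv_split)) if r2_cv_split else None,
        frac_within_train=float(np.mean(fw_tr_list)),
        frac_within_test=fw_test,
        class_accuracy_cv=acc,
        features=features,
        pooled_predictions=pooled,
        pooled_observations={u: obs[u] for u in pooled_ids},
        per_split=per_split,
        split_models=models,
    )


def _restrict(dataset: ModelingDataset, unit_ids: Sequence[str]) -> ModelingDataset:
    keep = set(unit_ids)
    if dataset.target_kind == "equilibrium":
        return ModelingDataset.from_equilibrium(
            dataset.descriptors,
            [e for e in dataset.equilibrium if e.polymer_id in keep],
        )
    mask = np.array([u in keep for u in dataset.unit_ids])
    return ModelingDataset(
        dataset.descriptors,
        "all_points",
        point_polymer_ids=tuple(
            p for p, m in zip(dataset.point_polymer_ids, mask) if m
        ),
        point_times=dataset.point_times[mask],
        point_wu=dataset.point_wu[mask],
        point_sd=dataset.point_sd[mask],
    )


# ---------------------------------------------------------------------------
# library-wide prediction with banding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandRules:
    """Class-band boundaries on the WU scale.

    ``low_medium`` and ``medium_high`` are posterior-equality crossings of
    the fitted mixture; ``very_high`` is the high component's mean plus one
    SD.
    """

    low_medium: float
    medium_high: float
    very_high: float

    @staticmethod
    def from_cluster(cluster: ClusterModel) -> "BandRules":
        if cluster.dim != 1 or cluster.K != 3:
            raise InvalidInputError("band rules require a univariate 3-class model")
        cuts = cluster.boundaries()
        hi = cluster.class_order[-1]
        mu = float(cluster.means[hi, 0] * cluster.scale_sd[-1] + cluster.scale_mean[-1])
        sd = float(
            np.sqrt(cluster.covariances[hi, 0, 0]) * cluster.scale_sd[-1]
        )
        return BandRules(cuts[0], cuts[1], mu + sd)

    def band(self, value: float) -> str:
        if value > self.very_high:
            return "very_high"
        if value > self.medium_high:
            return "high"
        if value > self.low_medium:
            return "medium"
        return "low"


@dataclass(frozen=True)
class LibraryPrediction:
    polymer_id: str
    mean_pred: float
    sd_pred: float
    band: str

    def as_record(self) -> dict:
        return {
            "polymer_id": self.polymer_id,
            "mean_pred": self.mean_pred,
            "sd_pred": self.sd_pred,
            "band": self.band,
        }


def predict_library(
    models: Sequence[MLPModel],
    X_rest: DescriptorTable,
    bands: BandRules,
    time: float | None = None,
) -> list[LibraryPrediction]:
    """Mean +/- SD prediction per remaining polymer across split models,
    banded and sorted from highest to lowest mean.

    ``time`` supplies the incubation-time feature value when the models
    were trained on the all-points target.
    """
    if not models:
        raise InvalidInputError("no split models supplied")
    feats = models[0].feature_names
    cols = []
    for f in feats:
        if f == TIME_FEATURE:
            if time is None:
                raise InvalidInputError(
                    "models use the time feature; supply a time value"
                )
            cols.append(np.full(X_rest.n_polymers, float(time)))
        else:
            try:
                cols.append(X_rest.column(f))
            except KeyError:
                raise InvalidInputError(
                    f"descriptor column {f!r} missing from library table"
                ) from None
    X = np.column_stack(cols)
    all_preds = np.array([predict(m, X) for m in models])  # (n_models, n_poly)
    mean = all_preds.mean(axis=0)
    sd = all_preds.std(axis=0, ddof=0)
    out = [
        LibraryPrediction(pid, float(m), float(s), bands.band(float(m)))
        for pid, m, s in zip(X_rest.polymer_ids, mean, sd)
    ]
    out.sort(key=lambda r: (-r.mean_pred, r.polymer_id))
    return out
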