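"""Config-driven orchestration of the full surrogate workflow.

Stages: simulate -> cluster -> select-descriptors -> train ->
crossvalidate -> predict-library.  Each stage reads only its declared
input artifacts from the run directory and writes its own outputs, so any
stage can be re-run in isolation.  All stage seeds are derived
deterministically from one master seed; a manifest captures config hash
and seeds (timings go to a separate file so artifacts are byte-stable).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .cluster import ClusterModel, EMSettings, assign_class, fit_em
from .core import (
    InvalidInputError,
    ModelingDataset,
    PlateauConfig,
)
from .evaluation import (
    BandRules,
    CVConfig,
    EvaluationReport,
    crossvalidate_pipeline,
    predict_library,
)
from .io import (
    read_descriptor_table,
    read_equilibrium_table,
    read_timeseries,
    write_descriptor_table,
    write_equilibrium_table,
    write_predictions,
    write_timeseries,
)
from .mlp import MLPHyperparams, train_seed_ensemble
from .selection import GASettings, SelectionConfig, select_descriptors
from .synthetic import GeneratorConfig, generate_library

log = logging.getLogger("polysorb")


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

__all__ = ["RunConfig", "run_pipeline", "run_stage", "compare_targets", "stage_seed"]

_STAGES = (
    "simulate",
    "cluster",
    "select-descriptors",
    "train",
    "crossvalidate",
    "predict-library",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (master seed x stage name)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    master_seed: int = 0
    target_kind: str = "equilibrium"  # or "all_points"
    # synthetic-library stage (ignored when external CSVs are supplied)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_train: int = 18  # first n polymers used for modelling; rest = library
    # external inputs (optional; override the simulate stage)
    descriptors_csv: str | None = None
    property_csv: str | None = None
    # module settings
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    em: EMSettings = field(default_factory=EMSettings)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    mlp: MLPHyperparams = field(default_factory=MLPHyperparams)
    cv: CVConfig = field(default_factory=CVConfig)

    def resolved(self) -> "RunConfig":
        """Thread the master seed into stage-level seed fields."""
        return replace(
            self,
            generator=replace(self.generator, seed=stage_seed(self.master_seed, "simulate")),
            selection=replace(
                self.selection,
                ga=replace(self.selection.ga, seed=stage_seed(self.master_seed, "ga")),
            ),
            cv=replace(
                self.cv,
                mlp=self.mlp,
                selection=replace(
                    self.selection,
                    ga=replace(self.selection.ga, seed=stage_seed(self.master_seed, "ga")),
                ),
                split_seed=stage_seed(self.master_seed, "splits"),
            ),
        )

    # -- YAML round trip --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # cv.mlp / cv.selection are always overridden from the top-level
        # settings when the config is resolved; do not serialize them
        d["cv"].pop("mlp", None)
        d["cv"].pop("selection", None)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(source: str | Path) -> "RunConfig":
        d = yaml.safe_load(_maybe_file(source)) or {}
        return RunConfig.from_dict(d)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        def sub(cls, key):
            v = dict(d.get(key) or {})
            for tup_key in ("target_range", "kinetics_rate_range", "times", "hidden_layout"):
                if tup_key in v and v[tup_key] is not None:
                    v[tup_key] = tuple(v[tup_key])
            return cls(**v)

        sel = dict(d.get("selection") or {})
        ga = GASettings(**(sel.pop("ga", None) or {}))
        tree_kwargs = sel.pop("tree", None) or {}
        from .selection import TreeSettings

        selection = SelectionConfig(ga=ga, tree=TreeSettings(**tree_kwargs), **sel)
        cv = dict(d.get("cv") or {})
        cv.pop("mlp", None)
        cv.pop("selection", None)
        return RunConfig(
            master_seed=d.get("master_seed", 0),
            target_kind=d.get("target_kind", "equilibrium"),
            generator=sub(GeneratorConfig, "generator"),
            n_train=d.get("n_train", 18),
            descriptors_csv=d.get("descriptors_csv"),
            property_csv=d.get("property_csv"),
            plateau=sub(PlateauConfig, "plateau"),
            em=sub(EMSettings, "em"),
            selection=selection,
            mlp=sub(MLPHyperparams, "mlp"),
            cv=CVConfig(**cv),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


# ---------------------------------------------------------------------------
# dataset loading shared by stages
# ---------------------------------------------------------------------------


def _load_training_dataset(cfg: RunConfig, outdir: Path) -> ModelingDataset:
    if cfg.descriptors_csv:
        table = read_descriptor_table(cfg.descriptors_csv)
        prop = Path(cfg.property_csv)
    else:
        table = read_descriptor_table(outdir / "descriptors.csv")
        prop = outdir / (
            "wu_equilibrium.csv" if cfg.target_kind == "equilibrium" else "wu_timeseries.csv"
        )
    train_ids = list(table.polymer_ids[: cfg.n_train]) if not cfg.descriptors_csv else list(
        table.polymer_ids
    )
    sub = table.rows(train_ids)
    keep = set(train_ids)
    import pandas as pd

    df = pd.read_csv(prop, nrows=1)
    if "time_days" in df.columns or "time_hours" in df.columns:
        series = [s for s in read_timeseries(prop) if s.polymer_id in keep]
        if cfg.target_kind == "all_points":
            return ModelingDataset.from_series(sub, series, cfg.plateau)
        from .core import estimate_equilibrium

        eqs = [estimate_equilibrium(s, cfg.plateau) for s in series]
        return ModelingDataset.from_equilibrium(sub, eqs)
    eqs = [e for e in read_equilibrium_table(prop) if e.polymer_id in keep]
    return ModelingDataset.from_equilibrium(sub, eqs)


def _cluster_points(cfg: RunConfig, ds: ModelingDataset) -> np.ndarray:
    if cfg.target_kind == "equilibrium":
        return np.array([[e.wu_eq] for e in ds.equilibrium])
    return np.column_stack([ds.point_times, ds.point_wu])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_stage(cfg: RunConfig, stage: str, outdir: str | Path) -> None:
    """Run one stage, reading prior artifacts from ``outdir``."""
    cfg = cfg.resolved()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()

    if stage == "simulate":
        table, series, eqs, truth = generate_library(cfg.generator)
        write_descriptor_table(outdir / "descriptors.csv", table)
        write_timeseries(outdir / "wu_timeseries.csv", series)
        write_equilibrium_table(outdir / "wu_equilibrium.csv", eqs)
        truth.to_json(outdir / "ground_truth.json")

    elif stage == "cluster":
        ds = _load_training_dataset(cfg, outdir)
        pts = _cluster_points(cfg, ds)
        model = fit_em(pts, K=3, seed=stage_seed(cfg.master_seed, "em"), settings=cfg.em)
        model.to_json(outdir / "cluster_model.json")
        labels = [
            {"unit_id": uid, "label": assign_class(model, pt)[0]}
            for uid, pt in zip(ds.unit_ids, pts)
        ]
        write_predictions(outdir / "labels.csv", labels)

    elif stage == "select-descriptors":
        ds = _load_training_dataset(cfg, outdir)
        model = ClusterModel.from_json(outdir / "cluster_model.json")
        progress: list = []
        sel = select_descriptors(ds, model, cfg.selection, ga_progress=progress)
        (outdir / "selection.json").write_text(json.dumps(sel.to_dict(), indent=1))
        (outdir / "ga_log.txt").write_text(
            "\n".join(f"generation {g}\tbest_merit {m:.6f}" for g, m in progress) + "\n"
        )

    elif stage == "train":
        ds = _load_training_dataset(cfg, outdir)
        sel = json.loads((outdir / "selection.json").read_text())
        feats = sel["final_descriptors"]
        X, y, names = ds.design_matrix()
        idx = [list(names).index(f) for f in feats]
        ens = train_seed_ensemble(X[:, idx], y, feats, cfg.mlp)
        ens.best_model.to_json(outdir / "model.json")
        write_predictions(
            outdir / "seeds_rmse.csv",
            [{"seed": s, "train_rmse": r} for s, r in ens.per_seed_rmse],
        )

    elif stage == "crossvalidate":
        ds = _load_training_dataset(cfg, outdir)
        model = ClusterModel.from_json(outdir / "cluster_model.json")
        sel = json.loads((outdir / "selection.json").read_text())
        report = crossvalidate_pipeline(
            ds, model, cfg.cv, features=sel["final_descriptors"]
        )
        report.to_json(outdir / "report.json")
        rows = [
            {
                "split": r["split"],
                "test_ids": ";".join(r["test_ids"]),
                "r2_train": r["r2_train"],
                "train_rmse": r["train_rmse"],
            }
            for r in report.per_split
        ]
        write_predictions(outdir / "per_split.csv", rows)
        # persist split models for the prediction stage
        (outdir / "split_models.json").write_text(
            json.dumps([json.loads(m.to_json()) for m in report.split_models])
        )

    elif stage == "predict-library":
        from .mlp import MLPModel

        ds = _load_training_dataset(cfg, outdir)
        cluster = ClusterModel.from_json(outdir / "cluster_model.json")
        if cluster.dim != 1:
            # banding is defined on the equilibrium scale
            eq_pts = np.array(
                [[e.wu_eq] for e in _load_training_dataset(
                    replace(cfg, target_kind="equilibrium"), outdir
                ).equilibrium]
            )
            cluster = fit_em(
                eq_pts, K=3, seed=stage_seed(cfg.master_seed, "em"), settings=cfg.em
            )
        bands = BandRules.from_cluster(cluster)
        models = [
            MLPModel.from_json(json.dumps(d))
            for d in json.loads((outdir / "split_models.json").read_text())
        ]
        table = read_descriptor_table(
            cfg.descriptors_csv or outdir / "descriptors.csv"
        )
        rest_ids = [p for p in table.polymer_ids if p not in set(ds.descriptors.polymer_ids)]
        rest = table.rows(rest_ids) if rest_ids else table
        time_val = max(cfg.generator.times) if cfg.target_kind == "all_points" else None
        preds = predict_library(models, rest, bands, time=time_val)
        write_predictions(outdir / "predictions.csv", [p.as_record() for p in preds])

    else:
        raise InvalidInputError(f"unknown stage {stage!r}")

    dt = _time.perf_counter() - t0
    log.info("stage %s finished in %.2fs (outdir=%s)", stage, dt, outdir)
    _record_timing(outdir, stage, dt)


def _record_timing(outdir: Path, stage: str, dt: float) -> None:
    path = outdir / "timings.json"
    data = json.loads(path.read_text()) if path.exists() else {}
    data[stage] = dt
    path.write_text(json.dumps(data, indent=1))


def run_pipeline(cfg: RunConfig, outdir: str | Path, stages: Sequence[str] = _STAGES) -> Path:
    """Run the stage sequence; halts on the failing stage by name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage == "simulate" and cfg.descriptors_csv:
            continue
        try:
            run_stage(cfg, stage, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": _plainify(cfg.to_dict()),
        "stage_seeds": {s: stage_seed(cfg.master_seed, s) for s in ("simulate", "em", "ga", "splits")},
        "version": __version__,
        "stages": list(stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


# ---------------------------------------------------------------------------
# consolidated-vs-all-points comparison
# ---------------------------------------------------------------------------


def compare_targets(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Fit both pipeline variants on the same synthetic library and
    tabulate the four headline metrics side by side.

    The all-points variant is cross-validated both row-wise (the permissive
    protocol: rows of one polymer may sit on both sides of a split) and
    grouped by polymer (honest: whole polymers held out), because rows of
    one time course are not independent.
    """
    cfg = cfg.resolved()
    table, series, eqs, truth = generate_library(cfg.generator)
    sub = table.rows(list(table.polymer_ids[: cfg.n_train]))
    eq_ds = ModelingDataset.from_equilibrium(
        sub, [e for e in eqs if e.polymer_id in set(sub.polymer_ids)]
    )
    ap_ds = ModelingDataset.from_series(
        sub, [s for s in series if s.polymer_id in set(sub.polymer_ids)], cfg.plateau
    )

    em_seed = stage_seed(cfg.master_seed, "em")
    eq_cluster = fit_em(
        np.array([[e.wu_eq] for e in eq_ds.equilibrium]), 3, em_seed, cfg.em
    )
    ap_cluster = fit_em(
        np.column_stack([ap_ds.point_times, ap_ds.point_wu]), 3, em_seed, cfg.em
    )

    cv = cfg.cv
    eq_rep = crossvalidate_pipeline(eq_ds, eq_cluster, cv)
    ap_row = crossvalidate_pipeline(ap_ds, ap_cluster, cv)
    ap_grp = crossvalidate_pipeline(
        ap_ds, ap_cluster, replace(cv, group_by_polymer=True),
        features=ap_row.features,
    )

    def cells(rep: EvaluationReport) -> dict:
        return {
            "r2_train": rep.r2_train,
            "frac_within_train": rep.frac_within_train,
            "r2_cv": rep.r2_cv,
            "frac_within_test": rep.frac_within_test,
            "class_accuracy_cv": rep.class_accuracy_cv,
            "n_splits": rep.n_splits,
        }

    result = {
        "equilibrium": cells(eq_rep),
        "all_points_rowwise": cells(ap_row),
        "all_points_grouped": cells(ap_grp),
    }
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "comparison.json").write_text(json.dumps(result, indent=1))
    return result
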