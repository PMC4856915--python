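"""statsmodels-style front end: a model object built from data whose
``fit()`` returns a results object with estimates, diagnostics and a
``summary()`` table.

``WaterUptakeModel`` bundles the whole surrogate workflow — mixture
discretization of the target, the descriptor-selection cascade, and the
seed-ensembled MLP — behind a two-object API:

>>> model = WaterUptakeModel(dataset, seed=7)      # doctest: +SKIP
>>> res = model.fit()                              # doctest: +SKIP
>>> print(res.summary())                           # doctest: +SKIP
>>> res.predict(library_table)                     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .cluster import ClusterModel, EMSettings, fit_em
from .core import DescriptorTable, ModelingDataset
from .evaluation import (
    BandRules,
    CVConfig,
    EvaluationReport,
    LibraryPrediction,
    crossvalidate_pipeline,
    predict_library,
)
from .mlp import MLPHyperparams, SeedEnsembleResult, predict as _mlp_predict, train_seed_ensemble
from .pipeline import stage_seed
from .selection import SelectionConfig, SelectionResult, select_descriptors

__all__ = ["WaterUptakeModel", "WaterUptakeResults"]


class WaterUptakeModel:
    """Surrogate model of (equilibrium) water uptake over a polymer library.

    Parameters
    ----------
    dataset : ModelingDataset
        Descriptors joined with the property target (equilibrium or
        all-points).
    seed : int
        Master seed; every stochastic stage derives its own seed from it.
    em, selection, mlp, cv : optional
        Stage settings; defaults follow the package's standard recipe
        (3-class mixture, CFS+GA -> tree -> regression cascade, 100-seed
        ensemble of [2]-hidden-node networks).
    """

    def __init__(
        self,
        dataset: ModelingDataset,
        seed: int = 0,
        em: EMSettings | None = None,
        selection: SelectionConfig | None = None,
        mlp: MLPHyperparams | None = None,
        cv: CVConfig | None = None,
    ) -> None:
        self.dataset = dataset
        self.seed = seed
        self.em_settings = em or EMSettings()
        sel = selection or SelectionConfig()
        self.selection_config = replace(
            sel, ga=replace(sel.ga, seed=stage_seed(seed, "ga"))
        )
        self.mlp_hyperparams = mlp or MLPHyperparams()
        base_cv = cv or CVConfig()
        self.cv_config = replace(
            base_cv,
            mlp=self.mlp_hyperparams,
            selection=self.selection_config,
            split_seed=stage_seed(seed, "splits"),
        )

    @classmethod
    def from_dataframe(
        cls, descriptors_df, equilibrium_df, **kwargs
    ) -> "WaterUptakeModel":
        """Build from two pandas frames: a descriptor table (first column
        ``polymer_id``) and an equilibrium table
        (``polymer_id, wu_eq_percent, sd_percent``)."""
        from .core import EquilibriumProperty

        names = [c for c in descriptors_df.columns if c != "polymer_id"]
        table = DescriptorTable(
            tuple(descriptors_df["polymer_id"].astype(str)),
            tuple(names),
            descriptors_df[names].to_numpy(dtype=float),
        )
        eqs = [
            EquilibriumProperty(str(r.polymer_id), float(r.wu_eq_percent), float(r.sd_percent))
            for r in equilibrium_df.itertuples()
        ]
        return cls(ModelingDataset.from_equilibrium(table, eqs), **kwargs)

    def fit(self, crossvalidate: bool = True) -> "WaterUptakeResults":
        """Run discretization, descriptor selection, ensemble training and
        (optionally) the exhaustive hold-out validation."""
        ds = self.dataset
        if ds.target_kind == "equilibrium":
            pts = np.array([[e.wu_eq] for e in ds.equilibrium])
        else:
            pts = np.column_stack([ds.point_times, ds.point_wu])
        cluster = fit_em(pts, K=3, seed=stage_seed(self.seed, "em"), settings=self.em_settings)
        selection = select_descriptors(ds, cluster, self.selection_config)
        X, y, names = ds.design_matrix()
        idx = [list(names).index(f) for f in selection.final_descriptors]
        ensemble = train_seed_ensemble(
            X[:, idx], y, selection.final_descriptors, self.mlp_hyperparams
        )
        report = (
            crossvalidate_pipeline(ds, cluster, self.cv_config, features=selection.final_descriptors)
            if crossvalidate
            else None
        )
        return WaterUptakeResults(self, cluster, selection, ensemble, report)


@dataclass
class WaterUptakeResults:
    """Fitted surrogate: selected descriptors, the best-of-seeds network,
    the class model, and cross-validation diagnostics."""

    model: WaterUptakeModel
    cluster: ClusterModel
    selection: SelectionResult
    ensemble: SeedEnsembleResult
    cv_report: EvaluationReport | None = None

    @property
    def features(self) -> tuple[str, ...]:
        return self.selection.final_descriptors

    @property
    def train_rmse(self) -> float:
        return self.ensemble.best_model.train_rmse

    def predict(self, descriptors: DescriptorTable, time: float | None = None) -> np.ndarray:
        """Point predictions from the best full-data network."""
        from .core import TIME_FEATURE

        cols = []
        for f in self.ensemble.best_model.feature_names:
            if f == TIME_FEATURE:
                cols.append(np.full(descriptors.n_polymers, float(time)))
            else:
                cols.append(descriptors.column(f))
        return _mlp_predict(self.ensemble.best_model, np.column_stack(cols))

    def predict_library(
        self, descriptors: DescriptorTable, time: float | None = None
    ) -> list[LibraryPrediction]:
        """Mean +/- SD predictions across split models with class bands;
        requires ``fit(crossvalidate=True)``."""
        if self.cv_report is None:
            raise ValueError("library prediction needs the cross-validated fit")
        if self.cluster.dim == 1:
            bands = BandRules.from_cluster(self.cluster)
        else:
            eqs = np.array([[e.wu_eq] for e in self.model.dataset.equilibrium]) \
                if self.model.dataset.target_kind == "equilibrium" else None
            if eqs is None:
                raise ValueError("banding requires an equilibrium target")
            bands = BandRules.from_cluster(self.cluster)
        return predict_library(self.cv_report.split_models, descriptors, bands, time=time)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        ds = self.model.dataset
        lines = [
            "Water-uptake surrogate model",
            "=" * 60,
            f"target:                 {ds.target_kind}",
            f"n units:                {len(ds.unit_ids)}",
            f"descriptors screened:   {ds.descriptors.n_descriptors}",
            f"selected descriptors:   {', '.join(self.features)}",
            f"  via tree ranking:     {', '.join(self.selection.tree_descriptors) or '-'}",
            f"  via regression:       {self.selection.regression_descriptor or '-'}",
            f"CFS merit of subset:    {self.selection.cfs_merit:.4f}",
            f"mixture classes (mean WU): "
            + ", ".join(
                f"{name}={float(self.cluster.means[k, -1] * self.cluster.scale_sd[-1] + self.cluster.scale_mean[-1]):.1f}%"
                for name, k in zip(self.cluster.class_names(), self.cluster.class_order)
            ),
            f"best-of-{len(self.ensemble.per_seed_rmse)} seeds train RMSE: {self.train_rmse:.3f} %",
        ]
        if self.cv_report is not None:
            r = self.cv_report
            lines += [
                "-" * 60,
                f"cross-validation:       {r.n_splits} splits"
                + (" (exhaustive)" if r.exhaustive else " (sampled)"),
                f"R^2 training (mean over splits):   {r.r2_train:.3f}",
                f"R^2 cross-validation (pooled):     {r.r2_cv:.3f}",
                f"within experimental SD (training): {r.frac_within_train:.0%}",
                f"within experimental SD (test):     {r.frac_within_test:.0%}",
                f"class accuracy (test, low/med/high): {r.class_accuracy_cv:.0%}",
            ]
        return "\n".join(lines)
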