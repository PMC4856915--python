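"""Hold-out splitting, headline metrics, CV driver, library prediction."""

from math import comb

import numpy as np
import pytest

from polysorb.cluster import fit_em
from polysorb.core import (
    DescriptorTable,
    EquilibriumProperty,
    InvalidInputError,
    ModelingDataset,
)
from polysorb.evaluation import (
    BandRules,
    CVConfig,
    EvaluationReport,
    class_accuracy,
    crossvalidate_pipeline,
    enumerate_splits,
    pearson,
    predict_library,
    r_squared,
    within_variability_fraction,
)
from polysorb.mlp import MLPHyperparams


class TestEnumerateSplits:
    def test_leave_two_out_of_eighteen(self):
        ids = [f"p{i}" for i in range(18)]
        scheme = enumerate_splits(ids, 0.10)
        assert scheme.test_size == 2
        assert len(scheme) == 153
        assert scheme.exhaustive

    def test_three_units_single_holdout(self):
        scheme = enumerate_splits(["a", "b", "c"], 0.10)
        assert scheme.test_size == 1
        assert len(scheme) == 3

    def test_each_id_appears_correct_number_of_times(self):
        ids = [f"p{i}" for i in range(10)]
        scheme = enumerate_splits(ids, 0.2)  # test size 2, C(10,2)=45 splits
        counts = {i: 0 for i in ids}
        for _, test in scheme.splits:
            for t in test:
                counts[t] += 1
        expected = comb(len(ids) - 1, scheme.test_size - 1)
        assert all(c == expected for c in counts.values())

    def test_no_duplicate_test_sets(self):
        scheme = enumerate_splits([f"p{i}" for i in range(12)], 0.2)
        tests = {frozenset(t) for _, t in scheme.splits}
        assert len(tests) == len(scheme)

    def test_train_test_partition(self):
        ids = [f"p{i}" for i in range(8)]
        scheme = enumerate_splits(ids, 0.25)
        for train, test in scheme.splits:
            assert sorted(train + test) == sorted(ids)
            assert not set(train) & set(test)

    def test_sampled_scheme_when_capped(self):
        ids = [f"p{i}" for i in range(18)]
        scheme = enumerate_splits(ids, 0.10, max_splits=20, seed=1)
        assert len(scheme) == 20
        assert not scheme.exhaustive
        tests = {frozenset(t) for _, t in scheme.splits}
        assert len(tests) == 20

    def test_too_small_rejected(self):
        with pytest.raises(InvalidInputError):
            enumerate_splits(["a", "b"], 0.1)


class TestMetrics:
    def test_within_variability_examples(self):
        eq = [EquilibriumProperty("succinate", 4.0, 0.3)]
        frac, flags = within_variability_fraction({"succinate": 4.2}, eq)
        assert frac == 1.0 and flags["succinate"]
        frac, flags = within_variability_fraction({"succinate": 5.0}, eq)
        assert frac == 0.0 and not flags["succinate"]

    def test_exact_predictions_all_within(self, reference_eqs):
        preds = {e.polymer_id: e.wu_eq for e in reference_eqs}
        frac, flags = within_variability_fraction(preds, reference_eqs)
        assert frac == 1.0
        assert sum(flags.values()) == 18

    def test_missing_id_rejected(self, reference_eqs):
        with pytest.raises(InvalidInputError):
            within_variability_fraction({"unknown": 1.0}, reference_eqs)

    def test_r_squared_sign_convention(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(-obs, obs) == pytest.approx(1.0)
        assert pearson(-obs, obs) == pytest.approx(-1.0)

    def test_r_squared_matches_direct_formula(self):
        preds = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        num = np.sum((preds - preds.mean()) * (obs - obs.mean()))
        den = np.sqrt(np.sum((preds - preds.mean()) ** 2) * np.sum((obs - obs.mean()) ** 2))
        assert r_squared(preds, obs) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_frac_within_monotone_in_sd_scale(self, reference_eqs):
        rng = np.random.default_rng(0)
        preds = {e.polymer_id: e.wu_eq + rng.normal(0, e.sd_exp) for e in reference_eqs}
        fracs = []
        for scale in (1.0, 0.5, 0.25, 0.1):
            scaled = [
                EquilibriumProperty(e.polymer_id, e.wu_eq, e.sd_exp * scale)
                for e in reference_eqs
            ]
            fracs.append(within_variability_fraction(preds, scaled)[0])
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))


class TestClassAccuracy:
    def test_perfect_predictions(self, reference_eqs):
        vals = np.array([e.wu_eq for e in reference_eqs])
        cl = fit_em(vals, K=3, seed=0)
        obs = {e.polymer_id: e.wu_eq for e in reference_eqs}
        assert class_accuracy(obs, obs, cl) == 1.0

    def test_all_predictions_pushed_high(self):
        # constructed toy with well-separated comparable-variance classes:
        # pushing every prediction just past the high boundary makes the
        # accuracy equal the observed-high fraction
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(5, 2, 8), rng.normal(50, 2, 6), rng.normal(100, 2, 4)]
        )
        cl = fit_em(vals, K=3, seed=0)
        obs = {f"p{i}": float(v) for i, v in enumerate(vals)}
        preds = {pid: 100.0 for pid in obs}
        from polysorb.cluster import assign_class

        observed_high = np.mean([assign_class(cl, [v])[0] == "high" for v in vals])
        assert class_accuracy(preds, obs, cl) == pytest.approx(observed_high)

    def test_single_class_degenerate_cluster(self):
        cl = fit_em(np.array([5.0, 5.1, 4.9, 5.0]), K=1, seed=0)
        preds = {"a": 1.0, "b": 9.0}
        obs = {"a": 5.0, "b": 5.0}
        assert class_accuracy(preds, obs, cl) == 1.0


class TestCrossvalidatePipeline:
    @pytest.fixture(scope="class")
    def cv_setup(self, small_library):
        table, _, eqs, truth = small_library
        ds = ModelingDataset.from_equilibrium(table, eqs)
        cl = fit_em(np.array([e.wu_eq for e in eqs]), K=3, seed=0)
        cfg = CVConfig(mlp=MLPHyperparams(n_seeds=3))
        report = crossvalidate_pipeline(ds, cl, cfg, features=truth.informative_names)
        return ds, cl, report

    def test_split_count_and_coverage(self, cv_setup):
        ds, _, report = cv_setup
        assert report.n_splits == 153
        # pooled predictions cover every polymer exactly once
        assert sorted(report.pooled_predictions) == sorted(ds.unit_ids)

    def test_report_serialization_round_trip(self, cv_setup, tmp_path):
        _, _, report = cv_setup
        path = tmp_path / "report.json"
        report.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.r2_cv == report.r2_cv
        assert back.frac_within_test == report.frac_within_test
        assert back.pooled_predictions == report.pooled_predictions

    def test_within_fraction_is_one_with_generous_sd(self, small_library):
        # zero-noise library, true descriptors forced, experimental SD set
        # far above the attainable fit error
        from polysorb.synthetic import GeneratorConfig, generate_library

        table, _, eqs, truth = generate_library(
            GeneratorConfig(n_polymers=10, n_descriptors=12, meas_noise_cv=0.0,
                            kinetics_rate_range=(2.0, 5.0), seed=21)
        )
        generous = [
            EquilibriumProperty(e.polymer_id, e.wu_eq, 40.0) for e in eqs
        ]
        ds = ModelingDataset.from_equilibrium(table, generous)
        cl = fit_em(np.array([e.wu_eq for e in generous]), K=3, seed=0)
        rep = crossvalidate_pipeline(
            ds, cl, CVConfig(mlp=MLPHyperparams(n_seeds=5)),
            features=truth.informative_names,
        )
        assert rep.frac_within_test == 1.0
        assert rep.frac_within_train == 1.0

    def test_ideal_metrics_attained_simultaneously(self, reference_eqs):
        # predictions identical to observations hit every ideal at once
        vals = np.array([e.wu_eq for e in reference_eqs])
        cl = fit_em(vals, K=3, seed=0)
        preds = {e.polymer_id: e.wu_eq for e in reference_eqs}
        obs = dict(preds)
        assert within_variability_fraction(preds, reference_eqs)[0] == 1.0
        assert r_squared(list(preds.values()), list(obs.values())) == pytest.approx(1.0)
        assert class_accuracy(preds, obs, cl) == 1.0


class TestPredictLibrary:
    @pytest.fixture(scope="class")
    def band_setup(self, reference_eqs):
        vals = np.array([e.wu_eq for e in reference_eqs])
        cl = fit_em(vals, K=3, seed=0)
        return BandRules.from_cluster(cl)

    def test_band_rules_are_ordered(self, band_setup):
        b = band_setup
        assert b.low_medium < b.medium_high < b.very_high
        assert b.band(b.low_medium - 1) == "low"
        assert b.band(0.5 * (b.low_medium + b.medium_high)) == "medium"
        assert b.band(0.5 * (b.medium_high + b.very_high)) == "high"
        assert b.band(b.very_high + 1) == "very_high"

    def test_single_model_gives_zero_sd(self, small_library, band_setup):
        table, _, eqs, truth = small_library
        from polysorb.mlp import train_seed_ensemble

        X = np.column_stack([table.column(n) for n in truth.informative_names])
        y = np.array([e.wu_eq for e in eqs])
        res = train_seed_ensemble(X, y, truth.informative_names,
                                  MLPHyperparams(n_seeds=2, epochs=100))
        preds = predict_library([res.best_model], table, band_setup)
        assert all(p.sd_pred == 0.0 for p in preds)
        means = [p.mean_pred for p in preds]
        assert means == sorted(means, reverse=True)

    def test_duplicated_polymer_rows_get_identical_predictions(
        self, small_library, band_setup
    ):
        table, _, eqs, truth = small_library
        from polysorb.mlp import train_seed_ensemble

        X = np.column_stack([table.column(n) for n in truth.informative_names])
        y = np.array([e.wu_eq for e in eqs])
        res = train_seed_ensemble(X, y, truth.informative_names,
                                  MLPHyperparams(n_seeds=2, epochs=100))
        dup = DescriptorTable(
            ("orig", "copy"),
            table.descriptor_names,
            np.vstack([table.values[0], table.values[0]]),
        )
        preds = {p.polymer_id: p.mean_pred for p in
                 predict_library([res.best_model], dup, band_setup)}
        assert preds["orig"] == preds["copy"]

    def test_missing_descriptor_column_is_named(self, small_library, band_setup):
        table, _, eqs, truth = small_library
        from polysorb.mlp import train_seed_ensemble

        X = np.column_stack([table.column(n) for n in truth.informative_names])
        y = np.array([e.wu_eq for e in eqs])
        res = train_seed_ensemble(X, y, truth.informative_names,
                                  MLPHyperparams(n_seeds=1, epochs=50))
        crippled = DescriptorTable(
            table.polymer_ids, ("other",), table.values[:, :1]
        )
        with pytest.raises(InvalidInputError, match=truth.informative_names[0]):
            predict_library([res.best_model], crippled, band_setup)

    def test_rank_recovery_with_true_descriptors(self):
        # held-out 38 polymers; models trained on 18 with the true inputs
        from scipy.stats import spearmanr

        from polysorb.synthetic import GeneratorConfig, generate_library

        table, _, eqs, truth = generate_library(GeneratorConfig(n_polymers=56, seed=0))
        train = table.rows(list(table.polymer_ids[:18]))
        ds = ModelingDataset.from_equilibrium(train, eqs[:18])
        cl = fit_em(np.array([e.wu_eq for e in eqs[:18]]), K=3, seed=0)
        rep = crossvalidate_pipeline(
            ds, cl, CVConfig(mlp=MLPHyperparams(n_seeds=5), max_splits=40),
            features=truth.informative_names,
        )
        rest = table.rows(list(table.polymer_ids[18:]))
        preds = predict_library(rep.split_models, rest, BandRules.from_cluster(cl))
        pm = {p.polymer_id: p.mean_pred for p in preds}
        rho = spearmanr(
            [pm[p] for p in rest.polymer_ids],
            [truth.true_wu_eq[p] for p in rest.polymer_ids],
        ).statistic
        assert rho > 0.7
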