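import numpy as np
import pandas as pd
import pytest

from promolearn import (
    EstimatorSpec,
    confusion_matrix,
    cross_validate,
    feature_importance,
    fit_estimator,
    make_target_spec,
    select_positions,
    split_train_test,
)
from promolearn.errors import EstimatorError
from promolearn.evaluate import export_artifacts, export_tree_rules, importance_to_frame
from promolearn.library import PromoterLibrary, PromoterRecord
from promolearn.synthetic import generate_library, planted_spec

from conftest import make_library


@pytest.fixture(scope="module")
def signal_library():
    spec = planted_spec(R=15, S=150, n_causal=3, mutation_rate=0.2,
                        noise_fraction=0.05, seed=8)
    return generate_library(spec)


@pytest.fixture(scope="module")
def rf_classifier(signal_library):
    lib, _ = signal_library
    espec = EstimatorSpec("RF", "classification", grid={"n_estimators": [100]})
    fspec = select_positions(lib, 0.0)
    tspec = make_target_spec(lib.expression_values(), 3)
    return fit_estimator(lib, espec, fspec, tspec, {"n_estimators": 100})


class TestCrossValidate:
    def test_produces_requested_score_pairs(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [50]})
        report = cross_validate(lib, espec, response_value=1, repeats=25,
                                seed=0, params={"n_estimators": 50})
        assert len(report.per_repeat_scores) == 25
        assert report.metric == "r2"

    def test_planted_regression_signal_recovered(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [100]})
        report = cross_validate(lib, espec, response_value=1, repeats=10,
                                seed=1, params={"n_estimators": 100})
        assert report.mean_test >= 0.8

    def test_cov_definition_matches_recomputation(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [30]})
        report = cross_validate(lib, espec, response_value=1, repeats=8,
                                seed=2, params={"n_estimators": 30})
        scores = report.test_scores
        assert report.cov_test == pytest.approx(
            scores.std(ddof=1) / scores.mean()
        )

    def test_zero_spread_scores_have_zero_cov(self):
        # CoV is sd/mean of the stored per-repeat test scores
        from promolearn.evaluate import EvaluationReport

        report = EvaluationReport(
            metric="r2",
            per_repeat_scores=((2.0, 2.0),) * 4,
            mean_test=2.0, sd_test=0.0, cov_test=0.0,
            excluded_repeats=(), confusion=None, mcc=None, settings={},
        )
        assert report.test_scores.std(ddof=1) / report.test_scores.mean() == 0.0
        assert report.cov_test == 0.0

    def test_no_sequence_spans_any_split(self, signal_library):
        lib, _ = signal_library
        for rep in range(25):
            train, test = split_train_test(lib, 0.9, seed=100 + rep)
            assert set(train.sequences).isdisjoint(test.sequences)

    def test_classification_reports_f1_and_confusion(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "classification", grid={"n_estimators": [50]})
        report = cross_validate(lib, espec, response_value=3, repeats=5,
                                seed=3, params={"n_estimators": 50},
                                compute_mcc=True)
        assert report.metric == "f1_weighted"
        assert report.confusion is not None
        assert report.mcc is not None

    def test_task_mismatch_rejected(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [10]})
        with pytest.raises(ValueError, match="task"):
            cross_validate(lib, espec, response_value=3, repeats=2)


class TestConfusionMatrix:
    def test_entries_sum_to_library_size(self, rf_classifier, signal_library):
        lib, _ = signal_library
        cm = confusion_matrix(rf_classifier, lib)
        assert cm.sum() == lib.size
        assert cm.shape == (3, 3)

    def test_perfect_predictor_is_diagonal(self, rf_classifier, signal_library):
        # evaluated on its own deep training set the forest is near-perfect;
        # check structure on the training library itself
        lib, _ = signal_library
        cm = confusion_matrix(rf_classifier, lib)
        assert np.trace(cm) >= 0.9 * lib.size

    def test_regression_estimator_rejected(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [10]})
        fspec = select_positions(lib, 0.0)
        tspec = make_target_spec(lib.expression_values(), 1)
        est = fit_estimator(lib, espec, fspec, tspec, {"n_estimators": 10})
        with pytest.raises(EstimatorError):
            confusion_matrix(est, lib)


class TestFeatureImportance:
    def test_importances_sum_to_one(self, rf_classifier):
        profile = feature_importance(rf_classifier)
        total = profile.matrix.sum() + (profile.gc_importance or 0.0)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert (profile.matrix >= 0).all()

    def test_causal_positions_dominate(self, signal_library):
        lib, truth = signal_library
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [300]})
        fspec = select_positions(lib, 0.0)
        tspec = make_target_spec(lib.expression_values(), 1)
        est = fit_estimator(lib, espec, fspec, tspec, {"n_estimators": 300})
        profile = feature_importance(est)
        totals = profile.position_totals()
        top3 = {profile.positions[i] for i in np.argsort(totals)[::-1][:3]}
        assert top3 == set(truth.causal_labels)

    def test_svm_has_no_importance(self, signal_library):
        lib, _ = signal_library
        espec = EstimatorSpec("SVM", "regression", grid={"C": [1.0]})
        fspec = select_positions(lib, 0.0)
        tspec = make_target_spec(lib.expression_values(), 1)
        est = fit_estimator(lib, espec, fspec, tspec, {"C": 1.0})
        with pytest.raises(EstimatorError):
            feature_importance(est)


class TestExports:
    def test_importance_csv_round_trips(self, rf_classifier, tmp_path):
        profile = feature_importance(rf_classifier)
        frame = importance_to_frame(profile)
        path = tmp_path / "imp.csv"
        frame.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.values, frame.values)
        assert list(back.index) == list(frame.index)

    def test_export_writes_expected_files(self, rf_classifier, signal_library,
                                          tmp_path):
        lib, _ = signal_library
        espec = EstimatorSpec("RF", "classification", grid={"n_estimators": [20]})
        report = cross_validate(lib, espec, response_value=3, repeats=3,
                                seed=4, params={"n_estimators": 20})
        profile = feature_importance(rf_classifier)
        files = export_artifacts(report, profile, rf_classifier,
                                 tmp_path / "run", tree_index=0)
        assert all(f.exists() for f in files)
        assert len(files) == 3

    def test_tree_index_out_of_range(self, rf_classifier):
        with pytest.raises(IndexError):
            export_tree_rules(rf_classifier, tree_index=10_000)

    def test_stump_reproduces_manual_split_rule(self):
        # one informative position: A at the only varying site doubles output
        rows = [("AAAA", 2.0)] * 6 + [("CAAA", 1.0)] * 6
        lib = make_library([(s, v + i * 1e-9) for i, (s, v) in enumerate(rows)])
        espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [1]})
        fspec = select_positions(lib, 0.0)
        tspec = make_target_spec(lib.expression_values(), 1)
        est = fit_estimator(
            lib, espec, fspec, tspec,
            {"n_estimators": 1, "max_depth": 1, "bootstrap": False},
        )
        rules = export_tree_rules(est, 0)
        # the single split must use the only informative site (one-hot
        # indicator of the varying position, or the equivalent GC feature)
        assert any(tok in rules for tok in ("-4:A", "-4:C", "GC"))
        # the two leaves reproduce the two group means
        assert "2.0" in rules and "1.0" in rules


def test_permuted_targets_are_not_learnable():
    """Negative control: shuffled labels give chance-level scores."""
    spec = planted_spec(R=15, S=150, n_causal=3, mutation_rate=0.2,
                        noise_fraction=0.05, seed=8)
    lib, _ = generate_library(spec)
    rng = np.random.default_rng(99)
    shuffled = rng.permutation(lib.expression_values())
    permuted = PromoterLibrary(
        records=tuple(
            PromoterRecord(r.id, r.sequence, (float(v),))
            for r, v in zip(lib.records, shuffled)
        ),
        position_labels=lib.position_labels,
    )
    espec = EstimatorSpec("RF", "regression", grid={"n_estimators": [100]})
    report = cross_validate(permuted, espec, response_value=1, repeats=10,
                            seed=5, params={"n_estimators": 100})
    assert report.mean_test <= 0.1
    cls = EstimatorSpec("RF", "classification", grid={"n_estimators": [100]})
    f1_report = cross_validate(permuted, cls, response_value=3, repeats=10,
                               seed=6, params={"n_estimators": 100})
    chance = 1.0 / 3.0  # balanced 3-class problem
    assert abs(f1_report.mean_test - chance) <= 3 * f1_report.sd_test
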