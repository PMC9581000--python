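"""Performance evaluation: repeated replicate-joint cross-validation,
prediction confidence, feature importance and artifact export.

The evaluation scheme repeats a 9:1 replicate-joint split (default 25
times); on each repeat feature selection and target encoding are
re-derived on the training fold only, the estimator is refit, and train
and test scores are recorded. Prediction confidence is summarized as the
coefficient of variation (sd/mean) of the per-repeat test scores — the
smaller the CoV, the more stable the estimator under resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import matthews_corrcoef
from sklearn.tree import export_text

from .errors import EstimatorError
from .featurize import (
    FeatureSpec,
    make_target_spec,
    one_hot_encode,
    select_positions,
    split_train_test,
)
from .library import NUCLEOTIDES, PromoterLibrary
from .train import (
    EstimatorSpec,
    TrainedEstimator,
    fit_estimator,
    score_predictions,
)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-repeat train/test scores and their summary statistics."""

    metric: str
    per_repeat_scores: tuple[tuple[float, float], ...]  # (train, test)
    mean_test: float
    sd_test: float
    cov_test: float
    excluded_repeats: tuple[int, ...]
    confusion: np.ndarray | None
    mcc: float | None
    settings: dict

    @property
    def test_scores(self) -> np.ndarray:
        return np.array([t for _, t in self.per_repeat_scores])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": range(len(self.per_repeat_scores)),
                "train_score": [tr for tr, _ in self.per_repeat_scores],
                "test_score": [te for _, te in self.per_repeat_scores],
                "metric": self.metric,
            }
        )


@dataclass(frozen=True)
class ImportanceProfile:
    """Impurity importances mapped back to (nucleotide, position) cells.

    ``matrix`` is 4 x P (rows A, C, G, T over the retained positions);
    ``gc_importance`` is the scalar share of the GC-content feature. For
    tree ensembles the total importance sums to 1.
    """

    matrix: np.ndarray
    gc_importance: float | None
    positions: tuple[int, ...]
    top_k: tuple[tuple[int, str, float], ...]

    def position_totals(self) -> np.ndarray:
        """Importance aggregated per position (summed over nucleotides)."""
        return self.matrix.sum(axis=0)


def cross_validate(
    lib: PromoterLibrary,
    espec: EstimatorSpec,
    response_value: int,
    entropy_cutoff_bits: float = 0.0,
    include_gc: bool = True,
    repeats: int = 25,
    train_fraction: float = 0.9,
    seed: int = 0,
    params: dict | None = None,
    compute_mcc: bool = False,
) -> EvaluationReport:
    """Repeated replicate-joint cross-validation of one estimator setting.

    Feature selection (entropy cutoff) and target encoding (bins or
    scaler) are re-derived inside every repeat from the training fold
    only, so no information leaks from test data. A repeat whose training
    fold misses a class is excluded with a warning; more than half
    excluded is an error.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    task = "regression" if response_value <= 1 else "classification"
    if espec.task != task:
        raise ValueError(
            f"estimator task {espec.task!r} does not match response_value "
            f"{response_value}"
        )
    scores: list[tuple[float, float]] = []
    excluded: list[int] = []
    confusions = []
    mcc_values = []
    for rep in range(repeats):
        train, test = split_train_test(lib, train_fraction, seed=seed + rep)
        try:
            fspec = select_positions(train, entropy_cutoff_bits, include_gc)
            tspec = make_target_spec(train.expression_values(), response_value)
            est = fit_estimator(train, espec, fspec, tspec, params)
        except Exception as exc:
            warnings.warn(f"repeat {rep} excluded: {exc}", stacklevel=2)
            excluded.append(rep)
            continue
        Xtr, Xte = one_hot_encode(train, fspec), one_hot_encode(test, fspec)
        ytr = tspec.encode(train.expression_values())
        yte = tspec.encode(test.expression_values())
        ptr, pte = est.model.predict(Xtr), est.model.predict(Xte)
        scores.append(
            (
                score_predictions(task, ytr, ptr),
                score_predictions(task, yte, pte),
            )
        )
        if task == "classification":
            k = tspec.n_classes
            confusions.append(_sk_confusion(yte, pte, labels=range(k)))
            if compute_mcc:
                mcc_values.append(matthews_corrcoef(yte, pte))
    if len(excluded) > repeats / 2:
        raise RuntimeError(
            f"{len(excluded)} of {repeats} repeats were excluded; "
            "the library is too degenerate to evaluate"
        )
    test_scores = np.array([t for _, t in scores])
    mean, sd = float(test_scores.mean()), float(test_scores.std(ddof=1))
    if abs(mean) < 1e-3:
        warnings.warn(
            "mean test score is near zero; the coefficient of variation is "
            "numerically unstable",
            stacklevel=2,
        )
    return EvaluationReport(
        metric="r2" if task == "regression" else "f1_weighted",
        per_repeat_scores=tuple(scores),
        mean_test=mean,
        sd_test=sd,
        cov_test=sd / mean if mean != 0 else float("inf"),
        excluded_repeats=tuple(excluded),
        confusion=(
            np.sum(confusions, axis=0) if confusions else None
        ),
        mcc=float(np.mean(mcc_values)) if mcc_values else None,
        settings={
            "kind": espec.kind,
            "response_value": response_value,
            "entropy_cutoff_bits": entropy_cutoff_bits,
            "repeats": repeats,
            "train_fraction": train_fraction,
            "seed": seed,
            "params": params or {},
        },
    )


def confusion_matrix(est: TrainedEstimator, lib: PromoterLibrary) -> np.ndarray:
    """k x k confusion matrix (rows = true class, columns = predicted).

    True classes come from applying the estimator's learned bin edges to
    the library's expression values; entries sum to the library size.
    """
    if est.target_spec.task != "classification":
        raise EstimatorError("confusion matrix requires a classification estimator")
    y_true = est.target_spec.encode(lib.expression_values())
    y_pred = est.predict(lib.sequences)
    k = est.target_spec.n_classes
    return _sk_confusion(y_true, y_pred, labels=range(k))


def feature_importance(est: TrainedEstimator, top_k: int = 10) -> ImportanceProfile:
    """Impurity-based importances of a tree ensemble, per nucleotide cell.

    Only RF and GBT expose impurity importances; SVM raises.
    """
    if est.spec.kind not in {"RF", "GBT"}:
        raise EstimatorError(
            f"feature importance is only defined for tree ensembles, "
            f"not {est.spec.kind}"
        )
    imp = np.asarray(est.model.feature_importances_, dtype=float)
    fspec = est.feature_spec
    P = len(fspec.retained_positions)
    block = imp[: 4 * P].reshape(P, 4).T  # rows A,C,G,T
    gc = float(imp[4 * P]) if fspec.include_gc else None
    cells = [
        (pos, NUCLEOTIDES[b], float(block[b, j]))
        for j, pos in enumerate(fspec.retained_positions)
        for b in range(4)
    ]
    cells.sort(key=lambda c: c[2], reverse=True)
    return ImportanceProfile(
        matrix=block,
        gc_importance=gc,
        positions=fspec.retained_positions,
        top_k=tuple(cells[:top_k]),
    )


def importance_to_frame(profile: ImportanceProfile) -> pd.DataFrame:
    """Logo-ready table: rows A, C, G, T (+GC), columns = position labels.

    The scalar GC importance occupies a dedicated ``GC`` column on a
    dedicated ``GC`` row; nucleotide rows are zero there and vice versa,
    so the frame round-trips to the identical matrix.
    """
    cols = [str(p) for p in profile.positions]
    frame = pd.DataFrame(profile.matrix, index=list(NUCLEOTIDES), columns=cols)
    if profile.gc_importance is not None:
        frame["GC"] = 0.0
        frame.loc["GC"] = 0.0
        frame.loc["GC", "GC"] = profile.gc_importance
    return frame


def export_tree_rules(est: TrainedEstimator, tree_index: int = 0) -> str:
    """Human-readable split rules of one tree of the ensemble."""
    if est.spec.kind not in {"RF", "GBT"}:
        raise EstimatorError("tree export requires a tree ensemble (RF or GBT)")
    trees = np.asarray(est.model.estimators_).ravel()
    if not 0 <= tree_index < len(trees):
        raise IndexError(
            f"tree index {tree_index} out of range for ensemble of {len(trees)}"
        )
    return export_text(
        trees[tree_index], feature_names=est.feature_spec.feature_names()
    )


def export_artifacts(
    report: EvaluationReport,
    profile: ImportanceProfile | None,
    est: TrainedEstimator | None,
    out_prefix: str | Path,
    tree_index: int | None = None,
) -> list[Path]:
    """Write evaluation and importance tables as CSV (plus optional tree).

    Returns the list of files written: ``<prefix>.cv_scores.csv``,
    ``<prefix>.importance.csv`` (when a profile is given; consumable by
    logo renderers) and ``<prefix>.tree_<i>.txt`` when requested.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    scores_path = out_prefix.with_name(out_prefix.name + ".cv_scores.csv")
    report.to_frame().to_csv(scores_path, index=False)
    written.append(scores_path)
    if profile is not None:
        imp_path = out_prefix.with_name(out_prefix.name + ".importance.csv")
        importance_to_frame(profile).to_csv(imp_path)
        written.append(imp_path)
    if tree_index is not None:
        if est is None:
            raise ValueError("tree export needs the trained estimator")
        tree_path = out_prefix.with_name(
            out_prefix.name + f".tree_{tree_index}.txt"
        )
        tree_path.write_text(export_tree_rules(est, tree_index))
        written.append(tree_path)
    return written
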