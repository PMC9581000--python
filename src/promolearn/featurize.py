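"""Model inputs and targets from a promoter library.

Features are the one-hot encoded nucleotides of entropy-selected positions
plus (optionally) the overall sequence GC content; the feature vector has
width 4*P + 1 for P retained positions. Targets follow the
``response_value`` convention: 0 = standardized regression, 1 = raw-value
regression, k >= 2 = classification into k equal-frequency expression bins.

Train/test splitting is replicate-joint: records sharing the exact same
sequence string always land on the same side of the split, so test
sequences are genuinely unseen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BinningError, FeatureSelectionError, SequenceLengthError
from .library import NUCLEOTIDES, PromoterLibrary, encode_sequences, validate_sequence
from .stats import position_entropy


@dataclass(frozen=True)
class FeatureSpec:
    """Which positions feed the model and how they are encoded.

    ``retained_positions`` keeps the original coordinate order; feature
    columns are position-major, nucleotide-minor (A, C, G, T), with the GC
    column last when ``include_gc`` is set.
    """

    retained_positions: tuple[int, ...]
    include_gc: bool = True
    entropy_cutoff_bits: float = 0.0
    nucleotide_order: tuple[str, ...] = NUCLEOTIDES

    @property
    def n_features(self) -> int:
        return 4 * len(self.retained_positions) + (1 if self.include_gc else 0)

    def feature_names(self) -> list[str]:
        names = [
            f"{pos}:{nt}"
            for pos in self.retained_positions
            for nt in self.nucleotide_order
        ]
        if self.include_gc:
            names.append("GC")
        return names


@dataclass(frozen=True)
class Scaler:
    """Affine target scaler (zero mean, unit variance; population sd)."""

    mean: float
    sd: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


@dataclass(frozen=True)
class TargetSpec:
    """Target encoding for training and prediction.

    For classification, ``bin_edges`` are the k+1 quantile edges learned on
    training data; values beyond the outer edges clamp to the extreme
    classes so a test value never falls outside the label range.
    """

    task: str  # "regression" | "classification"
    response_value: int
    bin_edges: tuple[float, ...] | None = None
    scaler: Scaler | None = None

    @property
    def n_classes(self) -> int:
        if self.task != "classification" or self.bin_edges is None:
            return 0
        return len(self.bin_edges) - 1

    def encode(self, values: np.ndarray) -> np.ndarray:
        if self.task == "classification":
            return apply_bins(values, np.asarray(self.bin_edges))
        if self.scaler is not None:
            return self.scaler.transform(values)
        return np.asarray(values, dtype=float)

    def decode(self, predicted: np.ndarray) -> np.ndarray:
        if self.task == "regression" and self.scaler is not None:
            return self.scaler.inverse(predicted)
        return np.asarray(predicted)


def select_positions(
    train_lib: PromoterLibrary,
    cutoff_bits: float,
    include_gc: bool = True,
) -> FeatureSpec:
    """Retain positions whose training-set entropy exceeds *cutoff_bits*.

    The cutoff is strict (H_i > cutoff) and must be applied to the
    training subset only, so test data never influences feature selection.
    Raises :class:`FeatureSelectionError` if no position survives.
    """
    if not 0.0 <= cutoff_bits <= 2.0:
        raise ValueError(f"entropy cutoff must lie in [0, 2] bits, got {cutoff_bits}")
    profile = position_entropy(train_lib)
    retained = tuple(
        pos
        for pos, h in zip(profile.position_labels, profile.entropy_bits)
        if h > cutoff_bits
    )
    if not retained:
        raise FeatureSelectionError(
            f"entropy cutoff {cutoff_bits} bits removed every position; "
            "lower the cutoff"
        )
    return FeatureSpec(
        retained_positions=retained,
        include_gc=include_gc,
        entropy_cutoff_bits=cutoff_bits,
    )


def one_hot_encode(lib: PromoterLibrary, spec: FeatureSpec) -> np.ndarray:
    """(S, F) feature matrix for *lib* under *spec*.

    GC content is always computed on the full-length sequence, not only the
    retained positions.
    """
    label_to_idx = {pos: i for i, pos in enumerate(lib.position_labels)}
    try:
        cols = [label_to_idx[pos] for pos in spec.retained_positions]
    except KeyError as exc:
        raise ValueError(
            f"feature spec references position {exc.args[0]} absent from the library"
        ) from exc
    codes = lib.sequence_matrix()[:, cols]
    S, P = codes.shape
    onehot = np.zeros((S, P, 4))
    onehot[np.arange(S)[:, None], np.arange(P), codes] = 1.0
    X = onehot.reshape(S, 4 * P)
    if spec.include_gc:
        full = lib.sequence_matrix()
        gc = ((full == 1) | (full == 2)).mean(axis=1)  # C=1, G=2
        X = np.column_stack([X, gc])
    return X


def encode_sequences_features(
    sequences: list[str], spec: FeatureSpec, position_labels: tuple[int, ...]
) -> np.ndarray:
    """Feature matrix for raw sequences (prediction path).

    Sequences must have the training library's length; positions are
    interpreted through *position_labels*.
    """
    R = len(position_labels)
    for seq in sequences:
        validate_sequence(seq)
        if len(seq) != R:
            raise SequenceLengthError(
                f"sequence length {len(seq)} != expected {R}"
            )
    label_to_idx = {pos: i for i, pos in enumerate(position_labels)}
    cols = [label_to_idx[pos] for pos in spec.retained_positions]
    codes_full = encode_sequences(sequences)
    codes = codes_full[:, cols]
    S, P = codes.shape
    onehot = np.zeros((S, P, 4))
    onehot[np.arange(S)[:, None], np.arange(P), codes] = 1.0
    X = onehot.reshape(S, 4 * P)
    if spec.include_gc:
        gc = ((codes_full == 1) | (codes_full == 2)).mean(axis=1)
        X = np.column_stack([X, gc])
    return X


def bin_targets(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency (quantile) binning into k classes labelled 0..k-1.

    Returns (labels, bin_edges). With distinct values the class sizes
    differ by at most one. Raises :class:`BinningError` when fewer than k
    distinct values exist (quantile edges would collapse).
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError(f"number of classes k must be >= 2, got {k}")
    if len(np.unique(values)) < k:
        raise BinningError(
            f"need at least {k} distinct expression values for {k} classes; "
            "use a smaller response_value"
        )
    try:
        labels, edges = pd.qcut(
            values, q=k, labels=False, retbins=True, duplicates="raise"
        )
    except ValueError as exc:
        raise BinningError(
            f"quantile edges are not unique for k={k}; use a smaller "
            "response_value"
        ) from exc
    return np.asarray(labels, dtype=int), np.asarray(edges, dtype=float)


def apply_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign class labels from previously learned bin edges.

    Values outside the outer edges clamp to class 0 or k-1, so bins
    learned on training data apply safely to test data.
    """
    values = np.asarray(values, dtype=float)
    k = len(edges) - 1
    labels = np.searchsorted(edges[1:-1], values, side="left")
    return np.clip(labels, 0, k - 1)


def standardize_targets(values: np.ndarray) -> tuple[np.ndarray, Scaler]:
    """Center to zero mean and scale to unit (population) variance."""
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=0))
    if sd == 0:
        raise ValueError("cannot standardize targets with zero variance")
    scaler = Scaler(mean=float(values.mean()), sd=sd)
    return scaler.transform(values), scaler


def make_target_spec(
    train_values: np.ndarray, response_value: int
) -> TargetSpec:
    """Build the target encoding for a given ``response_value``.

    0 → regression on standardized values; 1 → regression on raw values;
    k >= 2 → classification into k quantile bins learned on *train_values*.
    """
    if response_value == 0:
        _, scaler = standardize_targets(train_values)
        return TargetSpec("regression", 0, scaler=scaler)
    if response_value == 1:
        return TargetSpec("regression", 1)
    _, edges = bin_targets(train_values, response_value)
    return TargetSpec(
        "classification", response_value, bin_edges=tuple(edges)
    )


def split_train_test(
    lib: PromoterLibrary, train_fraction: float, seed: int
) -> tuple[PromoterLibrary, PromoterLibrary]:
    """Replicate-joint train/test split.

    Records are grouped by exact sequence string and whole groups are
    assigned to one side, so replicates never leak across the split. The
    number of test groups is ceil(G * (1 - train_fraction)) for G groups;
    a 63-group library at the default 0.9 therefore splits 56:7. Seeded
    and reproducible; record order within each side is preserved.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(lib):
        groups.setdefault(rec.sequence, []).append(i)
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError(
            "replicate-joint split needs at least 2 distinct sequences"
        )
    n_test = math.ceil(len(keys) * (1.0 - train_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    test_keys = {keys[i] for i in order[:n_test]}
    test_idx = sorted(i for k in test_keys for i in groups[k])
    train_idx = sorted(
        i for k in keys if k not in test_keys for i in groups[k]
    )
    return lib.subset(train_idx), lib.subset(test_idx)
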