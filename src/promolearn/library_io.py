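"""Reading, validating, transforming and writing promoter-library tables.

The interchange format is a header-bearing CSV with at least an identifier
column, a DNA sequence column (A/C/G/T, all rows the same length) and one
or more numeric expression columns; optional standard-deviation and
replicate-count columns enable replicate regeneration. Column names come
from a :class:`~promolearn.config.WorkflowConfig`.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import WorkflowConfig
from .errors import (
    ConfigurationError,
    DuplicateIdError,
    ExpressionParseError,
    SequenceLengthError,
)
from .library import PromoterLibrary, PromoterRecord, validate_sequence


def read_library(path: str | Path, config: WorkflowConfig) -> PromoterLibrary:
    """Load and validate a promoter library CSV.

    Raises :class:`ConfigurationError` if a configured column is missing,
    :class:`AlphabetError` for non-ACGT sequences (naming the record),
    :class:`SequenceLengthError` for unequal sequence lengths, and
    :class:`ExpressionParseError` for non-numeric expression values.
    """
    frame = pd.read_csv(path, dtype=str)
    needed = [config.id_col, config.seq_col, *config.expr_cols]
    if config.sd_col:
        needed.append(config.sd_col)
    if config.rep_col:
        needed.append(config.rep_col)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: configured column(s) {missing} not found in header "
            f"{list(frame.columns)}"
        )
    records = []
    for _, row in frame.iterrows():
        rec_id = str(row[config.id_col])
        sequence = validate_sequence(str(row[config.seq_col]).strip(), rec_id)
        expression = []
        for col in config.expr_cols:
            try:
                expression.append(float(row[col]))
            except (TypeError, ValueError) as exc:
                raise ExpressionParseError(
                    f"record {rec_id!r}: non-numeric expression value "
                    f"{row[col]!r} in column {col!r}"
                ) from exc
        sd = n_rep = None
        if config.sd_col and not _is_missing(row[config.sd_col]):
            sd = float(row[config.sd_col])
        if config.rep_col and not _is_missing(row[config.rep_col]):
            n_rep = int(float(row[config.rep_col]))
        records.append(
            PromoterRecord(rec_id, sequence, tuple(expression), sd, n_rep)
        )
    return PromoterLibrary(
        records=tuple(records), expression_columns=config.expr_cols
    )


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def write_library(
    lib: PromoterLibrary, path: str | Path, config: WorkflowConfig | None = None
) -> None:
    """Write a library CSV readable back with the same configuration."""
    config = config or WorkflowConfig(expr_cols=lib.expression_columns)
    frame = lib.to_frame(
        id_col=config.id_col,
        seq_col=config.seq_col,
        sd_col=config.sd_col or "SD",
        rep_col=config.rep_col or "Replicates",
    )
    frame.to_csv(path, index=False)


def regenerate_replicates(lib: PromoterLibrary, seed: int) -> PromoterLibrary:
    """Expand each record into normally distributed pseudo-replicates.

    Each record with mean expression m, standard deviation sd and replicate
    count n is replaced by n records sharing its sequence, with expression
    drawn from Normal(m, sd). Replicate ids are ``<parent id>_r<k>``. The
    draw is seeded and reproducible. Negative draws are kept (with a
    warning): the sampling model is a plain normal distribution.
    """
    for rec in lib:
        if rec.sd is None or rec.n_replicates is None:
            raise ValueError(
                f"record {rec.id!r} lacks sd and/or replicate count; "
                "replicate regeneration needs both"
            )
    rng = np.random.default_rng(seed)
    out = []
    negatives = 0
    for rec in lib:
        draws = rng.normal(
            loc=np.asarray(rec.expression, dtype=float),
            scale=rec.sd,
            size=(rec.n_replicates, len(rec.expression)),
        )
        negatives += int((draws < 0).sum())
        for k in range(rec.n_replicates):
            out.append(
                PromoterRecord(
                    id=f"{rec.id}_r{k + 1}",
                    sequence=rec.sequence,
                    expression=tuple(draws[k]),
                )
            )
    if negatives:
        warnings.warn(
            f"replicate regeneration produced {negatives} negative expression "
            "draw(s); kept as-is",
            stacklevel=2,
        )
    return PromoterLibrary(
        records=tuple(out),
        expression_columns=lib.expression_columns,
        position_labels=lib.position_labels,
    )


class OutlierResult(NamedTuple):
    library: PromoterLibrary
    removed_ids: tuple[str, ...]


def remove_outliers(
    lib: PromoterLibrary, z_threshold: float = 3.0, column: str | int = 0
) -> OutlierResult:
    """Drop records whose expression z-score exceeds *z_threshold*.

    The z-score is computed on one expression column over the whole
    library. With zero expression variance the library is returned
    unchanged (with a warning). Requires at least 3 records.
    """
    if len(lib) < 3:
        raise ValueError(
            f"outlier removal needs >= 3 records, library has {len(lib)}"
        )
    values = lib.expression_values(column)
    sd = values.std(ddof=0)
    if sd == 0:
        warnings.warn(
            "expression variance is zero; no outliers removed", stacklevel=2
        )
        return OutlierResult(lib, ())
    z = np.abs(values - values.mean()) / sd
    keep = np.flatnonzero(z <= z_threshold)
    removed = tuple(lib.records[i].id for i in np.flatnonzero(z > z_threshold))
    return OutlierResult(lib.subset(keep), removed)


def merge_libraries(a: PromoterLibrary, b: PromoterLibrary) -> PromoterLibrary:
    """Concatenate two libraries (a's records first, then b's).

    Both must share sequence length and expression columns; ids must be
    disjoint — silently deduplicating would corrupt replicate-joint
    cross-validation grouping downstream.
    """
    if a.size and b.size and a.sequence_length != b.sequence_length:
        raise SequenceLengthError(
            f"cannot merge libraries with sequence lengths "
            f"{a.sequence_length} and {b.sequence_length}"
        )
    if a.size and b.size and a.expression_columns != b.expression_columns:
        raise ValueError(
            "cannot merge libraries with different expression columns: "
            f"{a.expression_columns} vs {b.expression_columns}"
        )
    shared = set(a.ids) & set(b.ids)
    if shared:
        raise DuplicateIdError(
            f"libraries share record id(s): {sorted(shared)[:5]}"
        )
    base = a if a.size else b
    return PromoterLibrary(
        records=tuple(a.records) + tuple(b.records),
        expression_columns=base.expression_columns,
        position_labels=base.position_labels,
    )
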