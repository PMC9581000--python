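"""In-memory model of a promoter expression library.

A library is an ordered collection of records, each pairing a DNA sequence
of fixed length ``R`` with one or more measured expression values (for
example the same construct read out in two host organisms or with two
reporter proteins). Optional per-record standard deviations and replicate
counts support replicate regeneration.

Sequence positions carry integer coordinates. By default they run from
``-R`` to ``-1``, i.e. upstream of a transcription start site at 0, which is
the conventional coordinate system for bacterial promoter libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    DuplicateIdError,
    EmptyLibraryError,
    SequenceLengthError,
)

#: Fixed nucleotide ordering used for one-hot encoding, counting and
#: consensus tie-breaking throughout the package.
NUCLEOTIDES = ("A", "C", "G", "T")

_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
_VALID_CHARS = frozenset(NUCLEOTIDES)


def validate_sequence(sequence: str, record_id: str | None = None) -> str:
    """Check that *sequence* is a nonempty string over {A, C, G, T}.

    Returns the sequence unchanged; raises :class:`AlphabetError` naming the
    offending record otherwise.
    """
    bad = set(sequence) - _VALID_CHARS
    if bad or not sequence:
        where = f" in record {record_id!r}" if record_id is not None else ""
        raise AlphabetError(
            f"sequence{where} contains non-ACGT characters: {sorted(bad) or '<empty>'}"
        )
    return sequence


def encode_sequences(sequences: Iterable[str]) -> np.ndarray:
    """Encode sequences as an (S, R) integer matrix with A,C,G,T -> 0..3."""
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), len(seqs[0]))
    lut = np.full(128, -1, dtype=np.int8)
    for nt, i in _NT_INDEX.items():
        lut[ord(nt)] = i
    return lut[arr]


@dataclass(frozen=True)
class PromoterRecord:
    """One library entry: a sequence with its measured activity.

    ``expression`` holds one value per measurement column of the parent
    library. ``sd`` and ``n_replicates`` are optional and only required for
    replicate regeneration.
    """

    id: str
    sequence: str
    expression: tuple[float, ...]
    sd: float | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, self.id)
        if self.sd is not None and not self.sd >= 0:
            raise ValueError(f"record {self.id!r}: sd must be >= 0, got {self.sd}")
        if self.n_replicates is not None and self.n_replicates < 1:
            raise ValueError(
                f"record {self.id!r}: n_replicates must be >= 1, got {self.n_replicates}"
            )


@dataclass(frozen=True)
class PromoterLibrary:
    """Ordered, validated collection of :class:`PromoterRecord`.

    Invariants enforced on construction: all sequences share one length R,
    ids are unique, and ``position_labels`` is a strictly increasing integer
    vector of length R (default ``-R .. -1``).
    """

    records: tuple[PromoterRecord, ...]
    expression_columns: tuple[str, ...] = ("Expression",)
    position_labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        object.__setattr__(
            self, "expression_columns", tuple(self.expression_columns)
        )
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            raise SequenceLengthError(
                f"sequences of unequal length: {sorted(lengths)}"
            )
        r_len = lengths.pop() if lengths else 0
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise DuplicateIdError(f"duplicate record id {dup!r}")
        n_expr = len(self.expression_columns)
        for rec in records:
            if len(rec.expression) != n_expr:
                raise ValueError(
                    f"record {rec.id!r} has {len(rec.expression)} expression "
                    f"values, expected {n_expr}"
                )
        labels = tuple(self.position_labels) or tuple(range(-r_len, 0))
        if records and (
            len(labels) != r_len or any(b <= a for a, b in zip(labels, labels[1:]))
        ):
            raise ValueError(
                "position_labels must be strictly increasing with one label "
                f"per position (R={r_len})"
            )
        object.__setattr__(self, "position_labels", labels)

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def size(self) -> int:
        """Sample count S."""
        return len(self.records)

    @property
    def sequence_length(self) -> int:
        """Common sequence length R."""
        return len(self.records[0].sequence) if self.records else 0

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequence_matrix(self) -> np.ndarray:
        """(S, R) integer matrix with nucleotides coded 0..3 (A,C,G,T)."""
        return encode_sequences(self.sequences)

    def expression_values(self, column: str | int = 0) -> np.ndarray:
        """Expression vector for one measurement column (name or index)."""
        idx = (
            column
            if isinstance(column, int)
            else self.expression_columns.index(column)
        )
        return np.array([r.expression[idx] for r in self.records], dtype=float)

    def expression_matrix(self) -> np.ndarray:
        """(S, n_columns) matrix of all expression measurements."""
        return np.array([r.expression for r in self.records], dtype=float)

    def subset(self, indices: Sequence[int]) -> "PromoterLibrary":
        """New library with the records at *indices*, order preserved."""
        return PromoterLibrary(
            records=tuple(self.records[i] for i in indices),
            expression_columns=self.expression_columns,
            position_labels=self.position_labels,
        )

    def require_nonempty(self) -> "PromoterLibrary":
        if not self.records:
            raise EmptyLibraryError("operation requires a nonempty library")
        return self

    def to_frame(
        self,
        id_col: str = "ID",
        seq_col: str = "Sequence",
        sd_col: str = "SD",
        rep_col: str = "Replicates",
    ) -> pd.DataFrame:
        """Tabular view of the library (used by CSV export)."""
        data: dict[str, list] = {
            id_col: self.ids,
            seq_col: self.sequences,
        }
        expr = self.expression_matrix()
        for j, name in enumerate(self.expression_columns):
            data[name] = list(expr[:, j]) if len(self) else []
        if any(r.sd is not None for r in self.records):
            data[sd_col] = [r.sd for r in self.records]
        if any(r.n_replicates is not None for r in self.records):
            data[rep_col] = [r.n_replicates for r in self.records]
        return pd.DataFrame(data)
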