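"""Statistical overview of a promoter library.

Per-position nucleotide counts and Shannon entropies, consensus sequence,
sequence diversity (normalized Hamming distances), position-nucleotide
expression averages, GC content, and summary tables for plotting.

The per-position entropy is

    H_i = - sum_{b in {A,C,G,T}} p_b(i) * log2 p_b(i)

with 0*log2(0) := 0, so H_i ranges from 0 bits (invariant position) to
2 bits (all four nucleotides equally frequent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import SequenceLengthError
from .library import NUCLEOTIDES, PromoterLibrary, encode_sequences, validate_sequence


@dataclass(frozen=True)
class PositionProfile:
    """Nucleotide counts, frequencies and entropies per sequence position.

    All matrices are 4 x R with rows in A, C, G, T order; every column of
    ``counts`` sums to the sample count S.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    entropy_bits: np.ndarray
    position_labels: tuple[int, ...]

    @property
    def sample_count(self) -> int:
        return int(self.counts[:, 0].sum()) if self.counts.size else 0


@dataclass(frozen=True)
class ExpressionProfile:
    """Mean/sd expression per (nucleotide, position) cell.

    ``mean[b, i]`` is the average expression over all samples carrying
    nucleotide b at position i; ``sd`` is the sample standard deviation
    (ddof=1). Cells with no supporting sample are NaN (undefined), as are
    sd cells with support < 2; ``support`` records the sample counts.
    """

    mean: np.ndarray
    sd: np.ndarray
    support: np.ndarray
    position_labels: tuple[int, ...]


@dataclass(frozen=True)
class DiversityReport:
    """Normalized Hamming-distance diversity of a library.

    Distances are in [0, 1]: 0 means identical sequences, 1 means every
    position differs. ``mode`` records whether distances are taken to a
    reference sequence or averaged over all sequence pairs.
    """

    mode: str
    per_sequence_distance: np.ndarray
    mean_distance: float
    reference_used: str | None


def position_counts(lib: PromoterLibrary) -> np.ndarray:
    """4 x R matrix of nucleotide counts (rows A, C, G, T)."""
    lib.require_nonempty()
    codes = lib.sequence_matrix()
    return np.stack([(codes == b).sum(axis=0) for b in range(4)]).astype(np.int64)


def entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each column of a 4 x R count matrix."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    p = counts / totals
    return -xlogy(p, p).sum(axis=0) / np.log(2.0)


def position_entropy(lib: PromoterLibrary) -> PositionProfile:
    """Per-position nucleotide profile of the library."""
    counts = position_counts(lib)
    frequencies = counts / counts.sum(axis=0)
    return PositionProfile(
        counts=counts,
        frequencies=frequencies,
        entropy_bits=entropy_from_counts(counts),
        position_labels=lib.position_labels,
    )


def consensus_sequence(lib: PromoterLibrary) -> str:
    """Most common nucleotide at each position; ties break as A < C < G < T."""
    counts = position_counts(lib)
    return "".join(NUCLEOTIDES[b] for b in counts.argmax(axis=0))


def sequence_diversity(
    lib: PromoterLibrary,
    reference: str | None = None,
    mode: str = "auto",
    pairwise_limit: int = 1000,
) -> DiversityReport:
    """Sequence diversity as normalized Hamming distance.

    In ``reference`` mode each sequence is compared with *reference*
    (defaulting to the library consensus). In ``pairwise`` mode the mean
    distance over all unordered sequence pairs is reported, and each
    sequence's entry is its mean distance to all other sequences. ``auto``
    uses pairwise up to *pairwise_limit* samples and falls back to the
    cheaper reference mode for larger libraries.
    """
    lib.require_nonempty()
    if mode not in {"auto", "reference", "pairwise"}:
        raise ValueError(f"unknown diversity mode {mode!r}")
    if mode == "auto":
        mode = "pairwise" if lib.size <= pairwise_limit else "reference"

    codes = lib.sequence_matrix()
    S, R = codes.shape
    if mode == "reference":
        ref = reference if reference is not None else consensus_sequence(lib)
        validate_sequence(ref)
        if len(ref) != R:
            raise SequenceLengthError(
                f"reference length {len(ref)} != sequence length {R}"
            )
        ref_codes = encode_sequences([ref])[0]
        per_seq = (codes != ref_codes).mean(axis=1)
        return DiversityReport(
            mode="reference",
            per_sequence_distance=per_seq,
            mean_distance=float(per_seq.mean()),
            reference_used=ref,
        )

    # Pairwise: per position, the number of differing pairs is
    # S^2 - sum_b counts_b^2 over ordered pairs; halve for unordered.
    if S == 1:
        per_seq = np.zeros(1)
        return DiversityReport("pairwise", per_seq, 0.0, None)
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    # mean distance of each sequence to all others, vectorized via counts:
    # matches at position i for sequence s = counts[code(s,i), i] - 1
    matches = counts[codes, np.arange(R)] - 1  # (S, R)
    per_seq = 1.0 - matches.sum(axis=1) / (R * (S - 1))
    diff_pairs = (S * S - (counts**2).sum(axis=0)).sum() / 2.0
    mean_distance = diff_pairs / (R * S * (S - 1) / 2.0)
    return DiversityReport(
        mode="pairwise",
        per_sequence_distance=per_seq,
        mean_distance=float(mean_distance),
        reference_used=None,
    )


def position_expression(
    lib: PromoterLibrary, column: str | int = 0
) -> ExpressionProfile:
    """Average expression for each (nucleotide, position) pair.

    Implements the one-hot/expression outer product summarized over
    samples: the mean expression of all sequences carrying nucleotide b at
    position i, with the sample standard deviation and support count.
    """
    lib.require_nonempty()
    codes = lib.sequence_matrix()
    expr = lib.expression_values(column)
    S, R = codes.shape
    onehot = np.zeros((S, 4, R))
    onehot[np.arange(S)[:, None], codes, np.arange(R)] = 1.0
    support = onehot.sum(axis=0)
    total = np.einsum("s,sbr->br", expr, onehot)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(support > 0, total / support, np.nan)
        sq = np.einsum("s,sbr->br", expr**2, onehot)
        var = np.where(
            support > 1, (sq - support * mean**2) / (support - 1), np.nan
        )
    sd = np.sqrt(np.clip(var, 0.0, None))
    return ExpressionProfile(
        mean=mean,
        sd=sd,
        support=support.astype(np.int64),
        position_labels=lib.position_labels,
    )


def gc_content(sequence: str) -> float:
    """Fraction of G and C nucleotides in a nonempty ACGT string."""
    validate_sequence(sequence)
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


@dataclass(frozen=True)
class LibrarySummary:
    """Plot-ready tables: expression histogram, cross-library pairs,
    per-position counts and entropies."""

    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    cross_expression: pd.DataFrame | None
    profile: PositionProfile
    diversity: DiversityReport

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """All summary components as tidy DataFrames keyed by name."""
        tables = {
            "histogram": pd.DataFrame(
                {
                    "bin_left": self.histogram_edges[:-1],
                    "bin_right": self.histogram_edges[1:],
                    "count": self.histogram_counts,
                }
            ),
            "positions": pd.DataFrame(
                {
                    "position": self.profile.position_labels,
                    **{
                        nt: self.profile.counts[i]
                        for i, nt in enumerate(NUCLEOTIDES)
                    },
                    "entropy_bits": self.profile.entropy_bits,
                }
            ),
            "diversity": pd.DataFrame(
                {"distance": self.diversity.per_sequence_distance}
            ),
        }
        if self.cross_expression is not None:
            tables["cross_expression"] = self.cross_expression
        return tables


def library_summary(
    lib: PromoterLibrary,
    column: str | int = 0,
    bins: int = 10,
    pairwise_limit: int = 1000,
) -> LibrarySummary:
    """Compute the statistical overview of a library in one pass."""
    lib.require_nonempty()
    values = lib.expression_values(column)
    hist, edges = np.histogram(values, bins=bins)
    cross = None
    if len(lib.expression_columns) >= 2:
        cross = pd.DataFrame(
            lib.expression_matrix(), columns=list(lib.expression_columns)
        )
        cross.insert(0, "id", lib.ids)
    return LibrarySummary(
        histogram_counts=hist,
        histogram_edges=edges,
        cross_expression=cross,
        profile=position_entropy(lib),
        diversity=sequence_diversity(lib, pairwise_limit=pairwise_limit),
    )
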