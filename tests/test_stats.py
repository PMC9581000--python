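import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promolearn import (
    consensus_sequence,
    gc_content,
    library_summary,
    position_entropy,
    position_expression,
    sequence_diversity,
)
from promolearn.errors import EmptyLibraryError, SequenceLengthError
from promolearn.library import PromoterLibrary
from promolearn.stats import entropy_from_counts

from conftest import make_library


def shannon_oracle(counts):
    """Direct evaluation of H = -sum p log2 p (independent of the package path)."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return float(sum(-pi * np.log2(pi) for pi in p if pi > 0))


class TestPositionEntropy:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["A", "C", "G", "T"], 2.0),  # uniform maximum
            (["A", "A", "A", "A"], 0.0),  # invariant position
            (["A", "A", "C", "C"], 1.0),  # two equiprobable symbols
        ],
    )
    def test_single_position_entropies(self, seqs, expected):
        lib = make_library([(s, 1.0) for s in seqs])
        profile = position_entropy(lib)
        assert profile.entropy_bits[0] == pytest.approx(expected)

    def test_agrees_with_direct_formula_on_random_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(1000, 4))
        counts[counts.sum(axis=1) == 0, 0] = 1
        ours = entropy_from_counts(counts.T)
        expected = [shannon_oracle(c) for c in counts]
        np.testing.assert_allclose(ours, expected, atol=1e-12)

    def test_column_sums_equal_sample_count(self, random_library):
        profile = position_entropy(random_library)
        assert (profile.counts.sum(axis=0) == random_library.size).all()
        np.testing.assert_allclose(
            profile.frequencies.sum(axis=0), 1.0, atol=1e-12
        )
        assert ((profile.entropy_bits >= 0) & (profile.entropy_bits <= 2)).all()

    def test_empty_library_rejected(self):
        with pytest.raises(EmptyLibraryError):
            position_entropy(PromoterLibrary(records=()))


class TestConsensus:
    def test_majority_and_tiebreak(self):
        assert consensus_sequence(
            make_library([("AAC", 1), ("AAC", 1), ("ATC", 1)])
        ) == "AAC"
        # both positions tied between two nucleotides; A wins by fixed order
        assert consensus_sequence(make_library([("AC", 1), ("CA", 1)])) == "AA"

    def test_single_sequence_is_its_own_consensus(self):
        assert consensus_sequence(make_library([("GATTACA", 1)])) == "GATTACA"

    def test_duplicating_consensus_preserves_it(self, random_library):
        cons = consensus_sequence(random_library)
        extended = make_library(
            list(zip(random_library.sequences, random_library.expression_values()))
            + [(cons, 0.0), (cons, 0.0)]
        )
        assert consensus_sequence(extended) == cons


class TestSequenceDiversity:
    def test_identical_sequences_have_zero_distance(self):
        lib = make_library([("ACGT", 1), ("ACGT", 2), ("ACGT", 3)])
        for mode in ("reference", "pairwise"):
            assert sequence_diversity(lib, mode=mode).mean_distance == 0.0

    def test_fully_different_pair(self):
        lib = make_library([("ACGT", 1), ("TGCA", 2)])
        assert sequence_diversity(lib, mode="pairwise").mean_distance == 1.0

    def test_reference_mode_hand_computed(self):
        lib = make_library([("ACGT", 1), ("ACGA", 2)])
        report = sequence_diversity(lib, reference="ACGT", mode="reference")
        np.testing.assert_allclose(report.per_sequence_distance, [0.0, 0.25])
        assert report.mean_distance == pytest.approx(0.125)

    def test_pairwise_on_two_sequences_equals_hamming(self):
        lib = make_library([("AAAA", 1), ("AATT", 2)])
        assert sequence_diversity(lib, mode="pairwise").mean_distance == 0.5

    def test_pairwise_mean_matches_explicit_double_loop(self, random_library):
        report = sequence_diversity(random_library, mode="pairwise")
        seqs = random_library.sequences
        dists = [
            sum(a != b for a, b in zip(seqs[i], seqs[j])) / len(seqs[i])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        assert report.mean_distance == pytest.approx(np.mean(dists))

    def test_auto_switches_to_reference_above_limit(self, random_library):
        report = sequence_diversity(random_library, mode="auto", pairwise_limit=5)
        assert report.mode == "reference"

    def test_wrong_reference_length_rejected(self, random_library):
        with pytest.raises(SequenceLengthError):
            sequence_diversity(random_library, reference="ACG", mode="reference")


class TestPositionExpression:
    def test_hand_computed_two_sequences(self):
        lib = make_library([("AC", 2.0), ("AA", 4.0)])
        profile = position_expression(lib)
        assert profile.mean[0, 0] == pytest.approx(3.0)  # A at pos 1
        assert profile.mean[1, 1] == pytest.approx(2.0)  # C at pos 2
        assert profile.mean[0, 1] == pytest.approx(4.0)  # A at pos 2
        assert np.isnan(profile.mean[2, 0])  # G unseen -> undefined, not 0

    def test_single_sequence_fills_occupied_cells(self):
        lib = make_library([("ACGT", 5.0)])
        profile = position_expression(lib)
        occupied = profile.support > 0
        assert (profile.mean[occupied] == 5.0).all()
        assert np.isnan(profile.mean[~occupied]).all()

    def test_two_identical_sequences_sample_sd(self):
        lib = make_library([("AC", 1.0), ("AC", 3.0)])
        profile = position_expression(lib)
        assert profile.mean[0, 0] == pytest.approx(2.0)
        assert profile.sd[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_support_equals_position_counts(self, random_library):
        profile = position_expression(random_library)
        counts = position_entropy(random_library).counts
        np.testing.assert_array_equal(profile.support, counts)

    def test_agrees_with_groupby_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            S, R = rng.integers(2, 21), rng.integers(1, 11)
            seqs = ["".join(rng.choice(list("ACGT"), R)) for _ in range(S)]
            expr = rng.normal(size=S)
            lib = make_library(list(zip(seqs, expr)))
            profile = position_expression(lib)
            for i in range(R):
                for b, nt in enumerate("ACGT"):
                    vals = [e for s, e in zip(seqs, expr) if s[i] == nt]
                    if vals:
                        assert profile.mean[b, i] == pytest.approx(np.mean(vals))
                    else:
                        assert np.isnan(profile.mean[b, i])


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", 0.5), ("AAAA", 0.0), ("GGCC", 1.0)]
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            gc_content("")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=2, max_size=15
    )
)
def test_entropy_and_diversity_bounds_hold_for_any_library(seqs):
    lib = make_library([(s, float(i)) for i, s in enumerate(seqs)])
    profile = position_entropy(lib)
    assert (profile.counts.sum(axis=0) == lib.size).all()
    assert ((profile.entropy_bits >= 0) & (profile.entropy_bits <= 2 + 1e-12)).all()
    report = sequence_diversity(lib, mode="pairwise")
    assert 0.0 <= report.mean_distance <= 1.0
    assert ((report.per_sequence_distance >= 0) &
            (report.per_sequence_distance <= 1)).all()


class TestLibrarySummary:
    def test_histogram_counts_sum_to_sample_count(self, random_library):
        summary = library_summary(random_library)
        assert summary.histogram_counts.sum() == random_library.size
        assert summary.cross_expression is None

    def test_two_column_library_yields_paired_table(self):
        lib = make_library(
            [("ACGT", (1.0, 2.0)), ("AAGT", (3.0, 4.0))],
            columns=("GFP", "mCherry"),
        )
        summary = library_summary(lib)
        assert summary.cross_expression.shape == (2, 3)  # id + 2 value columns
        assert list(summary.cross_expression.columns) == ["id", "GFP", "mCherry"]
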