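import numpy as np
import pytest

from promolearn import (
    PromoterLibrary,
    PromoterRecord,
    WorkflowConfig,
)


def make_library(seq_expr, sd=None, n_rep=None, columns=("Expression",)):
    """Library from [(sequence, expression), ...] with generated ids."""
    records = []
    for i, (seq, expr) in enumerate(seq_expr):
        if not isinstance(expr, tuple):
            expr = (float(expr),)
        records.append(
            PromoterRecord(f"p{i + 1}", seq, expr, sd=sd, n_replicates=n_rep)
        )
    return PromoterLibrary(records=tuple(records), expression_columns=columns)


@pytest.fixture
def tiny_library():
    """Four 4-mers with hand-set expression values."""
    return make_library(
        [("ACGT", 2.0), ("AAGT", 4.0), ("ACGA", 6.0), ("TCGT", 8.0)]
    )


@pytest.fixture
def config():
    return WorkflowConfig(
        id_col="ID", seq_col="Seq", expr_cols=("Expr",), seed=7
    )


@pytest.fixture
def random_library():
    """Seeded random library for oracle comparisons (S=20, R=8)."""
    rng = np.random.default_rng(42)
    seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(20)]
    expr = rng.normal(10.0, 3.0, size=20)
    return make_library(list(zip(seqs, expr)))
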