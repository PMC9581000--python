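"""Synthetic promoter libraries with planted, known ground truth.

The generator emulates a mutagenesis library: every sequence derives from
one base sequence by independent per-position mutation, and expression
follows an additive position–nucleotide weight model

    expression(seq) = sum_i W[nt_i, i] + interaction(seq) + Normal(0, noise_sd)

where ``W`` is a 4 x R weight matrix whose nonzero spread is concentrated
on a small set of causal positions. Because the true weights are known,
downstream estimators can be checked for parameter recovery (do the causal
positions dominate the learned feature importances? does the fitted model
explain the planted variance?). An optional pairwise-interaction term
creates epistatic ("hard") fixtures; it is off by default, keeping the
generative model strictly additive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .library import NUCLEOTIDES, PromoterLibrary, PromoterRecord, validate_sequence


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative settings for one synthetic library.

    ``mutation_rate`` may be a scalar (uniform across positions) or a
    length-R vector of per-position probabilities of deviating from the
    base nucleotide; a deviating position is uniform over the other three
    nucleotides. ``weights`` rows follow the A, C, G, T order.
    """

    base_sequence: str
    S: int
    weights: np.ndarray  # 4 x R
    causal_positions: tuple[int, ...] = ()
    mutation_rate: float | np.ndarray = 0.1
    noise_sd: float = 0.0
    replicate_count: int = 1
    interaction: tuple[int, int, float] | None = None  # (pos_a, pos_b, coefficient)
    seed: int = 0

    def __post_init__(self) -> None:
        validate_sequence(self.base_sequence)
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != (4, self.R):
            raise ValueError(
                f"weights must be 4 x {self.R}, got {weights.shape}"
            )
        object.__setattr__(self, "weights", weights)
        rate = np.asarray(self.mutation_rate, dtype=float)
        if rate.ndim == 0:
            rate = np.full(self.R, float(rate))
        if rate.shape != (self.R,) or rate.min() < 0 or rate.max() > 1:
            raise ValueError("mutation_rate must be a probability (or R of them)")
        object.__setattr__(self, "mutation_rate", rate)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.S < 1 or self.replicate_count < 1:
            raise ValueError("S and replicate_count must be positive")

    @property
    def R(self) -> int:
        return len(self.base_sequence)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    base_sequence: str
    weights: np.ndarray
    causal_positions: tuple[int, ...]
    causal_labels: tuple[int, ...]
    noise_sd: float
    true_expression: np.ndarray  # noiseless expression per unique sequence

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_sequence": self.base_sequence,
                "weights": self.weights.tolist(),
                "causal_positions": list(self.causal_positions),
                "causal_labels": list(self.causal_labels),
                "noise_sd": self.noise_sd,
                "true_expression": self.true_expression.tolist(),
            },
            indent=2,
        )


def planted_spec(
    R: int = 40,
    S: int = 200,
    n_causal: int = 3,
    effect_size: float = 1.0,
    mutation_rate: float = 0.1,
    noise_fraction: float = 0.1,
    replicate_count: int = 1,
    seed: int = 0,
) -> SyntheticSpec:
    """Convenience constructor: random base sequence, a few causal positions.

    Causal positions receive per-nucleotide weights spread over
    ``[-effect_size, effect_size]``; all other positions are inert. The
    noise standard deviation is set to ``noise_fraction`` times the
    standard deviation of the noiseless expression of a provisional
    sample, so the signal-to-noise ratio is controlled rather than the
    absolute noise scale.
    """
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(NUCLEOTIDES), size=R))
    causal = tuple(sorted(rng.choice(R, size=n_causal, replace=False).tolist()))
    weights = np.zeros((4, R))
    for pos in causal:
        weights[:, pos] = rng.uniform(-effect_size, effect_size, size=4)
    spec = SyntheticSpec(
        base_sequence=base,
        S=S,
        weights=weights,
        causal_positions=causal,
        mutation_rate=mutation_rate,
        noise_sd=0.0,
        replicate_count=replicate_count,
        seed=seed,
    )
    if noise_fraction > 0:
        lib, truth = generate_library(spec)
        signal_sd = float(truth.true_expression.std(ddof=0))
        spec = replace(spec, noise_sd=noise_fraction * max(signal_sd, 1e-12))
    return spec


def _expression_of(codes: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    expr = spec.weights[codes, np.arange(spec.R)].sum(axis=1)
    if spec.interaction is not None:
        a, b, coef = spec.interaction
        expr = expr + coef * (codes[:, a] == codes[:, b])
    return expr


def generate_library(spec: SyntheticSpec) -> tuple[PromoterLibrary, GroundTruth]:
    """Draw a library from the generative model. Seeded and reproducible.

    Returns the library (``S * replicate_count`` records; replicates share
    a sequence and differ only in their independent noise draws) together
    with the planted ground truth. Position labels run from -R to -1,
    upstream of a transcription start at 0.
    """
    rng = np.random.default_rng(spec.seed)
    R, S = spec.R, spec.S
    base_codes = np.array(
        [NUCLEOTIDES.index(c) for c in spec.base_sequence], dtype=np.int8
    )
    mutate = rng.random((S, R)) < spec.mutation_rate
    shift = rng.integers(1, 4, size=(S, R), dtype=np.int8)
    codes = np.where(mutate, (base_codes + shift) % 4, base_codes).astype(np.int8)
    true_expr = _expression_of(codes, spec)
    noise = rng.normal(0.0, spec.noise_sd, size=(S, spec.replicate_count))
    observed = true_expr[:, None] + noise

    lut = np.array(list("ACGT"))
    records = []
    for s in range(S):
        seq = "".join(lut[codes[s]])
        for k in range(spec.replicate_count):
            rec_id = f"syn{s + 1}" if spec.replicate_count == 1 else f"syn{s + 1}_r{k + 1}"
            records.append(
                PromoterRecord(rec_id, seq, (float(observed[s, k]),))
            )
    position_labels = tuple(range(-R, 0))
    lib = PromoterLibrary(
        records=tuple(records),
        expression_columns=("Expression",),
        position_labels=position_labels,
    )
    causal_labels = tuple(position_labels[p] for p in spec.causal_positions)
    truth = GroundTruth(
        base_sequence=spec.base_sequence,
        weights=spec.weights,
        causal_positions=spec.causal_positions,
        causal_labels=causal_labels,
        noise_sd=spec.noise_sd,
        true_expression=true_expr,
    )
    return lib, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
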