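"""Workflow configuration: flat ``key = value`` text files.

The configuration names the CSV columns of a promoter library and carries
the workflow-wide parameters (target encoding, entropy cutoff, train/test
ratio, seed, output naming). Lines starting with ``#`` are comments; the
file is UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import ConfigurationError


@dataclass
class WorkflowConfig:
    """Column names and global parameters of one analysis run.

    ``response_value`` selects the target encoding: 0 standardizes the
    expression to zero mean / unit variance (regression), 1 uses the raw
    values (regression), and any k >= 2 bins the expression into k
    equal-frequency classes (classification).
    """

    id_col: str = "ID"
    seq_col: str = "Sequence"
    expr_cols: tuple[str, ...] = ("Expression",)
    sd_col: str | None = None
    rep_col: str | None = None
    response_value: int = 1
    entropy_cutoff: float = 0.2
    ratio: float = 0.9
    reference: str | None = None
    pairwise_limit: int = 1000
    seed: int = 0
    out_prefix: str = "promolearn"
    fig_format: str = "svg"

    def __post_init__(self) -> None:
        if isinstance(self.expr_cols, str):
            self.expr_cols = tuple(
                c.strip() for c in self.expr_cols.split(",") if c.strip()
            )
        else:
            self.expr_cols = tuple(self.expr_cols)
        if self.response_value < 0:
            raise ConfigurationError(
                f"response_value must be >= 0, got {self.response_value}"
            )
        if not 0.0 <= self.entropy_cutoff <= 2.0:
            raise ConfigurationError(
                f"entropy_cutoff must lie in [0, 2] bits, got {self.entropy_cutoff}"
            )
        if not 0.0 < self.ratio < 1.0:
            raise ConfigurationError(
                f"ratio (train fraction) must lie in (0, 1), got {self.ratio}"
            )
        if self.pairwise_limit < 1:
            raise ConfigurationError("pairwise_limit must be a positive integer")

    def with_overrides(self, **kwargs) -> "WorkflowConfig":
        return replace(self, **kwargs)


_INT_KEYS = {"response_value", "pairwise_limit", "seed"}
_FLOAT_KEYS = {"entropy_cutoff", "ratio"}
_OPTIONAL_KEYS = {"sd_col", "rep_col", "reference"}


def read_config(path: str | Path) -> WorkflowConfig:
    """Parse a ``key = value`` configuration file into a WorkflowConfig."""
    known = {f.name for f in fields(WorkflowConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            if key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            elif key in _OPTIONAL_KEYS and value.lower() in {"", "none"}:
                values[key] = None
            else:
                values[key] = value
        except ValueError as exc:
            raise ConfigurationError(
                f"{path}:{lineno}: cannot parse value for {key!r}: {value!r}"
            ) from exc
    return WorkflowConfig(**values)  # type: ignore[arg-type]


def write_config(config: WorkflowConfig, path: str | Path) -> None:
    """Write *config* in the same flat ``key = value`` dialect."""
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        if value is None:
            value = "none"
        elif isinstance(value, tuple):
            value = ",".join(value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
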