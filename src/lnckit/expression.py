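"""Abundance matrices: FPKM computation, log transforms and correlation.

The canonical container is :class:`ExpressionMatrix`, a thin wrapper around a
transcripts x samples :class:`pandas.DataFrame` plus a sample-to-group map.
FPKM follows the standard definition

    FPKM[t, s] = fragments[t, s] * 1e9 / (length[t] * total_mapped[s])

Correlation analyses throughout the pipeline operate on log10(FPKM + 1)
values, which stabilises the heavy right skew of FPKM; raw-scale correlation
is available via the ``transform`` flag of the callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ZeroVarianceError",
    "compute_fpkm",
    "log_transform",
    "pearson_correlation",
    "read_expression",
    "read_groups",
    "read_two_column_tsv",
]


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant vector."""


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance table with a sample->group mapping.

    Parameters
    ----------
    values
        Non-negative DataFrame; index = transcript ids, columns = sample ids.
    sample_groups
        Mapping from each sample id to its group label.
    unit
        ``"fragments"`` (raw counts) or ``"FPKM"``.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("fragments", "FPKM"):
            raise ValueError(f"invalid unit: {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.sample_groups[s] == group]
        if not out:
            raise ValueError(f"unknown or empty group: {group!r}")
        return out

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(transcript_ids)], dict(self.sample_groups), self.unit
        )

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript_id")


def compute_fpkm(
    fragments: ExpressionMatrix,
    lengths: Mapping[str, int],
    totals: Mapping[str, float],
) -> ExpressionMatrix:
    """Normalise fragment counts to FPKM.

    Every transcript needs a positive length and every sample a positive
    total mapped-fragment count; missing entries raise ``ValueError``.
    """
    if fragments.unit != "fragments":
        raise ValueError("compute_fpkm expects a matrix in fragment counts")
    missing_len = [t for t in fragments.transcript_ids if t not in lengths]
    if missing_len:
        raise ValueError(f"transcripts without length: {missing_len[:10]}")
    missing_tot = [s for s in fragments.samples if s not in totals]
    if missing_tot:
        raise ValueError(f"samples without total count: {missing_tot}")
    length = np.array([lengths[t] for t in fragments.transcript_ids], dtype=float)
    total = np.array([totals[s] for s in fragments.samples], dtype=float)
    if (length <= 0).any() or (total <= 0).any():
        raise ValueError("lengths and totals must be positive")
    vals = fragments.values.to_numpy(dtype=float) * 1e9 / np.outer(length, total)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=fragments.values.index, columns=fragments.values.columns),
        dict(fragments.sample_groups),
        unit="FPKM",
    )


def log_transform(
    m: ExpressionMatrix, pseudocount: float = 1.0, base: float = 2.0
) -> pd.DataFrame:
    """Elementwise ``log_base(value + pseudocount)``; monotone, order-preserving."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log(m.values + pseudocount) / np.log(base)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Constant input raises :class:`ZeroVarianceError` rather than silently
    returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def read_expression(
    matrix_path: str | Path, groups_path: str | Path, unit: str = "fragments"
) -> ExpressionMatrix:
    """Read a TSV matrix (first column transcript_id) plus a sample->group TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, read_groups(groups_path), unit=unit)


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV with header: sample_id <tab> group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_two_column_tsv(path: str | Path, value_type=float) -> dict:
    """Generic id -> value TSV reader (lengths, totals, coding scores)."""
    df = pd.read_csv(path, sep="\t")
    return {str(k): value_type(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
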