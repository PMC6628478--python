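"""Gene-level count matrices: I/O, quality filtering, normalization.

The filter removes genes whose expression is too unreliable for rank
statistics: a gene is excluded if its count is zero in ``zero_sample_min``
or more samples (default 10), or its average count over all samples is below
``mean_min`` (default 8).  Normalization is counts-per-million (CPM) by
default; any strictly monotone per-sample scaling leaves Spearman-based
downstream statistics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with an optional normalized view."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValueError("normalized view shape mismatch")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class FilterParams:
    zero_sample_min: int = 10  # exclude if zero in >= this many samples
    mean_min: float = 8.0      # exclude if mean count < this

    def __post_init__(self) -> None:
        if self.zero_sample_min < 1:
            raise ValueError("zero_sample_min must be >= 1")
        if self.mean_min < 0:
            raise ValueError("mean_min must be >= 0")


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample count table (TSV or CSV, gene ids in column 0)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(counts=df)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.counts.to_csv(path, sep=sep)


def filter_genes(
    matrix: ExpressionMatrix, params: FilterParams = FilterParams()
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop unreliable genes; return (filtered matrix, removal report).

    A gene is kept iff its zero-count sample number is strictly below
    ``zero_sample_min`` AND its mean raw count is >= ``mean_min`` ("10 or
    more" is inclusive, "smaller than eight" is strict).  The report lists
    every removed gene with the rule(s) that fired.
    """
    counts = matrix.counts
    if counts.empty:
        raise ValueError("empty count matrix")
    n_zero = (counts == 0).sum(axis=1)
    means = counts.mean(axis=1)
    too_many_zeros = n_zero >= params.zero_sample_min
    too_low_mean = means < params.mean_min
    removed = too_many_zeros | too_low_mean
    report = pd.DataFrame({
        "gene_id": counts.index[removed],
        "n_zero_samples": n_zero[removed].values,
        "mean_count": means[removed].values,
        "zero_rule": too_many_zeros[removed].values,
        "mean_rule": too_low_mean[removed].values,
    }).set_index("gene_id")
    kept = ExpressionMatrix(counts=counts.loc[~removed])
    return kept, report


def normalize_counts(matrix: ExpressionMatrix, method: str = "cpm") -> ExpressionMatrix:
    """Attach a normalized view (default counts-per-million).

    CPM scales each sample by its library size; it is strictly monotone per
    sample, so gene ranks within a sample — and all downstream Spearman
    statistics across samples — are unchanged by this choice.
    """
    counts = matrix.counts
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    if method != "cpm":
        raise ValueError(f"unknown normalization method {method!r}")
    normalized = counts / lib * 1e6
    return ExpressionMatrix(counts=counts, normalized=normalized)
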