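"""Gene × sample count matrices: container, I/O, filtering and summaries.

Shotgun-metagenomic gene abundance data arrives as a table of non-negative
integer counts with genes as rows and samples as columns.  ``CountMatrix``
is the in-memory representation used throughout the package; it validates
its invariants eagerly so downstream stages can assume a clean matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "filter_genes",
    "library_sizes",
]

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


@dataclass
class CountMatrix:
    """Non-negative integer gene abundance table.

    Parameters
    ----------
    counts
        ``(m, n)`` array of non-negative integers; genes in rows,
        samples in columns.
    gene_ids
        ``m`` unique, non-empty gene identifiers.
    sample_ids
        ``n`` unique, non-empty sample identifiers.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("counts must have at least one gene and one sample")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.any(arr != rounded):
                raise ValueError("counts must be integers")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=False)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        self.counts = arr

        m, n = arr.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != m:
            raise ValueError(f"expected {m} gene ids, got {len(self.gene_ids)}")
        if len(self.sample_ids) != n:
            raise ValueError(f"expected {n} sample ids, got {len(self.sample_ids)}")
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if any(i == "" for i in ids):
                raise ValueError(f"empty {label} id")
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label} ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), list(self.gene_ids), list(self.sample_ids))

    def subset_samples(self, indices: Sequence[int]) -> "CountMatrix":
        """Return a new matrix restricted to the given sample columns."""
        idx = list(indices)
        return CountMatrix(
            self.counts[:, idx].copy(),
            list(self.gene_ids),
            [self.sample_ids[j] for j in idx],
        )

    def with_counts(self, counts: np.ndarray) -> "CountMatrix":
        """Return a new matrix with the same ids but replaced counts."""
        return CountMatrix(np.asarray(counts), list(self.gene_ids), list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_counts(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a count table (first column gene ids, header row sample ids)."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"dialect must be one of {sorted(_DIALECT_SEP)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], index_col=0, header=0)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (missing header?)")
    # A header made entirely of numbers means the first data row was consumed
    # as column names, i.e. the file has no header.
    header_numeric = all(_is_number(str(c)) for c in df.columns)
    if header_numeric:
        raise ValueError(f"{path}: header row appears to be data (missing header)")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise ValueError(f"{path}: non-numeric value in count table body")
    return CountMatrix(body, [str(i) for i in df.index], [str(c) for c in df.columns])


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_counts(cm: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count table readable by :func:`read_counts`."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"dialect must be one of {sorted(_DIALECT_SEP)}")
    sep = _DIALECT_SEP[dialect]
    for ident in [*cm.gene_ids, *cm.sample_ids]:
        if ident == "":
            raise ValueError("empty identifier cannot be written")
        if sep in ident or "\n" in ident:
            raise ValueError(f"identifier {ident!r} contains the field separator")
    cm.to_dataframe().to_csv(Path(path), sep=sep, index_label="gene_id")


def filter_genes(
    cm: CountMatrix,
    max_zero_fraction: float = 0.75,
    min_mean: float = 3.0,
) -> CountMatrix:
    """Drop sparse and low-abundance genes.

    A gene is retained iff its fraction of zero counts is at most
    ``max_zero_fraction`` **and** its mean count is at least ``min_mean``
    (both thresholds strict on the removal side: exactly 75% zeros or a
    mean of exactly three survives).  Gene order and the sample set are
    preserved.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    if min_mean < 0:
        raise ValueError("min_mean must be non-negative")
    zero_frac = np.mean(cm.counts == 0, axis=1)
    means = cm.counts.mean(axis=1)
    keep = (zero_frac <= max_zero_fraction) & (means >= min_mean)
    if not keep.any():
        raise ValueError(
            "gene filter removed every gene; relax max_zero_fraction/min_mean"
        )
    return CountMatrix(
        cm.counts[keep].copy(),
        [g for g, k in zip(cm.gene_ids, keep) if k],
        list(cm.sample_ids),
    )


def library_sizes(cm: CountMatrix) -> np.ndarray:
    """Per-sample sequencing depth: the column sums of the count matrix."""
    return cm.counts.sum(axis=0)
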