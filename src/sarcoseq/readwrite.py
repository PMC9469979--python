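"""Count-matrix containers, I/O and normalization.

A study ships as two text files: a tab-delimited gene x sample matrix of
raw counts (first column gene IDs, header row of sample IDs) and a CSV
metadata table with at least ``sample_id`` and ``subtype`` columns
(``batch`` optional). Everything downstream — differential expression,
outlier QC, marker screens — consumes the :class:`CountMatrix` built here
or one of the derived :class:`ExpressionMatrix` transforms.

Normalization follows the median-of-ratios convention: each sample's size
factor is the median, over genes expressed in every sample, of the ratio
of its count to the gene's geometric mean. Log-normalization is
``log2(count / size_factor + pseudocount)`` with pseudocount 0.5, which is
defined at zero while still permitting negative values for weakly
expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "size_factors",
    "normalized",
    "log_normalized",
    "zscore",
    "top_variable_genes",
]


class FormatError(ValueError):
    """Raised when an input file violates the count-matrix contract."""


class MetadataError(ValueError):
    """Raised when sample metadata does not cover the count matrix."""


class NormalizationError(ValueError):
    """Raised when size factors cannot be computed."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, index = gene IDs,
        columns = sample IDs.
    metadata
        DataFrame indexed by sample ID with a ``subtype`` column and an
        optional ``batch`` column. Rows are aligned to the count columns
        on construction.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicated gene ID: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicated sample ID: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise MetadataError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        if "subtype" not in self.metadata.columns:
            raise MetadataError("metadata lacks required 'subtype' column")
        # align metadata rows to count-matrix column order
        self.metadata = self.metadata.loc[self.counts.columns]
        if self.metadata["subtype"].isna().any():
            bad = self.metadata.index[self.metadata["subtype"].isna()][0]
            raise MetadataError(f"sample {bad!r} has no subtype label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def subtypes(self) -> pd.Series:
        return self.metadata["subtype"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.metadata.loc[ids].copy())

    def relabel(self, new_labels: dict[str, str]) -> "CountMatrix":
        md = self.metadata.copy()
        for sid, lab in new_labels.items():
            md.loc[sid, "subtype"] = lab
        return CountMatrix(self.counts.copy(), md)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix carrying its transform tag."""

    values: pd.DataFrame
    transform_tag: str  # one of {"normalized", "log_normalized", "zscore"}

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a tab-delimited count matrix and its CSV metadata table.

    Raises
    ------
    FormatError
        For non-integer/negative entries or duplicated IDs, naming the
        offending row/column.
    MetadataError
        When a sample in the matrix header is absent from the metadata.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    md = pd.read_csv(metadata_path)
    if "sample_id" not in md.columns:
        raise MetadataError("metadata lacks required 'sample_id' column")
    md = md.set_index("sample_id")
    md.index = md.index.astype(str)
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric count at gene {bad.index[0]!r}, sample {col!r}"
            )
    return CountMatrix(counts, md)


def write_counts(cm: CountMatrix, path: str | Path,
                 metadata_path: str | Path | None = None) -> None:
    """Write counts as tab-delimited text (and metadata as CSV)."""
    cm.counts.to_csv(path, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        out = cm.metadata.copy()
        out.index.name = "sample_id"
        out.to_csv(metadata_path, lineterminator="\n")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only genes with a nonzero count in every sample enter the per-gene
    geometric means; the factor for sample *j* is the median over those
    genes of ``count_gj / geometric_mean_g``.
    """
    arr = cm.counts.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; filter the matrix "
            "or merge fewer samples before computing size factors"
        )
    logged = np.log(arr[expressed])
    geo_mean = np.exp(logged.mean(axis=1))
    sf = np.median(arr[expressed] / geo_mean[:, None], axis=0)
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalized(cm: CountMatrix,
               factors: pd.Series | None = None) -> ExpressionMatrix:
    """Linear-scale normalized expression: count / size factor."""
    if factors is None:
        factors = size_factors(cm)
    vals = cm.counts.div(factors, axis=1)
    return ExpressionMatrix(vals, "normalized")


def log_normalized(cm: CountMatrix, pseudocount: float = 0.5,
                   factors: pd.Series | None = None) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount); negatives permitted."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if factors is None:
        factors = size_factors(cm)
    vals = np.log2(cm.counts.div(factors, axis=1) + pseudocount)
    return ExpressionMatrix(vals, "log_normalized")


def zscore(em: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise z-scores; rows with zero variance become all-zero."""
    vals = em.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mu) / sd, 0.0)
    return ExpressionMatrix(
        pd.DataFrame(z, index=em.gene_ids, columns=em.sample_ids), "zscore"
    )


def top_variable_genes(em: ExpressionMatrix, k: int) -> list[str]:
    """The *k* genes with the largest row variance.

    Ties are broken by lexicographic gene ID so the ranking is
    deterministic.
    """
    n = len(em.gene_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    var = em.values.var(axis=1, ddof=1).to_numpy()
    ids = em.gene_ids.to_numpy(dtype=object)
    order = np.lexsort((ids, -var))
    return [str(g) for g in ids[order[:k]]]
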