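"""Core domain types and tabular I/O.

The toolkit moves four kinds of tables around: a raw gene x sample count
matrix, a sample metadata table, per-contrast differential-expression result
tables produced by an external DE engine, and an optional gene-ID -> display
name mapping.  Everything is plain TSV/CSV (UTF-8, "." decimal point,
``NA``/empty parsed as missing); there is no HDF5/AnnData ingestion and no
deserialization of R-native objects — flat tables are the interchange format.

Orientation is fixed as genes-in-rows, samples-in-columns, matching the
convention of the common DE engines.  Transposed input is only handled when
the caller says so explicitly; no orientation heuristics are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StructureError",
    "ValidationError",
    "ContrastLabel",
    "CountMatrix",
    "SampleMetadata",
    "ContrastResult",
    "GeneMap",
    "PairReport",
    "DEFAULT_DIALECT",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "read_contrast_table",
    "write_contrast_table",
    "validate_pair",
]


class StructureError(ValueError):
    """The shape or identifiers of a table violate a structural invariant."""


class ValidationError(ValueError):
    """A cell value violates a domain constraint (sign, range, missingness)."""


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise StructureError(f"duplicate {what} ID(s): {', '.join(map(str, dups))}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer gene x sample counts; the root input of every analysis.

    ``counts`` is a DataFrame indexed by gene ID with sample IDs as columns.
    Construction validates the invariants: unique IDs, non-negative integer
    cells, at least one gene and two samples.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise StructureError(
                f"count matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(arr))
            r, c = bad[0]
            raise ValidationError(
                f"non-numeric count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise ValidationError(
                f"missing count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count {arr[r, c]} at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            frac = np.abs(arr - np.round(arr)) > 0
            r, c = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count {arr[r, c]} at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample factor table, indexed by sample ID.

    Factor columns are categorical; no missing entries are allowed (a sample
    without a level for some factor cannot be grouped, so it is rejected at
    load time rather than silently dropped later).
    """

    factors: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.factors
        _check_unique(df.index, "sample")
        if df.isna().any().any():
            mask = df.isna()
            for col in df.columns:
                if mask[col].any():
                    sample = df.index[mask[col]][0]
                    raise ValidationError(
                        f"missing value for sample {sample!r} in factor {col!r}"
                    )
        object.__setattr__(
            self, "factors", df.apply(lambda c: c.astype("category"))
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    def levels(self, factor: str) -> list[str]:
        if factor not in self.factors.columns:
            raise KeyError(
                f"unknown factor {factor!r}; available: {self.factor_names}"
            )
        return list(self.factors[factor].cat.categories)


@dataclass(frozen=True)
class ContrastLabel:
    """Identity of a pairwise comparison: numerator vs denominator on a factor."""

    numerator: str
    denominator: str
    factor: str

    def __str__(self) -> str:
        return f"{self.factor}:{self.numerator}_vs_{self.denominator}"

    @classmethod
    def parse(cls, text: str) -> "ContrastLabel":
        factor, _, rest = text.partition(":")
        num, _, den = rest.partition("_vs_")
        if not (factor and num and den):
            raise ValueError(f"cannot parse contrast label {text!r}")
        return cls(num, den, factor)


#: Header synonyms understood by :func:`read_contrast_table`, keyed by the
#: canonical column name.  Covers the common DE-engine output headers.
DEFAULT_DIALECT: dict[str, tuple[str, ...]] = {
    "gene": ("gene", "gene_id", "id", "feature", "row"),
    "mean_expr": ("mean_expr", "baseMean", "AveExpr", "logCPM", "base_mean"),
    "log2fc": ("log2fc", "log2FoldChange", "logFC", "lfc", "log2_fold_change"),
    "pvalue": ("pvalue", "PValue", "P.Value", "pval", "p_value"),
    "padj": ("padj", "FDR", "adj.P.Val", "qvalue", "p_adj", "adjusted_pvalue"),
}


@dataclass(frozen=True)
class ContrastResult:
    """One contrast's per-gene DE statistics.

    ``table`` is indexed by gene ID with columns ``mean_expr``, ``log2fc``,
    ``pvalue``, ``padj``.  A missing ``padj`` is routine (external engines
    emit NA for genes removed by independent filtering) and is kept as NaN;
    a missing ``pvalue`` indicates a corrupt table and is rejected.
    """

    label: ContrastLabel
    table: pd.DataFrame
    all_padj_missing: bool = False

    def __post_init__(self) -> None:
        df = self.table
        required = ["mean_expr", "log2fc", "pvalue", "padj"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise StructureError(f"contrast table missing column(s) {missing}")
        _check_unique(df.index, "gene")
        df = df[required].astype(float)
        if df["pvalue"].isna().any():
            gene = df.index[df["pvalue"].isna()][0]
            raise ValidationError(f"missing pvalue for gene {gene!r}")
        for col in ("pvalue", "padj"):
            vals = df[col]
            bad = vals.notna() & ((vals < 0) | (vals > 1))
            if bad.any():
                gene = df.index[bad][0]
                raise ValidationError(
                    f"{col} {vals[gene]} outside [0,1] for gene {gene!r}"
                )
        both = df["padj"].notna()
        below = both & (df["padj"] < df["pvalue"] - 1e-12)
        if below.any():
            gene = df.index[below][0]
            raise ValidationError(
                f"padj < pvalue for gene {gene!r} "
                f"({df.loc[gene, 'padj']} < {df.loc[gene, 'pvalue']})"
            )
        object.__setattr__(self, "table", df)
        object.__setattr__(self, "all_padj_missing", bool(df["padj"].isna().all()))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class GeneMap:
    """Gene ID -> display name mapping with an explicit unmapped-ID policy.

    policy: ``keep-original`` keeps the input ID, ``drop`` removes the entry,
    ``error`` raises on the first unmapped ID.
    """

    mapping: Mapping[str, str]
    policy: str = "keep-original"

    def __post_init__(self) -> None:
        if self.policy not in ("keep-original", "drop", "error"):
            raise ValueError(f"unknown unmapped-ID policy {self.policy!r}")
        object.__setattr__(self, "mapping", dict(self.mapping))


@dataclass(frozen=True)
class PairReport:
    """Sample-ID reconciliation between a count matrix and its metadata."""

    counts_only: tuple[str, ...]
    metadata_only: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.counts_only and not self.metadata_only


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a gene x sample TSV/CSV count table.

    First column holds gene IDs, header row holds sample IDs.  The delimiter
    is inferred from the extension (``.csv`` -> comma, otherwise tab) unless
    given explicitly.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, delimiter: str | None = None
) -> Path:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    cm.counts.to_csv(path, sep=sep, index_label="gene")
    return path


def read_metadata(
    path: str | Path, id_column: str = "sample", delimiter: str | None = None
) -> SampleMetadata:
    """Read a sample metadata table; all non-ID columns become factors."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", ""])
    if id_column not in df.columns:
        raise StructureError(
            f"id column {id_column!r} not found; available: {list(df.columns)}"
        )
    df = df.set_index(id_column)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_contrast_table(
    path: str | Path,
    dialect: Mapping[str, tuple[str, ...]] | None = None,
    label: ContrastLabel | None = None,
    delimiter: str | None = None,
) -> ContrastResult:
    """Read one contrast's DE result table in any recognised header dialect.

    ``dialect`` maps canonical names (gene, mean_expr, log2fc, pvalue, padj)
    to accepted header synonyms; it extends :data:`DEFAULT_DIALECT`.  A table
    lacking a padj column entirely is accepted and flagged all-missing.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    syn = {k: tuple(v) for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        for k, v in dialect.items():
            syn[k] = tuple(v) + syn.get(k, ())

    rename: dict[str, str] = {}
    for canonical, names in syn.items():
        hit = next((c for c in df.columns if c in names), None)
        if hit is not None:
            rename[hit] = canonical
    df = df.rename(columns=rename)

    if "gene" not in df.columns:
        # fall back: unnamed first column as gene IDs
        df = df.rename(columns={df.columns[0]: "gene"})
    required = ["mean_expr", "log2fc", "pvalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructureError(
            f"cannot map required column(s) {missing}; accepted headers: "
            + "; ".join(f"{k}: {list(syn[k])}" for k in missing)
        )
    if "padj" not in df.columns:
        df["padj"] = np.nan
    df = df.set_index(df["gene"].astype(str)).drop(columns=["gene"])
    df.index.name = "gene"
    if label is None:
        label = ContrastLabel("unknown", "unknown", "unknown")
    return ContrastResult(label=label, table=df)


def write_contrast_table(
    cr: ContrastResult, path: str | Path, delimiter: str | None = None
) -> Path:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    cr.table.to_csv(path, sep=sep, index_label="gene", na_rep="NA")
    return path


def validate_pair(cm: CountMatrix, md: SampleMetadata) -> PairReport:
    """Report sample IDs present in only one of counts / metadata.

    Report-only: an empty report means the two inputs cover the same samples.
    """
    c = set(cm.sample_ids)
    m = set(md.sample_ids)
    return PairReport(
        counts_only=tuple(sorted(c - m)),
        metadata_only=tuple(sorted(m - c)),
    )
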