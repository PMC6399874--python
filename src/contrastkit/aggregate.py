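"""Multi-contrast aggregation: the master result set and its manipulation.

Many experiments produce one DE contrast per time point or treatment, each
with its own significant gene set; direct comparison needs a common gene
universe.  ``aggregate`` merges contrasts by union or intersection of their
significant genes and then re-extracts the fold change and adjusted p-value
of every retained gene from every contrast — including contrasts where the
gene did not reach significance — so cross-contrast heat maps and profile
plots have a complete matrix to draw.  The boolean ``sig`` matrix keeps the
per-contrast significance distinction.

Agreement densities (one smoothed curve of padj or log2fc per contrast,
restricted to the master genes) show whether merging the contrasts was
sensible: strong overlap of the curves supports a union, divergence argues
for intersection or a different grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .de import SignificanceSet, call_significance
from .io import ContrastResult, CountMatrix, SampleMetadata, StructureError
from .stats import kde_1d, silverman_bandwidth

__all__ = [
    "MasterResult",
    "AgreementDensity",
    "aggregate",
    "agreement_density",
    "filter_master",
    "subset_samples",
    "derive_metadata_field",
    "sort_genes",
]

_SORT_STATS = ("max", "min", "mean", "variance", "sd")


@dataclass(frozen=True)
class MasterResult:
    """Gene x contrast matrices built by aggregating several contrasts.

    ``lfc``, ``padj`` and ``sig`` share identical row (gene) and column
    (contrast label) ordering.  ``mode`` records whether the row set is the
    union or the intersection of the per-contrast significant sets at the
    recorded thresholds; ``provenance`` accumulates the filters applied
    since aggregation.
    """

    lfc: pd.DataFrame
    padj: pd.DataFrame
    sig: pd.DataFrame
    mode: str
    p_cut: float
    lfc_cut: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("union", "intersection"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        for name, df in (("padj", self.padj), ("sig", self.sig)):
            if list(df.index) != list(self.lfc.index) or list(df.columns) != list(
                self.lfc.columns
            ):
                raise StructureError(f"{name} matrix not aligned with lfc matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lfc.index)

    @property
    def contrast_names(self) -> list[str]:
        return list(self.lfc.columns)

    @property
    def n_genes(self) -> int:
        return self.lfc.shape[0]

    def overlap_counts(self) -> pd.Series:
        """Per gene, the number of contrasts in which it is significant."""
        return self.sig.sum(axis=1).astype(int)

    def to_tsvs(self, directory: str | Path, stem: str) -> list[Path]:
        """Write the three aligned matrices plus a key-value sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in (("lfc", self.lfc), ("padj", self.padj), ("sig", self.sig)):
            p = directory / f"{stem}_{name}.tsv"
            out = df.astype(int) if name == "sig" else df
            out.to_csv(p, sep="\t", index_label="gene", na_rep="NA")
            paths.append(p)
        side = directory / f"{stem}_provenance.txt"
        with open(side, "w") as fh:
            fh.write(f"mode={self.mode}\n")
            fh.write(f"p_cut={self.p_cut}\n")
            fh.write(f"lfc_cut={self.lfc_cut}\n")
            fh.write(f"contrasts={','.join(self.contrast_names)}\n")
            for step in self.provenance:
                fh.write(f"filter={step}\n")
        paths.append(side)
        return paths


@dataclass(frozen=True)
class AgreementDensity:
    """Per-contrast density of padj or log2fc over the master gene set."""

    grid: np.ndarray
    densities: dict  # contrast name -> density values on grid
    on: str  # "padj" | "lfc"
    overlap: pd.Series  # gene -> number of contrasts significant in


def aggregate(
    contrasts: list[ContrastResult],
    mode: str = "union",
    p_cut: float = 0.05,
    lfc_cut: float = 0.0,
) -> MasterResult:
    """Merge contrasts by union or intersection of their significant genes.

    Retained genes get their lfc/padj re-extracted from every contrast.  A
    gene absent from some contrast's table is kept with missing values in
    that column under union mode, but excluded under intersection mode —
    intersection semantics demand evidence in every contrast.  Rows are
    ordered lexicographically by gene ID; columns follow input order.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if not contrasts:
        raise ValueError("need at least one contrast")
    names = [str(c.label) for c in contrasts]
    if len(set(names)) != len(names):
        raise StructureError(f"duplicate contrast labels: {names}")

    sig_sets = [call_significance(c, p_cut, lfc_cut).as_set() for c in contrasts]
    if mode == "union":
        genes = set().union(*sig_sets)
    else:
        genes = set.intersection(*map(set, sig_sets))
        for c in contrasts:  # evidence required in every contrast
            genes &= set(c.gene_ids)
    gene_order = sorted(genes)
    if not gene_order:
        warnings.warn("aggregation produced an empty master result", stacklevel=2)

    lfc = pd.DataFrame(index=gene_order, columns=names, dtype=float)
    padj = pd.DataFrame(index=gene_order, columns=names, dtype=float)
    sig = pd.DataFrame(False, index=gene_order, columns=names)
    for c, name, sset in zip(contrasts, names, sig_sets):
        present = [g for g in gene_order if g in set(c.gene_ids)]
        lfc.loc[present, name] = c.table.loc[present, "log2fc"]
        padj.loc[present, name] = c.table.loc[present, "padj"]
        sig.loc[list(genes & sset), name] = True
    lfc.index.name = padj.index.name = sig.index.name = "gene"
    return MasterResult(
        lfc=lfc, padj=padj, sig=sig, mode=mode, p_cut=p_cut, lfc_cut=lfc_cut
    )


def agreement_density(
    mr: MasterResult, contrasts: list[ContrastResult], on: str = "padj"
) -> AgreementDensity:
    """One density curve per contrast over the master genes, shared grid.

    Gaussian kernels with Silverman bandwidths per contrast; the grid spans
    the pooled values plus four of the largest bandwidth on each side, so
    the curves overlay directly and each integrates to one within 1e-3.
    """
    if on not in ("padj", "lfc"):
        raise ValueError(f"density statistic must be 'padj' or 'lfc', got {on!r}")
    if mr.n_genes < 2:
        raise ValueError("density undefined for fewer than 2 master genes")
    col = "padj" if on == "padj" else "log2fc"
    per_contrast = {}
    for c in contrasts:
        name = str(c.label)
        if name not in mr.contrast_names:
            raise StructureError(f"contrast {name!r} was not used to build master")
        genes = [g for g in mr.gene_ids if g in set(c.gene_ids)]
        vals = c.table.loc[genes, col].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"contrast {name!r} has <2 usable values for density")
        per_contrast[name] = vals

    bws = {n: silverman_bandwidth(v) for n, v in per_contrast.items()}
    pooled = np.concatenate(list(per_contrast.values()))
    # 4 bandwidths of padding keeps the truncated tail mass below the
    # 1e-3 normalization tolerance even for edge-heavy value sets
    pad = 4 * max(bws.values())
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, 512)
    densities = {
        n: kde_1d(v, bandwidth=bws[n], grid=grid).density
        for n, v in per_contrast.items()
    }
    return AgreementDensity(
        grid=grid, densities=densities, on=on, overlap=mr.overlap_counts()
    )


def filter_master(
    mr: MasterResult, p_cut: float, lfc_cut: float, scope: str = "any"
) -> MasterResult:
    """Keep genes meeting the cuts in at least one ('any') or all contrasts.

    A missing cell never satisfies the cuts.  Idempotent at fixed
    parameters; the applied filter is appended to the provenance trail.
    """
    if scope not in ("any", "all"):
        raise ValueError(f"scope must be 'any' or 'all', got {scope!r}")
    cell = mr.padj.notna() & (mr.padj < p_cut) & (mr.lfc.abs() >= lfc_cut)
    keep = cell.any(axis=1) if scope == "any" else cell.all(axis=1)
    idx = mr.lfc.index[keep]
    return MasterResult(
        lfc=mr.lfc.loc[idx],
        padj=mr.padj.loc[idx],
        sig=mr.sig.loc[idx],
        mode=mr.mode,
        p_cut=mr.p_cut,
        lfc_cut=mr.lfc_cut,
        provenance=mr.provenance
        + (f"p_cut={p_cut},lfc_cut={lfc_cut},scope={scope}",),
    )


def subset_samples(
    cm: CountMatrix, md: SampleMetadata, predicate: dict[str, str]
) -> tuple[CountMatrix, SampleMetadata]:
    """Restrict samples to those satisfying every factor=value clause.

    An empty predicate is the identity; a predicate matching no sample is an
    error (an empty count matrix is never useful downstream).
    """
    for factor in predicate:
        if factor not in md.factor_names:
            raise KeyError(
                f"unknown factor {factor!r}; available: {md.factor_names}"
            )
    keep = pd.Series(True, index=md.factors.index)
    for factor, value in predicate.items():
        keep &= md.factors[factor].astype(str) == str(value)
    ids = [s for s in cm.sample_ids if keep.get(s, False)]
    if not ids:
        raise ValueError(f"predicate {predicate} matches no sample")
    return (
        CountMatrix(cm.counts[ids]),
        SampleMetadata(md.factors.loc[ids].apply(lambda c: c.cat.remove_unused_categories())),
    )


def derive_metadata_field(
    md: SampleMetadata, fields: list[str], sep: str = "_", name: str | None = None
) -> SampleMetadata:
    """Append a composite factor whose values join the given fields by sep."""
    for f in fields:
        if f not in md.factor_names:
            raise KeyError(f"unknown factor {f!r}; available: {md.factor_names}")
    if not fields:
        raise ValueError("need at least one field")
    if name is None:
        name = sep.join(fields)
    if name in md.factor_names:
        raise StructureError(f"factor {name!r} already exists")
    combined = md.factors[fields].astype(str).agg(sep.join, axis=1)
    out = md.factors.copy()
    out[name] = combined
    return SampleMetadata(out)


def sort_genes(mr: MasterResult, stat: str = "max", descending: bool = True) -> list[str]:
    """Order master genes by a summary of their lfc row across contrasts.

    ``variance``/``sd`` use the sample (n-1) denominator; a single-contrast
    master has undefined spread, treated as 0.  Missing cells are skipped.
    The sort is stable with ties broken lexicographically by gene ID.
    """
    if stat not in _SORT_STATS:
        raise ValueError(f"unknown sort stat {stat!r}; choose from {_SORT_STATS}")
    if mr.n_genes == 0:
        raise ValueError("cannot sort an empty master result")
    lfc = mr.lfc
    if stat == "max":
        key = lfc.max(axis=1)
    elif stat == "min":
        key = lfc.min(axis=1)
    elif stat == "mean":
        key = lfc.mean(axis=1)
    elif stat == "variance":
        key = lfc.var(axis=1, ddof=1).fillna(0.0)
    else:
        key = lfc.var(axis=1, ddof=1).fillna(0.0).pow(0.5)
    frame = pd.DataFrame(
        {"key": key.to_numpy(), "gid": list(key.index)}
    ).sort_values(["key", "gid"], ascending=[not descending, True], kind="stable")
    return list(frame["gid"])
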