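"""Normalization, transformation, replicate merging and ID transposition.

The between-sample scaling method is TMM (trimmed mean of M-values): library
size differences are absorbed first, then a weighted trimmed mean of per-gene
log-ratios against a reference sample yields one scale factor per sample.
Counts are reported on the counts-per-million (CPM) scale, optionally
log2-transformed with a pseudocount, or as a shrunken ("regularized") log
that adds the pseudocount on the raw-count scale to tame low-count variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneMap, SampleMetadata, StructureError, ValidationError

__all__ = [
    "NormFactors",
    "NormalizedMatrix",
    "MergeResult",
    "tmm_factors",
    "normalize",
    "merge_replicates",
    "transpose_ids",
]


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scale factors, rescaled to geometric mean one."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        f = self.factors.astype(float)
        if (f <= 0).any():
            raise ValidationError("normalization factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-10:
            raise ValidationError(
                f"factors must have geometric mean 1 (got {gm!r})"
            )
        object.__setattr__(self, "factors", f)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Gene x sample real matrix with the method tag and parameters recorded."""

    values: pd.DataFrame
    method: str
    prior: float
    factors: NormFactors

    def __post_init__(self) -> None:
        if self.method not in ("cpm", "log2cpm", "reglog"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("normalized matrix contains non-finite entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def _tmm_one(
    y: np.ndarray, yr: np.ndarray, nk: float, nr: float, trim_m: float, trim_a: float
) -> float:
    """log2 TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded (log of zero).
    Trims ``trim_m`` of genes from each tail ranked by M and ``trim_a`` from
    each tail ranked by A; the intersection of the kept sets enters a
    weighted mean with inverse asymptotic-variance weights.
    """
    keep = (y > 0) & (yr > 0)
    y, yr = y[keep].astype(float), yr[keep].astype(float)
    if y.size == 0:
        return 0.0
    m = np.log2((y / nk) / (yr / nr))
    a = 0.5 * np.log2((y / nk) * (yr / nr))
    w = (nk - y) / (nk * y) + (nr - yr) / (nr * yr)

    n = m.size
    lo_m, lo_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
    kept = (
        (rank_m >= lo_m)
        & (rank_m < n - lo_m)
        & (rank_a >= lo_a)
        & (rank_a < n - lo_a)
    )
    if not kept.any() or w[kept].sum() == 0:
        return 0.0
    return float(np.sum(w[kept] * m[kept]) / np.sum(w[kept]))


def tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th-percentile CPM across samples (ties broken by column
    order).  For each sample k, over genes with positive counts in both k
    and the reference r:

        M_g = log2((y_gk/N_k)/(y_gr/N_r))
        A_g = 1/2 * log2((y_gk/N_k)*(y_gr/N_r))
        w_g = (N_k-y_gk)/(N_k*y_gk) + (N_r-y_gr)/(N_r*y_gr)

    with the top/bottom ``trim_m`` of genes by M and ``trim_a`` by A trimmed
    (intersection kept), factor_k = 2**(sum w*M / sum w).  Factors are then
    rescaled to geometric mean 1, so pure library-size differences yield all
    factors equal to one.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ValidationError(f"sample {bad!r} has zero library size")
    if counts.shape[1] < 2:
        raise StructureError("TMM needs at least two samples")

    cpm = counts / lib * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))  # argmin keeps earliest tie

    logf = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        logf[k] = _tmm_one(
            counts[:, k], counts[:, ref], lib[k], lib[ref], trim_m, trim_a
        )
    logf -= logf.mean()  # geometric mean of 2**logf becomes 1
    return NormFactors(
        factors=pd.Series(2.0**logf, index=cm.counts.columns),
        reference_sample=cm.sample_ids[ref],
    )


def normalize(
    cm: CountMatrix,
    nf: NormFactors,
    method: str = "log2cpm",
    prior: float | None = None,
) -> NormalizedMatrix:
    """Scale counts to CPM using TMM-adjusted library sizes.

    cpm      = 1e6 * count / (library * factor)
    log2cpm  = log2(cpm + prior)                      (prior default 1)
    reglog   = log2(1e6 * (count + prior) / (library * factor))
                                                      (prior default 4)

    ``reglog`` adds the pseudocount on the raw-count scale before scaling —
    a shrunken log that damps the variance of low-count genes, serving the
    same visual purpose as a regularized-log transform.
    """
    if method not in ("cpm", "log2cpm", "reglog"):
        raise ValueError(f"unknown normalization method {method!r}")
    if list(nf.factors.index) != cm.sample_ids:
        nf_aligned = nf.factors.reindex(cm.counts.columns)
        if nf_aligned.isna().any():
            raise StructureError("normalization factors not aligned to samples")
    else:
        nf_aligned = nf.factors
    if prior is None:
        prior = 1.0 if method == "log2cpm" else 4.0

    eff = cm.library_sizes().astype(float) * nf_aligned
    counts = cm.counts.astype(float)
    if method == "cpm":
        vals = counts.div(eff, axis=1) * 1e6
    elif method == "log2cpm":
        vals = np.log2(counts.div(eff, axis=1) * 1e6 + prior)
    else:  # reglog
        vals = np.log2((counts + prior).div(eff, axis=1) * 1e6)
    return NormalizedMatrix(values=vals, method=method, prior=float(prior), factors=nf)


class MergeResult(NamedTuple):
    counts: CountMatrix
    metadata: SampleMetadata
    dropped_factors: tuple[str, ...]


def merge_replicates(cm: CountMatrix, md: SampleMetadata, key: str) -> MergeResult:
    """Sum counts within each level of ``key``; total counts are conserved.

    Merged metadata keeps only factors that are constant within every level;
    factors that vary within a level are dropped and reported in
    ``dropped_factors``.
    """
    if key not in md.factor_names:
        raise StructureError(
            f"merge key {key!r} not a metadata factor; available: {md.factor_names}"
        )
    groups = md.factors[key].astype(str)
    groups = groups.reindex(cm.counts.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise StructureError(f"samples missing from metadata: {missing}")

    merged_counts = cm.counts.T.groupby(groups).sum().T
    merged_counts = merged_counts[list(dict.fromkeys(groups))]  # first-seen order

    kept: dict[str, list] = {}
    dropped: list[str] = []
    for factor in md.factor_names:
        if factor == key:
            continue
        per_level = md.factors.groupby(groups, observed=True)[factor].nunique()
        if (per_level <= 1).all():
            firsts = md.factors.groupby(groups, observed=True)[factor].first()
            kept[factor] = [firsts[g] for g in merged_counts.columns]
        else:
            dropped.append(factor)
    meta = pd.DataFrame(kept, index=merged_counts.columns)
    if meta.empty:
        meta = pd.DataFrame(index=merged_counts.columns)
        meta[key] = list(merged_counts.columns)
    else:
        meta.insert(0, key, list(merged_counts.columns))
    return MergeResult(
        counts=CountMatrix(merged_counts),
        metadata=SampleMetadata(meta),
        dropped_factors=tuple(dropped),
    )


def transpose_ids(ids: Sequence[str], gm: GeneMap) -> list[str]:
    """Replace gene IDs by display names per the map's unmapped-ID policy.

    Any display name produced by two or more inputs is disambiguated by
    suffixing the original ID as ``NAME|ID`` for every colliding entry.
    """
    out: list[tuple[str, str]] = []  # (name, original id)
    for gid in ids:
        if gid in gm.mapping:
            out.append((gm.mapping[gid], gid))
        elif gm.policy == "keep-original":
            out.append((gid, gid))
        elif gm.policy == "drop":
            continue
        else:
            raise KeyError(f"unmapped gene ID {gid!r}")
    counts: dict[str, int] = {}
    for name, _ in out:
        counts[name] = counts.get(name, 0) + 1
    return [name if counts[name] == 1 else f"{name}|{gid}" for name, gid in out]
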