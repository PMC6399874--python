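"""Self-contained statistical primitives used across the toolkit.

Three pieces: the Wilcoxon rank-sum (Mann-Whitney) test with an exact
enumeration path for small tie-free samples, Benjamini-Hochberg step-up
adjustment with missing-value passthrough, and 1-D Gaussian kernel density
estimation with Silverman's bandwidth rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "DensityCurve", "wilcoxon_rank_sum", "bh_adjust", "kde_1d"]

#: Exact enumeration is used when the pooled sample is at most this large and
#: tie-free: C(12,6)=924 rank splits, enumerated instantly and exactly testable.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    """Rank-sum test outcome; ``statistic`` is the rank sum W of group one."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approx"
    n1: int
    n2: int
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum test of two independent samples.

    The p-value is exact — by full enumeration of all C(n1+n2, n1) rank
    assignments — when n1+n2 <= 12 and the pooled data has no ties; the
    two-sided exact p doubles the smaller tail probability, capped at 1.
    Otherwise a normal approximation with tie-corrected variance and a
    0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # average ranks on ties
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_LIMIT and not has_ties:
        sums = np.array(
            [sum(c) for c in combinations(range(1, n + 1), n1)], dtype=float
        )
        total = sums.size
        p_ge = np.count_nonzero(sums >= w - 1e-9) / total
        p_le = np.count_nonzero(sums <= w + 1e-9) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(w, p, "exact", n1, n2, alternative)

    mu = n1 * (n + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t**3 - t) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(w, 1.0, "normal-approx", n1, n2, alternative)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (w - mu - 0.5 * np.sign(w - mu)) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w, float(min(max(p, np.nextafter(0, 1)), 1.0)),
                      "normal-approx", n1, n2, alternative)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN/None) stay missing and do not count toward the
    number of tests m.  Adjusted values are monotone (cumulative minimum
    from the largest rank down) and capped at 1.  Accepts any 1-D sequence;
    returns a float array of the same length.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in np.asarray(pvals, dtype=object)],
        dtype=float,
    )
    ok = ~np.isnan(arr)
    p = arr[ok]
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    m = p.size
    out = np.full(arr.shape, np.nan)
    if m:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        tmp = np.empty(m)
        tmp[order] = adj
        out[ok] = tmp
    return out


@dataclass(frozen=True)
class DensityCurve:
    """A 1-D kernel density estimate evaluated on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n**(-1/5), skipping degenerate candidates.

    If both the standard deviation and the IQR are zero the data carries no
    spread and no automatic bandwidth exists.
    """
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    candidates = [c for c in (sd, iqr / 1.34) if c > 0]
    if not candidates:
        raise ValueError(
            "data has zero variance and zero IQR; pass an explicit bandwidth"
        )
    return 0.9 * min(candidates) * values.size ** (-1 / 5)


def kde_1d(
    values,
    bandwidth: float | str = "auto",
    grid: np.ndarray | None = None,
    gridsize: int = 512,
) -> DensityCurve:
    """Gaussian kernel density estimate.

    With ``bandwidth='auto'`` Silverman's rule is applied.  The default grid
    spans the data plus three bandwidths on each side, at ``gridsize``
    points; a shared external grid may be supplied for curves meant to be
    overlaid.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("kernel density needs at least two values")
    bw = silverman_bandwidth(values) if bandwidth == "auto" else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, gridsize)
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))
    return DensityCurve(grid=np.asarray(grid, dtype=float), density=dens, bandwidth=bw)
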