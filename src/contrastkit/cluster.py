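"""Distances, hierarchical clustering, classical MDS and group overlays.

Sample relationships are examined before any DE call: a Euclidean or
Poisson-model distance matrix between samples, an agglomerative dendrogram,
and a classical (Torgerson) multidimensional scaling embedding with either
normal-theory confidence ellipses or convex hulls drawn per metadata group.
After aggregation, genes are clustered by the shape of their fold-change
profile across contrasts (rows z-scored so shape, not magnitude, drives the
grouping).

The agglomeration is implemented here rather than delegated so that ties in
the merge order are broken deterministically (the pair whose lexicographically
smallest IDs compare lowest merges first); the result is exposed in the
standard SciPy linkage encoding so cutting, leaf ordering and cophenetic
distances reuse ``scipy.cluster.hierarchy``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .io import CountMatrix, SampleMetadata, StructureError, ValidationError
from .preprocess import NormalizedMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Embedding",
    "EllipseSpec",
    "GroupOverlay",
    "ProfileClusters",
    "distance_matrix",
    "hcluster",
    "classical_mds",
    "group_overlay",
    "cluster_profiles",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise StructureError(f"distance matrix shape {v.shape} != ({n},{n})")
        if not np.array_equal(v, v.T):
            raise ValidationError("distance matrix not exactly symmetric")
        if np.diagonal(v).any():
            raise ValidationError("distance matrix diagonal not zero")
        if (v < 0).any():
            raise ValidationError("negative distance")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in SciPy linkage encoding.

    ``merges`` is the (n-1, 4) linkage array: each row merges two cluster
    indices (leaves are 0..n-1, new clusters n, n+1, ...) at a height, with
    the resulting cluster size in the last column.
    """

    merges: np.ndarray
    ids: tuple[str, ...]
    linkage: str

    def __post_init__(self) -> None:
        z = np.asarray(self.merges, dtype=float)
        if z.shape != (len(self.ids) - 1, 4):
            raise StructureError("linkage array shape mismatch")
        object.__setattr__(self, "merges", z)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in sch.leaves_list(self.merges)]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k groups."""
        labels = sch.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.ids), name="cluster")

    def cophenetic(self) -> np.ndarray:
        return squareform(sch.cophenet(self.merges))

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = len(self.ids)
        height = {i: 0.0 for i in range(n)}
        text = {i: _newick_escape(self.ids[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + step
            text[node] = (
                f"({text[a]}:{h - height[a]:.10g},{text[b]}:{h - height[b]:.10g})"
            )
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


def _newick_escape(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional coordinates from classical scaling.

    Coordinates are column-centered; axes are ordered by descending
    eigenvalue of the double-centered matrix, and ``proportion`` gives the
    share of (positive) eigenvalue mass captured per axis.
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    proportion: np.ndarray

    @property
    def ids(self) -> list[str]:
        return list(self.coords.index)


@dataclass(frozen=True)
class EllipseSpec:
    """Normal-theory confidence ellipse: center, semi-axes, angle (degrees)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float
    level: float


@dataclass(frozen=True)
class GroupOverlay:
    """Per-group ellipses or convex hulls on a 2-D embedding.

    ``groups`` maps group name to an :class:`EllipseSpec` or an (m, 2) array
    of hull vertices in counter-clockwise order; groups with too few or
    degenerate points are listed in ``skipped`` instead.
    """

    style: str
    level: float
    groups: dict
    skipped: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProfileClusters:
    """Gene clusters by fold-change profile shape across contrasts."""

    labels: pd.Series  # gene -> cluster id (1..k)
    centers: pd.DataFrame  # cluster id x contrast, mean z-scored profile
    excluded: tuple[str, ...]  # genes dropped for missing values


def _as_frame(data) -> tuple[pd.DataFrame, bool]:
    """Extract a DataFrame and whether the values are raw integer counts."""
    if isinstance(data, CountMatrix):
        return data.counts, True
    if isinstance(data, NormalizedMatrix):
        return data.values, False
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy()
        is_counts = np.issubdtype(arr.dtype, np.integer) or (
            np.issubdtype(arr.dtype, np.number) and np.allclose(arr, np.round(arr))
        )
        return data, bool(is_counts)
    raise TypeError(f"cannot compute distances from {type(data).__name__}")


def distance_matrix(data, metric: str = "euclidean", axis: str = "samples") -> DistanceMatrix:
    """Pairwise distances between samples (columns) or genes (rows).

    ``euclidean`` accepts any real matrix.  ``poisson`` requires raw counts
    and samples on the chosen axis: counts are divided by size factors
    s_i = N_i / geometric-mean(N), and the distance is the square root of
    the symmetrized Poisson deviance divergence
    sum_g x'_gi ln(x'_gi/mu_g) + x'_gj ln(x'_gj/mu_g) with
    mu_g = (x'_gi + x'_gj)/2 and 0*ln(0/.) = 0 — zero iff the size-adjusted
    profiles coincide, so pure sequencing-depth differences vanish.
    """
    if axis not in ("samples", "genes"):
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    frame, is_counts = _as_frame(data)
    mat = frame.to_numpy(dtype=float)
    if axis == "samples":
        items = list(frame.columns)
        vectors = mat.T  # item x feature
    else:
        items = list(frame.index)
        vectors = mat

    if metric == "euclidean":
        d = squareform(pdist(vectors, metric="euclidean"))
    elif metric == "poisson":
        if not is_counts:
            raise ValidationError("poisson distance requires raw integer counts")
        if axis != "samples":
            raise ValueError("poisson distance is defined between samples")
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValidationError("poisson distance needs positive library sizes")
        size = lib / np.exp(np.mean(np.log(lib)))
        x = mat / size  # gene x sample, depth-adjusted
        n = x.shape[1]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                xi, xj = x[:, i], x[:, j]
                mu = (xi + xj) / 2.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    ti = np.where(xi > 0, xi * np.log(xi / mu), 0.0)
                    tj = np.where(xj > 0, xj * np.log(xj / mu), 0.0)
                d[i, j] = d[j, i] = np.sqrt(max(float(np.sum(ti + tj)), 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}")

    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry (fp addition commutes)
    return DistanceMatrix(ids=tuple(map(str, items)), values=d, metric=metric)


def hcluster(dm: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    At each step the closest pair of clusters merges; among equally close
    pairs the one whose (sorted) smallest member IDs are lexicographically
    lowest merges first.  Inter-cluster distance is updated per the linkage:
    complete = max, average = size-weighted mean, single = min.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two items to cluster")

    d = dm.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    alive = np.ones(n, dtype=bool)
    node = {i: i for i in range(n)}  # row index -> linkage node id
    size = {i: 1 for i in range(n)}
    minid = {i: dm.ids[i] for i in range(n)}  # lexicographic tie-break key
    merges = []
    next_node = n

    for _ in range(n - 1):
        m = d.min()
        cand = np.argwhere(d == m)
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda p: tuple(sorted((minid[p[0]], minid[p[1]]))))
        dist = float(d[i, j])
        na, nb = node[i], node[j]
        merges.append([min(na, nb), max(na, nb), dist, size[i] + size[j]])

        others = alive.copy()
        others[[i, j]] = False
        if linkage == "complete":
            upd = np.maximum(d[i], d[j])
        elif linkage == "single":
            upd = np.minimum(d[i], d[j])
        else:
            upd = (size[i] * d[i] + size[j] * d[j]) / (size[i] + size[j])
        d[i, others] = upd[others]
        d[others, i] = upd[others]
        alive[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
        node[i] = next_node
        size[i] = size[i] + size[j]
        minid[i] = min(minid[i], minid[j])
        next_node += 1

    return Dendrogram(merges=np.array(merges, dtype=float), ids=dm.ids, linkage=linkage)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> Embedding:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -1/2 J D^2 J, eigendecomposes, and scales the top-k
    eigenvectors by the square roots of their (non-negative) eigenvalues;
    negative eigenvalues — distances that are not exactly Euclidean — are
    truncated to unused axes (zero coordinates).  Each axis's sign is fixed
    so its largest-magnitude coordinate is positive.
    """
    n = len(dm.ids)
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n items, got k={k}, n={n}")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if np.allclose(dm.values, 0.0):
        warnings.warn("all items coincide; embedding is all-zero", stacklevel=2)
    coords = np.zeros((n, k))
    for axis in range(k):
        if evals[axis] > 0:
            coords[:, axis] = evecs[:, axis] * np.sqrt(evals[axis])
            top = np.argmax(np.abs(coords[:, axis]))
            if coords[top, axis] < 0:
                coords[:, axis] = -coords[:, axis]
    pos = np.clip(evals, 0.0, None)
    total = pos.sum()
    proportion = pos[:k] / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"dim{i+1}" for i in range(k)]
    )
    return Embedding(coords=frame, eigenvalues=evals, proportion=proportion)


def group_overlay(
    emb: Embedding,
    md: SampleMetadata,
    factor: str,
    style: str = "ellipse",
    level: float = 0.95,
) -> GroupOverlay:
    """Confidence ellipses or convex hulls per metadata group on a 2-D embedding.

    Ellipses come from the group's 2-D sample covariance scaled by the
    chi-square quantile at ``level`` with 2 degrees of freedom (for 0.95
    that factor is 5.991); semi-axes are the square roots of the scaled
    covariance eigenvalues.  Hulls use the counter-clockwise vertex list of
    the convex hull.  Groups with fewer than three points (or collinear
    points for hulls) are skipped and reported.
    """
    if style not in ("ellipse", "hull"):
        raise ValueError(f"style must be 'ellipse' or 'hull', got {style!r}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if factor not in md.factor_names:
        raise KeyError(f"unknown factor {factor!r}; available: {md.factor_names}")
    if emb.coords.shape[1] < 2:
        raise ValueError("group overlays need a 2-D embedding")

    xy = emb.coords.iloc[:, :2]
    groups_of = md.factors[factor].astype(str)
    out: dict = {}
    skipped: list[str] = []
    for gname in sorted(set(groups_of.reindex(xy.index).dropna())):
        pts = xy.loc[[s for s in xy.index if groups_of.get(s) == gname]].to_numpy()
        if pts.shape[0] < 3:
            skipped.append(gname)
            continue
        if style == "ellipse":
            cov = np.cov(pts, rowvar=False, ddof=1)
            evals, evecs = np.linalg.eigh(cov)
            evals = np.clip(evals, 0.0, None)[::-1]
            evecs = evecs[:, ::-1]
            if evals[1] <= 0:
                skipped.append(gname)
                continue
            scale = sps.chi2.ppf(level, df=2)
            axes = np.sqrt(evals * scale)
            angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
            out[gname] = EllipseSpec(
                center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                semi_axes=(float(axes[0]), float(axes[1])),
                angle_deg=angle,
                level=level,
            )
        else:
            try:
                hull = ConvexHull(pts)
            except QhullError:
                skipped.append(gname)
                continue
            out[gname] = pts[hull.vertices]  # CCW for 2-D Qhull
    return GroupOverlay(style=style, level=level, groups=out, skipped=tuple(skipped))


def cluster_profiles(mr, k: int) -> ProfileClusters:
    """Cluster master genes by z-scored fold-change profile shape.

    Rows with any missing lfc are excluded (and reported); rows with zero
    variance get an all-zero profile.  Genes are clustered with complete
    linkage on Euclidean distances between z-scored rows and the tree cut
    into k groups; cluster centers are the mean z-scored profiles.
    """
    lfc = mr.lfc
    if lfc.shape[1] < 2:
        raise ValueError("profile clustering needs at least two contrasts")
    complete = lfc.dropna()
    excluded = tuple(g for g in lfc.index if g not in set(complete.index))
    n = complete.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= {n} complete genes, got {k}")

    arr = complete.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zf = pd.DataFrame(z, index=complete.index, columns=complete.columns)

    dm = distance_matrix(zf.T, metric="euclidean", axis="samples")
    tree = hcluster(dm, linkage="complete")
    labels = tree.cut(k).reindex(complete.index)
    centers = zf.groupby(labels).mean()
    centers.index.name = "cluster"
    return ProfileClusters(labels=labels, centers=centers, excluded=excluded)
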