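import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

import contrastkit as ck
from contrastkit.cluster import DistanceMatrix
from contrastkit.io import CountMatrix, SampleMetadata, ValidationError


def _dm_from_points(points, ids=None):
    d = squareform(pdist(points))
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(ids=tuple(ids), values=d, metric="euclidean")


def naive_agglomerate(ids, d, linkage):
    """Exhaustive agglomeration oracle: dict-of-frozensets bookkeeping.

    Independent of the implementation: clusters are frozensets, the linkage
    distance is recomputed from the ORIGINAL distance matrix at every step,
    and ties are broken on the sorted smallest member IDs.
    """
    d0 = {(a, b): d[i, j] for (i, a), (j, b) in itertools.product(enumerate(ids), repeat=2)}

    def clu_dist(c1, c2):
        vals = [d0[(a, b)] for a in c1 for b in c2]
        if linkage == "complete":
            return max(vals)
        if linkage == "single":
            return min(vals)
        return sum(vals) / len(vals)

    clusters = [frozenset([i]) for i in ids]
    merges = []
    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(clusters, 2):
            dist = clu_dist(c1, c2)
            key = tuple(sorted((min(c1), min(c2))))
            if best is None or (dist, key) < (best[0], best[1]):
                best = (dist, key, c1, c2)
        dist, _, c1, c2 = best
        merges.append((frozenset(c1 | c2), dist))
        clusters = [c for c in clusters if c not in (c1, c2)] + [c1 | c2]
    return merges


def _merge_sets(dend):
    """(cluster membership, height) pairs from a Dendrogram."""
    n = len(dend.ids)
    members = {i: frozenset([dend.ids[i]]) for i in range(n)}
    out = []
    for step, (a, b, h, _) in enumerate(dend.merges):
        members[n + step] = members[int(a)] | members[int(b)]
        out.append((members[n + step], h))
    return out


class TestDistanceMatrix:
    def test_identical_columns_distance_zero(self, fixtures):
        cm = fixtures["small_counts"]
        dup = cm.counts.copy()
        dup["a2"] = dup["a1"]
        dcm = CountMatrix(dup)
        for metric in ("euclidean", "poisson"):
            dm = ck.distance_matrix(dcm, metric=metric)
            i, j = dm.ids.index("a1"), dm.ids.index("a2")
            assert dm.values[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five(self):
        df = pd.DataFrame({"x": [0, 3], "y": [4, 0]}, index=["g1", "g2"])
        dm = ck.distance_matrix(df, metric="euclidean", axis="samples")
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_poisson_absorbs_depth(self, fixtures):
        cm = fixtures["small_counts"]
        doubled = cm.counts.copy()
        doubled["a2"] = 2 * doubled["a1"]
        dm = ck.distance_matrix(CountMatrix(doubled), metric="poisson")
        i, j = dm.ids.index("a1"), dm.ids.index("a2")
        assert dm.values[i, j] == pytest.approx(0.0, abs=1e-8)

    def test_poisson_rejects_non_integer(self):
        df = pd.DataFrame({"a": [1.5, 2.0], "b": [2.0, 3.0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError, match="integer"):
            ck.distance_matrix(df, metric="poisson", axis="samples")

    def test_invariants_hold_exactly(self, smoke_sim):
        for metric in ("euclidean", "poisson"):
            dm = ck.distance_matrix(smoke_sim.counts, metric=metric)
            assert np.array_equal(dm.values, dm.values.T)
            assert not np.diagonal(dm.values).any()
            assert (dm.values >= 0).all()


class TestHcluster:
    def test_three_item_hand_agglomeration(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dm = DistanceMatrix(ids=("i1", "i2", "i3"), values=d, metric="euclidean")
        dend = ck.hcluster(dm, linkage="complete")
        sets = _merge_sets(dend)
        assert sets[0] == (frozenset({"i1", "i2"}), 1.0)
        assert sets[1] == (frozenset({"i1", "i2", "i3"}), 10.0)

    def test_two_items_single_merge(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.5], [3.5, 0.0]]), "euclidean")
        dend = ck.hcluster(dm)
        assert dend.heights.tolist() == [3.5]

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_agrees_with_naive_oracle(self, linkage):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, 3))
            ids = [f"i{k}" for k in range(n)]
            dm = _dm_from_points(pts, ids)
            got = _merge_sets(ck.hcluster(dm, linkage=linkage))
            want = naive_agglomerate(ids, dm.values, linkage)
            for (gs, gh), (ws, wh) in zip(got, want):
                assert gs == ws
                assert gh == pytest.approx(wh, abs=1e-10)

    def test_cophenetic_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            pts = rng.normal(size=(6, 2))
            dm = _dm_from_points(pts)
            off = ~np.eye(6, dtype=bool)
            coph_c = ck.hcluster(dm, "complete").cophenetic()
            coph_s = ck.hcluster(dm, "single").cophenetic()
            assert (coph_c[off] >= dm.values[off] - 1e-10).all()
            assert (coph_s[off] <= dm.values[off] + 1e-10).all()

    def test_heights_monotone(self, smoke_sim):
        dm = ck.distance_matrix(smoke_sim.counts, metric="euclidean")
        for linkage in ("complete", "average"):
            h = ck.hcluster(dm, linkage).heights
            assert (np.diff(h) >= -1e-10).all()

    def test_newick_parses_with_all_leaves(self):
        import io as _io

        from Bio import Phylo

        dm = _dm_from_points(np.random.default_rng(0).normal(size=(5, 2)))
        newick = ck.hcluster(dm).to_newick()
        tree = Phylo.read(_io.StringIO(newick), "newick")
        assert {t.name for t in tree.get_terminals()} == set(dm.ids)


def procrustes_residual(a, b):
    """Smallest sum of squared distances after optimal rigid alignment."""
    from scipy.linalg import orthogonal_procrustes

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    r, _ = orthogonal_procrustes(b, a)
    return float(np.sum((b @ r - a) ** 2))


class TestClassicalMds:
    def test_planar_points_recovered(self, fixtures):
        pts = fixtures["planar_points_4"]
        emb = ck.classical_mds(_dm_from_points(pts), k=2)
        rec = squareform(pdist(emb.coords.to_numpy()))
        assert np.allclose(rec, squareform(pdist(pts)), atol=1e-8)
        assert procrustes_residual(pts, emb.coords.to_numpy()) < 1e-8

    def test_two_items_at_half_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 4.0], [4.0, 0.0]]), "euclidean")
        emb = ck.classical_mds(dm, k=1)
        assert sorted(emb.coords["dim1"]) == pytest.approx([-2.0, 2.0])

    def test_coordinates_centered(self, smoke_sim):
        dm = ck.distance_matrix(smoke_sim.counts, metric="euclidean")
        emb = ck.classical_mds(dm, k=2)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)
        assert (np.diff(emb.eigenvalues) <= 1e-9).all()

    def test_permutation_invariant_up_to_rotation(self, fixtures):
        pts = fixtures["planar_points_4"]
        dm = _dm_from_points(pts)
        emb1 = ck.classical_mds(dm, k=2)
        perm = [2, 0, 3, 1]
        dm2 = DistanceMatrix(
            tuple(dm.ids[i] for i in perm), dm.values[np.ix_(perm, perm)], "euclidean"
        )
        emb2 = ck.classical_mds(dm2, k=2)
        a = emb1.coords.loc[list(dm.ids)].to_numpy()
        b = emb2.coords.loc[list(dm.ids)].to_numpy()
        assert procrustes_residual(a, b) < 1e-8

    def test_agrees_with_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 4))
        dm = _dm_from_points(pts)
        emb = ck.classical_mds(dm, k=2)
        ref = pcoa(dm.values, number_of_dimensions=2)
        assert procrustes_residual(
            ref.samples.to_numpy(), emb.coords.to_numpy()
        ) < 1e-8

    def test_zero_matrix_warns_and_zeroes(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)), "euclidean")
        with pytest.warns(UserWarning):
            emb = ck.classical_mds(dm, k=2)
        assert (emb.coords.to_numpy() == 0).all()

    def test_kruskal_raw_stress_near_zero_on_euclidean_input(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(9, 2))
        dm = _dm_from_points(pts)
        emb = ck.classical_mds(dm, k=2)
        rec = squareform(pdist(emb.coords.to_numpy()))
        stress = np.sqrt(np.sum((rec - dm.values) ** 2) / np.sum(dm.values**2))
        assert stress < 1e-8


class TestGroupOverlay:
    def _embedding(self, pts, ids):
        return ck.classical_mds(_dm_from_points(pts, ids), k=2)

    def _md(self, assignment):
        return SampleMetadata(
            pd.DataFrame(
                {"group": list(assignment.values())},
                index=pd.Index(list(assignment), name="sample"),
            )
        )

    def test_square_hull_ccw(self, fixtures):
        pts = fixtures["square_corners"]
        ids = [f"s{i}" for i in range(4)]
        emb = ck.Embedding(
            coords=pd.DataFrame(pts, index=ids, columns=["dim1", "dim2"]),
            eigenvalues=np.array([1.0, 1.0]),
            proportion=np.array([0.5, 0.5]),
        )
        md = self._md({i: "g" for i in ids})
        ov = ck.group_overlay(emb, md, "group", style="hull")
        verts = ov.groups["g"]
        assert len(verts) == 4
        # counter-clockwise: shoelace area positive
        x, y = verts[:, 0], verts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0
        # containment: all points inside or on hull bounding box
        assert {tuple(v) for v in verts} == {tuple(p) for p in pts}

    def test_chi_square_scale_at_95(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 2))
        ids = [f"s{i}" for i in range(40)]
        emb = ck.Embedding(
            coords=pd.DataFrame(pts, index=ids, columns=["dim1", "dim2"]),
            eigenvalues=np.array([1.0, 1.0]),
            proportion=np.array([0.5, 0.5]),
        )
        md = self._md({i: "g" for i in ids})
        ov = ck.group_overlay(emb, md, "group", style="ellipse", level=0.95)
        spec = ov.groups["g"]
        cov_evals = np.sort(np.linalg.eigvalsh(np.cov(pts, rowvar=False)))[::-1]
        expected = np.sqrt(cov_evals * sps.chi2.ppf(0.95, 2))
        assert sps.chi2.ppf(0.95, 2) == pytest.approx(5.991, abs=5e-4)
        assert spec.semi_axes[0] == pytest.approx(expected[0], rel=1e-9)
        assert spec.semi_axes[1] == pytest.approx(expected[1], rel=1e-9)

    def test_isotropic_cloud_axes_nearly_equal(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(500, 2))
        ids = [f"s{i}" for i in range(500)]
        emb = ck.Embedding(
            coords=pd.DataFrame(pts, index=ids, columns=["dim1", "dim2"]),
            eigenvalues=np.array([1.0, 1.0]),
            proportion=np.array([0.5, 0.5]),
        )
        ov = ck.group_overlay(emb, self._md({i: "g" for i in ids}), "group")
        a, b = ov.groups["g"].semi_axes
        assert a / b < 1.25

    def test_small_group_skipped_and_reported(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5]], dtype=float)
        ids = [f"s{i}" for i in range(5)]
        emb = ck.Embedding(
            coords=pd.DataFrame(pts, index=ids, columns=["dim1", "dim2"]),
            eigenvalues=np.array([1.0, 1.0]),
            proportion=np.array([0.5, 0.5]),
        )
        md = self._md(dict(zip(ids, ["big", "big", "big", "tiny", "tiny"])))
        ov = ck.group_overlay(emb, md, "group", style="hull")
        assert "tiny" in ov.skipped and "big" in ov.groups


class TestClusterProfiles:
    def _master(self, lfc):
        padj = lfc * 0 + 0.01
        return ck.MasterResult(lfc=lfc, padj=padj, sig=padj < 0.05,
                               mode="union", p_cut=0.05, lfc_cut=0.0)

    def test_separable_families_split_exactly(self):
        rng = np.random.default_rng(2)
        rows, names = [], []
        for i in range(6):
            rows.append(np.array([1.0, 2.0, 3.0]) * rng.uniform(0.5, 2))
            names.append(f"up{i}")
        for i in range(6):
            rows.append(np.array([3.0, 2.0, 1.0]) * rng.uniform(0.5, 2))
            names.append(f"down{i}")
        lfc = pd.DataFrame(rows, index=pd.Index(names, name="gene"),
                           columns=["c1", "c2", "c3"])
        pc = ck.cluster_profiles(self._master(lfc), k=2)
        up = {pc.labels[n] for n in names if n.startswith("up")}
        down = {pc.labels[n] for n in names if n.startswith("down")}
        assert len(up) == 1 and len(down) == 1 and up != down

    def test_k_equals_n_gives_singletons(self):
        lfc = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 3)),
            index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
            columns=["c1", "c2", "c3"],
        )
        pc = ck.cluster_profiles(self._master(lfc), k=5)
        assert pc.labels.nunique() == 5

    def test_row_order_invariant_up_to_relabeling(self):
        rng = np.random.default_rng(8)
        lfc = pd.DataFrame(
            rng.normal(size=(10, 4)),
            index=pd.Index([f"g{i}" for i in range(10)], name="gene"),
            columns=list("wxyz"),
        )
        a = ck.cluster_profiles(self._master(lfc), k=3).labels
        b = ck.cluster_profiles(self._master(lfc.iloc[::-1]), k=3).labels
        # same partition: co-membership matrices agree
        genes = list(lfc.index)
        com_a = np.equal.outer(a[genes].to_numpy(), a[genes].to_numpy())
        com_b = np.equal.outer(b[genes].to_numpy(), b[genes].to_numpy())
        assert (com_a == com_b).all()

    def test_missing_rows_excluded_and_reported(self):
        lfc = pd.DataFrame(
            np.random.default_rng(0).normal(size=(6, 3)),
            index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
            columns=["c1", "c2", "c3"],
        )
        lfc.iloc[0, 1] = np.nan
        padj = lfc * 0 + 0.01
        mr = ck.MasterResult(lfc=lfc, padj=padj, sig=padj.notna(),
                             mode="union", p_cut=0.05, lfc_cut=0.0)
        pc = ck.cluster_profiles(mr, k=2)
        assert pc.excluded == ("g0",)
        assert "g0" not in pc.labels.index

    def test_invalid_k_rejected(self):
        lfc = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 2)),
            index=pd.Index([f"g{i}" for i in range(4)], name="gene"),
            columns=["c1", "c2"],
        )
        mr = self._master(lfc)
        with pytest.raises(ValueError):
            ck.cluster_profiles(mr, k=1)
        with pytest.raises(ValueError):
            ck.cluster_profiles(mr, k=9)
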