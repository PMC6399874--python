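import numpy as np
import pandas as pd
import pytest

import contrastkit as ck
from contrastkit.io import ContrastLabel, ContrastResult


def _label(name):
    return f"cond:{name}_vs_ctrl"


def _contrast(name, sig, universe=("A", "B", "C", "D", "E")):
    padj = [0.01 if u in sig else 0.5 for u in universe]
    return ContrastResult(
        label=ContrastLabel(name, "ctrl", "cond"),
        table=pd.DataFrame(
            {
                "mean_expr": [50.0] * len(universe),
                # lfc varies per gene so downstream densities are well-defined
                "log2fc": [
                    (1.5 + 0.4 * i) if u in sig else (0.1 + 0.05 * i)
                    for i, u in enumerate(universe)
                ],
                "pvalue": [p / 2 for p in padj],
                "padj": padj,
            },
            index=pd.Index(list(universe), name="gene"),
        ),
    )


class TestAggregate:
    def test_union_and_intersection_of_two_sets(self):
        c1, c2 = _contrast("c1", {"A", "B"}), _contrast("c2", {"B", "C"})
        union = ck.aggregate([c1, c2], "union", 0.05, 1.0)
        inter = ck.aggregate([c1, c2], "intersection", 0.05, 1.0)
        assert set(union.gene_ids) == {"A", "B", "C"}
        assert set(inter.gene_ids) == {"B"}

    def test_single_contrast_identity(self):
        c1 = _contrast("c1", {"A", "B"})
        for mode in ("union", "intersection"):
            mr = ck.aggregate([c1], mode, 0.05, 1.0)
            assert set(mr.gene_ids) == {"A", "B"}

    def test_three_contrast_overlap_counts(self, fixtures):
        mr = ck.aggregate(fixtures["three_contrasts"], "union", 0.05, 1.0)
        assert set(mr.gene_ids) == {"A", "B", "C", "D"}
        counts = mr.overlap_counts()
        assert counts.to_dict() == {"A": 1, "B": 3, "C": 1, "D": 1}

    def test_nonsignificant_cells_reextracted(self):
        c1, c2 = _contrast("c1", {"A"}), _contrast("c2", {"B"})
        mr = ck.aggregate([c1, c2], "union", 0.05, 1.0)
        # A is not significant in c2 but its values are still stored
        assert mr.lfc.loc["A", _label("c2")] == pytest.approx(0.1)
        assert not mr.sig.loc["A", _label("c2")]
        assert mr.sig.loc["A", _label("c1")]

    def test_gene_missing_from_one_contrast(self):
        c1 = _contrast("c1", {"A", "B"})
        c2 = _contrast("c2", {"A", "B"}, universe=("B", "C", "D"))
        union = ck.aggregate([c1, c2], "union", 0.05, 1.0)
        assert np.isnan(union.lfc.loc["A", _label("c2")])  # retained, missing
        inter = ck.aggregate([c1, c2], "intersection", 0.05, 1.0)
        assert set(inter.gene_ids) == {"B"}  # A lacks evidence in c2

    def test_empty_intersection_warns(self):
        c1, c2 = _contrast("c1", {"A"}), _contrast("c2", {"B"})
        with pytest.warns(UserWarning, match="empty"):
            mr = ck.aggregate([c1, c2], "intersection", 0.05, 1.0)
        assert mr.n_genes == 0

    def test_permutation_invariant_up_to_column_order(self, fixtures):
        cs = fixtures["three_contrasts"]
        a = ck.aggregate(cs, "union", 0.05, 1.0)
        b = ck.aggregate(cs[::-1], "union", 0.05, 1.0)
        pd.testing.assert_frame_equal(a.lfc, b.lfc[a.lfc.columns])

    def test_union_contains_intersection(self, fixtures):
        cs = fixtures["three_contrasts"]
        union = ck.aggregate(cs, "union", 0.05, 1.0)
        inter = ck.aggregate(cs, "intersection", 0.05, 1.0)
        assert set(inter.gene_ids) <= set(union.gene_ids)


class TestAgreementDensity:
    def test_identical_contrasts_give_identical_curves(self):
        c1 = _contrast("c1", {"A", "B"})
        c2 = ContrastResult(
            label=ContrastLabel("c2", "ctrl", "cond"), table=c1.table.copy()
        )
        mr = ck.aggregate([c1, c2], "union", 0.05, 1.0)
        ad = ck.agreement_density(mr, [c1, c2], on="lfc")
        assert np.allclose(ad.densities["cond:c1_vs_ctrl"],
                           ad.densities["cond:c2_vs_ctrl"])

    def test_curves_integrate_to_one(self, smoke_bundle):
        mr, cs = smoke_bundle["master"], smoke_bundle["contrasts"]
        for on in ("padj", "lfc"):
            ad = ck.agreement_density(mr, cs, on=on)
            for dens in ad.densities.values():
                assert np.trapezoid(dens, ad.grid) == pytest.approx(1.0, abs=1e-3)

    def test_overlap_matches_sig_matrix(self, fixtures):
        mr = ck.aggregate(fixtures["three_contrasts"], "union", 0.05, 1.0)
        ad = ck.agreement_density(mr, fixtures["three_contrasts"], on="lfc")
        assert ad.overlap.to_dict() == {"A": 1, "B": 3, "C": 1, "D": 1}

    def test_too_few_genes_rejected(self):
        c1 = _contrast("c1", {"A"})
        mr = ck.aggregate([c1], "union", 0.05, 1.0)
        with pytest.raises(ValueError, match="2"):
            ck.agreement_density(mr, [c1], on="lfc")


class TestFilterMaster:
    def _master(self):
        lfc = pd.DataFrame(
            {"c1": [3.0, 0.5, -2.5, 1.0, 4.0], "c2": [2.2, 0.1, -0.2, 3.0, -4.0]},
            index=pd.Index(list("ABCDE"), name="gene"),
        )
        padj = pd.DataFrame(
            {"c1": [0.001, 0.2, 0.005, 0.04, 0.009],
             "c2": [0.02, 0.3, 0.5, 0.002, 0.001]},
            index=lfc.index,
        )
        sig = padj < 0.05
        return ck.MasterResult(lfc=lfc, padj=padj, sig=sig, mode="union",
                               p_cut=0.05, lfc_cut=0.0)

    def test_enumerated_survivors(self):
        """cuts (0.01, 2.0), scope any: row-wise check over printed values."""
        mr = self._master()
        out = ck.filter_master(mr, 0.01, 2.0, scope="any")
        # A: c1 padj .001<.01 & |3.0|>=2 -> keep; B: no cell passes;
        # C: c1 .005<.01 & 2.5>=2 -> keep; D: c2 .002<.01 & 3.0>=2 -> keep;
        # E: c1 .009<.01 & 4.0>=2 keep (c2 .001 & 4.0 also passes)
        assert set(out.gene_ids) == {"A", "C", "D", "E"}

    def test_idempotent(self):
        mr = self._master()
        once = ck.filter_master(mr, 0.01, 2.0, scope="any")
        twice = ck.filter_master(once, 0.01, 2.0, scope="any")
        assert once.gene_ids == twice.gene_ids

    def test_infinite_lfc_cut_empties(self):
        out = ck.filter_master(self._master(), 0.05, np.inf, scope="any")
        assert out.n_genes == 0

    def test_matching_cuts_and_scope_is_identity(self, fixtures):
        mr = ck.aggregate(fixtures["three_contrasts"], "union", 0.05, 1.0)
        out = ck.filter_master(mr, 0.05, 1.0, scope="any")
        assert out.gene_ids == mr.gene_ids

    def test_provenance_appended(self):
        out = ck.filter_master(self._master(), 0.01, 2.0, scope="all")
        assert any("scope=all" in s for s in out.provenance)


class TestSubsetAndMetadata:
    def test_predicate_subsets_columns(self, smoke_sim):
        cm, md = ck.subset_samples(
            smoke_sim.counts, smoke_sim.metadata, {"treatment": "ebov"}
        )
        assert cm.shape[1] == 3
        assert set(md.factors["treatment"].astype(str)) == {"ebov"}

    def test_empty_predicate_identity(self, smoke_sim):
        cm, _ = ck.subset_samples(smoke_sim.counts, smoke_sim.metadata, {})
        assert cm.sample_ids == smoke_sim.counts.sample_ids

    def test_conjunction_equals_intersection(self, smoke_sim):
        both, _ = ck.subset_samples(
            smoke_sim.counts, smoke_sim.metadata,
            {"time": "1d", "treatment": "ebov"},
        )
        t_only, _ = ck.subset_samples(smoke_sim.counts, smoke_sim.metadata, {"time": "1d"})
        tr_only, _ = ck.subset_samples(
            smoke_sim.counts, smoke_sim.metadata, {"treatment": "ebov"}
        )
        assert set(both.sample_ids) == set(t_only.sample_ids) & set(tr_only.sample_ids)

    def test_no_match_rejected(self, smoke_sim):
        with pytest.raises(ValueError, match="no sample"):
            ck.subset_samples(smoke_sim.counts, smoke_sim.metadata, {"time": "9d"})

    def test_derive_composite_field(self, smoke_sim):
        md = ck.derive_metadata_field(smoke_sim.metadata, ["treatment", "time"], "_")
        assert "treatment_time" in md.factor_names
        assert "ebov_1d" in set(md.factors["treatment_time"].astype(str))
        n_tuples = (
            smoke_sim.metadata.factors[["treatment", "time"]]
            .astype(str).drop_duplicates().shape[0]
        )
        assert len(md.levels("treatment_time")) == n_tuples

    def test_single_field_copies_column(self, smoke_sim):
        md = ck.derive_metadata_field(smoke_sim.metadata, ["time"], "_", name="t2")
        assert list(md.factors["t2"].astype(str)) == list(
            smoke_sim.metadata.factors["time"].astype(str)
        )

    def test_name_collision_rejected(self, smoke_sim):
        with pytest.raises(Exception, match="time"):
            ck.derive_metadata_field(smoke_sim.metadata, ["time"], "_", name="time")


class TestSortGenes:
    def _master(self, rows):
        lfc = pd.DataFrame({g: rows[g] for g in rows}, index=["c1", "c2"]).T
        lfc.index.name = "gene"
        padj = lfc * 0 + 0.01
        return ck.MasterResult(lfc=lfc, padj=padj, sig=padj < 0.05,
                               mode="union", p_cut=0.05, lfc_cut=0.0)

    def test_max_descending(self):
        mr = self._master({"gA": [1.0, 3.0], "gB": [2.0, 2.0]})
        assert ck.sort_genes(mr, "max", descending=True) == ["gA", "gB"]

    def test_zero_variance_sorts_last_descending(self):
        mr = self._master({"gA": [1.0, 3.0], "gB": [2.0, 2.0]})
        assert ck.sort_genes(mr, "variance", descending=True)[-1] == "gB"

    def test_sd_is_sqrt_variance(self):
        mr = self._master({"gA": [1.0, 3.0], "gB": [2.0, 2.0], "gC": [0.0, 5.0]})
        var = mr.lfc.var(axis=1, ddof=1)
        sd_order = ck.sort_genes(mr, "sd")
        var_order = ck.sort_genes(mr, "variance")
        assert sd_order == var_order
        assert np.allclose(np.sqrt(var), mr.lfc.std(axis=1, ddof=1))

    def test_ties_broken_lexicographically(self):
        mr = self._master({"gB": [1.0, 1.0], "gA": [1.0, 1.0], "gC": [2.0, 0.0]})
        assert ck.sort_genes(mr, "max", descending=True) == ["gC", "gA", "gB"]

    def test_unknown_stat_rejected(self):
        mr = self._master({"gA": [1.0, 3.0]})
        with pytest.raises(ValueError, match="median"):
            ck.sort_genes(mr, "median")


class TestMasterExport:
    def test_tsv_trio_and_sidecar(self, tmp_path, fixtures):
        mr = ck.aggregate(fixtures["three_contrasts"], "union", 0.05, 1.0)
        paths = mr.to_tsvs(tmp_path, "demo")
        names = {p.name for p in paths}
        assert names == {
            "demo_lfc.tsv", "demo_padj.tsv", "demo_sig.tsv", "demo_provenance.txt"
        }
        side = (tmp_path / "demo_provenance.txt").read_text()
        assert "mode=union" in side and "p_cut=0.05" in side
        back = pd.read_csv(tmp_path / "demo_lfc.tsv", sep="\t", index_col=0)
        assert list(back.index) == mr.gene_ids
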