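import numpy as np
import pytest

import contrastkit as ck


@pytest.fixture(scope="session")
def fixtures():
    return ck.fixture_suite()


@pytest.fixture(scope="session")
def smoke_sim():
    """Small simulated study: 300 genes, 1 time x 4 treatments x 3 reps."""
    planted = {
        "ebov": (np.arange(0, 40), np.where(np.arange(40) % 2 == 0, 2.0, -2.0)),
        "restv": (np.arange(20, 60), np.where(np.arange(40) % 2 == 0, 2.0, -2.0)),
        "lps": (np.arange(80, 120), np.full(40, 2.0)),
    }
    design = ck.SimDesign(
        times=("1d",), replicates=3, n_genes=300, planted=planted, seed=11
    )
    return ck.simulate_counts(design)


@pytest.fixture(scope="session")
def smoke_bundle(smoke_sim):
    """Everything the plot registry consumes, built once from the smoke sim."""
    sim = smoke_sim
    nf = ck.tmm_factors(sim.counts)
    normalized = ck.normalize(sim.counts, nf, method="log2cpm")
    contrasts = [
        ck.nb_reference_test(sim.counts, sim.metadata, "treatment", a, "mock", nf)
        for a in ("ebov", "restv")
    ]
    master = ck.aggregate(contrasts, mode="union", p_cut=0.05, lfc_cut=1.0)
    return {
        "counts": sim.counts,
        "metadata": sim.metadata,
        "normalized": normalized,
        "contrast": contrasts[0],
        "contrasts": contrasts,
        "master": master,
        "factors": nf,
    }


def smoke_inputs_for(plot_type, bundle):
    """Input kwargs and params to compute any registered plot type."""
    kw = dict(
        counts=bundle["counts"],
        metadata=bundle["metadata"],
        normalized=bundle["normalized"],
        contrast=bundle["contrast"],
        contrasts=bundle["contrasts"],
        master=bundle["master"],
    )
    params = {}
    if plot_type == "gene_boxplot_wilcoxon":
        params = {"gene": bundle["normalized"].gene_ids[0], "factor": "treatment"}
    elif plot_type == "coexpression_series":
        params = {"k": 3}
    elif plot_type == "gene_heatmap":
        params = {"top_n": 10, "stat": "max"}
    elif plot_type == "profile_plot":
        params = {"top_n": 8}
    elif plot_type == "volcano":
        params = {"p_cut": 0.05, "lfc_cut": 1.0}
    return kw, params
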