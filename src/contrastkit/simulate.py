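"""Deterministic synthetic count data with known differential structure.

The generator emulates a multi-time-point, multi-treatment infection study
in miniature: a 3-level time factor (6h, 1d, 2d) crossed with a 4-level
treatment factor (ebov, restv, lps, mock), replicated per cell, with
negative-binomial counts.  Gene baselines are log-normal, per-sample
sequencing depth varies log-uniformly, and chosen genes carry planted log2
effects in chosen treatments (relative to the mock control), so every
downstream operation can be tested against known truth without downloads.

The negative binomial is parameterized by mean and dispersion
(var = mu + alpha * mu^2), matching DE-engine convention, so a planted
effect of e log2 units is exactly the expected log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContrastLabel, ContrastResult, CountMatrix, SampleMetadata

__all__ = ["SimDesign", "SimResult", "simulate_counts", "fixture_suite"]


@dataclass(frozen=True)
class SimDesign:
    """Specification of a simulated experiment.

    ``planted`` maps a treatment level to (gene indices, log2 effects): those
    genes' means are multiplied by 2**effect in every sample of that
    treatment, at every time point.  Defaults mirror the study shape the
    toolkit targets: 2000 genes, 3 times x 4 treatments, 5 replicates,
    dispersion 0.05, 200 planted genes per non-control treatment at |log2
    effect| 2 with overlapping sets so union and intersection merges differ.
    """

    times: tuple[str, ...] = ("6h", "1d", "2d")
    treatments: tuple[str, ...] = ("ebov", "restv", "lps", "mock")
    replicates: int = 5
    n_genes: int = 2000
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05
    planted: dict = field(default_factory=dict)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per cell")
        if not self.planted:
            object.__setattr__(self, "planted", _default_planted(self.n_genes))
        for trt, (idx, eff) in self.planted.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ValueError(f"planted gene index out of range for {trt!r}")
            if len(np.asarray(eff)) != idx.size:
                raise ValueError(f"effects and indices differ in length for {trt!r}")


def _default_planted(n_genes: int) -> dict:
    """200 planted genes per treated condition, alternating sign, effect 2.

    ebov and restv share 100 genes (indices 100-199), so the ebov/restv
    intersection is non-trivial; lps is disjoint from both.
    """
    if n_genes < 600:
        raise ValueError("default planted sets need at least 600 genes")
    eff = np.where(np.arange(200) % 2 == 0, 2.0, -2.0)
    return {
        "ebov": (np.arange(0, 200), eff.copy()),
        "restv": (np.arange(100, 300), eff.copy()),
        "lps": (np.arange(400, 600), eff.copy()),
    }


@dataclass(frozen=True)
class SimResult:
    counts: CountMatrix
    metadata: SampleMetadata
    truth: dict  # ContrastLabel-string -> DataFrame(gene, log2_effect)


def simulate_counts(design: SimDesign) -> SimResult:
    """Draw the count matrix, metadata and truth tables for a design.

    Counts are NB(mean = baseline * 2**effect * libfactor, dispersion);
    identical seeds give bit-identical output.  Truth tables list, for each
    treated-vs-mock contrast, the planted genes and their log2 effects.
    """
    rng = np.random.default_rng(design.seed)
    g = design.n_genes
    genes = [f"g{i:04d}" for i in range(g)]
    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, g)

    effects = {trt: np.zeros(g) for trt in design.treatments}
    for trt, (idx, eff) in design.planted.items():
        effects[trt][np.asarray(idx, dtype=int)] = np.asarray(eff, dtype=float)

    sample_ids, rows, cols = [], [], []
    disp = np.broadcast_to(np.asarray(design.dispersion, dtype=float), (g,))
    nb_n = 1.0 / np.maximum(disp, 1e-12)
    lo, hi = design.libsize_range
    for time in design.times:
        for trt in design.treatments:
            for rep in range(1, design.replicates + 1):
                sid = f"{trt}_{time}_r{rep}"
                libf = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                mu = baseline * 2.0 ** effects[trt] * libf
                p = nb_n / (nb_n + mu)
                cols.append(rng.negative_binomial(nb_n, p))
                sample_ids.append(sid)
                rows.append({"sample": sid, "time": time, "treatment": trt})

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    meta = pd.DataFrame(rows).set_index("sample")

    truth = {}
    control = design.treatments[-1] if "mock" not in design.treatments else "mock"
    for trt, (idx, eff) in design.planted.items():
        label = str(ContrastLabel(trt, control, "treatment"))
        truth[label] = pd.DataFrame(
            {"gene": [genes[i] for i in np.asarray(idx, dtype=int)],
             "log2_effect": np.asarray(eff, dtype=float)}
        ).set_index("gene")
    return SimResult(
        counts=CountMatrix(counts), metadata=SampleMetadata(meta), truth=truth
    )


def fixture_suite() -> dict:
    """Small canonical objects used across tests and examples.

    Purely constructed in code — no files, no randomness.
    """
    toy_contrast = ContrastResult(
        label=ContrastLabel("treated", "control", "treatment"),
        table=pd.DataFrame(
            {
                "mean_expr": [100.0, 50.0, 80.0, 10.0, 200.0],
                "log2fc": [2.0, -3.0, 0.5, 9.0, -1.2],
                "pvalue": [0.005, 0.1, 0.02, 0.001, 0.03],
                "padj": [0.01, 0.2, 0.04, np.nan, 0.049],
            },
            index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene"),
        ),
    )

    def _contrast(name: str, sig_genes: set[str]) -> ContrastResult:
        universe = ["A", "B", "C", "D", "E"]
        padj = [0.01 if u in sig_genes else 0.5 for u in universe]
        return ContrastResult(
            label=ContrastLabel(name, "ctrl", "cond"),
            table=pd.DataFrame(
                {
                    "mean_expr": [50.0] * 5,
                    "log2fc": [1.5 if u in sig_genes else 0.1 for u in universe],
                    "pvalue": [p / 2 for p in padj],
                    "padj": padj,
                },
                index=pd.Index(universe, name="gene"),
            ),
        )

    three_contrasts = [
        _contrast("c1", {"A", "B"}),
        _contrast("c2", {"B", "C"}),
        _contrast("c3", {"B", "D"}),
    ]

    planar_points = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0], [-1.0, 2.0]])
    square_corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])

    tmm_toy = CountMatrix(
        pd.DataFrame(
            {"s1": [10, 20, 5, 80, 40, 15], "s2": [30, 25, 10, 60, 200, 20]},
            index=pd.Index([f"g{i}" for i in range(1, 7)], name="gene"),
        )
    )

    small = pd.DataFrame(
        {
            "a1": [10, 0, 25, 3, 100, 7],
            "a2": [12, 1, 30, 2, 90, 8],
            "b1": [40, 0, 24, 3, 10, 9],
            "b2": [38, 2, 28, 4, 12, 6],
        },
        index=pd.Index([f"g{i}" for i in range(1, 7)], name="gene"),
    )
    small_md = pd.DataFrame(
        {"group": ["a", "a", "b", "b"]},
        index=pd.Index(["a1", "a2", "b1", "b2"], name="sample"),
    )

    return {
        "toy_contrast_5gene": toy_contrast,
        "three_contrasts": three_contrasts,
        "planar_points_4": planar_points,
        "square_corners": square_corners,
        "tmm_toy_6x2": tmm_toy,
        "small_counts": CountMatrix(small),
        "small_metadata": SampleMetadata(small_md),
    }
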