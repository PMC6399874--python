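"""Significance calling and a minimal built-in reference DE test.

The toolkit is designed to consume contrast tables from an external DE
engine; this module is the interchange point.  ``call_significance`` turns a
contrast table into the gene set passing adjusted-p and fold-change cutoffs.
``nb_reference_test`` is a deliberately simple negative-binomial Wald test —
moment dispersion, no shrinkage, no independent filtering — whose role is
fixture generation and pipeline testing, not publication-grade inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ContrastLabel, ContrastResult, CountMatrix, SampleMetadata
from .preprocess import NormFactors
from .stats import bh_adjust

__all__ = ["SignificanceSet", "call_significance", "nb_reference_test"]

#: Default cutoffs for significance calls; exposed as parameters everywhere.
DEFAULT_P_CUT = 0.05
DEFAULT_LFC_CUT = 0.0


@dataclass(frozen=True)
class SignificanceSet:
    """Genes passing padj < p_cut and |log2fc| >= lfc_cut in one contrast.

    The inequality on padj is strict (the common reading of "padj < 0.05"),
    the one on |log2fc| non-strict; genes with missing padj are never
    significant.  Thresholds and the source contrast are recorded.
    """

    genes: tuple[str, ...]
    p_cut: float
    lfc_cut: float
    label: ContrastLabel

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def call_significance(
    cr: ContrastResult,
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> SignificanceSet:
    """Apply adjusted-p and fold-change cutoffs to one contrast."""
    if not (0 < p_cut <= 1):
        raise ValueError(f"p_cut must be in (0, 1], got {p_cut}")
    if lfc_cut < 0:
        raise ValueError(f"lfc_cut must be non-negative, got {lfc_cut}")
    t = cr.table
    mask = t["padj"].notna() & (t["padj"] < p_cut) & (t["log2fc"].abs() >= lfc_cut)
    return SignificanceSet(
        genes=tuple(t.index[mask]), p_cut=p_cut, lfc_cut=lfc_cut, label=cr.label
    )


def nb_reference_test(
    cm: CountMatrix,
    md: SampleMetadata,
    factor: str,
    level_a: str,
    level_b: str,
    nf: NormFactors,
) -> ContrastResult:
    """Two-group negative-binomial Wald test on TMM-normalized counts.

    Counts are put on a common scale q = y / (N * f) * G (G the geometric
    mean of the effective library sizes), so the mean/variance moments keep
    their count-scale meaning.  Per gene:

    - group means on the CPM scale; log2fc = log2((m_a + 0.5) / (m_b + 0.5))
    - gene-wise dispersion alpha from the method of moments
      (var = mu + alpha * mu^2), pooled across the two groups weighted by
      degrees of freedom, floored at 1e-8
    - a two-sided Wald p-value from the delta-method standard error of the
      log2 fold change, with Var(q-bar) = (mu + alpha mu^2) / n per group
    - padj by Benjamini-Hochberg.

    Swapping the two levels negates log2fc and leaves p unchanged.
    """
    if factor not in md.factor_names:
        raise KeyError(f"unknown factor {factor!r}; available: {md.factor_names}")
    groups = md.factors[factor].astype(str)
    a_ids = [s for s in cm.sample_ids if groups.get(s) == str(level_a)]
    b_ids = [s for s in cm.sample_ids if groups.get(s) == str(level_b)]
    for level, ids in ((level_a, a_ids), (level_b, b_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"level {level!r} of factor {factor!r} has {len(ids)} sample(s); "
                "need at least 2"
            )

    ids = a_ids + b_ids
    counts = cm.counts[ids].to_numpy(dtype=float)
    eff = (cm.library_sizes().astype(float) * nf.factors)[ids].to_numpy()
    g_mean = float(np.exp(np.mean(np.log(eff))))
    q = counts / eff * g_mean  # common-scale counts
    cpm_scale = 1e6 / g_mean

    na, nb = len(a_ids), len(b_ids)
    qa, qb = q[:, :na], q[:, na:]

    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    var_a, var_b = qa.var(axis=1, ddof=1), qb.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
        alpha_b = np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
    alpha = np.maximum(((na - 1) * alpha_a + (nb - 1) * alpha_b) / (na + nb - 2), 1e-8)

    m_a, m_b = mu_a * cpm_scale, mu_b * cpm_scale  # CPM-scale group means
    log2fc = np.log2((m_a + 0.5) / (m_b + 0.5))

    ln2 = np.log(2.0)
    var_qbar_a = (mu_a + alpha * mu_a**2) / na
    var_qbar_b = (mu_b + alpha * mu_b**2) / nb
    se_a = cpm_scale * np.sqrt(var_qbar_a) / ((m_a + 0.5) * ln2)
    se_b = cpm_scale * np.sqrt(var_qbar_b) / ((m_b + 0.5) * ln2)
    se = np.sqrt(se_a**2 + se_b**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    table = pd.DataFrame(
        {
            "mean_expr": q.mean(axis=1) * cpm_scale,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        },
        index=cm.counts.index,
    )
    return ContrastResult(
        label=ContrastLabel(str(level_a), str(level_b), factor), table=table
    )
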