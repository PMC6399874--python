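"""The plot registry: 16 visualization types, each split into a pure
data-computation step and a rendering step.

Every plot is computed first as a :class:`PlotData` — the exact numeric
tables behind the figure, serializable to TSV sidecars — and only then
rendered.  This is the data-retrieval contract: given a PlotData and a
Theme, the rendered figure is a pure function of the two, and the tables a
user sees on screen can always be re-loaded for further analysis.

Six built-in themes control palette and layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import cluster as cl
from .aggregate import MasterResult, agreement_density, sort_genes
from .io import ContrastResult, CountMatrix, SampleMetadata
from .preprocess import NormalizedMatrix
from .stats import wilcoxon_rank_sum

__all__ = [
    "PlotData",
    "Theme",
    "PLOT_TYPES",
    "list_plot_types",
    "list_themes",
    "compute_plot_data",
    "render",
]

#: The canonical census of plot types.  Pre- and post-normalization boxplots
#: are distinct entries, and the aggregation agreement density is split by
#: the statistic it shows (adjusted p-value vs log fold change).
PLOT_TYPES: tuple[str, ...] = (
    "sample_distance_heatmap",
    "group_dendrogram",
    "mds_confidence",
    "mds_hull",
    "boxplot_prenorm",
    "boxplot_postnorm",
    "foldchange_boxplot",
    "divergence_plot",
    "updown_summary",
    "volcano",
    "gene_heatmap",
    "profile_plot",
    "gene_boxplot_wilcoxon",
    "coexpression_series",
    "aggregation_density_p",
    "aggregation_density_lfc",
)

#: Plot types whose figure height scales with the number of rows displayed.
ROW_INDEXED_TYPES = frozenset({"gene_heatmap", "profile_plot", "sample_distance_heatmap"})


@dataclass(frozen=True)
class Theme:
    name: str
    palette: tuple[str, ...]
    font_scale: float = 1.0
    legend_loc: str = "best"
    background: str = "white"


def _pal(name: str) -> tuple[str, ...]:
    return tuple(matplotlib.colors.to_hex(c) for c in sns.color_palette(name, 10))


_THEMES: tuple[Theme, ...] = (
    Theme("classic", _pal("deep")),
    Theme("muted", _pal("muted"), font_scale=0.95),
    Theme("pastel", _pal("pastel")),
    Theme("dark", _pal("dark"), background="#f0f0f0"),
    Theme("colorblind", _pal("colorblind")),
    Theme("bright", _pal("bright"), font_scale=1.1),
)


def list_plot_types() -> list[str]:
    """The registered plot type names, in canonical order."""
    return list(PLOT_TYPES)


def list_themes() -> list[Theme]:
    """The built-in layout/color themes."""
    return list(_THEMES)


def get_theme(name: str) -> Theme:
    for t in _THEMES:
        if t.name == name:
            return t
    raise KeyError(f"unknown theme {name!r}; available: {[t.name for t in _THEMES]}")


@dataclass(frozen=True)
class PlotData:
    """The numeric tables behind one figure, plus the parameters used.

    ``tables`` maps a short name to a DataFrame; ``params`` records the
    computation parameters and ``provenance`` identifies the inputs.  A
    PlotData fully determines the rendered figure given a Theme, and
    round-trips exactly through its TSV serialization.
    """

    plot_type: str
    tables: dict
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plot_type not in PLOT_TYPES:
            raise ValueError(f"unknown plot type {self.plot_type!r}")

    def to_tsvs(self, directory: str | Path, stem: str) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in self.tables.items():
            p = directory / f"{stem}.{name}.tsv"
            df.to_csv(p, sep="\t", na_rep="NA")
            paths.append(p)
        meta = directory / f"{stem}.plotdata.json"
        with open(meta, "w") as fh:
            json.dump(
                {
                    "plot_type": self.plot_type,
                    "tables": list(self.tables),
                    "params": self.params,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
                default=str,
            )
        paths.append(meta)
        return paths

    @classmethod
    def from_tsvs(cls, directory: str | Path, stem: str) -> "PlotData":
        directory = Path(directory)
        with open(directory / f"{stem}.plotdata.json") as fh:
            meta = json.load(fh)
        tables = {}
        for name in meta["tables"]:
            df = pd.read_csv(
                directory / f"{stem}.{name}.tsv",
                sep="\t",
                index_col=0,
                na_values=["NA"],
                keep_default_na=False,
                float_precision="round_trip",
            )
            tables[name] = df
        return cls(
            plot_type=meta["plot_type"],
            tables=tables,
            params=meta["params"],
            provenance=meta["provenance"],
        )


class MissingInputError(ValueError):
    """A plot type was asked to compute without one of its required inputs."""


def _need(kwargs: dict, plot_type: str, *names: str) -> list:
    got = []
    for n in names:
        if kwargs.get(n) is None:
            raise MissingInputError(f"{plot_type} requires input {n!r}")
        got.append(kwargs[n])
    return got


def _box_stats(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey five-number summaries per column, whiskers at 1.5*IQR."""
    rows, outliers = [], []
    for col in frame.columns:
        v = frame[col].dropna().to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        whisk_lo = inside.min() if inside.size else q1
        whisk_hi = inside.max() if inside.size else q3
        rows.append(
            {
                "group": col,
                "whisker_low": whisk_lo,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_high": whisk_hi,
            }
        )
        for o in v[(v < lo_fence) | (v > hi_fence)]:
            outliers.append({"group": col, "value": o})
    stats = pd.DataFrame(rows).set_index("group")
    out = (
        pd.DataFrame(outliers).set_index("group")
        if outliers
        else pd.DataFrame(columns=["value"], index=pd.Index([], name="group"))
    )
    return stats, out


# ---------------------------------------------------------------------------
# per-type builders


def _pd_sample_distance_heatmap(params, **kw):
    metric = params.get("metric", "euclidean")
    if metric == "poisson":
        (data,) = _need(kw, "sample_distance_heatmap", "counts")
    else:
        data = kw.get("normalized") or kw.get("counts")
        if data is None:
            raise MissingInputError(
                "sample_distance_heatmap requires input 'normalized' or 'counts'"
            )
    linkage = params.get("linkage", "complete")
    dm = cl.distance_matrix(data, metric=metric, axis="samples")
    tree = cl.hcluster(dm, linkage=linkage)
    order = tree.leaf_order()
    dist = dm.to_frame().loc[order, order]
    dist.index.name = "sample"
    merges = pd.DataFrame(
        tree.merges, columns=["child_a", "child_b", "height", "size"]
    )
    merges.index.name = "merge"
    return PlotData(
        "sample_distance_heatmap",
        {"distance": dist, "merges": merges},
        params={"metric": metric, "linkage": linkage, "leaf_order": order},
    )


def _pd_group_dendrogram(params, **kw):
    md: SampleMetadata
    data = kw.get("normalized") or kw.get("counts")
    if data is None:
        raise MissingInputError("group_dendrogram requires 'normalized' or 'counts'")
    (md,) = _need(kw, "group_dendrogram", "metadata")
    factor = params.get("factor") or md.factor_names[0]
    metric = params.get("metric", "euclidean")
    linkage = params.get("linkage", "complete")
    dm = cl.distance_matrix(data, metric=metric, axis="samples")
    tree = cl.hcluster(dm, linkage=linkage)
    leaves = pd.DataFrame(
        {
            "position": range(len(tree.ids)),
            "group": [str(md.factors[factor].get(s, "?")) for s in tree.leaf_order()],
        },
        index=pd.Index(tree.leaf_order(), name="sample"),
    )
    merges = pd.DataFrame(
        tree.merges, columns=["child_a", "child_b", "height", "size"]
    )
    merges.index.name = "merge"
    return PlotData(
        "group_dendrogram",
        {"leaves": leaves, "merges": merges},
        params={
            "factor": factor,
            "metric": metric,
            "linkage": linkage,
            "newick": tree.to_newick(),
        },
    )


def _pd_mds(style: str, params, **kw):
    plot_type = "mds_confidence" if style == "ellipse" else "mds_hull"
    data = kw.get("normalized") or kw.get("counts")
    if data is None:
        raise MissingInputError(f"{plot_type} requires 'normalized' or 'counts'")
    (md,) = _need(kw, plot_type, "metadata")
    factor = params.get("factor") or md.factor_names[0]
    level = params.get("level", 0.95)
    dm = cl.distance_matrix(data, metric=params.get("metric", "euclidean"), axis="samples")
    emb = cl.classical_mds(dm, k=2)
    overlay = cl.group_overlay(emb, md, factor, style=style, level=level)
    coords = emb.coords.copy()
    coords["group"] = [str(md.factors[factor].get(s, "?")) for s in coords.index]
    coords.index.name = "sample"
    if style == "ellipse":
        rows = [
            {
                "group": g,
                "center_x": e.center[0],
                "center_y": e.center[1],
                "semi_major": e.semi_axes[0],
                "semi_minor": e.semi_axes[1],
                "angle_deg": e.angle_deg,
            }
            for g, e in overlay.groups.items()
        ]
        shape = (
            pd.DataFrame(rows).set_index("group")
            if rows
            else pd.DataFrame(
                columns=[
                    "center_x", "center_y", "semi_major", "semi_minor", "angle_deg"
                ],
                index=pd.Index([], name="group"),
            )
        )
    else:
        rows = []
        for g, verts in overlay.groups.items():
            for i, (x, y) in enumerate(verts):
                rows.append({"group": g, "vertex": i, "x": x, "y": y})
        shape = (
            pd.DataFrame(rows).set_index("group")
            if rows
            else pd.DataFrame(
                columns=["vertex", "x", "y"], index=pd.Index([], name="group")
            )
        )
    return PlotData(
        plot_type,
        {"coords": coords, "overlay": shape},
        params={
            "factor": factor,
            "level": level,
            "style": style,
            "variance_explained": [float(p) for p in emb.proportion],
            "skipped_groups": list(overlay.skipped),
        },
    )


def _pd_boxplot(which: str, params, **kw):
    plot_type = f"boxplot_{which}"
    if which == "prenorm":
        (cm,) = _need(kw, plot_type, "counts")
        frame = np.log2(cm.counts.astype(float) + 1.0)
        label = "log2(count + 1)"
    else:
        (nm,) = _need(kw, plot_type, "normalized")
        frame = nm.values
        label = nm.method
    stats, outliers = _box_stats(frame)
    stats.index.name = "sample"
    outliers.index.name = "sample"
    return PlotData(
        plot_type, {"stats": stats, "outliers": outliers}, params={"value": label}
    )


def _pd_foldchange_boxplot(params, **kw):
    (mr,) = _need(kw, "foldchange_boxplot", "master")
    stats, outliers = _box_stats(mr.lfc)
    stats.index.name = "contrast"
    outliers.index.name = "contrast"
    return PlotData(
        "foldchange_boxplot",
        {"stats": stats, "outliers": outliers},
        params={"n_genes": int(mr.n_genes)},
    )


def _pd_divergence_plot(params, **kw):
    (mr,) = _need(kw, "divergence_plot", "master")
    rows = []
    for name in mr.contrast_names:
        sig = mr.sig[name]
        lfc = mr.lfc[name]
        up = lfc[sig & (lfc > 0)]
        down = lfc[sig & (lfc < 0)]
        rows.append(
            {
                "contrast": name,
                "mean_up": float(up.mean()) if up.size else 0.0,
                "mean_down": float(down.mean()) if down.size else 0.0,
                "n_up": int(up.size),
                "n_down": int(down.size),
            }
        )
    return PlotData(
        "divergence_plot", {"divergence": pd.DataFrame(rows).set_index("contrast")}
    )


def _pd_updown_summary(params, **kw):
    (mr,) = _need(kw, "updown_summary", "master")
    rows = []
    for name in mr.contrast_names:
        sig = mr.sig[name]
        lfc = mr.lfc[name]
        rows.append(
            {
                "contrast": name,
                "up": int(((lfc > 0) & sig).sum()),
                "down": int(((lfc < 0) & sig).sum()),
            }
        )
    return PlotData(
        "updown_summary", {"counts": pd.DataFrame(rows).set_index("contrast")}
    )


def _pd_volcano(params, **kw):
    (cr,) = _need(kw, "volcano", "contrast")
    p_cut = params.get("p_cut", 0.05)
    lfc_cut = params.get("lfc_cut", 1.0)
    t = cr.table
    padj = t["padj"].to_numpy(dtype=float)
    pos = padj[(~np.isnan(padj)) & (padj > 0)]
    floor = pos.min() if pos.size else np.nextafter(0, 1)
    clamped = np.where(padj == 0, floor, padj)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(clamped)
    p_ok = (~np.isnan(padj)) & (padj < p_cut)
    lfc_ok = t["log2fc"].abs().to_numpy() >= lfc_cut
    cls = np.select(
        [p_ok & lfc_ok, p_ok & ~lfc_ok, ~p_ok & lfc_ok],
        ["both", "p_only", "lfc_only"],
        default="ns",
    )
    points = pd.DataFrame(
        {"log2fc": t["log2fc"], "neg_log10_padj": neglog, "class": cls},
        index=t.index,
    )
    return PlotData(
        "volcano",
        {"points": points},
        params={"p_cut": p_cut, "lfc_cut": lfc_cut},
        provenance={"contrast": str(cr.label)},
    )


def _pd_gene_heatmap(params, **kw):
    (mr,) = _need(kw, "gene_heatmap", "master")
    stat = params.get("stat", "max")
    descending = params.get("descending", True)
    top_n = params.get("top_n", 50)
    import warnings as _w

    if top_n > mr.n_genes:
        _w.warn(
            f"top_n={top_n} exceeds {mr.n_genes} available genes; clamped",
            stacklevel=2,
        )
        top_n = mr.n_genes
    selected = sort_genes(mr, stat=stat, descending=descending)[:top_n]
    sub = mr.lfc.loc[selected]
    if len(selected) >= 3:
        dm = cl.distance_matrix(sub.T.fillna(0.0), metric="euclidean", axis="samples")
        tree = cl.hcluster(dm, linkage="complete")
        row_order = tree.leaf_order()
    else:
        row_order = selected
    values = sub.loc[row_order]  # columns stay in user-supplied contrast order
    values.index.name = "gene"
    return PlotData(
        "gene_heatmap",
        {"lfc": values},
        params={
            "stat": stat,
            "descending": descending,
            "top_n": int(top_n),
            "selection_order": selected,
        },
    )


def _pd_profile_plot(params, **kw):
    (mr,) = _need(kw, "profile_plot", "master")
    genes = params.get("genes")
    if genes is None:
        top_n = params.get("top_n", 20)
        genes = sort_genes(mr, stat=params.get("stat", "variance"))[:top_n]
    missing = [g for g in genes if g not in set(mr.gene_ids)]
    if missing:
        raise KeyError(f"genes not in master result: {missing}")
    traj = mr.lfc.loc[genes]
    traj.index.name = "gene"
    return PlotData("profile_plot", {"trajectories": traj}, params={"genes": list(genes)})


def _pd_gene_boxplot_wilcoxon(params, **kw):
    nm, md = _need(kw, "gene_boxplot_wilcoxon", "normalized", "metadata")
    gene = params.get("gene")
    if gene is None:
        raise MissingInputError("gene_boxplot_wilcoxon requires params['gene']")
    if gene not in nm.values.index:
        raise KeyError(f"gene {gene!r} not in normalized matrix")
    factor = params.get("factor") or md.factor_names[0]
    groups_of = md.factors[factor].astype(str)
    expr = nm.values.loc[gene]
    values = pd.DataFrame(
        {"expression": expr, "group": [str(groups_of.get(s, "?")) for s in expr.index]},
        index=expr.index,
    )
    values.index.name = "sample"
    levels = sorted(values["group"].unique())
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            x = values.loc[values["group"] == levels[i], "expression"]
            y = values.loc[values["group"] == levels[j], "expression"]
            tr = wilcoxon_rank_sum(x, y)
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "statistic": tr.statistic,
                    "p_value": tr.p_value,
                    "method": tr.method,
                }
            )
    tests = pd.DataFrame(rows)
    tests.index.name = "pair"
    return PlotData(
        "gene_boxplot_wilcoxon",
        {"values": values, "tests": tests},
        params={"gene": gene, "factor": factor},
    )


def _pd_coexpression_series(params, **kw):
    (mr,) = _need(kw, "coexpression_series", "master")
    k = params.get("k", 4)
    pc = cl.cluster_profiles(mr, k=k)
    labels = pc.labels.to_frame()
    labels.index.name = "gene"
    return PlotData(
        "coexpression_series",
        {"labels": labels, "centers": pc.centers},
        params={"k": int(k), "excluded": list(pc.excluded)},
    )


def _pd_aggregation_density(on: str, params, **kw):
    plot_type = f"aggregation_density_{'p' if on == 'padj' else 'lfc'}"
    mr, contrasts = _need(kw, plot_type, "master", "contrasts")
    ad = agreement_density(mr, contrasts, on=on)
    dens = pd.DataFrame(ad.densities, index=pd.Index(ad.grid, name="grid"))
    overlap = ad.overlap.to_frame("n_significant")
    overlap.index.name = "gene"
    return PlotData(plot_type, {"density": dens, "overlap": overlap}, params={"on": on})


_BUILDERS = {
    "sample_distance_heatmap": _pd_sample_distance_heatmap,
    "group_dendrogram": _pd_group_dendrogram,
    "mds_confidence": lambda params, **kw: _pd_mds("ellipse", params, **kw),
    "mds_hull": lambda params, **kw: _pd_mds("hull", params, **kw),
    "boxplot_prenorm": lambda params, **kw: _pd_boxplot("prenorm", params, **kw),
    "boxplot_postnorm": lambda params, **kw: _pd_boxplot("postnorm", params, **kw),
    "foldchange_boxplot": _pd_foldchange_boxplot,
    "divergence_plot": _pd_divergence_plot,
    "updown_summary": _pd_updown_summary,
    "volcano": _pd_volcano,
    "gene_heatmap": _pd_gene_heatmap,
    "profile_plot": _pd_profile_plot,
    "gene_boxplot_wilcoxon": _pd_gene_boxplot_wilcoxon,
    "coexpression_series": _pd_coexpression_series,
    "aggregation_density_p": lambda params, **kw: _pd_aggregation_density(
        "padj", params, **kw
    ),
    "aggregation_density_lfc": lambda params, **kw: _pd_aggregation_density(
        "lfc", params, **kw
    ),
}


def compute_plot_data(
    plot_type: str,
    *,
    counts: CountMatrix | None = None,
    metadata: SampleMetadata | None = None,
    normalized: NormalizedMatrix | None = None,
    contrast: ContrastResult | None = None,
    contrasts: list[ContrastResult] | None = None,
    master: MasterResult | None = None,
    params: dict | None = None,
) -> PlotData:
    """Compute the numeric tables behind one plot type.

    Inputs are passed by role; a builder raises :class:`MissingInputError`
    naming the first missing one.  No input is mutated.
    """
    if plot_type not in _BUILDERS:
        raise ValueError(f"unknown plot type {plot_type!r}; see list_plot_types()")
    return _BUILDERS[plot_type](
        dict(params or {}),
        counts=counts,
        metadata=metadata,
        normalized=normalized,
        contrast=contrast,
        contrasts=contrasts,
        master=master,
    )


# ---------------------------------------------------------------------------
# rendering


def _apply_theme(fig, ax_list, theme: Theme) -> None:
    fig.patch.set_facecolor(theme.background)
    for ax in ax_list:
        for item in (
            [ax.title, ax.xaxis.label, ax.yaxis.label]
            + ax.get_xticklabels()
            + ax.get_yticklabels()
        ):
            item.set_fontsize(item.get_fontsize() * theme.font_scale)


def _render_boxes(ax, stats: pd.DataFrame, outliers: pd.DataFrame, theme: Theme):
    boxes = []
    for name, row in stats.iterrows():
        fliers = (
            outliers.loc[[name], "value"].tolist() if name in outliers.index else []
        )
        boxes.append(
            {
                "label": str(name),
                "whislo": row["whisker_low"],
                "q1": row["q1"],
                "med": row["median"],
                "q3": row["q3"],
                "whishi": row["whisker_high"],
                "fliers": fliers,
            }
        )
    bp = ax.bxp(boxes, showfliers=True, patch_artist=True)
    for i, patch in enumerate(bp["boxes"]):
        patch.set_facecolor(theme.palette[i % len(theme.palette)])
    ax.tick_params(axis="x", rotation=90)


def render(
    pd_obj: PlotData,
    theme: Theme | str = "classic",
    path: str | Path = "figure.pdf",
    fmt: str | None = None,
    dpi: int = 300,
    size: tuple[float, float] | None = None,
) -> Path:
    """Render a PlotData to a pdf or png file.

    The format defaults to the path suffix; size defaults to the automatic
    rescaling rule applied to a 7x6-inch base.
    """
    from .project import figure_size

    if isinstance(theme, str):
        theme = get_theme(theme)
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "pdf"
    if fmt not in ("pdf", "png"):
        raise ValueError(f"unknown format {fmt!r}; use 'pdf' or 'png'")
    if path.suffix.lstrip(".").lower() != fmt:
        path = path.with_suffix(f".{fmt}")
    if size is None:
        size = figure_size(pd_obj)

    fig, ax = plt.subplots(figsize=size)
    try:
        _draw(pd_obj, theme, fig, ax)
        _apply_theme(fig, [ax], theme)
        fig.tight_layout()
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, format=fmt, dpi=dpi, facecolor=fig.get_facecolor())
    finally:
        plt.close(fig)
    return path


def _draw(pd_obj: PlotData, theme: Theme, fig, ax) -> None:
    t = pd_obj.plot_type
    tabs = pd_obj.tables
    pal = theme.palette
    if t in ("sample_distance_heatmap",):
        sns.heatmap(tabs["distance"], ax=ax, cmap="viridis", square=True)
        ax.set_title("Sample distances")
    elif t == "group_dendrogram":
        from scipy.cluster import hierarchy as sch

        merges = tabs["merges"].to_numpy(dtype=float)
        leaves = tabs["leaves"]
        groups = sorted(leaves["group"].unique())
        color_of = {g: pal[i % len(pal)] for i, g in enumerate(groups)}
        sch.dendrogram(merges, labels=list(leaves.index), ax=ax, link_color_func=lambda _: "0.4")
        for lbl in ax.get_xmajorticklabels():
            lbl.set_color(color_of[leaves.loc[lbl.get_text(), "group"]])
        ax.set_title(f"Dendrogram by {pd_obj.params.get('factor', '')}")
    elif t in ("mds_confidence", "mds_hull"):
        coords = tabs["coords"]
        groups = sorted(coords["group"].unique())
        for i, g in enumerate(groups):
            sub = coords[coords["group"] == g]
            ax.scatter(sub["dim1"], sub["dim2"], color=pal[i % len(pal)], label=g)
        overlay = tabs["overlay"]
        if t == "mds_confidence":
            from matplotlib.patches import Ellipse

            for i, g in enumerate(groups):
                if g in overlay.index:
                    row = overlay.loc[g]
                    ax.add_patch(
                        Ellipse(
                            (row["center_x"], row["center_y"]),
                            2 * row["semi_major"],
                            2 * row["semi_minor"],
                            angle=row["angle_deg"],
                            fill=False,
                            color=pal[i % len(pal)],
                        )
                    )
        else:
            for i, g in enumerate(groups):
                if g in overlay.index:
                    verts = overlay.loc[[g]][["x", "y"]].to_numpy(dtype=float)
                    poly = np.vstack([verts, verts[:1]])
                    ax.plot(poly[:, 0], poly[:, 1], color=pal[i % len(pal)])
        ax.legend(loc=theme.legend_loc, fontsize="small")
        ax.set_xlabel("MDS 1")
        ax.set_ylabel("MDS 2")
    elif t in ("boxplot_prenorm", "boxplot_postnorm", "foldchange_boxplot"):
        _render_boxes(ax, tabs["stats"], tabs["outliers"], theme)
        ax.set_ylabel(pd_obj.params.get("value", "log2 fold change"))
    elif t == "divergence_plot":
        div = tabs["divergence"]
        x = np.arange(len(div))
        ax.bar(x - 0.2, div["mean_up"], width=0.4, color=pal[0], label="up")
        ax.bar(x + 0.2, div["mean_down"], width=0.4, color=pal[1], label="down")
        ax.axhline(0.0, color="0.3", lw=0.8)
        ax.set_xticks(x, [str(i) for i in div.index], rotation=90)
        ax.set_ylabel("mean log2 fold change")
        ax.legend(loc=theme.legend_loc)
    elif t == "updown_summary":
        counts = tabs["counts"]
        x = np.arange(len(counts))
        ax.bar(x - 0.2, counts["up"], width=0.4, color=pal[0], label="up")
        ax.bar(x + 0.2, counts["down"], width=0.4, color=pal[1], label="down")
        ax.set_xticks(x, [str(i) for i in counts.index], rotation=90)
        ax.set_ylabel("significant genes")
        ax.legend(loc=theme.legend_loc)
    elif t == "volcano":
        pts = tabs["points"]
        colors = {"ns": "0.7", "p_only": pal[2], "lfc_only": pal[3], "both": pal[0]}
        for klass, color in colors.items():
            sub = pts[pts["class"] == klass]
            ax.scatter(sub["log2fc"], sub["neg_log10_padj"], s=8, color=color, label=klass)
        ax.axvline(pd_obj.params["lfc_cut"], color="0.4", lw=0.6, ls="--")
        ax.axvline(-pd_obj.params["lfc_cut"], color="0.4", lw=0.6, ls="--")
        ax.axhline(-np.log10(pd_obj.params["p_cut"]), color="0.4", lw=0.6, ls="--")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 adjusted p")
        ax.legend(loc=theme.legend_loc, fontsize="small")
    elif t == "gene_heatmap":
        sns.heatmap(tabs["lfc"], ax=ax, cmap="RdBu_r", center=0.0)
        ax.set_title("log2 fold change")
    elif t == "profile_plot":
        traj = tabs["trajectories"]
        x = np.arange(traj.shape[1])
        for i, (gene, row) in enumerate(traj.iterrows()):
            ax.plot(x, row.to_numpy(dtype=float), color=pal[i % len(pal)], alpha=0.7)
        ax.set_xticks(x, [str(c) for c in traj.columns], rotation=90)
        ax.set_ylabel("log2 fold change")
    elif t == "gene_boxplot_wilcoxon":
        values = tabs["values"]
        groups = sorted(values["group"].unique())
        frame = pd.DataFrame(
            {
                g: pd.Series(
                    values.loc[values["group"] == g, "expression"].to_numpy()
                )
                for g in groups
            }
        )
        stats, outliers = _box_stats(frame)
        _render_boxes(ax, stats, outliers, theme)
        tests = tabs["tests"]
        lines = [
            f"{r.group_a} vs {r.group_b}: p={r.p_value:.3g}"
            for r in tests.itertuples()
        ]
        ax.set_title(
            f"{pd_obj.params.get('gene', '')}\n" + "; ".join(lines), fontsize=9
        )
        ax.set_ylabel("normalized expression")
    elif t == "coexpression_series":
        centers = tabs["centers"]
        x = np.arange(centers.shape[1])
        for i, (cid, row) in enumerate(centers.iterrows()):
            ax.plot(
                x, row.to_numpy(dtype=float), color=pal[i % len(pal)],
                label=f"cluster {cid}", lw=2,
            )
        ax.set_xticks(x, [str(c) for c in centers.columns], rotation=90)
        ax.set_ylabel("mean z-scored log2 fold change")
        ax.legend(loc=theme.legend_loc, fontsize="small")
    elif t in ("aggregation_density_p", "aggregation_density_lfc"):
        dens = tabs["density"]
        for i, col in enumerate(dens.columns):
            ax.plot(dens.index, dens[col], color=pal[i % len(pal)], label=str(col))
        ax.set_xlabel("adjusted p" if t.endswith("_p") else "log2 fold change")
        ax.set_ylabel("density")
        ax.legend(loc=theme.legend_loc, fontsize="small")
    else:  # pragma: no cover - registry closure guards this
        raise ValueError(f"no renderer for {t!r}")
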