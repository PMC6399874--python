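"""Standardized project workspace: scaffold, auto-export, figure sizing.

A project root contains a fixed directory tree created at initialization:

    root/
      results/de_lists/   per-contrast DE tables and significance sets
      results/master/     aggregated master result sets
      figures/pdf/        rendered figures, pdf
      figures/png/        rendered figures, png
      figures/data/       PlotData TSV sidecars
      logs/               append-only audit log
      config/             flat key-value config snapshot

Fixed names keep results navigable long after an analysis is done.  Exports
never overwrite: a name collision gets a versioned suffix.  Every file
written into results/ or figures/ is recorded by exactly one timestamped
log line, so the scaffold contents can be audited against the log.
"""

from __future__ import annotations

import datetime as _dt
import re
import shutil
from dataclasses import dataclass, replace
from pathlib import Path

from .aggregate import MasterResult
from .de import SignificanceSet
from .io import ContrastResult, write_contrast_table
from .viz import ROW_INDEXED_TYPES, PlotData, Theme, render

__all__ = [
    "ProjectLayout",
    "SUBDIRS",
    "init_project",
    "load_project",
    "set_autosave",
    "figure_size",
    "export_result",
    "save_plot",
]

SUBDIRS = (
    "results/de_lists",
    "results/master",
    "figures/pdf",
    "figures/png",
    "figures/data",
    "logs",
    "config",
)

_CONFIG_NAME = "config/project.cfg"
_LOG_NAME = "logs/project.log"


@dataclass(frozen=True)
class ProjectLayout:
    """Paths and export toggles of one project workspace."""

    root: Path
    autosave_data: bool = True
    autosave_figures: bool = True
    default_fmt: str = "pdf"
    default_dpi: int = 300

    def path(self, sub: str) -> Path:
        return self.root / sub

    @property
    def de_lists_dir(self) -> Path:
        return self.root / "results/de_lists"

    @property
    def master_dir(self) -> Path:
        return self.root / "results/master"

    @property
    def figures_data_dir(self) -> Path:
        return self.root / "figures/data"

    def figures_dir(self, fmt: str) -> Path:
        return self.root / "figures" / fmt

    @property
    def log_file(self) -> Path:
        return self.root / _LOG_NAME

    @property
    def config_file(self) -> Path:
        return self.root / _CONFIG_NAME


def _write_config(pl: ProjectLayout) -> None:
    lines = [
        f"autosave_data={str(pl.autosave_data).lower()}",
        f"autosave_figures={str(pl.autosave_figures).lower()}",
        f"default_fmt={pl.default_fmt}",
        f"default_dpi={pl.default_dpi}",
    ]
    pl.config_file.write_text("\n".join(lines) + "\n")


def _log(pl: ProjectLayout, action: str, detail: str) -> None:
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(pl.log_file, "a") as fh:
        fh.write(f"{stamp}\t{action}\t{detail}\n")


def init_project(root: str | Path, overwrite_policy: str = "refuse") -> ProjectLayout:
    """Create (or merge into) the standard scaffold under ``root``.

    ``refuse`` errors on an existing non-empty root that is not already a
    project; ``merge`` creates any missing directories and leaves existing
    files untouched, so re-initialization is lossless and idempotent.
    """
    if overwrite_policy not in ("refuse", "merge"):
        raise ValueError(f"unknown overwrite policy {overwrite_policy!r}")
    root = Path(root)
    if root.exists() and any(root.iterdir()) and overwrite_policy == "refuse":
        raise FileExistsError(
            f"{root} exists and is not empty; use overwrite_policy='merge'"
        )
    existing_cfg = root / _CONFIG_NAME
    if overwrite_policy == "merge" and existing_cfg.exists():
        pl = load_project(root)
    else:
        pl = ProjectLayout(root=root)
    for sub in SUBDIRS:
        (root / sub).mkdir(parents=True, exist_ok=True)
    _write_config(pl)
    pl.log_file.touch()
    return pl


def load_project(root: str | Path) -> ProjectLayout:
    """Reload a project, restoring toggles from the config snapshot."""
    root = Path(root)
    cfg_path = root / _CONFIG_NAME
    if not cfg_path.exists():
        raise FileNotFoundError(f"no project config at {cfg_path}")
    cfg: dict[str, str] = {}
    for line in cfg_path.read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            cfg[k.strip()] = v.strip()
    return ProjectLayout(
        root=root,
        autosave_data=cfg.get("autosave_data", "true") == "true",
        autosave_figures=cfg.get("autosave_figures", "true") == "true",
        default_fmt=cfg.get("default_fmt", "pdf"),
        default_dpi=int(cfg.get("default_dpi", "300")),
    )


def set_autosave(pl: ProjectLayout, data: bool, figures: bool) -> ProjectLayout:
    """Toggle automatic export of sidecar data and figures; persisted."""
    pl = replace(pl, autosave_data=bool(data), autosave_figures=bool(figures))
    _write_config(pl)
    return pl


def figure_size(
    pd_obj: PlotData, base: tuple[float, float] = (7.0, 6.0)
) -> tuple[float, float]:
    """Automatic figure size from the number of displayed rows/columns.

    Row-indexed plots (heat maps, profile plots) grow 0.15 inch per row
    beyond 20, clamped to four times the base height; width grows 0.3 inch
    per column beyond 12, clamped to four times the base width.  Other plot
    types keep the base size.
    """
    base_w, base_h = base
    if pd_obj.plot_type not in ROW_INDEXED_TYPES:
        return base
    main = next(iter(pd_obj.tables.values()))
    n_rows, n_cols = main.shape
    h = min(base_h + 0.15 * max(0, n_rows - 20), 4 * base_h)
    w = min(base_w + 0.30 * max(0, n_cols - 12), 4 * base_w)
    return (max(w, base_w), max(h, base_h))


_SANITIZE = re.compile(r"[^A-Za-z0-9._-]+")


def sanitize_name(name: str) -> str:
    clean = _SANITIZE.sub("_", name).strip("_")
    if not clean:
        raise ValueError(f"name {name!r} has no filesystem-safe characters")
    return clean


def _versioned(base: Path, exists) -> Path:
    """First non-colliding variant of ``base``: base, base_v2, base_v3, ..."""
    if not exists(base):
        return base
    v = 2
    while True:
        cand = base.with_name(f"{base.stem}_v{v}{base.suffix}")
        if not exists(cand):
            return cand
        v += 1


def export_result(pl: ProjectLayout, obj, name: str) -> list[Path]:
    """Write a result object into its scaffold slot, logged, never overwriting.

    MasterResult -> results/master/<name>_{lfc,padj,sig}.tsv + provenance;
    ContrastResult -> results/de_lists/<name>.tsv;
    SignificanceSet -> results/de_lists/<name>.sig.txt (one gene per line,
    thresholds in a header comment).
    """
    clean = sanitize_name(name)
    if clean != name:
        _log(pl, "sanitize", f"{name} -> {clean}")
    if isinstance(obj, MasterResult):
        target_dir = pl.master_dir
        probe = _versioned(
            target_dir / f"{clean}.tsv",
            lambda p: any(
                (target_dir / f"{p.stem}_{part}.tsv").exists()
                for part in ("lfc", "padj", "sig")
            ),
        )
        stem = probe.stem
        paths = obj.to_tsvs(target_dir, stem)
    elif isinstance(obj, ContrastResult):
        target = _versioned(pl.de_lists_dir / f"{clean}.tsv", Path.exists)
        write_contrast_table(obj, target)
        paths = [target]
    elif isinstance(obj, SignificanceSet):
        target = _versioned(pl.de_lists_dir / f"{clean}.sig.txt", Path.exists)
        with open(target, "w") as fh:
            fh.write(
                f"# contrast={obj.label} p_cut={obj.p_cut} lfc_cut={obj.lfc_cut}\n"
            )
            for g in obj.genes:
                fh.write(f"{g}\n")
        paths = [target]
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    for p in paths:
        _log(pl, "export", str(p.relative_to(pl.root)))
    return paths


def save_plot(
    pl: ProjectLayout,
    pd_obj: PlotData,
    theme: Theme | str = "classic",
    name: str | None = None,
    dpi: int | None = None,
) -> list[Path]:
    """Render a plot into the scaffold in both pdf and png, with sidecars.

    Figures are written when ``autosave_figures`` is on (both formats), the
    PlotData TSV sidecars when ``autosave_data`` is on; each written file
    gets one log line.  With both toggles off this is a no-op.
    """
    clean = sanitize_name(name or pd_obj.plot_type)
    written: list[Path] = []
    if pl.autosave_figures:
        for fmt in ("pdf", "png"):
            target = _versioned(pl.figures_dir(fmt) / f"{clean}.{fmt}", Path.exists)
            render(pd_obj, theme=theme, path=target, fmt=fmt, dpi=dpi or pl.default_dpi)
            written.append(target)
    if pl.autosave_data:
        # version the sidecar stem against its json manifest
        probe = _versioned(
            pl.figures_data_dir / f"{clean}.x",
            lambda p: (pl.figures_data_dir / f"{p.stem}.plotdata.json").exists(),
        )
        written.extend(pd_obj.to_tsvs(pl.figures_data_dir, probe.stem))
    for p in written:
        _log(pl, "save_plot", str(p.relative_to(pl.root)))
    return written
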