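"""Config-driven orchestration of the three analyses plus summary rendering.

A single YAML config names the panel, the input samples (colony TIFFs, a
flow sample sheet, confocal stacks) and the algorithm parameters; the
pipeline runs panel design enumeration and then each analysis for the
listed inputs, writing one CSV per result plus a JSON run report that
accounts for every input sample (processed or skipped with a reason).
All parameters default to the study's conventions — 1% radial bins, a
120% profile cutoff, the 99.9% control gate quantile, a 24,000-event QC
floor and 10-pixel voxels — and every figure's numbers also exist in a
CSV: figures are views, never the only record.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from dualreporter import __version__
from dualreporter import colony as colony_mod
from dualreporter import flow as flow_mod
from dualreporter import synth as synth_mod
from dualreporter import voxel as voxel_mod
from dualreporter.panel import GenePanel, default_panel, enumerate_design, load_panel

log = logging.getLogger("dualreporter")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class Parameters:
    """Algorithm parameters shared across stages (study-convention defaults)."""

    log_sigma: float = 2.0
    bin_resolution: float = 1.0
    max_percent: float = 120.0
    gate_quantile: float = flow_mod.DEFAULT_GATE_QUANTILE
    min_events: int = flow_mod.DEFAULT_MIN_EVENTS
    voxel_edge: int = voxel_mod.DEFAULT_EDGE
    pixel_size_um: float = voxel_mod.DEFAULT_PIXEL_SIZE_UM
    background_threshold: float = 0.0
    min_fluor_fraction: float = voxel_mod.DEFAULT_MIN_FLUOR_FRACTION

    def __post_init__(self) -> None:
        if not 0 < self.gate_quantile < 1:
            raise ConfigError("gate_quantile must be in (0, 1)")
        if self.voxel_edge < 2:
            raise ConfigError("voxel_edge must be >= 2")
        if self.bin_resolution <= 0 or self.max_percent <= 0:
            raise ConfigError("bin_resolution and max_percent must be positive")


@dataclass(frozen=True)
class RunConfig:
    output_dir: Path = Path("dualreporter_out")
    panel_file: Path | None = None
    exclusions: tuple[str, ...] = ("sunA",)
    parameters: Parameters = field(default_factory=Parameters)
    colony_images: tuple[Mapping[str, Any], ...] = ()
    flow_sheet: Path | None = None
    stacks: tuple[Mapping[str, Any], ...] = ()
    synthetic_demo: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = Parameters(**raw.get("parameters", {}))
        panel_cfg = raw.get("panel", {})
        return cls(
            output_dir=Path(raw.get("output_dir", "dualreporter_out")),
            panel_file=Path(panel_cfg["file"]) if panel_cfg.get("file") else None,
            exclusions=tuple(panel_cfg.get("exclusions", ["sunA"])),
            parameters=params,
            colony_images=tuple(raw.get("colony_images", [])),
            flow_sheet=Path(raw["flow"]["sheet"]) if raw.get("flow", {}).get("sheet") else None,
            stacks=tuple(raw.get("stacks", [])),
            synthetic_demo=bool(raw.get("synthetic_demo", False)),
            seed=int(raw.get("seed", 0)),
        )

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["panel_file"] = str(self.panel_file) if self.panel_file else None
        d["flow_sheet"] = str(self.flow_sheet) if self.flow_sheet else None
        return d


@dataclass
class RunReport:
    """Accounting of one pipeline run: outputs, QC flags, provenance."""

    processed: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    qc_flags: list[str] = field(default_factory=list)
    version: str = __version__
    config_echo: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @property
    def n_success(self) -> int:
        return len(self.processed)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _load_config_panel(config: RunConfig) -> GenePanel:
    if config.panel_file is not None:
        return load_panel(config.panel_file, exclusions=config.exclusions)
    return default_panel(exclusions=config.exclusions)


def _run_design(panel: GenePanel, out_dir: Path, report: RunReport) -> None:
    design = enumerate_design(panel)
    path = out_dir / "design.csv"
    design.to_frame().to_csv(path, index=False)
    report.outputs.append(str(path))
    report.processed.append({
        "stage": "design", "sample": "panel",
        "n_active_genes": panel.n_active,
        "n_pairs": design.n_pairs,
        "n_configurations": design.n_configurations,
    })


def _run_colony(config: RunConfig, out_dir: Path, report: RunReport) -> list[colony_mod.RadialProfile]:
    p = config.parameters
    profiles = []
    for entry in config.colony_images:
        sample_id = entry.get("sample_id") or Path(entry["path"]).stem
        try:
            image = colony_mod.load_colony_tiff(entry["path"], channel_names=entry.get("channels"))
            mask, profile = colony_mod.profile_colony(
                image, log_sigma=p.log_sigma, bin_resolution=p.bin_resolution,
                max_percent=p.max_percent, normalize=None)
            normed = colony_mod.normalize_profile(profile)
            out = profile.to_frame()
            for name in normed.means:
                out[f"norm_mean_{name}"] = normed.means[name]
            path = out_dir / f"profile_{sample_id}.csv"
            out.to_csv(path, index=False)
            report.outputs.append(str(path))
            report.processed.append({
                "stage": "colony", "sample": sample_id,
                "mask_area_px": mask.area, "mean_radius_px": mask.mean_radius,
            })
            profiles.append(normed)
        except Exception as exc:  # per-sample isolation: one bad input never stops the run
            log.warning("colony sample %s skipped: %s", sample_id, exc)
            report.skipped.append({"stage": "colony", "sample": sample_id, "reason": str(exc)})
    return profiles


def _run_flow(config: RunConfig, out_dir: Path, report: RunReport) -> flow_mod.CoexpressionMatrix | None:
    p = config.parameters
    sheet = pd.read_csv(config.flow_sheet)
    required = {"sample_id", "path", "is_control"}
    if missing := required - set(sheet.columns):
        raise ConfigError(f"flow sheet missing columns: {sorted(missing)}")
    controls = sheet[sheet["is_control"].astype(bool)]
    if controls.empty:
        raise ConfigError("flow sheet designates no control sample")
    base = config.flow_sheet.parent
    ctrl_row = controls.iloc[0]
    control = flow_mod.load_flow_csv(base / ctrl_row["path"], is_control=True,
                                     sample_id=str(ctrl_row["sample_id"]))
    gates = flow_mod.fit_gates(control, quantile=p.gate_quantile)
    report.processed.append({
        "stage": "flow_gates", "sample": control.sample_id,
        "ypet_threshold": gates.ypet_threshold, "mturq_threshold": gates.mturq_threshold,
        "quantile": gates.quantile,
    })

    summaries = []
    for _, row in sheet[~sheet["is_control"].astype(bool)].iterrows():
        sid = str(row["sample_id"])
        try:
            sample = flow_mod.load_flow_csv(
                base / row["path"],
                gene_ypet=row.get("gene_ypet"), gene_mturq=row.get("gene_mturq"),
                orientation=int(row["orientation"]) if "orientation" in row and pd.notna(row["orientation"]) else None,
                sample_id=sid,
            )
            summary = flow_mod.classify_quadrants(sample, gates, min_events=p.min_events)
            if not summary.qc_pass:
                report.qc_flags.append(f"flow sample {sid}: {summary.n} events < {p.min_events}")
            summaries.append(summary)
            report.processed.append({"stage": "flow", "sample": sid, "n": summary.n,
                                     "percent_both": summary.percent_both,
                                     "qc_pass": summary.qc_pass})
        except Exception as exc:
            log.warning("flow sample %s skipped: %s", sid, exc)
            report.skipped.append({"stage": "flow", "sample": sid, "reason": str(exc)})

    if not summaries:
        return None
    path = out_dir / "flow_quadrants.csv"
    flow_mod.summary_frame(summaries).to_csv(path, index=False)
    report.outputs.append(str(path))

    matrix = None
    if any(s.pair is not None for s in summaries):
        matrix = flow_mod.build_coexpression_matrix(summaries)
        mpath = out_dir / "coexpression_matrix.csv"
        matrix.matrix.to_csv(mpath)
        report.outputs.append(str(mpath))
        ppath = out_dir / "coexpression_provenance.csv"
        matrix.provenance.to_csv(ppath, index=False)
        report.outputs.append(str(ppath))
        epath = out_dir / "percent_expressing.csv"
        flow_mod.percent_expressing_by_gene(summaries).to_csv(epath, index=False)
        report.outputs.append(str(epath))
    return matrix


def _run_stacks(config: RunConfig, out_dir: Path, report: RunReport) -> list[voxel_mod.CorrelationMap]:
    p = config.parameters
    maps = []
    for entry in config.stacks:
        sample_id = entry.get("sample_id") or Path(entry["path"]).stem
        try:
            stack = voxel_mod.load_stack_tiff(entry["path"], pixel_size_um=p.pixel_size_um)
            grid = voxel_mod.tile_voxels(stack, edge=p.voxel_edge)
            thr = p.background_threshold
            if "background_box" in entry:
                box = tuple(slice(a, b) for a, b in entry["background_box"])
                thr = voxel_mod.estimate_background(stack, box)
            cmap = voxel_mod.voxel_pearson(stack, grid, background_threshold=thr,
                                           min_fluor_fraction=p.min_fluor_fraction)
            path = out_dir / f"voxcorr_{sample_id}.csv"
            cmap.to_frame().to_csv(path, index=False)
            report.outputs.append(str(path))
            report.processed.append({
                "stage": "voxcorr", "sample": sample_id,
                "n_voxels": cmap.grid.n_voxels,
                "n_retained": int(cmap.retained.sum()),
                "background_threshold": thr,
            })
            maps.append(cmap)
        except Exception as exc:
            log.warning("stack %s skipped: %s", sample_id, exc)
            report.skipped.append({"stage": "voxcorr", "sample": sample_id, "reason": str(exc)})
    return maps


def _synthetic_demo_inputs(config: RunConfig, demo_dir: Path) -> RunConfig:
    """Generate a small self-contained demo dataset and point the config at it."""
    demo_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    colony = synth_mod.make_colony(synth_mod.ColonySpec(
        shape=(384, 384), radius=120.0,
        channels={"YPet": synth_mod.Ring(center=50.0, width=5.0),
                  "mTurq": synth_mod.EdgePeaked()},
        seed=seed,
    ))
    colony_path = demo_dir / "colony.tiff"
    synth_mod.write_colony(colony, colony_path)

    stack = synth_mod.two_region_stack(
        shape=(20, 60, 60), rho_inner=0.7, rho_outer=-0.7,
        background_frac=0.2, seed=seed + 1)
    stack_path = demo_dir / "stack.ome.tiff"
    synth_mod.write_stack(stack, stack_path)

    control = synth_mod.make_control(n=50_000, seed=seed + 2)
    ctrl_path = demo_dir / "control.csv"
    synth_mod.write_flow(control, ctrl_path)
    rows = [{"sample_id": "control", "path": ctrl_path.name, "is_control": True,
             "gene_ypet": "", "gene_mturq": "", "orientation": ""}]
    for i, (ga, gb) in enumerate([("hag", "tapA"), ("sdpA", "skfA")]):
        for orientation, (gy, gm) in enumerate([(ga, gb), (gb, ga)], start=1):
            spec = synth_mod.FlowMixtureSpec(
                fractions=(0.4, 0.2, 0.2, 0.2), n=24_000,
                seed=seed + 10 + 2 * i + orientation)
            sample = synth_mod.make_flow(spec, gene_ypet=gy, gene_mturq=gm,
                                         orientation=orientation)
            fname = f"flow_{gy}_{gm}.csv"
            synth_mod.write_flow(sample, demo_dir / fname)
            rows.append({"sample_id": fname[:-4], "path": fname, "is_control": False,
                         "gene_ypet": gy, "gene_mturq": gm, "orientation": orientation})
    sheet_path = demo_dir / "samples.csv"
    pd.DataFrame(rows).to_csv(sheet_path, index=False)

    return dataclasses.replace(
        config,
        colony_images=config.colony_images + (
            {"path": str(colony_path), "channels": ["brightfield", "YPet", "mTurq"],
             "sample_id": "demo_colony"},),
        stacks=config.stacks + (
            {"path": str(stack_path), "sample_id": "demo_stack",
             "background_box": [[0, 20], [0, 60], [50, 60]]},),
        flow_sheet=sheet_path if config.flow_sheet is None else config.flow_sheet,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every configured stage; skip bad samples, never the run.

    Returns a :class:`RunReport` accounting for all inputs.  Deterministic
    stages (everything except report timestamps) write byte-identical CSVs
    on rerun with the same config and inputs.
    """
    report = RunReport(started=_now(), config_echo=config.echo())
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic_demo:
        config = _synthetic_demo_inputs(config, out_dir / "demo_inputs")

    panel = _load_config_panel(config)
    _run_design(panel, out_dir, report)

    profiles = _run_colony(config, out_dir, report)
    matrix = None
    if config.flow_sheet is not None:
        matrix = _run_flow(config, out_dir, report)
    maps = _run_stacks(config, out_dir, report)

    if matrix is not None or profiles or maps:
        figures = render_summary(matrix, profiles, maps, out_dir, panel=panel)
        report.outputs.extend(str(f) for f in figures)

    report.finished = _now()
    report.write(out_dir / "run_report.json")
    return report


def render_summary(
    matrix: flow_mod.CoexpressionMatrix | None,
    profiles: Sequence[colony_mod.RadialProfile],
    maps: Sequence[voxel_mod.CorrelationMap],
    out_dir: Path,
    panel: GenePanel | None = None,
) -> list[Path]:
    """Render the summary figures (heatmap, profile panels, cross-sections).

    The co-expression heatmap is ordered by the panel's gene order, the
    profile panels share the 0-120% x-axis, and correlation sections use a
    diverging scale (yellow = +1 through dark blue = -1).  Raises on
    all-empty input.
    """
    if matrix is None and not profiles and not maps:
        raise ConfigError("render_summary needs at least one non-empty input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if matrix is not None:
        order = [g for g in (panel.active_genes if panel else matrix.genes)
                 if g in matrix.genes]
        m = matrix.matrix.loc[order, order]
        fig, ax = plt.subplots(figsize=(0.5 * len(order) + 2.5,) * 2)
        im = ax.imshow(m.to_numpy(), vmin=0, vmax=100, cmap="viridis")
        ax.set_xticks(range(len(order)), order, rotation=90)
        ax.set_yticks(range(len(order)), order)
        fig.colorbar(im, ax=ax, label="% co-expressing")
        path = out_dir / "coexpression_heatmap.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if profiles:
        fig, axes = plt.subplots(1, len(profiles),
                                 figsize=(4 * len(profiles), 3), squeeze=False)
        for ax, prof in zip(axes[0], profiles):
            for name, values in prof.means.items():
                ax.plot(prof.bins, values, label=name)
            ax.set_xlim(0, prof.max_percent)
            ax.set_xlabel("% of colony radius")
            ax.set_ylabel("normalized mean intensity")
            ax.legend(fontsize=8)
        path = out_dir / "radial_profiles.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    for i, cmap in enumerate(maps):
        mid = cmap.grid.shape[0] // 2
        section = cross_section_figure(cmap, "z", mid)
        path = out_dir / f"correlation_section_{i}.png"
        section.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(section)
        written.append(path)
    return written


def cross_section_figure(cmap: voxel_mod.CorrelationMap, axis: str, index: int) -> plt.Figure:
    """One cross-section rendered with the yellow(+1)/dark-blue(-1) scale."""
    section = voxel_mod.cross_section(cmap, axis, index)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(section, vmin=-1, vmax=1, cmap="cividis", interpolation="nearest")
    lo, hi = cmap.axis_labels.get("x", ("Center", "End"))
    ax.set_xlabel(f"{lo}  →  {hi}")
    fig.colorbar(im, ax=ax, label="Pearson r")
    return fig
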