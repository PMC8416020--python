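"""Config-driven orchestration of the three analyses.

A run config is a single YAML file with optional ``spectra``, ``hydration``
and ``pca`` blocks plus a ``seed`` and an ``output_dir``.  Every referenced
path is validated before any computation starts; every tunable that a stage
uses is echoed into the report so there are no silent defaults.  Outputs
are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from . import hydration as hyd
from . import pca as pcamod
from . import spectra as spec
from . import trajectory as traj

__all__ = ["RunConfig", "RunReport", "load_config", "run_config", "make_report"]


class ConfigError(ValueError):
    """Raised when a run config is structurally invalid before execution."""


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    spectra: dict | None = None
    hydration: dict | None = None
    pca: dict | None = None

    def enabled_stages(self) -> list[str]:
        return [s for s in ("spectra", "hydration", "pca") if getattr(self, s)]


@dataclass
class RunReport:
    seed: int
    version: str
    parameters: dict
    stages: dict = field(default_factory=dict)  # stage -> summary dict
    wall_clock: dict = field(default_factory=dict)  # stage -> seconds


def _require_path(block: str, key: str, value) -> Path:
    if value is None:
        raise ConfigError(f"{block}.{key} is required")
    p = Path(value)
    if not p.exists():
        raise ConfigError(f"{block}.{key}: path does not exist: {p}")
    return p


def load_config(config_path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config (paths checked up front)."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "aquaprobe_out")),
        spectra=raw.get("spectra"),
        hydration=raw.get("hydration"),
        pca=raw.get("pca"),
    )
    if not cfg.enabled_stages():
        raise ConfigError("config enables no stage (spectra/hydration/pca)")
    # Validate every referenced input path before any computation.
    if cfg.spectra:
        _require_path("spectra", "manifest", cfg.spectra.get("manifest"))
    if cfg.hydration:
        for state_key in ("inactive", "active"):
            block = cfg.hydration.get(state_key)
            if block is None:
                continue
            _require_path(f"hydration.{state_key}", "topology", block.get("topology"))
            if block.get("trajectory"):
                _require_path(f"hydration.{state_key}", "trajectory", block["trajectory"])
        if not any(cfg.hydration.get(k) for k in ("inactive", "active")):
            raise ConfigError("hydration block needs at least one state")
    if cfg.pca:
        _require_path("pca", "alignment", cfg.pca.get("alignment"))
        _require_path("pca", "coords", cfg.pca.get("coords"))
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_spectra_stage(block: dict, seed: int, out_dir: Path) -> dict:
    manifest = pd.read_csv(block["manifest"], sep=None, engine="python")
    required = {"path", "condition", "probe", "replicate"}
    if not required.issubset(manifest.columns):
        raise ConfigError(f"spectra manifest needs columns {sorted(required)}")
    shape = block.get("shape", "gaussian")
    reference = block.get("reference", "apo")
    base = Path(block["manifest"]).parent

    rows, band_rows = [], []
    for rec in manifest.itertuples():
        path = Path(rec.path)
        if not path.is_absolute():
            path = base / path
        s = spec.read_spectrum(
            path,
            condition_label=str(rec.condition),
            probe_position=str(rec.probe),
            replicate_id=int(rec.replicate),
        )
        result = spec.fit_band_model(s, shape=shape, random_state=seed)
        rows.append(
            dict(
                condition=s.condition_label,
                probe=s.probe_position,
                replicate=s.replicate_id,
                H=result.H,
                r_squared=result.r_squared,
            )
        )
        for comp in result.components:
            band_rows.append(
                dict(
                    condition=s.condition_label,
                    probe=s.probe_position,
                    replicate=s.replicate_id,
                    species=comp.species,
                    center_nm=comp.center,
                    width_nm=comp.width,
                    amplitude=comp.amplitude,
                    fractional_area=result.fractional_areas[comp.species],
                )
            )
    h_table = pd.DataFrame(rows)
    _float_csv(h_table, out_dir / "h_values.csv")
    _float_csv(pd.DataFrame(band_rows), out_dir / "fitted_bands.csv")

    comparison_rows = []
    for probe, sub in h_table.groupby("probe"):
        groups = {c: g["H"].tolist() for c, g in sub.groupby("condition")}
        if reference not in groups or len(groups) < 2:
            continue
        if all(len(v) < 2 for v in groups.values()):
            continue
        cmp_res = spec.compare_hydration_groups(groups, reference=reference, rng=seed)
        for lab in cmp_res.group_labels:
            comparison_rows.append(
                dict(
                    probe=probe,
                    condition=lab,
                    n=cmp_res.n_per_group[lab],
                    mean_H=cmp_res.group_means[lab],
                    sd_H=cmp_res.group_sds[lab],
                    anova_p=cmp_res.anova_p,
                    dunnett_adjusted_p=cmp_res.dunnett_adjusted_p.get(lab, np.nan),
                    reference=reference,
                )
            )
    if comparison_rows:
        _float_csv(pd.DataFrame(comparison_rows), out_dir / "h_comparison.csv")
    summary = dict(
        n_spectra=len(h_table),
        conditions=sorted(h_table["condition"].unique().tolist()),
        probes=sorted(h_table["probe"].unique().tolist()),
        reference=reference,
        shape=shape,
        mean_H_by_condition={
            c: float(g["H"].mean()) for c, g in h_table.groupby("condition")
        },
        comparisons=len(comparison_rows),
    )
    return summary


def run_hydration_stage(block: dict, seed: int, out_dir: Path) -> dict:
    spacing = float(block.get("spacing", hyd.DEFAULT_SPACING))
    padding = float(block.get("padding", hyd.DEFAULT_PADDING))
    cutoff = float(block.get("cutoff", hyd.DEFAULT_CUTOFF))
    iso = float(block.get("iso_threshold", hyd.DEFAULT_ISO_THRESHOLD))
    delta_threshold = float(block.get("delta_threshold", hyd.DEFAULT_DELTA_THRESHOLD))
    probes = [int(p) for p in block.get("probes", [])]

    states: dict[str, traj.TrajectoryEnsemble] = {}
    for state_key in ("inactive", "active"):
        sub = block.get(state_key)
        if sub is None:
            continue
        e = traj.load_ensemble(
            sub["topology"], sub.get("trajectory"), state_label=state_key
        )
        states[state_key] = traj.superpose_frames(e)

    sel = hyd.water_oxygen_selection()
    grids: dict[str, hyd.HydrationGrid] = {}
    profile_rows = []
    # Common bounds so state grids share geometry and can be differenced.
    all_pts = []
    for e in states.values():
        idx = sel.resolve(e)
        all_pts.append(e.frames[:, idx, :].reshape(-1, 3))
    pts = np.concatenate(all_pts)
    bounds = (pts.min(axis=0) - padding, pts.max(axis=0) + padding)

    for state, e in states.items():
        g = hyd.occupancy_grid(e, sel, spacing=spacing, padding=padding, bounds=bounds)
        grids[state] = g
        hyd.write_dx(g, out_dir / f"occupancy_{state}.dx")
        _, volume = hyd.threshold_mask(g, iso)
        for probe in probes:
            prof = hyd.probe_hydration(e, probe, sel, cutoff=cutoff)
            profile_rows.append(
                dict(
                    state=state,
                    probe_residue=probe,
                    contact_fraction=prof.contact_fraction,
                    mean_count=prof.mean_count,
                    cutoff=cutoff,
                )
            )
    if profile_rows:
        _float_csv(pd.DataFrame(profile_rows), out_dir / "probe_profiles.csv")

    summary = dict(
        states=sorted(states),
        spacing=spacing,
        padding=padding,
        cutoff=cutoff,
        iso_threshold=iso,
        delta_threshold=delta_threshold,
        n_probes=len(probes),
    )
    for state, g in grids.items():
        _, vol = hyd.threshold_mask(g, iso)
        summary[f"iso_volume_{state}_A3"] = vol

    if {"inactive", "active"} <= set(states):
        diff = hyd.difference_grid(grids["active"], grids["inactive"])
        hyd.write_dx(diff, out_dir / "occupancy_difference.dx")
        change_rows = []
        for probe in probes:
            pi = hyd.probe_hydration(states["inactive"], probe, sel, cutoff=cutoff)
            pa = hyd.probe_hydration(states["active"], probe, sel, cutoff=cutoff)
            ch = hyd.classify_hydration_change(pi, pa, delta_threshold)
            change_rows.append(
                dict(
                    probe_residue=ch.probe_residue,
                    fraction_inactive=ch.fraction_inactive,
                    fraction_active=ch.fraction_active,
                    delta=ch.delta,
                    call=ch.call,
                )
            )
        if change_rows:
            _float_csv(pd.DataFrame(change_rows), out_dir / "state_comparison.csv")
            summary["direction_calls"] = {
                str(r["probe_residue"]): r["call"] for r in change_rows
            }
    return summary


def run_pca_stage(block: dict, seed: int, out_dir: Path) -> dict:
    entries = pcamod.build_coordinate_table(block["alignment"], block["coords"])
    curated = pcamod.curate_ensemble(entries, iterate=bool(block.get("iterate", False)))
    aligned = pcamod.superpose_ensemble(curated, mode=block.get("superpose", "iterative-mean"))
    model = pcamod.fit_pca(aligned, n_components=block.get("n_components"))

    scores = model.transform(aligned)
    k = min(scores.shape[1], 10)
    score_df = pd.DataFrame(
        scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
    )
    score_df.insert(0, "structure_id", list(curated.structure_ids))
    _float_csv(score_df, out_dir / "pca_scores.csv")
    eig_df = pd.DataFrame(
        dict(
            component=[f"PC{i + 1}" for i in range(model.explained_variance_.size)],
            eigenvalue=model.explained_variance_,
            explained_fraction=model.explained_variance_ratio_,
        )
    )
    _float_csv(eig_df, out_dir / "pca_eigenvalues.csv")
    with open(out_dir / "curation_report.txt", "w") as fh:
        fh.write(f"retained structures: {curated.n_structures}\n")
        fh.write(f"retained columns: {curated.n_columns}\n")
        fh.write(f"deleted structures: {', '.join(curated.deleted_structure_ids) or '(none)'}\n")
        fh.write(
            "deleted columns (0-based): "
            + (", ".join(map(str, curated.deleted_columns)) or "(none)")
            + "\n"
        )

    n_proj = 0
    if block.get("project"):
        proj_path = _require_path("pca", "project", block["project"])
        conf = pd.read_csv(proj_path, sep=None, engine="python")
        ids = conf.iloc[:, 0].astype(str).tolist()
        mat = conf.iloc[:, 1:].to_numpy(dtype=float)
        projections = pcamod.project_conformers(model, mat, conformer_ids=ids)
        pj = pd.DataFrame(
            [p.scores[:k] for p in projections],
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        pj.insert(0, "conformer_id", [p.conformer_id for p in projections])
        _float_csv(pj, out_dir / "projected_conformers.csv")
        n_proj = len(projections)

    return dict(
        n_structures_in=len(entries),
        n_structures_retained=curated.n_structures,
        n_columns_retained=curated.n_columns,
        deleted_structure_ids=list(curated.deleted_structure_ids),
        explained_variance_pc1=float(model.explained_variance_ratio_[0]),
        explained_variance_pc2=float(
            model.explained_variance_ratio_[1]
            if model.explained_variance_ratio_.size > 1
            else 0.0
        ),
        n_projected_conformers=n_proj,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAGE_RUNNERS = {
    "spectra": run_spectra_stage,
    "hydration": run_hydration_stage,
    "pca": run_pca_stage,
}


def run_config(config_path: str | Path) -> RunReport:
    """Validate the config, run the requested stages, write the report."""
    cfg = load_config(config_path)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=cfg.seed,
        version=_version,
        parameters={
            stage: dict(getattr(cfg, stage)) for stage in cfg.enabled_stages()
        },
    )
    for stage in cfg.enabled_stages():
        stage_dir = cfg.output_dir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        try:
            summary = _STAGE_RUNNERS[stage](getattr(cfg, stage), cfg.seed, stage_dir)
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report.stages[stage] = summary
        report.wall_clock[stage] = time.perf_counter() - t0
    make_report(report, cfg.output_dir)
    return report


def make_report(report: RunReport, out_dir: str | Path) -> Path:
    """Write the human-readable run report; returns its path."""
    if not report.stages:
        raise ValueError("no completed stages to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.txt"
    lines = [
        "aquaprobe run report",
        f"version: {report.version}",
        f"seed: {report.seed}",
        "",
    ]
    for stage, summary in report.stages.items():
        lines.append(f"[{stage}]  ({report.wall_clock.get(stage, 0.0):.2f} s)")
        lines.append("  parameters:")
        for key, val in sorted(report.parameters.get(stage, {}).items()):
            lines.append(f"    {key}: {val}")
        lines.append("  results:")
        for key, val in summary.items():
            lines.append(f"    {key}: {val}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path
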