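"""Configuration-driven pipeline: YAML config, schema validation, stage
execution and a run manifest.

The config schema (version 1) is a mapping with:

- ``seed``: integer used for every random stage (default 1234)
- ``out_dir``: output directory
- ``stages``: ordered list from {simulate, thickness, curvature, profile,
  tilt, superpose, displace, mapthick}
- one optional mapping per stage holding its parameters

Analysis stages operate on the trajectory produced by a preceding
``simulate`` stage, or on ``topology``/``trajectory`` paths given in their
own parameter block.  The manifest records the files written, the parameters
used, the package version and the seed; on stage failure a partial manifest
with the failure record is still written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "RunConfig", "load_config",
           "validate_config", "run_pipeline", "DEFAULT_SEED"]

DEFAULT_SEED = 1234
SCHEMA_VERSION = 1
KNOWN_STAGES = ("simulate", "thickness", "curvature", "profile", "tilt",
                "superpose", "displace", "mapthick")


class ConfigError(ValueError):
    """The run configuration violates the schema."""


class DataError(RuntimeError):
    """A stage failed on its input data."""


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    stages: list[str]
    params: dict = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def load_config(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping; raises ConfigError before anything runs."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    problems = []
    stages = raw.get("stages")
    if not isinstance(stages, list) or not stages:
        problems.append("'stages' must be a non-empty list")
        stages = []
    for s in stages:
        if s not in KNOWN_STAGES:
            problems.append(f"unknown stage {s!r} (known: {', '.join(KNOWN_STAGES)})")
    seed = raw.get("seed", DEFAULT_SEED)
    if not isinstance(seed, int):
        problems.append("'seed' must be an integer")
    out_dir = raw.get("out_dir", "memdeform_out")
    known_keys = set(KNOWN_STAGES) | {"stages", "seed", "out_dir", "schema_version"}
    for k in raw:
        if k not in known_keys:
            problems.append(f"unknown config key {k!r}")
    for s in KNOWN_STAGES:
        if s in raw and not isinstance(raw[s], dict):
            problems.append(f"stage parameter block {s!r} must be a mapping")
    if problems:
        raise ConfigError("; ".join(problems))
    params = {s: raw[s] for s in KNOWN_STAGES if s in raw}
    return RunConfig(seed=seed, out_dir=Path(out_dir), stages=list(stages), params=params)


def _build_fields(p: dict):
    from .synthetic import make_deformation_field

    out = {}
    for key in ("height_field", "thickness_field"):
        if key in p:
            f = dict(p.pop(key))
            out[key] = make_deformation_field(f.pop("kind"), **f)
    return out


def _stage_simulate(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .synthetic import (BilayerSpec, InclusionSpec, generate_trajectory,
                            save_ground_truth)
    from .trajio import write_gro, write_trajectory

    fields = _build_fields(p)
    inc = None
    if "inclusion" in p:
        ip = dict(p.pop("inclusion"))
        if "residue_id_range" in ip:
            ip["residue_id_range"] = tuple(ip["residue_id_range"])
        if "anchor" in ip:
            ip["anchor"] = tuple(ip["anchor"])
        inc = InclusionSpec(**ip)
    if "species_fractions" in p:
        p["species_fractions"] = tuple((n, f) for n, f in p["species_fractions"])
    spec = BilayerSpec(seed=cfg.seed, **fields, **p)
    traj, truth = generate_trajectory(spec, inc)
    out = cfg.out_dir
    write_gro(traj.topology, out / "system.gro")
    write_trajectory(traj, out / "trajectory.xtc")
    save_ground_truth(truth, out / "ground_truth.txt")
    state["trajectory"], state["truth"] = traj, truth
    manifest["files"] += ["system.gro", "trajectory.xtc", "ground_truth.txt"]


def _get_trajectory(p: dict, state: dict):
    from .trajio import read_trajectory

    if "topology" in p and "trajectory" in p:
        return read_trajectory(p.pop("topology"), p.pop("trajectory"))
    if "trajectory" in state:
        return state["trajectory"]
    raise DataError("no trajectory available: run a simulate stage first or "
                    "give topology/trajectory paths")


def _grid_spec(p: dict, traj):
    from .membrane import GridSpec

    spacing = float(p.pop("grid_spacing", 8.0))
    return GridSpec(spacing, (traj.boxes[0][0], traj.boxes[0][1]))


def _warn_masked(field) -> None:
    frac = 1.0 - field.mask.mean()
    if frac > 0.10:
        logger.warning("%.0f%% of grid cells are masked", 100 * frac)


def _stage_thickness(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .membrane import thickness_map
    from .reporting import heatmap_png, write_gridfield_tsv

    traj = _get_trajectory(p, state)
    spec = _grid_spec(p, traj)
    beads = p.pop("surface_beads", "bead GL1")
    min_frac = float(p.pop("min_frame_fraction", 0.5))
    png = p.pop("png", False)
    tmap = thickness_map(traj, bead_selection=beads, spec=spec,
                         min_frame_fraction=min_frac)
    _warn_masked(tmap.field)
    state["thickness"] = tmap
    write_gridfield_tsv(tmap.field, cfg.out_dir / "thickness.tsv",
                        {"stage": "thickness", "grid_spacing": spec.cell_size,
                         "surface_beads": beads, "min_frame_fraction": min_frac,
                         "n_frames": tmap.n_frames, "seed": cfg.seed})
    manifest["files"].append("thickness.tsv")
    if png:
        heatmap_png(tmap.field, cfg.out_dir / "thickness.png", "thickness")
        manifest["files"].append("thickness.png")


def _stage_curvature(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .membrane import average_leaflet_surfaces, mean_curvature, midplane_height
    from .reporting import heatmap_png, write_gridfield_tsv

    traj = _get_trajectory(p, state)
    spec = _grid_spec(p, traj)
    beads = p.pop("surface_beads", "bead GL1")
    sigma = float(p.pop("presmooth_sigma_cells", 1.0))
    png = p.pop("png", False)
    upper, lower = average_leaflet_surfaces(traj, bead_selection=beads, spec=spec)
    cmap = mean_curvature(midplane_height(upper, lower), sigma)
    _warn_masked(cmap.field)
    state["curvature"] = cmap
    write_gridfield_tsv(cmap.field, cfg.out_dir / "curvature.tsv",
                        {"stage": "curvature", "grid_spacing": spec.cell_size,
                         "surface_beads": beads, "presmooth_sigma_cells": sigma,
                         "seed": cfg.seed})
    manifest["files"].append("curvature.tsv")
    if png:
        heatmap_png(cmap.field, cfg.out_dir / "curvature.png", "curvature")
        manifest["files"].append("curvature.png")


def _stage_profile(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .membrane import radial_profile, thickness_map
    from .reporting import write_profile_tsv

    if "thickness" in state:
        tmap = state["thickness"]
    else:
        traj = _get_trajectory(p, state)
        tmap = thickness_map(traj, spec=_grid_spec(p, traj))
    spec = tmap.field.spec
    center = tuple(float(c) for c in p.pop("center", (spec.box[0] / 2, spec.box[1] / 2)))
    bin_width = float(p.pop("bin_width", spec.cell_size))
    prof = radial_profile(tmap.field, center, bin_width)
    write_profile_tsv(prof, cfg.out_dir / "profile.tsv",
                      {"stage": "profile", "center": center,
                       "bin_width": bin_width, "seed": cfg.seed})
    manifest["files"].append("profile.tsv")


def _stage_tilt(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .geometry import HelixSelectionSpec, tilt_series
    from .reporting import write_tilt_tsv

    traj = _get_trajectory(p, state)
    resid = p.pop("resid", "106-134")
    lo, hi = (int(v) for v in str(resid).split("-"))
    hspec = HelixSelectionSpec((lo, hi), p.pop("backbone_name", "BB"),
                               p.pop("chain", None))
    series = tilt_series(traj, hspec, n_blocks=int(p.pop("n_blocks", 5)))
    state["tilt"] = series
    write_tilt_tsv(series, cfg.out_dir / "tilt.tsv",
                   {"stage": "tilt", "resid": resid,
                    "backbone_name": hspec.backbone_name, "seed": cfg.seed})
    manifest["files"].append("tilt.tsv")


def _stage_superpose(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .geometry import pair_by_identity, superpose_rmsd
    from .reporting import write_metrics_report
    from .trajio import read_coordinates

    ref = read_coordinates(p.pop("reference"))
    mob = read_coordinates(p.pop("mobile"))
    selection = p.pop("select", None)
    mob_xyz, ref_xyz, keys = pair_by_identity(mob, ref, selection)
    sup = superpose_rmsd(mob_xyz, ref_xyz)
    write_metrics_report({"rmsd": sup.rmsd, "n_pairs": sup.n_pairs,
                          "degenerate": sup.degenerate},
                         cfg.out_dir / "superpose.txt",
                         {"stage": "superpose", "select": selection})
    manifest["files"].append("superpose.txt")


def _stage_displace(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .geometry import displacement_metrics
    from .reporting import write_metrics_report
    from .trajio import read_coordinates

    m_open = read_coordinates(p.pop("model_open"))
    m_closed = read_coordinates(p.pop("model_closed"))
    metrics = displacement_metrics(m_open, m_closed, p.pop("align_selection"),
                                   p.pop("probe_selection"),
                                   p.pop("probe_selection_2", None))
    write_metrics_report(metrics, cfg.out_dir / "displace.txt",
                         {"stage": "displace"})
    manifest["files"].append("displace.txt")


def _stage_mapthick(cfg: RunConfig, p: dict, state: dict, manifest: dict) -> None:
    from .density import (ThicknessProbe, lowpass_filter, read_density_map,
                          sigma_level, slab_thickness)
    from .reporting import write_metrics_report

    dmap = read_density_map(p.pop("map"))
    lowpass = p.pop("lowpass", 6.0)
    if lowpass:
        dmap = lowpass_filter(dmap, float(lowpass))
    n_sigma = float(p.pop("sigma", 6.5))
    level = sigma_level(dmap, n_sigma)
    anchors = p.pop("anchors", None) or [p.pop("anchor")]
    direction = p.pop("direction", (0.0, 0.0, 1.0))
    step = float(p.pop("step", float(np.min(dmap.spacing)) / 4.0))
    extent = float(p.pop("max_extent", float(np.max(
        np.asarray(dmap.shape) * dmap.spacing))))
    metrics = {}
    for k, anchor in enumerate(anchors):
        probe = ThicknessProbe(np.asarray(anchor, dtype=float),
                               np.asarray(direction, dtype=float), step, extent)
        res = slab_thickness(dmap, level, probe)
        key = f"anchor_{k}"
        metrics[f"{key}_thickness"] = res.thickness if res.found else "no density at level"
    metrics["level"] = level
    write_metrics_report(metrics, cfg.out_dir / "mapthick.txt",
                         {"stage": "mapthick", "lowpass": lowpass, "sigma": n_sigma})
    manifest["files"].append("mapthick.txt")


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "thickness": _stage_thickness,
    "curvature": _stage_curvature,
    "profile": _stage_profile,
    "tilt": _stage_tilt,
    "superpose": _stage_superpose,
    "displace": _stage_displace,
    "mapthick": _stage_mapthick,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write a run manifest.

    With a fixed seed two runs produce byte-identical TSV outputs; the
    manifest differs only in content that reflects the run itself.
    """
    from . import __version__

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "parameters": {s: cfg.stage_params(s) for s in cfg.stages},
        "files": [],
    }
    state: dict = {}
    try:
        for stage in cfg.stages:
            logger.info("running stage %s", stage)
            _STAGE_RUNNERS[stage](cfg, cfg.stage_params(stage), state, manifest)
            manifest["stages"].append({"name": stage, "status": "ok"})
    except Exception as exc:
        manifest["stages"].append({"name": stage, "status": "failed",
                                   "error": str(exc)})
        _write_manifest(cfg, manifest)
        raise
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: RunConfig, manifest: dict) -> None:
    (cfg.out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
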