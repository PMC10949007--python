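"""End-to-end pipeline: world → distances → risks → reports.

The pipeline writes exactly six labeled matrices (three distance, three
risk) plus the combined risk, a per-pair path-summary table, a
reachability report and a run log.  Reruns on identical inputs are
byte-identical for all data files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import synthetic
from .environment import env_distance, summarize_region_env
from .grid import EARTH_RADIUS_M, GridSpec, build_transition, carve_channels, rasterize_water
from .regions import RegionSet, load_channels, load_water_polygons
from .risk import combine_risks, standardize_risk
from .voyage import (
    all_pairs_distance,
    cross_latitude_matrix,
    path_summaries,
    unreachable_pairs,
)

MATRIX_FILES = {
    "environmental_distance": "environmental_distance.csv",
    "environmental_similarity_risk": "environmental_similarity_risk.csv",
    "physical_distance_m": "physical_distance_m.csv",
    "voyage_duration_risk": "voyage_duration_risk.csv",
    "cross_latitude_distance_deg": "cross_latitude_distance_deg.csv",
    "voyage_path_risk": "voyage_path_risk.csv",
    "combined_risk": "combined_risk.csv",
}


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``synthetic`` holds toy-world parameter overrides (see
    :class:`searisk.synthetic.ToyWorldSpec`), or the file inputs
    (``water_geojson``, ``regions_geojson``, ``env_netcdf``, optional
    ``channels``) plus ``grid`` bounds are given.  ``weights`` orders the
    combination as (environmental similarity, voyage duration, voyage
    path).
    """

    outdir: str = "searisk_out"
    seed: int = 0
    synthetic: dict | None = None
    grid: dict | None = None
    water_geojson: str | None = None
    channels: str | None = None
    regions_geojson: str | None = None
    env_netcdf: str | None = None
    earth_radius_m: float = EARTH_RADIUS_M
    metric: str = "standardized_euclidean"
    area_weighted: bool = True
    weights: tuple = (1.0, 1.0, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "weights" in data:
            data["weights"] = tuple(float(w) for w in data["weights"])
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_world(config: PipelineConfig):
    if config.synthetic is not None:
        overrides = dict(config.synthetic)
        overrides.setdefault("seed", config.seed)
        if "canal" in overrides and overrides["canal"] is not None:
            overrides["canal"] = tuple(tuple(p) for p in overrides["canal"])
        if "land_rects" in overrides:
            overrides["land_rects"] = tuple(tuple(r) for r in overrides["land_rects"])
        if "regions" in overrides:
            overrides["regions"] = tuple(tuple(r) for r in overrides["regions"])
        world = synthetic.make_toy_world(synthetic.ToyWorldSpec(**overrides))
        return world.grid, world.regions, world.env
    import xarray as xr

    for name in ("grid", "water_geojson", "regions_geojson", "env_netcdf"):
        if getattr(config, name) is None:
            raise ValueError(f"file-based run requires config field '{name}'")
    spec = GridSpec(**config.grid)
    grid = rasterize_water(load_water_polygons(config.water_geojson), spec)
    if config.channels:
        grid = carve_channels(grid, load_channels(config.channels))
    regions = RegionSet.from_geojson(config.regions_geojson)
    env = xr.open_dataset(config.env_netcdf, engine="scipy")
    return grid, regions, env


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle to ``config.outdir``.

    Returns a dict with the seven matrices, the path-summary table, the
    reachability report and the per-matrix rounding caps.  Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = ["searisk pipeline run", f"seed: {config.seed}", "config:"]
    for f in dataclasses.fields(config):
        log_lines.append(f"  {f.name}: {getattr(config, f.name)!r}")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    grid, regions, env = stage("build_world", lambda: _load_world(config))
    graph = stage("build_transition", lambda: build_transition(grid, config.earth_radius_m))
    phys = stage("least_cost_distances", lambda: all_pairs_distance(graph, regions, grid))
    summaries = stage("path_summaries", lambda: path_summaries(graph, regions, grid))
    cross = stage("cross_latitude", lambda: cross_latitude_matrix(summaries, regions))
    env_summary = stage(
        "environment_summaries",
        lambda: summarize_region_env(env, regions, area_weighted=config.area_weighted),
    )
    envd = stage("environmental_distance", lambda: env_distance(env_summary, metric=config.metric))
    risk_env = stage("standardize_environmental", lambda: standardize_risk(envd))
    risk_dur = stage("standardize_duration", lambda: standardize_risk(phys))
    risk_path = stage("standardize_path", lambda: standardize_risk(cross))
    combined = stage(
        "combine_risks",
        lambda: combine_risks([risk_env, risk_dur, risk_path], list(config.weights)),
    )
    report = unreachable_pairs(phys)

    matrices = {
        "environmental_distance": envd,
        "environmental_similarity_risk": risk_env,
        "physical_distance_m": phys,
        "voyage_duration_risk": risk_dur,
        "cross_latitude_distance_deg": cross,
        "voyage_path_risk": risk_path,
        "combined_risk": combined,
    }
    for key, obj in matrices.items():
        obj.to_csv(out / MATRIX_FILES[key])
    summaries.to_csv(out / "path_summaries.csv", index=False)
    env_summary.to_csv(out / "environment_summaries.csv", index_label="region")

    reach_lines = ["reachability report", f"unreachable pairs: {len(report)}"]
    reach_lines += [f"  {a} <-> {b}" for a, b in report]
    (out / "reachability_report.txt").write_text("\n".join(reach_lines) + "\n")

    caps = {
        "environmental_similarity_risk": risk_env.cap,
        "voyage_duration_risk": risk_dur.cap,
        "voyage_path_risk": risk_path.cap,
    }
    log_lines.append("rounding caps M (risk = 1 - d/M):")
    for k, v in caps.items():
        log_lines.append(f"  {k}: {v}")
    log_lines.append(f"unreachable pairs: {len(report)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "matrices": matrices,
        "path_summaries": summaries,
        "environment_summaries": env_summary,
        "unreachable": report,
        "caps": caps,
        "grid": grid,
        "regions": regions,
    }
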