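"""Deterministic toy worlds with known ground truth.

The generator emulates, at desk scale, the ingredients of the global
analysis: an ocean raster split by a meridional continent, a canal carved
through the isthmus, latitude-banded coastal regions on both shores, a
sea-surface temperature field that decays linearly with |latitude|, and a
salinity field with per-region offsets.  Every stage of the pipeline can
be checked against closed-form values derived from this construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import shapely
import xarray as xr

from .grid import GridSpec, OceanGrid, carve_channels, rasterize_water
from .regions import Region, RegionSet, save_channels_geojson

# (id, name, lon0, lon1, lat0, lat1) coastal boxes flanking the continent
_DEFAULT_REGIONS = (
    (1, "west-high", 14.0, 18.0, 18.0, 26.0),
    (2, "west-tropical", 14.0, 18.0, -4.0, 4.0),
    (3, "west-south", 14.0, 18.0, -26.0, -18.0),
    (4, "east-high", 22.0, 26.0, 18.0, 26.0),
    (5, "east-tropical", 22.0, 26.0, -4.0, 4.0),
    (6, "east-south", 22.0, 26.0, -26.0, -18.0),
)


@dataclass(frozen=True)
class ToyWorldSpec:
    """Parameters of a synthetic world.

    Defaults: a 40°×60° basin at 1° cells split by a continent spanning
    lon 18–22°, a canal through it at lat 0.5°, six coastal lat-band
    regions, equatorial SST 28 °C falling 0.4 °C per degree of |latitude|
    with 0.25 °C Gaussian cell noise, and 35 PSU salinity with per-region
    offsets within ±1 PSU.  ``seed`` fixes all randomness.
    """

    lon_min: float = 0.0
    lon_max: float = 40.0
    lat_min: float = -30.0
    lat_max: float = 30.0
    cell_size: float = 1.0
    wrap_longitude: bool = False
    land_rects: tuple = ((18.0, 22.0, -30.0, 30.0),)  # (lon0, lon1, lat0, lat1)
    canal: tuple | None = ((17.0, 0.5), (23.0, 0.5))
    regions: tuple = _DEFAULT_REGIONS
    excluded_ids: tuple = ()
    t_eq: float = 28.0  # °C at the equator
    t_gradient: float = 0.4  # °C lost per degree |latitude|
    salinity_base: float = 35.0  # PSU
    salinity_offsets: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 0.0, 3: -0.5, 4: 0.5, 5: -1.0, 6: 0.0}
    )
    noise_sd: float = 0.25  # °C, SST cell noise
    seed: int = 0

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            self.lon_min, self.lon_max, self.lat_min, self.lat_max,
            self.cell_size, wrap_longitude=self.wrap_longitude,
        )


@dataclass
class ToyWorld:
    """A generated world: ocean grid, regions, and environment fields."""

    spec: ToyWorldSpec
    grid: OceanGrid
    regions: RegionSet
    env: xr.Dataset

    def save(self, outdir: str | Path) -> None:
        """Emit the same formats the real pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.water_polygons_geojson(outdir / "water.geojson")
        self.regions.to_geojson(outdir / "regions.geojson")
        self.grid.to_ascii_grid(outdir / "ocean_grid.asc")
        self.env.to_netcdf(outdir / "environment.nc", engine="scipy")
        if self.spec.canal is not None:
            save_channels_geojson([list(self.spec.canal)], outdir / "channels.geojson")

    def water_polygons_geojson(self, path: str | Path) -> None:
        import json

        from shapely.geometry import mapping

        geom = _water_geometry(self.spec)
        Path(path).write_text(
            json.dumps(
                {
                    "type": "FeatureCollection",
                    "features": [
                        {"type": "Feature", "properties": {}, "geometry": mapping(geom)}
                    ],
                },
                sort_keys=True,
            )
        )


def _water_geometry(spec: ToyWorldSpec):
    extent = shapely.box(spec.lon_min, spec.lat_min, spec.lon_max, spec.lat_max)
    land = [shapely.box(x0, y0, x1, y1) for x0, x1, y0, y1 in spec.land_rects]
    return extent.difference(shapely.union_all(land)) if land else extent


def _region_set(spec: ToyWorldSpec) -> RegionSet:
    regions = []
    for rid, name, x0, x1, y0, y1 in spec.regions:
        regions.append(
            Region(
                id=int(rid),
                name=str(name),
                geometry=shapely.box(x0, y0, x1, y1),
                excluded=rid in spec.excluded_ids,
            )
        )
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            inter = a.geometry.intersection(b.geometry)
            if not inter.is_empty and inter.area > 0:
                raise ValueError(f"regions {a.id} and {b.id} overlap")
    return RegionSet(regions)


def make_toy_world(spec: ToyWorldSpec | None = None) -> ToyWorld:
    """Generate a toy world; deterministic given (spec, seed).

    SST at cell-center latitude φ is ``t_eq − t_gradient·|φ| + noise``;
    salinity is ``salinity_base`` plus the region's offset inside region
    polygons.  Land cells carry NaN environment values.
    """
    spec = spec or ToyWorldSpec()
    gspec = spec.grid_spec()
    grid = rasterize_water(_water_geometry(spec), gspec)
    if spec.canal is not None:
        grid = carve_channels(grid, [list(spec.canal)])
    regions = _region_set(spec)

    rng = np.random.default_rng(spec.seed)
    lat = gspec.lat_centers
    lon = gspec.lon_centers
    sst = spec.t_eq - spec.t_gradient * np.abs(lat)[:, None] + np.zeros((1, lon.size))
    if spec.noise_sd > 0:
        sst = sst + rng.normal(0.0, spec.noise_sd, size=sst.shape)
    sss = np.full((lat.size, lon.size), spec.salinity_base, dtype=float)
    lon_grid, lat_grid = np.meshgrid(lon, lat)
    for region in regions:
        off = float(spec.salinity_offsets.get(region.id, 0.0))
        if off != 0.0:
            inside = shapely.contains_xy(region.geometry, lon_grid, lat_grid)
            sss[inside] += off
    sst = np.where(grid.water_mask, sst, np.nan)
    sss = np.where(grid.water_mask, sss, np.nan)
    env = xr.Dataset(
        {
            "sst": (("lat", "lon"), sst, {"units": "degC", "long_name": "sea surface temperature"}),
            "sss": (("lat", "lon"), sss, {"units": "PSU", "long_name": "sea surface salinity"}),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"seed": spec.seed, "resolution_deg": spec.cell_size},
    )
    return ToyWorld(spec=spec, grid=grid, regions=regions, env=env)


def expected_sst(spec: ToyWorldSpec, lat: float) -> float:
    """Closed-form noise-free SST of the construction at a latitude."""
    return spec.t_eq - spec.t_gradient * abs(lat)


def make_canal_scenario(
    spec: ToyWorldSpec | None = None,
) -> tuple[ToyWorld, ToyWorld]:
    """Paired worlds: isthmus sealed (canal closed) vs canal carved open.

    With the default full-height continent the two basins are disconnected
    when closed; opening the canal connects the flanking regions and the
    over-water distance between them strictly drops whenever a detour
    existed.
    """
    spec = spec or ToyWorldSpec()
    if spec.canal is None:
        raise ValueError("spec has no canal to open")
    closed = make_toy_world(replace(spec, canal=None))
    open_ = make_toy_world(spec)
    return closed, open_
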