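"""Coastal regions: polygons, centroids, exclusion flags, GeoJSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class Region:
    """One coastal region (e.g. a biogeographic province).

    ``centroid_override`` reproduces manually repositioned centroids (a
    region whose area centroid falls on land, or deliberately placed near
    the busiest shipping waters).  ``excluded`` regions produce NA in every
    pairwise output.
    """

    id: int
    name: str
    geometry: BaseGeometry
    centroid_override: tuple[float, float] | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError(f"region {self.id} has empty geometry")


class RegionSet:
    """Ordered collection of regions with unique integer ids."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: list[Region] = list(regions)
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        self._by_id = {r.id: r for r in self.regions}

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, region_id: int) -> Region:
        return self._by_id[region_id]

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._by_id

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.regions]

    @property
    def active_ids(self) -> list[int]:
        return [r.id for r in self.regions if not r.excluded]

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for r in self.regions:
            props = {"id": r.id, "name": r.name, "excluded": r.excluded}
            if r.centroid_override is not None:
                props["centroid_lon"], props["centroid_lat"] = r.centroid_override
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(r.geometry)}
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionSet":
        data = json.loads(Path(path).read_text())
        regions = []
        for feat in data["features"]:
            props = feat.get("properties", {})
            override = None
            if "centroid_lon" in props and "centroid_lat" in props:
                override = (float(props["centroid_lon"]), float(props["centroid_lat"]))
            regions.append(
                Region(
                    id=int(props["id"]),
                    name=str(props.get("name", props["id"])),
                    geometry=shape(feat["geometry"]),
                    centroid_override=override,
                    excluded=bool(props.get("excluded", False)),
                )
            )
        return cls(regions)


def load_water_polygons(path: str | Path) -> list[BaseGeometry]:
    """Read ocean polygons from a GeoJSON FeatureCollection or geometry."""
    data = json.loads(Path(path).read_text())
    if data.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in data["features"]]
    if data.get("type") == "Feature":
        return [shape(data["geometry"])]
    return [shape(data)]


def load_channels(path: str | Path) -> list[list[tuple[float, float]]]:
    """Read channel chains from GeoJSON LineStrings or a lon/lat CSV.

    CSV layout: columns ``channel_id, lon, lat``; rows ordered along each
    chain.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        data = json.loads(path.read_text())
        feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
        chains = []
        for f in feats:
            geom = f["geometry"] if "geometry" in f else f
            if geom["type"] != "LineString":
                raise ValueError(f"channel features must be LineStrings, got {geom['type']}")
            chains.append([(float(x), float(y)) for x, y in geom["coordinates"]])
        return chains
    import csv

    chains_by_id: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            chains_by_id.setdefault(row["channel_id"], []).append(
                (float(row["lon"]), float(row["lat"]))
            )
    return list(chains_by_id.values())


def save_channels_geojson(
    channels: list[list[tuple[float, float]]], path: str | Path
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"channel_id": i},
            "geometry": {"type": "LineString", "coordinates": [list(p) for p in chain]},
        }
        for i, chain in enumerate(channels)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )
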