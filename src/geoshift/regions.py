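"""Named region polygons in longitude/latitude degrees.

Regions are simple shapely polygons used as operational biogeographic units
(e.g. the three tropical regions plus a pooled non-tropical unit).  Polygons
are treated as *closed* sets: a point on the boundary counts as inside.
Regions must be interior-disjoint so that every point receives at most one
label.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
import shapely.geometry
import shapely.wkt
from shapely.geometry.base import BaseGeometry

__all__ = ["RegionSet", "UNASSIGNED"]

#: label given to points covered by no region polygon
UNASSIGNED = "unassigned"


class RegionSet:
    """An ordered collection of named, interior-disjoint polygons.

    The order of ``names`` doubles as the precedence order used to break
    ties deterministically (e.g. equal record counts under the
    single-region filter).
    """

    def __init__(self, regions: Mapping[str, BaseGeometry],
                 precedence: Sequence[str] | None = None):
        self.regions = dict(regions)
        if precedence is None:
            precedence = list(self.regions)
        if set(precedence) != set(self.regions) or \
                len(set(precedence)) != len(list(precedence)):
            raise ValueError("precedence must list each region name once")
        self.names = list(precedence)
        self.validate()

    def validate(self) -> None:
        """Check pairwise interior-disjointness; raise on overlap."""
        names = self.names
        for i, a in enumerate(names):
            ga = self.regions[a]
            if ga.is_empty or not ga.is_valid:
                raise ValueError(f"region {a!r} is empty or invalid")
            for b in names[i + 1:]:
                inter = ga.intersection(self.regions[b])
                if inter.area > 0:
                    raise ValueError(
                        f"regions {a!r} and {b!r} overlap (area "
                        f"{inter.area:g} sq. deg.)")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def assign(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Label each (lon, lat) point with its covering region.

        Boundary points count as inside (closed-polygon rule); points
        covered by no polygon get :data:`UNASSIGNED`.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        pts = shapely.points(lon, lat)
        labels = np.full(lon.shape, UNASSIGNED, dtype=object)
        unresolved = np.ones(lon.shape, dtype=bool)
        for name in self.names:
            if not unresolved.any():
                break
            hit = shapely.covers(self.regions[name], pts) & unresolved
            labels[hit] = name
            unresolved &= ~hit
        return labels

    # ------------------------------------------------------------------
    # I/O: two-column WKT text, or GeoJSON FeatureCollection
    # ------------------------------------------------------------------
    def to_wkt(self, path: str) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f"{name}\t{self.regions[name].wkt}\n")

    @classmethod
    def from_wkt(cls, path: str) -> "RegionSet":
        regions: dict[str, BaseGeometry] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, wkt = line.split("\t", 1)
                if name in regions:
                    raise ValueError(f"duplicate region name {name!r}")
                regions[name] = shapely.wkt.loads(wkt)
                order.append(name)
        return cls(regions, order)

    def to_geojson(self, path: str) -> None:
        feats = [{"type": "Feature",
                  "properties": {"name": name},
                  "geometry": shapely.geometry.mapping(self.regions[name])}
                 for name in self.names]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path: str) -> "RegionSet":
        with open(path) as fh:
            gj = json.load(fh)
        regions: dict[str, BaseGeometry] = {}
        order: list[str] = []
        for feat in gj["features"]:
            name = feat["properties"]["name"]
            regions[name] = shapely.geometry.shape(feat["geometry"])
            order.append(name)
        return cls(regions, order)

    @classmethod
    def from_file(cls, path: str) -> "RegionSet":
        if str(path).endswith((".geojson", ".json")):
            return cls.from_geojson(path)
        return cls.from_wkt(path)
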