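"""Gridded-surface and vector-feature containers with text-based geospatial I/O.

A :class:`Raster` is a rectangular grid of values anchored at its upper-left
corner in a projected metric CRS, row-major, with half-open cells: the cell at
(row, col) covers ``[x0 + col*c, x0 + (col+1)*c) x (y0 - (row+1)*c, y0 - row*c]``
and its center sits at ``(x0 + (col+0.5)*c, y0 - (row+0.5)*c)``.  A
:class:`FeatureSet` holds shapely geometries plus per-feature attributes.

Rasters round-trip through the ESRI ASCII grid format (plain text) and feature
sets through GeoJSON, so every artifact the pipeline writes is human-readable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ValidationError

#: Default sentinel for missing cells.  Chosen far outside every physical
#: range used by the pipeline (pH, meters, persons/km2, 1-9 scores).
NODATA = -9999.0

#: Projected CRS the study layers are expressed in (WGS 84 / UTM zone 34S).
DEFAULT_CRS = "EPSG:32734"


@dataclass
class Raster:
    """Single-band grid with affine georeferencing on a projected CRS.

    Parameters
    ----------
    values:
        2-D array (float for continuous surfaces, integer codes allowed for
        categorical layers).  ``nodata`` marks missing cells.
    origin_x, origin_y:
        Projected coordinates (meters) of the grid's upper-left corner.
    cell_size_m:
        Square cell edge in meters; must be positive.
    nodata:
        Sentinel for missing data; never a valid value.
    crs_id:
        Identifier of the projected CRS (informational; no reprojection).
    categorical:
        True for class-coded layers (land cover); forbids interpolation.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size_m: float
    nodata: float = NODATA
    crs_id: str = DEFAULT_CRS
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be a 2-D array")
        if not self.cell_size_m > 0:
            raise ValidationError(f"cell_size_m must be positive, got {self.cell_size_m}")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid footprint in meters."""
        c = self.cell_size_m
        return (
            self.origin_x,
            self.origin_y - self.nrows * c,
            self.origin_x + self.ncols * c,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: (xs of length ncols, ys of length nrows)."""
        c = self.cell_size_m
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * c
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * c
        return xs, ys

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cell_size_m, other.cell_size_m, rel_tol=1e-12)
        )

    def with_values(self, values: np.ndarray, *, categorical: bool | None = None) -> "Raster":
        """New raster on the same grid carrying different values."""
        out = replace(self, values=np.asarray(values))
        if categorical is not None:
            out.categorical = categorical
        return out

    # -- I/O (ESRI ASCII grid) -------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        minx, miny, _, _ = self.bounds
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {minx!r}\n"
            f"yllcorner {miny!r}\n"
            f"cellsize {self.cell_size_m!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read_ascii(
        cls,
        path: str | Path,
        crs_id: str = DEFAULT_CRS,
        categorical: bool = False,
    ) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nrows = int(meta["nrows"])
        cell = meta["cellsize"]
        return cls(
            values=values,
            origin_x=meta["xllcorner"],
            origin_y=meta["yllcorner"] + nrows * cell,
            cell_size_m=cell,
            nodata=meta.get("nodata_value", NODATA),
            crs_id=crs_id,
            categorical=categorical,
        )


@dataclass
class FeatureSet:
    """Vector features (points/lines/polygons) with per-feature attributes."""

    geometries: list[BaseGeometry] = field(default_factory=list)
    attributes: list[dict[str, Any]] = field(default_factory=list)
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValidationError("attributes and geometries must align")
        for geom in self.geometries:
            if geom.geom_type in ("Polygon", "MultiPolygon") and not geom.is_valid:
                raise ValidationError("invalid polygon geometry (self-intersection?)")

    def __len__(self) -> int:
        return len(self.geometries)

    @property
    def is_empty(self) -> bool:
        return len(self.geometries) == 0

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.geometries)

    def total_area(self) -> float:
        return float(sum(g.area for g in self.geometries))

    def centroids(self) -> np.ndarray:
        """(n, 2) array of feature centroid coordinates."""
        return np.array([[g.centroid.x, g.centroid.y] for g in self.geometries])

    # -- I/O (GeoJSON) ----------------------------------------------------
    def write_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
            for geom, attrs in zip(self.geometries, self.attributes)
        ]
        doc = {
            "type": "FeatureCollection",
            "crs_id": self.crs_id,
            "features": features,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def read_geojson(cls, path: str | Path) -> "FeatureSet":
        doc = json.loads(Path(path).read_text())
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        attrs = [f.get("properties") or {} for f in doc["features"]]
        return cls(geometries=geoms, attributes=attrs, crs_id=doc.get("crs_id", DEFAULT_CRS))


def distances_to_features(
    xs: np.ndarray, ys: np.ndarray, features: FeatureSet
) -> np.ndarray:
    """Planar distance (m) from each (x, y) point to the nearest feature.

    ``xs``/``ys`` are broadcast together; points lying on or inside a feature
    get distance 0.
    """
    if features.is_empty:
        raise ValidationError("distance to an empty feature set is undefined")
    pts = shapely.points(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))
    geom = features.union()
    return shapely.distance(pts, geom)


def features_from_points(coords: Iterable[tuple[float, float]], crs_id: str = DEFAULT_CRS) -> FeatureSet:
    pts = [shapely.Point(x, y) for x, y in coords]
    return FeatureSet(geometries=pts, crs_id=crs_id)
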