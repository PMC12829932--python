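"""Raster/vector computational primitives.

Conventions (used consistently across the package):

* Cell membership is by **cell-center containment** in half-open cells with
  the origin at the grid's upper-left corner, row-major.  A polygon burns the
  cells whose centers it covers; lines and points (which almost never pass
  through a center exactly) burn the cells whose squares they intersect.
* All distances are planar Euclidean in the projected CRS (meters).
* Decision units are squares on two nested resolutions (fine, default 250 m,
  and coarse, default 1000 m) that tile the study extent exactly: a coarse
  unit is emitted only where the full coarse square qualifies, otherwise the
  square is decomposed into fine units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .errors import ValidationError
from .raster import DEFAULT_CRS, NODATA, FeatureSet, Raster, distances_to_features

Stat = Literal["mean", "max", "majority"]


# ---------------------------------------------------------------------------
# Rasterization and distance surfaces
# ---------------------------------------------------------------------------

def _center_grid(template: Raster) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = template.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    return gx, gy


def rasterize_features(
    features: FeatureSet,
    template: Raster,
    burn: float | str = 1.0,
    background: float | None = None,
) -> Raster:
    """Burn vector features onto the template grid.

    ``burn`` is either a constant or the name of a per-feature attribute.
    Cells not touched by any feature carry ``background`` (the template's
    nodata by default).
    """
    if features.crs_id != template.crs_id:
        raise ValidationError(
            f"CRS mismatch: features {features.crs_id} vs template {template.crs_id}"
        )
    bg = template.nodata if background is None else background
    out = np.full(template.shape, bg, dtype=float)
    if features.is_empty:
        import warnings

        warnings.warn("rasterizing an empty FeatureSet: all-background raster")
        return template.with_values(out)

    gx, gy = _center_grid(template)
    centers = shapely.points(gx.ravel(), gy.ravel())
    c = template.cell_size_m
    for geom, attrs in zip(features.geometries, features.attributes):
        value = float(attrs[burn]) if isinstance(burn, str) else float(burn)
        if geom.geom_type in ("Polygon", "MultiPolygon"):
            hit = shapely.covers(geom, centers).reshape(template.shape)
        else:
            # lines/points: a thin geometry intersects the cell square iff it
            # comes within half a cell diagonal... use exact box intersection
            # restricted to a bounding-box window for speed
            hit = np.zeros(template.shape, dtype=bool)
            minx, miny, maxx, maxy = geom.bounds
            xs, ys = template.cell_centers()
            cols = np.where((xs + c / 2 >= minx) & (xs - c / 2 <= maxx))[0]
            rows = np.where((ys + c / 2 >= miny) & (ys - c / 2 <= maxy))[0]
            if len(cols) and len(rows):
                sub_x, sub_y = np.meshgrid(xs[cols], ys[rows])
                boxes = shapely.box(
                    sub_x.ravel() - c / 2,
                    sub_y.ravel() - c / 2,
                    sub_x.ravel() + c / 2,
                    sub_y.ravel() + c / 2,
                )
                sub_hit = shapely.intersects(boxes, geom).reshape(len(rows), len(cols))
                hit[np.ix_(rows, cols)] = sub_hit
        out[hit] = value
    return template.with_values(out)


def euclidean_distance_surface(features: FeatureSet, template: Raster) -> Raster:
    """Distance (m) from every cell center to the nearest feature."""
    if features.is_empty:
        raise ValidationError("distance surface undefined for an empty FeatureSet")
    if features.crs_id != template.crs_id:
        raise ValidationError("CRS mismatch between features and template")
    gx, gy = _center_grid(template)
    dist = distances_to_features(gx.ravel(), gy.ravel(), features)
    return template.with_values(dist.reshape(template.shape))


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def slope_from_dem(dem: Raster) -> Raster:
    """Per-cell slope in degrees from finite differences on the DEM.

    Central differences at interior cells, one-sided at the border; a cell
    becomes nodata if it, or any neighbor its difference stencil reads, is
    nodata.
    """
    if dem.nrows < 2 or dem.ncols < 2:
        raise ValidationError("slope requires a grid of at least 2x2 cells")
    z = dem.values.astype(float)
    invalid = ~dem.mask()
    zf = np.where(invalid, np.nan, z)
    dzdy, dzdx = np.gradient(zf, dem.cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # nodata propagates to every cell whose stencil saw a nodata neighbor
    # (central differences skip the cell itself, so include it explicitly)
    bad = np.isnan(slope) | invalid
    slope = np.where(bad, dem.nodata, slope)
    return dem.with_values(slope)


# ---------------------------------------------------------------------------
# Grid harmonization
# ---------------------------------------------------------------------------

def align_to_grid(
    src: Raster,
    template: Raster,
    mode: Literal["nearest", "bilinear"] = "nearest",
) -> Raster:
    """Resample ``src`` onto the template grid.

    Categorical layers must use nearest-neighbor; bilinear never blends
    nodata into valid cells (such cells fall back to the nearest valid
    sample, or nodata when none exists).
    """
    if mode not in ("nearest", "bilinear"):
        raise ValidationError(f"unknown resampling mode {mode!r}")
    if mode == "bilinear" and src.categorical:
        raise ValidationError("bilinear resampling is not allowed for categorical layers")

    xs, ys = template.cell_centers()
    # fractional index of each template center in src's array coordinates
    cols = (xs - src.origin_x) / src.cell_size_m - 0.5
    rows = (src.origin_y - ys) / src.cell_size_m - 0.5
    ci, ri = np.meshgrid(cols, rows)
    coords = np.array([ri.ravel(), ci.ravel()])

    valid = src.mask().astype(float)
    nearest = ndimage.map_coordinates(
        src.values.astype(float), coords, order=0, mode="nearest"
    )
    nearest_valid = ndimage.map_coordinates(valid, coords, order=0, mode="nearest")
    inside = (
        (ri.ravel() >= -0.5)
        & (ri.ravel() <= src.nrows - 0.5)
        & (ci.ravel() >= -0.5)
        & (ci.ravel() <= src.ncols - 0.5)
    )

    if mode == "nearest":
        out = np.where(inside & (nearest_valid > 0.5), nearest, template.nodata)
    else:
        filled = np.where(valid > 0, src.values, 0.0).astype(float)
        interp = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
        wsum = ndimage.map_coordinates(valid, coords, order=1, mode="nearest")
        clean = wsum >= 1.0 - 1e-9  # stencil saw no nodata
        out = np.where(clean, interp, nearest)
        out = np.where(inside & (nearest_valid > 0.5), out, template.nodata)
    result = template.with_values(out.reshape(template.shape))
    result.categorical = src.categorical
    result.nodata = template.nodata
    return result


# ---------------------------------------------------------------------------
# Decision units
# ---------------------------------------------------------------------------

CORE_COLUMNS = ["uid", "res_class", "row0", "col0", "size", "cx", "cy", "area_km2"]


@dataclass
class DecisionUnitGrid:
    """Multi-resolution square tessellation carrying per-unit score columns.

    ``df`` holds one row per unit: grid indices (``row0``, ``col0`` in fine
    cells, ``size`` fine cells per edge), the centroid, the polygon area and
    any number of score columns added by zonal aggregation or criterion
    evaluation.
    """

    df: pd.DataFrame
    origin_x: float
    origin_y: float
    fine_m: float
    crs_id: str = DEFAULT_CRS
    nodata: float = NODATA

    @property
    def n_units(self) -> int:
        return len(self.df)

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    def copy(self) -> "DecisionUnitGrid":
        return DecisionUnitGrid(
            self.df.copy(), self.origin_x, self.origin_y, self.fine_m, self.crs_id, self.nodata
        )

    def with_score(self, name: str, values: np.ndarray) -> "DecisionUnitGrid":
        out = self.copy()
        out.df[name] = np.asarray(values, dtype=float)
        return out

    def scores(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def geometries(self) -> list[shapely.Polygon]:
        c = self.fine_m
        geoms = []
        for row in self.df.itertuples():
            x0 = self.origin_x + row.col0 * c
            y0 = self.origin_y - row.row0 * c
            edge = row.size * c
            geoms.append(shapely.box(x0, y0 - edge, x0 + edge, y0))
        return geoms

    def total_area_km2(self) -> float:
        return float(self.df["area_km2"].sum())

    def template_raster(self) -> Raster:
        """Fine-resolution template raster spanning the tessellated extent."""
        nrows = int((self.df["row0"] + self.df["size"]).max())
        ncols = int((self.df["col0"] + self.df["size"]).max())
        return Raster(
            values=np.full((nrows, ncols), self.nodata),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size_m=self.fine_m,
            nodata=self.nodata,
            crs_id=self.crs_id,
        )

    def write_geojson(self, path: str | Path) -> None:
        fs = FeatureSet(
            geometries=self.geometries(),
            attributes=[
                {k: (None if pd.isna(v) else v) for k, v in rec.items()}
                for rec in self.df.to_dict("records")
            ],
            crs_id=self.crs_id,
        )
        fs.write_geojson(path)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        origin_x: float,
        origin_y: float,
        fine_m: float,
        crs_id: str = DEFAULT_CRS,
    ) -> "DecisionUnitGrid":
        df = pd.read_csv(path)
        return cls(df, origin_x, origin_y, fine_m, crs_id)


def build_decision_units(
    extent: tuple[float, float, float, float],
    developed: FeatureSet,
    protected: FeatureSet,
    fine_m: float = 250.0,
    coarse_m: float = 1000.0,
    developed_buffer_m: float = 2000.0,
) -> DecisionUnitGrid:
    """Tile the extent with fine squares, merging to coarse inside protected
    zones away from development.

    A coarse unit is emitted only where **every** fine cell of the coarse
    square lies inside a protected polygon and **no** fine cell center is
    within ``developed_buffer_m`` of a developed feature; any other coarse
    square is decomposed into fine units.  The result partitions the extent
    exactly.
    """
    minx, miny, maxx, maxy = extent
    if not (maxx > minx and maxy > miny):
        raise ValidationError("extent must have positive area")
    ratio = coarse_m / fine_m
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(f"fine_m={fine_m} must divide coarse_m={coarse_m}")
    ratio = int(round(ratio))

    ncols = int(round((maxx - minx) / fine_m))
    nrows = int(round((maxy - miny) / fine_m))
    if ncols < 1 or nrows < 1:
        raise ValidationError("extent smaller than one fine cell")

    xs = minx + (np.arange(ncols) + 0.5) * fine_m
    ys = maxy - (np.arange(nrows) + 0.5) * fine_m
    gx, gy = np.meshgrid(xs, ys)

    if protected.is_empty:
        in_prot = np.zeros((nrows, ncols), dtype=bool)
    else:
        pts = shapely.points(gx.ravel(), gy.ravel())
        in_prot = shapely.covers(protected.union(), pts).reshape(nrows, ncols)

    if developed.is_empty:
        near_dev = np.zeros((nrows, ncols), dtype=bool)
    else:
        d = distances_to_features(gx.ravel(), gy.ravel(), developed)
        near_dev = (d.reshape(nrows, ncols) <= developed_buffer_m)

    coarse_ok = in_prot & ~near_dev

    records: list[tuple] = []
    fine_km2 = (fine_m / 1000.0) ** 2
    coarse_km2 = (coarse_m / 1000.0) ** 2
    taken = np.zeros((nrows, ncols), dtype=bool)
    uid = 0
    for br in range(0, nrows - nrows % ratio, ratio):
        for bc in range(0, ncols - ncols % ratio, ratio):
            block = coarse_ok[br : br + ratio, bc : bc + ratio]
            if block.all():
                cx = minx + (bc + ratio / 2) * fine_m
                cy = maxy - (br + ratio / 2) * fine_m
                records.append((uid, "coarse", br, bc, ratio, cx, cy, coarse_km2))
                uid += 1
                taken[br : br + ratio, bc : bc + ratio] = True
    rows_left, cols_left = np.where(~taken)
    for r, c in zip(rows_left, cols_left):
        records.append(
            (int(uid), "fine", int(r), int(c), 1, float(xs[c]), float(ys[r]), fine_km2)
        )
        uid += 1

    df = pd.DataFrame(records, columns=CORE_COLUMNS)
    return DecisionUnitGrid(df, origin_x=minx, origin_y=maxy, fine_m=fine_m)


def zonal_aggregate(
    raster: Raster,
    units: DecisionUnitGrid,
    stat: Stat = "mean",
    name: str | None = None,
) -> DecisionUnitGrid:
    """Aggregate raster cells (by center containment) into each unit.

    The raster must already sit on the units' fine grid (use
    :func:`align_to_grid` first if it does not).  Units covering only nodata
    cells get nodata.
    """
    if stat not in ("mean", "max", "majority"):
        raise ValidationError(f"unknown zonal statistic {stat!r}")
    tmpl = units.template_raster()
    if not raster.same_grid(tmpl):
        raise ValidationError(
            "raster grid does not match the decision-unit fine grid; align first"
        )
    vals = raster.values.astype(float)
    valid = raster.mask()
    if not valid.any():
        raise ValidationError("raster has no valid cells over the units' extent")

    out = np.full(units.n_units, units.nodata, dtype=float)
    r0 = units.df["row0"].to_numpy()
    c0 = units.df["col0"].to_numpy()
    size = units.df["size"].to_numpy()

    # fine units: one cell each, fully vectorized
    fine = size == 1
    fv = vals[r0[fine], c0[fine]]
    fm = valid[r0[fine], c0[fine]]
    out[np.where(fine)[0][fm]] = fv[fm]

    for i in np.where(~fine)[0]:
        r, c, s = r0[i], c0[i], size[i]
        block = vals[r : r + s, c : c + s]
        bmask = valid[r : r + s, c : c + s]
        if not bmask.any():
            continue
        data = block[bmask]
        if stat == "mean":
            out[i] = data.mean()
        elif stat == "max":
            out[i] = data.max()
        else:
            codes, counts = np.unique(data, return_counts=True)
            out[i] = codes[np.argmax(counts)]

    col = name or "zonal"
    return units.with_score(col, out)
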