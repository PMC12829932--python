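"""Seeded synthetic landscape scenes for end-to-end pipeline testing.

The generator emulates the layer inventory a district-scale land-use
conflict study consumes: smooth autocorrelated environmental fields (soils,
elevation, habitat suitability), a categorical land-cover map consistent
with the vector features, road corridors with settlements and farms
clustered along them, point water sources, and large protected-area
polygons.  One global seed drives a fixed per-layer seed sequence, so adding
a layer never perturbs existing layers and identical configs reproduce
bit-identical scenes.

``farm_wildlife_overlap`` is the key ecological knob: the fraction of farm
centroids deliberately placed inside the top tercile of the combined
wildlife-habitat surface.  It operationalizes agricultural expansion into a
wildlife corridor — the mechanism that generates human-wildlife conflict
downstream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import shapely
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, box

from .errors import ValidationError
from .raster import DEFAULT_CRS, NODATA, FeatureSet, Raster, distances_to_features

#: Species with individual habitat-suitability surfaces (the large predators
#: and the dominant crop-raiding herbivore of northern-Botswana systems).
SPECIES = ("elephant", "lion", "leopard", "spotted_hyaena")

#: Fixed per-layer seed offsets (never reorder: scene reproducibility).
_LAYER_SEEDS = {
    "dem": 1,
    "soil_ph": 2,
    "root_zone_depth": 3,
    "drainage": 4,
    "habitat": 5,  # +index of species
    "roads": 20,
    "protected_areas": 21,
    "settlements": 22,
    "farms": 23,
    "cattle_posts": 24,
    "boreholes": 25,
    "population_density": 26,
    "lulc": 27,
}


@dataclass
class LandscapeConfig:
    """Parameters of a synthetic scene.

    The defaults describe a 50 x 50 km study window at 250 m resolution —
    the working scale of the analysis — with a handful of road corridors,
    tens of farms and cattle posts, and roughly a third of the extent under
    protection, mirroring a frontier agricultural district abutting
    conservation land.
    """

    extent: tuple[float, float, float, float] = (350_000.0, 7_950_000.0, 400_000.0, 8_000_000.0)
    cell_size_m: float = 250.0
    seed: int = 0
    n_roads: int = 4
    n_settlements: int = 8
    n_farms: int = 40
    n_boreholes: int = 25
    n_cattle_posts: int = 15
    protected_fraction: float = 0.30
    field_range_m: float = 5_000.0
    farm_wildlife_overlap: float = 0.6
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        minx, miny, maxx, maxy = self.extent
        if not (maxx > minx and maxy > miny):
            raise ValidationError("extent must have positive area")
        if self.cell_size_m <= 0:
            raise ValidationError("cell_size_m must be positive")
        for edge in (maxx - minx, maxy - miny):
            n = edge / self.cell_size_m
            if abs(n - round(n)) * self.cell_size_m > self.cell_size_m:
                raise ValidationError("cell_size_m must divide extent edges within one cell")
        if not 0.0 <= self.protected_fraction <= 1.0:
            raise ValidationError("protected_fraction must be in [0, 1]")
        if not 0.0 <= self.farm_wildlife_overlap <= 1.0:
            raise ValidationError("farm_wildlife_overlap must be in [0, 1]")
        if self.field_range_m <= 0:
            raise ValidationError("field_range_m must be positive")
        for name in ("n_roads", "n_settlements", "n_farms", "n_boreholes", "n_cattle_posts"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        minx, miny, maxx, maxy = self.extent
        return (
            int(round((maxy - miny) / self.cell_size_m)),
            int(round((maxx - minx) / self.cell_size_m)),
        )

    def template(self) -> Raster:
        nrows, ncols = self.shape
        return Raster(
            values=np.full((nrows, ncols), NODATA),
            origin_x=self.extent[0],
            origin_y=self.extent[3],
            cell_size_m=self.cell_size_m,
            crs_id=self.crs_id,
        )

    def layer_rng(self, layer: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _LAYER_SEEDS[layer] + extra])
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = list(self.extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        if "extent" in d:
            d["extent"] = tuple(float(v) for v in d["extent"])
        return cls(**d)


@dataclass
class SyntheticScene:
    """Named raster and vector layers sharing one grid and CRS."""

    rasters: dict[str, Raster]
    vectors: dict[str, FeatureSet]
    config: LandscapeConfig

    def combined_habitat(self, stat: str = "mean") -> Raster:
        """Multi-species habitat surface (cell statistic over species layers)."""
        layers = [self.rasters[f"habitat_{sp}"] for sp in SPECIES if f"habitat_{sp}" in self.rasters]
        if not layers:
            raise ValidationError("scene has no habitat_* rasters")
        stack = np.stack([r.values for r in layers])
        combined = stack.max(axis=0) if stat == "max" else stack.mean(axis=0)
        return layers[0].with_values(combined)

    def validate(self) -> None:
        tmpl = next(iter(self.rasters.values()))
        for name, r in self.rasters.items():
            if not r.same_grid(tmpl):
                raise ValidationError(f"raster {name!r} is not on the shared grid")
        minx, miny, maxx, maxy = self.config.extent
        frame = box(minx - 1e-6, miny - 1e-6, maxx + 1e-6, maxy + 1e-6)
        for name, fs in self.vectors.items():
            for g in fs.geometries:
                if not frame.covers(g):
                    raise ValidationError(f"geometry in layer {name!r} exceeds the extent")
        prot = self.vectors["protected_areas"]
        realized = prot.total_area() / ((maxx - minx) * (maxy - miny))
        if abs(realized - self.config.protected_fraction) > 0.05:
            raise ValidationError(
                f"protected fraction realized {realized:.3f} deviates from "
                f"requested {self.config.protected_fraction:.3f} by more than 0.05"
            )

    # -- persistence ------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "rasters").mkdir(parents=True, exist_ok=True)
        (directory / "vectors").mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "crs_id": self.config.crs_id,
            "config": self.config.to_dict(),
            "rasters": {},
            "vectors": {},
        }
        for name, r in sorted(self.rasters.items()):
            rel = f"rasters/{name}.asc"
            r.write_ascii(directory / rel)
            manifest["rasters"][name] = {"path": rel, "categorical": r.categorical}
        for name, fs in sorted(self.vectors.items()):
            rel = f"vectors/{name}.geojson"
            fs.write_geojson(directory / rel)
            manifest["vectors"][name] = {"path": rel}
        (directory / "scene.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    @classmethod
    def read(cls, directory: str | Path) -> "SyntheticScene":
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "scene.yaml").read_text())
        config = LandscapeConfig.from_dict(manifest["config"])
        rasters = {
            name: Raster.read_ascii(
                directory / meta["path"],
                crs_id=manifest["crs_id"],
                categorical=meta.get("categorical", False),
            )
            for name, meta in manifest["rasters"].items()
        }
        vectors = {
            name: FeatureSet.read_geojson(directory / meta["path"])
            for name, meta in manifest["vectors"].items()
        }
        return cls(rasters=rasters, vectors=vectors, config=config)


# ---------------------------------------------------------------------------
# Random fields
# ---------------------------------------------------------------------------

def generate_random_field(
    config: LandscapeConfig,
    mean: float,
    sd: float,
    range_m: float | None = None,
    rng: np.random.Generator | None = None,
) -> Raster:
    """Spatially autocorrelated Gaussian random field on the config grid.

    White noise is smoothed with a Gaussian kernel whose bandwidth derives
    from the correlation range (sigma = range/2 in map units), then
    affine-rescaled to the exact requested mean and standard deviation.
    Correlation decays to near zero beyond about three range lengths.
    """
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    range_m = config.field_range_m if range_m is None else range_m
    if range_m <= 0:
        raise ValidationError("range_m must be positive")
    tmpl = config.template()
    if sd == 0:
        return tmpl.with_values(np.full(tmpl.shape, float(mean)))
    rng = rng or np.random.default_rng(int(config.seed))
    noise = rng.standard_normal(tmpl.shape)
    sigma_cells = (range_m / 2.0) / config.cell_size_m
    smooth = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    s = smooth.std()
    if s == 0:  # pathological (tiny grid, huge kernel): fall back to raw noise
        smooth, s = noise, noise.std()
    values = (smooth - smooth.mean()) / s * sd + mean
    return tmpl.with_values(values)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def _random_crossing_path(
    rng: np.random.Generator, extent: tuple[float, float, float, float]
) -> LineString:
    """Piecewise-linear path entering and leaving on opposite extent edges."""
    minx, miny, maxx, maxy = extent
    w, h = maxx - minx, maxy - miny
    if rng.random() < 0.5:  # west-east
        p0 = (minx, miny + rng.random() * h)
        p1 = (maxx, miny + rng.random() * h)
    else:  # south-north
        p0 = (minx + rng.random() * w, miny)
        p1 = (minx + rng.random() * w, maxy)
    ts = np.sort(rng.uniform(0.15, 0.85, size=3))
    jitter = min(w, h) * 0.08
    mids = [
        (
            float(np.clip(p0[0] + t * (p1[0] - p0[0]) + rng.normal(0, jitter), minx, maxx)),
            float(np.clip(p0[1] + t * (p1[1] - p0[1]) + rng.normal(0, jitter), miny, maxy)),
        )
        for t in ts
    ]
    return LineString([p0, *mids, p1])


def _clamp_point(x, y, extent, margin):
    minx, miny, maxx, maxy = extent
    return (
        float(np.clip(x, minx + margin, maxx - margin)),
        float(np.clip(y, miny + margin, maxy - margin)),
    )


def generate_scene(config: LandscapeConfig) -> SyntheticScene:
    """Build a full synthetic scene (all rasters and vector layers)."""
    nrows, ncols = config.shape
    n_cells = nrows * ncols
    n_points = config.n_settlements + config.n_farms + config.n_boreholes + config.n_cattle_posts
    if n_points > n_cells:
        raise ValidationError(
            f"extent of {n_cells} cells is too small for {n_points} requested features"
        )
    extent = config.extent
    minx, miny, maxx, maxy = extent
    w, h = maxx - minx, maxy - miny
    tmpl = config.template()
    crs = config.crs_id

    rasters: dict[str, Raster] = {}
    rasters["dem"] = generate_random_field(config, 1000.0, 15.0, rng=config.layer_rng("dem"))
    rasters["soil_ph"] = generate_random_field(config, 6.5, 0.7, rng=config.layer_rng("soil_ph"))
    rasters["root_zone_depth"] = generate_random_field(
        config, 80.0, 25.0, rng=config.layer_rng("root_zone_depth")
    )
    rasters["drainage"] = generate_random_field(config, 3.0, 1.0, rng=config.layer_rng("drainage"))
    for i, sp in enumerate(SPECIES):
        f = generate_random_field(
            config, 0.5, 0.2, range_m=2 * config.field_range_m, rng=config.layer_rng("habitat", i)
        )
        rasters[f"habitat_{sp}"] = f.with_values(np.clip(f.values, 0.0, 1.0))

    # roads -----------------------------------------------------------------
    rng = config.layer_rng("roads")
    roads = FeatureSet(
        geometries=[_random_crossing_path(rng, extent) for _ in range(config.n_roads)],
        crs_id=crs,
    )

    # protected areas: one side strip with exact requested area --------------
    rng = config.layer_rng("protected_areas")
    prot_geoms = []
    if config.protected_fraction > 0:
        side = rng.integers(0, 4)
        frac = config.protected_fraction
        if side == 0:
            prot_geoms = [box(maxx - frac * w, miny, maxx, maxy)]
        elif side == 1:
            prot_geoms = [box(minx, miny, minx + frac * w, maxy)]
        elif side == 2:
            prot_geoms = [box(minx, maxy - frac * h, maxx, maxy)]
        else:
            prot_geoms = [box(minx, miny, maxx, miny + frac * h)]
    protected = FeatureSet(geometries=prot_geoms, crs_id=crs)

    # settlements: at road vertices, jittered --------------------------------
    rng = config.layer_rng("settlements")
    margin = config.cell_size_m
    settle_pts = []
    road_vertices = [
        (x, y) for g in roads.geometries for x, y in list(g.coords)[1:-1]
    ]
    for _ in range(config.n_settlements):
        if road_vertices:
            vx, vy = road_vertices[rng.integers(0, len(road_vertices))]
            x, y = vx + rng.normal(0, 1000.0), vy + rng.normal(0, 1000.0)
        else:
            x, y = minx + rng.random() * w, miny + rng.random() * h
        settle_pts.append(Point(*_clamp_point(x, y, extent, margin)))
    settlements = FeatureSet(geometries=settle_pts, crs_id=crs)

    # farms: overlap fraction sited in top-tercile habitat, near roads -------
    rng = config.layer_rng("farms")
    habitat = SyntheticScene(rasters=rasters, vectors={}, config=config).combined_habitat()
    hv = habitat.values
    tercile = np.quantile(hv, 2.0 / 3.0)
    xs, ys = tmpl.cell_centers()
    farm_edge = 1000.0  # 1 km commercial-farm blocks
    top_rows, top_cols = np.where(hv >= tercile)
    # keep only cells where a farm block fits without clamping the centroid
    interior = (
        (xs[top_cols] >= minx + farm_edge / 2)
        & (xs[top_cols] <= maxx - farm_edge / 2)
        & (ys[top_rows] >= miny + farm_edge / 2)
        & (ys[top_rows] <= maxy - farm_edge / 2)
    )
    if interior.any():
        top_rows, top_cols = top_rows[interior], top_cols[interior]
    n_in = int(round(config.farm_wildlife_overlap * config.n_farms))
    farm_geoms = []
    for i in range(config.n_farms):
        if i < n_in and len(top_rows):
            # pick, among candidate high-habitat cells, the one closest to a road
            k = min(12, len(top_rows))
            cand = rng.choice(len(top_rows), size=k, replace=False)
            cx = xs[top_cols[cand]]
            cy = ys[top_rows[cand]]
            if not roads.is_empty:
                d = distances_to_features(cx, cy, roads)
                j = int(np.argmin(d))
            else:
                j = 0
            x, y = float(cx[j]), float(cy[j])
        elif not roads.is_empty:
            # random point along a road, pushed aside a little
            g = roads.geometries[rng.integers(0, len(roads.geometries))]
            p = g.interpolate(rng.random(), normalized=True)
            x, y = p.x + rng.normal(0, 1500.0), p.y + rng.normal(0, 1500.0)
        else:
            x, y = minx + rng.random() * w, miny + rng.random() * h
        x, y = _clamp_point(x, y, extent, farm_edge / 2)
        farm_geoms.append(box(x - farm_edge / 2, y - farm_edge / 2, x + farm_edge / 2, y + farm_edge / 2))
    farms = FeatureSet(geometries=farm_geoms, crs_id=crs)

    # cattle posts: near farms (or roads when no farms) ----------------------
    rng = config.layer_rng("cattle_posts")
    post_pts = []
    for _ in range(config.n_cattle_posts):
        if not farms.is_empty:
            g = farms.geometries[rng.integers(0, len(farms.geometries))]
            x, y = g.centroid.x + rng.normal(0, 2500.0), g.centroid.y + rng.normal(0, 2500.0)
        elif not roads.is_empty:
            g = roads.geometries[rng.integers(0, len(roads.geometries))]
            p = g.interpolate(rng.random(), normalized=True)
            x, y = p.x + rng.normal(0, 2500.0), p.y + rng.normal(0, 2500.0)
        else:
            x, y = minx + rng.random() * w, miny + rng.random() * h
        post_pts.append(Point(*_clamp_point(x, y, extent, margin)))
    cattle_posts = FeatureSet(geometries=post_pts, crs_id=crs)

    # boreholes: half near settlements/farms, half dispersed -----------------
    rng = config.layer_rng("boreholes")
    anchors = settle_pts + [g.centroid for g in farm_geoms]
    bore_pts = []
    for i in range(config.n_boreholes):
        if anchors and i % 2 == 0:
            a = anchors[rng.integers(0, len(anchors))]
            x, y = a.x + rng.normal(0, 2000.0), a.y + rng.normal(0, 2000.0)
        else:
            x, y = minx + rng.random() * w, miny + rng.random() * h
        bore_pts.append(Point(*_clamp_point(x, y, extent, margin)))
    boreholes = FeatureSet(geometries=bore_pts, crs_id=crs)

    # population density: decays away from settlements -----------------------
    rng = config.layer_rng("population_density")
    xs_g, ys_g = np.meshgrid(xs, ys)
    if settlements.is_empty:
        pop = np.zeros(tmpl.shape)
    else:
        d = distances_to_features(xs_g.ravel(), ys_g.ravel(), settlements).reshape(tmpl.shape)
        pop = 500.0 * np.exp(-d / 2000.0)
    pop = pop + np.abs(rng.normal(0, 0.5, size=tmpl.shape))
    rasters["population_density"] = tmpl.with_values(pop)

    # land cover: thresholded field + overrides where farms/settlements sit --
    lulc_field = generate_random_field(config, 0.0, 1.0, rng=config.layer_rng("lulc"))
    qs = np.quantile(lulc_field.values, [0.35, 0.65, 0.9])
    lulc = np.digitize(lulc_field.values, qs) + 1.0  # 1 grass, 2 shrub, 3 wood, 4 bare
    from .geoprimitives import rasterize_features  # local import avoids a cycle

    if not farms.is_empty:
        burned = rasterize_features(farms, tmpl, burn=5.0, background=0.0)  # cropland
        lulc = np.where(burned.values == 5.0, 5.0, lulc)
    if not settlements.is_empty:
        town = FeatureSet([g.buffer(500.0) for g in settle_pts], crs_id=crs)
        burned = rasterize_features(town, tmpl, burn=6.0, background=0.0)  # built-up
        lulc = np.where(burned.values == 6.0, 6.0, lulc)
    rasters["lulc"] = tmpl.with_values(lulc, categorical=True)

    vectors = {
        "roads": roads,
        "settlements": settlements,
        "farms": farms,
        "cattle_posts": cattle_posts,
        "boreholes": boreholes,
        "protected_areas": protected,
    }
    scene = SyntheticScene(rasters=rasters, vectors=vectors, config=config)
    scene.validate()
    return scene
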