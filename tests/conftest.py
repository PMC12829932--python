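"""Shared fixtures: small seeded scenes and a deterministic toy landscape."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from lucis import (
    FeatureSet,
    LandscapeConfig,
    SyntheticScene,
    build_decision_units,
    generate_scene,
)
from lucis.synthetic import SPECIES


SMALL_KW = dict(
    extent=(0.0, 0.0, 20_000.0, 20_000.0),
    cell_size_m=250.0,
    n_roads=3,
    n_settlements=5,
    n_farms=15,
    n_boreholes=10,
    n_cattle_posts=6,
    protected_fraction=0.25,
    field_range_m=3_000.0,
    farm_wildlife_overlap=0.6,
)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(seed=7, **SMALL_KW)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def small_units(small_scene):
    scene = small_scene
    developed = FeatureSet(
        scene.vectors["settlements"].geometries + scene.vectors["farms"].geometries
    )
    return build_decision_units(
        scene.config.extent,
        developed=developed,
        protected=scene.vectors["protected_areas"],
        developed_buffer_m=2_000.0,
    )


def make_toy_scene() -> SyntheticScene:
    """Deterministic 60x60-cell landscape with a built-in east-west contrast.

    Wildlife habitat rises eastward; all farms and cattle posts sit in the
    high-habitat east; the road, settlements and boreholes sit in the west.
    Gives a known, hand-analyzable geometry for directional checks.
    """
    cfg = LandscapeConfig(
        extent=(0.0, 0.0, 15_000.0, 15_000.0),
        cell_size_m=250.0,
        seed=0,
        n_roads=1,
        n_settlements=2,
        n_farms=6,
        n_boreholes=3,
        n_cattle_posts=3,
        protected_fraction=0.1,
        field_range_m=2_000.0,
        farm_wildlife_overlap=1.0,
    )
    tmpl = cfg.template()
    xs, ys = tmpl.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    grad_e = gx / 15_000.0
    grad_n = gy / 15_000.0
    rasters = {f"habitat_{sp}": tmpl.with_values(grad_e) for sp in SPECIES}
    rasters["dem"] = tmpl.with_values(1000.0 + 5.0 * grad_n)
    rasters["soil_ph"] = tmpl.with_values(6.0 + grad_n)
    rasters["root_zone_depth"] = tmpl.with_values(60.0 + 30.0 * grad_n)
    rasters["drainage"] = tmpl.with_values(2.0 + grad_n)
    rasters["population_density"] = tmpl.with_values(100.0 * np.exp(-gx / 3000.0))
    rasters["lulc"] = tmpl.with_values(np.ones(tmpl.shape), categorical=True)
    vectors = {
        "roads": FeatureSet([LineString([(3000.0, 0.0), (3000.0, 15_000.0)])]),
        "settlements": FeatureSet([Point(3000, 5000), Point(3000, 10_000)]),
        "farms": FeatureSet(
            [
                box(11_000 + 500 * i, 2000 + 1800 * i, 12_000 + 500 * i, 3000 + 1800 * i)
                for i in range(6)
            ]
        ),
        "cattle_posts": FeatureSet(
            [Point(12_000, 3000), Point(12_500, 8000), Point(13_000, 12_000)]
        ),
        "boreholes": FeatureSet(
            [Point(2500, 4000), Point(3500, 9000), Point(2800, 13_000)]
        ),
        "protected_areas": FeatureSet([box(0, 13_500, 15_000, 15_000)]),
    }
    return SyntheticScene(rasters=rasters, vectors=vectors, config=cfg)


@pytest.fixture(scope="session")
def toy_scene():
    scene = make_toy_scene()
    scene.validate()
    return scene


@pytest.fixture(scope="session")
def toy_units(toy_scene):
    scene = toy_scene
    developed = FeatureSet(
        scene.vectors["settlements"].geometries + scene.vectors["farms"].geometries
    )
    return build_decision_units(
        scene.config.extent,
        developed=developed,
        protected=scene.vectors["protected_areas"],
        developed_buffer_m=2_000.0,
    )
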