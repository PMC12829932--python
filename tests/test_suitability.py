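"""Suitability pipeline: criterion evaluation and hierarchy aggregation."""

import numpy as np
import pytest
from shapely.geometry import Point, box

from lucis import (
    CriterionSpec,
    FeatureSet,
    HierarchyNode,
    ValidationError,
    build_decision_units,
    build_goal_suitability,
    evaluate_criterion,
    evaluate_hierarchy,
    load_hierarchies,
    zonal_aggregate,
)
from lucis.mce import rescale_linear_1_9_array
from lucis.synthetic import SPECIES, LandscapeConfig, SyntheticScene

NODATA = -9999.0


def leaf(name, weight, layer="x", transform="identity", **params):
    crit = CriterionSpec(
        name=name, source_layer=layer, transform=transform,
        transform_params=params.pop("transform_params", {}),
        invert=params.pop("invert", False),
    )
    return HierarchyNode(name=name, weight=weight, criterion=crit)


# ---------------------------------------------------------------------------
# Default hierarchies encode the printed weight tables
# ---------------------------------------------------------------------------

def weights_of(node):
    return {c.name: round(c.weight, 2) for c in node.children}


class TestDefaultHierarchies:
    def test_agriculture_goal_split(self):
        ag = load_hierarchies()["agriculture"]
        assert weights_of(ag) == {"crop_farming": 0.7, "livestock": 0.3}

    def test_crop_farming_tree(self):
        ag = load_hierarchies()["agriculture"]
        crop = next(c for c in ag.children if c.name == "crop_farming")
        assert weights_of(crop) == {"physical": 0.60, "economic": 0.40}
        phys = next(c for c in crop.children if c.name == "physical")
        assert weights_of(phys) == {
            "existing_farms": 0.30,
            "soil_condition": 0.20,
            "terrain_characteristics": 0.20,
            "development_constraints": 0.30,
        }
        econ = next(c for c in crop.children if c.name == "economic")
        assert weights_of(econ) == {
            "transport_accessibility": 0.25,
            "water_proximity": 0.25,
            "market_accessibility": 0.25,
            "distance_to_crop_farms": 0.25,
        }

    def test_livestock_tree(self):
        ag = load_hierarchies()["agriculture"]
        ls = next(c for c in ag.children if c.name == "livestock")
        assert weights_of(ls) == {
            "physical": 0.40,
            "economic": 0.30,
            "wildlife_condition": 0.30,
        }
        phys = next(c for c in ls.children if c.name == "physical")
        assert weights_of(phys) == {
            "existing_livestock_location": 0.40,
            "terrain_characteristics": 0.30,
            "development_constraints": 0.30,
        }
        econ = next(c for c in ls.children if c.name == "economic")
        assert weights_of(econ) == {
            "transport_accessibility": 0.33,
            "water_accessibility": 0.34,
            "livestock_buffer": 0.33,
        }
        wc = next(c for c in ls.children if c.name == "wildlife_condition")
        assert weights_of(wc) == {
            "elephant_habitat": 0.10,
            "lion_habitat": 0.50,
            "leopard_habitat": 0.20,
            "spotted_hyaena_habitat": 0.20,
        }

    def test_livestock_buffer_is_300m(self):
        ag = load_hierarchies()["agriculture"]
        buf = ag.find("livestock_buffer")[0]
        assert buf.criterion.transform == "buffer_exclusion"
        assert buf.criterion.transform_params["buffer_m"] == 300.0

    def test_settlement_tree(self):
        hs = load_hierarchies()["settlement"]
        assert weights_of(hs) == {"physical": 0.50, "economic": 0.50}
        phys = next(c for c in hs.children if c.name == "physical")
        assert weights_of(phys) == {
            "population_density": 0.40,
            "terrain_characteristics": 0.30,
            "development_constraints": 0.30,
        }
        econ = next(c for c in hs.children if c.name == "economic")
        assert weights_of(econ) == {
            "road_accessibility": 0.50,
            "distance_to_settlement": 0.50,
        }

    def test_all_trees_validate(self):
        for tree in load_hierarchies().values():
            tree.validate()


# ---------------------------------------------------------------------------
# Hierarchy aggregation arithmetic
# ---------------------------------------------------------------------------

class TestEvaluateHierarchy:
    def test_settlement_economic_hand_wlc(self):
        node = HierarchyNode(
            name="economic",
            children=[leaf("road_accessibility", 0.50), leaf("distance_to_settlement", 0.50)],
        )
        scores = {
            "economic/road_accessibility": np.array([9.0]),
            "economic/distance_to_settlement": np.array([5.0]),
        }
        out = evaluate_hierarchy(node, scores, NODATA)
        assert out[0] == pytest.approx(7.0)

    def test_single_child_passthrough(self):
        node = HierarchyNode(name="top", children=[leaf("only", 1.0)])
        out = evaluate_hierarchy(node, {"top/only": np.array([3.3, 8.8])}, NODATA)
        np.testing.assert_allclose(out, [3.3, 8.8])

    def test_agriculture_goal_split_arithmetic(self):
        node = HierarchyNode(
            name="agriculture",
            children=[leaf("crop_farming", 0.7), leaf("livestock", 0.3)],
        )
        scores = {
            "agriculture/crop_farming": np.array([9.0]),
            "agriculture/livestock": np.array([5.0]),
        }
        assert evaluate_hierarchy(node, scores, NODATA)[0] == pytest.approx(7.8)

    def test_bad_sibling_weights_name_the_node(self):
        node = HierarchyNode(
            name="broken", children=[leaf("a", 0.5), leaf("b", 0.3)]
        )
        with pytest.raises(ValidationError, match="broken"):
            evaluate_hierarchy(
                node, {"broken/a": np.array([1.0]), "broken/b": np.array([1.0])}, NODATA
            )

    def test_order_invariance_of_siblings(self, toy_scene, toy_units):
        h = load_hierarchies()["settlement"]
        a = build_goal_suitability("settlement", toy_scene, toy_units, h)
        h2 = h.copy()
        for node in (h2, *h2.children):
            node.children = node.children[::-1]
        b = build_goal_suitability("settlement", toy_scene, toy_units, h2)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)

    def test_monotone_in_benefit_criterion(self):
        node = HierarchyNode(
            name="goal",
            children=[
                HierarchyNode(
                    name="obj", weight=0.6,
                    children=[leaf("a", 0.5), leaf("b", 0.5)],
                ),
                leaf("c", 0.4),
            ],
        )
        rng = np.random.default_rng(12)
        base = {
            "goal/obj/a": rng.uniform(1, 9, 20),
            "goal/obj/b": rng.uniform(1, 9, 20),
            "goal/c": rng.uniform(1, 9, 20),
        }
        lo = evaluate_hierarchy(node, base, NODATA)
        bumped = dict(base)
        bumped["goal/obj/a"] = base["goal/obj/a"] + 1.0
        hi = evaluate_hierarchy(node, bumped, NODATA)
        assert (hi >= lo - 1e-12).all()


# ---------------------------------------------------------------------------
# Criterion evaluation on scenes
# ---------------------------------------------------------------------------

class TestEvaluateCriterion:
    def test_inverted_road_distance_endpoints(self, toy_scene, toy_units):
        spec = CriterionSpec(
            name="road_access", source_layer="roads", transform="distance", invert=True
        )
        out = evaluate_criterion(spec, toy_scene, toy_units)
        s = out.scores("road_access")
        d = np.abs(toy_units.df["cx"].to_numpy() - 3000.0)  # toy road is x=3000
        assert s[np.argmin(d)] == pytest.approx(9.0)
        assert s[np.argmax(d)] == pytest.approx(1.0)

    def test_cattle_post_buffer_rule(self):
        # one post; units centered 200 m and 500 m away
        units = build_decision_units(
            (0, 0, 1000, 250), FeatureSet([]), FeatureSet([]), 250, 1000, 100
        )
        scene = _mini_scene_with_post(Point(175, 125))
        spec = CriterionSpec(
            name="livestock_buffer",
            source_layer="cattle_posts",
            transform="buffer_exclusion",
            transform_params={"buffer_m": 300.0},
        )
        out = evaluate_criterion(spec, scene, units)
        s = out.scores("livestock_buffer")
        cx = units.df["cx"].to_numpy()
        assert s[np.argmin(np.abs(cx - 375))] == 1.0  # 200 m from the post
        assert s[np.argmin(np.abs(cx - 675))] == 9.0  # 500 m from the post

    def test_reclass_table_majority_mapping(self):
        units = build_decision_units(
            (0, 0, 1000, 250), FeatureSet([]), FeatureSet([]), 250, 1000, 100
        )
        scene = _mini_scene_with_post(Point(125, 125))
        lulc = units.template_raster().with_values(
            np.array([[1.0, 2.0, 3.0, 1.0]]), categorical=True
        )
        scene.rasters["lulc"] = lulc
        spec = CriterionSpec(
            name="land_cover",
            source_layer="lulc",
            transform="reclass_table",
            transform_params={"table": {1: 9, 2: 5, 3: 1}},
        )
        out = evaluate_criterion(spec, scene, units)
        np.testing.assert_allclose(out.scores("land_cover"), [9.0, 5.0, 1.0, 9.0])

    def test_reclass_missing_class_lists_it(self):
        units = build_decision_units(
            (0, 0, 500, 250), FeatureSet([]), FeatureSet([]), 250, 1000, 100
        )
        scene = _mini_scene_with_post(Point(125, 125))
        scene.rasters["lulc"] = units.template_raster().with_values(
            np.array([[1.0, 4.0]]), categorical=True
        )
        spec = CriterionSpec(
            name="land_cover", source_layer="lulc", transform="reclass_table",
            transform_params={"table": {1: 9}},
        )
        with pytest.raises(ValidationError, match=r"4"):
            evaluate_criterion(spec, scene, units)

    def test_missing_layer_named(self, toy_scene, toy_units):
        spec = CriterionSpec(name="x", source_layer="airports", transform="distance")
        with pytest.raises(ValidationError, match="airports"):
            evaluate_criterion(spec, toy_scene, toy_units)

    def test_buffer_exclusion_requires_positive_buffer(self):
        with pytest.raises(ValidationError):
            CriterionSpec(
                name="bad", source_layer="cattle_posts", transform="buffer_exclusion",
                transform_params={"buffer_m": 0},
            )


def _mini_scene_with_post(post: Point) -> SyntheticScene:
    cfg = LandscapeConfig(
        extent=(0.0, 0.0, 1000.0, 250.0), cell_size_m=250.0, seed=0,
        n_roads=0, n_settlements=0, n_farms=0, n_boreholes=0, n_cattle_posts=1,
        protected_fraction=0.0,
    )
    return SyntheticScene(
        rasters={}, vectors={"cattle_posts": FeatureSet([post])}, config=cfg
    )


# ---------------------------------------------------------------------------
# Goal suitability
# ---------------------------------------------------------------------------

class TestGoalSuitability:
    def test_scores_within_1_9(self, toy_scene, toy_units):
        for goal in ("agriculture", "settlement", "wildlife"):
            gs = build_goal_suitability(goal, toy_scene, toy_units)
            valid = gs.scores != toy_units.nodata
            assert (gs.scores[valid] >= 1).all() and (gs.scores[valid] <= 9).all()

    def test_wildlife_single_species_is_rescaled_zonal_mean(self, toy_units):
        scene = _mini_wildlife_scene(n_species=1)
        gs = build_goal_suitability("wildlife", scene, _units_for(scene))
        units = _units_for(scene)
        agg = zonal_aggregate(scene.rasters["habitat_lion"], units, "mean", name="m")
        expect = rescale_linear_1_9_array(agg.scores("m"), units.nodata, False)
        np.testing.assert_allclose(gs.scores, expect)

    def test_wildlife_identical_species_idempotent(self):
        scene1 = _mini_wildlife_scene(n_species=1)
        scene4 = _mini_wildlife_scene(n_species=4)  # all layers identical
        a = build_goal_suitability("wildlife", scene1, _units_for(scene1))
        b = build_goal_suitability("wildlife", scene4, _units_for(scene4))
        np.testing.assert_allclose(a.scores, b.scores)

    def test_wildlife_missing_layers_rejected(self, toy_units):
        cfg = _mini_wildlife_scene(1).config
        scene = SyntheticScene(
            rasters={"dem": _mini_wildlife_scene(1).rasters["habitat_lion"]},
            vectors={}, config=cfg,
        )
        with pytest.raises(ValidationError):
            build_goal_suitability("wildlife", scene, _units_for(scene))

    def test_wildlife_condition_weights_valid(self):
        from lucis.mce import WeightVector

        WeightVector(np.array([0.50, 0.20, 0.20, 0.10]))  # lion/leopard/hyaena/elephant


def _mini_wildlife_scene(n_species: int) -> SyntheticScene:
    cfg = LandscapeConfig(
        extent=(0.0, 0.0, 2000.0, 2000.0), cell_size_m=250.0, seed=0,
        n_roads=0, n_settlements=0, n_farms=0, n_boreholes=0, n_cattle_posts=0,
        protected_fraction=0.0,
    )
    tmpl = cfg.template()
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 1, size=tmpl.shape)
    rasters = {
        f"habitat_{sp}": tmpl.with_values(base.copy()) for sp in SPECIES[:n_species]
    }
    if n_species == 1:
        rasters = {"habitat_lion": tmpl.with_values(base.copy())}
    return SyntheticScene(rasters=rasters, vectors={}, config=cfg)


def _units_for(scene):
    return build_decision_units(
        scene.config.extent, FeatureSet([]), FeatureSet([]), 250, 1000, 100
    )
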