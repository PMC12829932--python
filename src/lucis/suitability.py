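"""Hierarchical land-suitability assembly.

Each land-use goal (agriculture, human settlement, wildlife) is scored on
the decision units by evaluating criterion layers (distance transforms,
slope, land-cover reclassification, regulatory buffers) to the 1-9
suitability scale and aggregating them bottom-up through a three-tier
weight hierarchy (sub-objectives -> objectives -> goal) with weighted
linear combinations.  Only the goal-level composite is re-standardized to
[1, 9]; intermediate composites stay on the scale their children share.

The shipped default hierarchies encode the study's printed weight tables:
agriculture splits 0.7 crop farming / 0.3 livestock; livestock weighs
physical 0.40 / economic 0.30 / wildlife condition 0.30 (lion 0.50,
leopard 0.20, hyaena 0.20, elephant 0.10); settlement splits physical and
economic 0.50/0.50.  A 300 m regulatory buffer around cattle posts enters
as a binary exclusion criterion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .errors import ValidationError
from .geoprimitives import (
    DecisionUnitGrid,
    euclidean_distance_surface,
    slope_from_dem,
    zonal_aggregate,
)
from .mce import WeightVector, rescale_linear_1_9_array, wlc_aggregate_columns
from .raster import FeatureSet, Raster, distances_to_features
from .synthetic import SPECIES, SyntheticScene

Goal = Literal["agriculture", "settlement", "wildlife"]

TRANSFORMS = ("distance", "slope", "reclass_table", "identity", "buffer_exclusion")


@dataclass
class CriterionSpec:
    """Leaf of the hierarchy: how one layer becomes a 1-9 unit score."""

    name: str
    source_layer: str
    transform: str
    transform_params: dict = field(default_factory=dict)
    invert: bool = False

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"criterion {self.name!r}: unknown transform {self.transform!r}"
            )
        if self.transform == "buffer_exclusion":
            if float(self.transform_params.get("buffer_m", 0)) <= 0:
                raise ValidationError(
                    f"criterion {self.name!r}: buffer_exclusion requires buffer_m > 0"
                )
        if self.transform == "reclass_table" and not self.transform_params.get("table"):
            raise ValidationError(f"criterion {self.name!r}: reclass_table requires a table")

    def cache_key(self) -> tuple:
        params = tuple(sorted((k, repr(v)) for k, v in self.transform_params.items()))
        return (self.transform, self.source_layer, self.invert, params)


@dataclass
class HierarchyNode:
    """Goal/objective/sub-objective tree node with a sibling weight.

    Internal nodes carry children whose weights sum to 1 (within the
    printing tolerance of the weight tables); leaves carry a
    :class:`CriterionSpec`.
    """

    name: str
    weight: float = 1.0
    children: list["HierarchyNode"] = field(default_factory=list)
    criterion: CriterionSpec | None = None

    @property
    def is_leaf(self) -> bool:
        return self.criterion is not None

    def validate(self) -> None:
        if self.is_leaf:
            if self.children:
                raise ValidationError(f"node {self.name!r} has both a criterion and children")
            return
        if not self.children:
            raise ValidationError(f"node {self.name!r} has neither criterion nor children")
        try:
            WeightVector(np.array([c.weight for c in self.children]))
        except ValidationError as exc:
            raise ValidationError(f"node {self.name!r}: sibling weights invalid: {exc}") from exc
        for c in self.children:
            c.validate()

    def leaves(self, prefix: str = "") -> list[tuple[str, CriterionSpec]]:
        """(path, spec) pairs for every criterion leaf under this node."""
        path = f"{prefix}/{self.name}" if prefix else self.name
        if self.is_leaf:
            return [(path, self.criterion)]
        out: list[tuple[str, CriterionSpec]] = []
        for c in self.children:
            out.extend(c.leaves(path))
        return out

    def find(self, name: str) -> list["HierarchyNode"]:
        hits = [self] if self.name == name else []
        for c in self.children:
            hits.extend(c.find(name))
        return hits

    def copy(self) -> "HierarchyNode":
        return copy.deepcopy(self)

    # -- (de)serialization ------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyNode":
        if "criterion" in d:
            spec = d["criterion"]
            crit = CriterionSpec(
                name=d["name"],
                source_layer=spec["source_layer"],
                transform=spec["transform"],
                transform_params=spec.get("transform_params", {}) or {},
                invert=bool(spec.get("invert", False)),
            )
            return cls(name=d["name"], weight=float(d.get("weight", 1.0)), criterion=crit)
        children = [cls.from_dict(c) for c in d.get("children", [])]
        return cls(name=d["name"], weight=float(d.get("weight", 1.0)), children=children)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "weight": self.weight}
        if self.is_leaf:
            d["criterion"] = {
                "source_layer": self.criterion.source_layer,
                "transform": self.criterion.transform,
                "transform_params": self.criterion.transform_params,
                "invert": self.criterion.invert,
            }
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d


def load_hierarchies(path: str | Path | None = None) -> dict[str, HierarchyNode]:
    """Load goal hierarchies from YAML (the packaged defaults if no path)."""
    if path is None:
        text = resources.files("lucis.defaults").joinpath("hierarchies.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = {}
    for goal, tree in doc.items():
        node = HierarchyNode.from_dict(tree)
        node.validate()
        out[goal] = node
    return out


@dataclass
class GoalSuitability:
    """Per-unit suitability (continuous [1, 9]) for one land-use goal."""

    goal: str
    units: DecisionUnitGrid
    scores: np.ndarray

    def __post_init__(self) -> None:
        valid = self.scores != self.units.nodata
        if valid.any() and not (
            (self.scores[valid] >= 1 - 1e-9) & (self.scores[valid] <= 9 + 1e-9)
        ).all():
            raise ValidationError("goal suitability scores must lie in [1, 9]")


# ---------------------------------------------------------------------------
# Criterion evaluation
# ---------------------------------------------------------------------------

class CriterionEvaluator:
    """Evaluates criterion specs against a scene, caching shared transforms.

    Several criteria reuse the same expensive surface (e.g. distance to
    roads appears in every goal); the cache keys on the full transform
    signature so identical criteria are computed once per scene/units pair.
    """

    def __init__(self, scene: SyntheticScene, units: DecisionUnitGrid):
        self.scene = scene
        self.units = units
        self._cache: dict[tuple, np.ndarray] = {}

    def _vector_layer(self, name: str) -> FeatureSet:
        if name not in self.scene.vectors:
            raise ValidationError(f"scene has no vector layer {name!r}")
        return self.scene.vectors[name]

    def _raster_layer(self, name: str) -> Raster:
        if name not in self.scene.rasters:
            raise ValidationError(f"scene has no raster layer {name!r}")
        return self.scene.rasters[name]

    def evaluate(self, spec: CriterionSpec) -> np.ndarray:
        key = spec.cache_key()
        if key not in self._cache:
            self._cache[key] = self._evaluate(spec)
        return self._cache[key]

    def _evaluate(self, spec: CriterionSpec) -> np.ndarray:
        units = self.units
        nodata = units.nodata
        tmpl = units.template_raster()

        if spec.transform == "distance":
            surf = euclidean_distance_surface(self._vector_layer(spec.source_layer), tmpl)
            agg = zonal_aggregate(surf, units, "mean", name="_tmp")
            return rescale_linear_1_9_array(agg.scores("_tmp"), nodata, spec.invert)

        if spec.transform == "slope":
            surf = slope_from_dem(self._raster_layer(spec.source_layer))
            agg = zonal_aggregate(surf, units, "mean", name="_tmp")
            return rescale_linear_1_9_array(agg.scores("_tmp"), nodata, spec.invert)

        if spec.transform == "identity":
            agg = zonal_aggregate(self._raster_layer(spec.source_layer), units, "mean", name="_tmp")
            return rescale_linear_1_9_array(agg.scores("_tmp"), nodata, spec.invert)

        if spec.transform == "reclass_table":
            raster = self._raster_layer(spec.source_layer)
            agg = zonal_aggregate(raster, units, "majority", name="_tmp")
            classes = agg.scores("_tmp")
            table = {float(k): float(v) for k, v in spec.transform_params["table"].items()}
            present = set(np.unique(classes[classes != nodata]))
            unmapped = sorted(present - set(table))
            if unmapped:
                raise ValidationError(
                    f"criterion {spec.name!r}: reclass_table misses classes {unmapped}"
                )
            out = np.full(len(classes), nodata)
            ok = classes != nodata
            out[ok] = [table[c] for c in classes[ok]]
            return out

        if spec.transform == "buffer_exclusion":
            features = self._vector_layer(spec.source_layer)
            buffer_m = float(spec.transform_params["buffer_m"])
            inside = float(spec.transform_params.get("inside_score", 1.0))
            outside = float(spec.transform_params.get("outside_score", 9.0))
            if features.is_empty:
                return np.full(units.n_units, outside)
            cx = units.df["cx"].to_numpy()
            cy = units.df["cy"].to_numpy()
            d = distances_to_features(cx, cy, features)
            return np.where(d <= buffer_m, inside, outside).astype(float)

        raise ValidationError(f"unknown transform {spec.transform!r}")  # pragma: no cover


def evaluate_criterion(
    spec: CriterionSpec, scene: SyntheticScene, units: DecisionUnitGrid
) -> DecisionUnitGrid:
    """Score one criterion onto the units (column named after the spec)."""
    values = CriterionEvaluator(scene, units).evaluate(spec)
    return units.with_score(spec.name, values)


# ---------------------------------------------------------------------------
# Hierarchy aggregation
# ---------------------------------------------------------------------------

def evaluate_hierarchy(
    node: HierarchyNode,
    leaf_scores: dict[str, np.ndarray],
    nodata: float,
    prefix: str = "",
) -> np.ndarray:
    """Bottom-up WLC through the tree; leaf arrays keyed by leaf path."""
    path = f"{prefix}/{node.name}" if prefix else node.name
    if node.is_leaf:
        try:
            return leaf_scores[path]
        except KeyError:
            raise ValidationError(f"criterion {path!r} has not been evaluated") from None
    child_arrays = [
        evaluate_hierarchy(c, leaf_scores, nodata, path) for c in node.children
    ]
    try:
        weights = WeightVector(np.array([c.weight for c in node.children]))
    except ValidationError as exc:
        raise ValidationError(f"node {path!r}: {exc}") from exc
    return wlc_aggregate_columns(np.stack(child_arrays), weights, nodata)


def build_goal_suitability(
    goal: Goal,
    scene: SyntheticScene,
    units: DecisionUnitGrid,
    hierarchy: HierarchyNode | None = None,
    wildlife_combine: str = "mean",
) -> GoalSuitability:
    """Goal-level suitability on the units, rescaled to [1, 9].

    Agriculture and settlement evaluate their weight hierarchies; wildlife
    combines the per-species habitat rasters with a cell statistic
    (mean by default, max optionally), zonal-aggregates and rescales.
    """
    nodata = units.nodata
    if goal == "wildlife":
        missing = [sp for sp in SPECIES if f"habitat_{sp}" not in scene.rasters]
        if len(missing) == len(SPECIES):
            raise ValidationError(f"scene lacks habitat rasters for {missing}")
        combined = scene.combined_habitat(stat=wildlife_combine)
        agg = zonal_aggregate(combined, units, "mean", name="_wl")
        scores = rescale_linear_1_9_array(agg.scores("_wl"), nodata, invert=False)
        return GoalSuitability(goal=goal, units=units, scores=scores)

    if hierarchy is None:
        hierarchy = load_hierarchies()[goal]
    hierarchy.validate()
    evaluator = CriterionEvaluator(scene, units)
    leaf_scores = {path: evaluator.evaluate(spec) for path, spec in hierarchy.leaves()}
    composite = evaluate_hierarchy(hierarchy, leaf_scores, nodata)
    scores = rescale_linear_1_9_array(composite, nodata, invert=False)
    return GoalSuitability(goal=goal, units=units, scores=scores)
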