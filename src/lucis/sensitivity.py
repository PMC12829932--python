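"""One-at-a-time map-removal sensitivity analysis.

Each named factor group (existing land use, terrain characteristics, road
accessibility, water proximity, development constraints) is removed from the
agriculture and settlement hierarchies in turn; surviving sibling weights
are renormalized proportionally, the full pipeline (suitability -> Jenks
preference binning -> conflict overlay -> area accounting) reruns, and the
per-class area changes against the base scenario are reported.  Jenks
breaks are refit inside every scenario — removing a layer is allowed to
shift the class boundaries, exactly as a full rerun would.

The wildlife surface is an external ecological input carrying none of the
five factors, so it is identical across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .conflict import (
    CLASSES,
    AreaSummary,
    overlay_conflict,
    bin_preferences,
    summarize_areas,
)
from .geoprimitives import DecisionUnitGrid
from .suitability import GoalSuitability, HierarchyNode, build_goal_suitability
from .synthetic import SyntheticScene


@dataclass(frozen=True)
class FactorGroup:
    """A named set of (goal, node-name) members removed together."""

    name: str
    members: tuple[tuple[str, str], ...]

    def names_for(self, goal: str) -> set[str]:
        return {n for g, n in self.members if g == goal}


def load_factor_groups(path: str | Path | None = None) -> list[FactorGroup]:
    """Load factor groups from YAML (the packaged five defaults if no path)."""
    if path is None:
        text = resources.files("lucis.defaults").joinpath("factor_groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return [
        FactorGroup(name=name, members=tuple((g, n) for g, n in members))
        for name, members in doc.items()
    ]


# ---------------------------------------------------------------------------
# Hierarchy surgery
# ---------------------------------------------------------------------------

def _prune(node: HierarchyNode, names: set[str]) -> HierarchyNode | None:
    """Remove named nodes; drop internal nodes left childless; renormalize."""
    if node.name in names:
        return None
    if node.is_leaf:
        return node
    kept = [c for c in (_prune(child, names) for child in node.children) if c is not None]
    if not kept:
        return None
    total = sum(c.weight for c in kept)
    for c in kept:
        c.weight = c.weight / total
    out = HierarchyNode(name=node.name, weight=node.weight, children=kept)
    return out


def remove_factor_group(
    hierarchy: HierarchyNode, group: FactorGroup, goal: str | None = None
) -> HierarchyNode:
    """Copy of the hierarchy with the group's members deleted and surviving
    sibling weights renormalized proportionally.

    ``goal`` selects which members apply (defaults to the hierarchy's root
    name).  Removing a group with no members in the goal is a no-op;
    removal that would empty the whole goal is rejected.
    """
    goal = goal or hierarchy.name
    names = group.names_for(goal)
    tree = hierarchy.copy()
    if not names:
        return tree
    found = {n for n in names if tree.find(n)}
    missing = names - found
    if missing:
        raise ValidationError(
            f"factor group {group.name!r}: nodes {sorted(missing)} not present in "
            f"goal {goal!r}"
        )
    pruned = _prune(tree, names)
    if pruned is None:
        raise ValidationError(
            f"removing factor group {group.name!r} would empty goal {goal!r}"
        )
    pruned.validate()
    return pruned


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def _conflict_areas(
    scene: SyntheticScene,
    units: DecisionUnitGrid,
    hierarchies: dict[str, HierarchyNode],
    wildlife_combine: str,
    seed: int,
    wildlife: GoalSuitability | None = None,
) -> AreaSummary:
    wl = wildlife or build_goal_suitability(
        "wildlife", scene, units, wildlife_combine=wildlife_combine
    )
    ag = build_goal_suitability("agriculture", scene, units, hierarchies["agriculture"])
    hs = build_goal_suitability("settlement", scene, units, hierarchies["settlement"])
    # per-goal derived seeds keep Jenks subsampling deterministic per goal
    levels = {
        name: bin_preferences(g, rng=np.random.default_rng((seed + i) % 2**31))
        for i, (name, g) in enumerate([("wl", wl), ("ag", ag), ("hs", hs)])
    }
    cmap = overlay_conflict(levels["wl"], levels["ag"], levels["hs"], units)
    return summarize_areas(cmap, units)


def run_oat_scenario(
    scene: SyntheticScene,
    units: DecisionUnitGrid,
    hierarchies: dict[str, HierarchyNode],
    group: FactorGroup | None,
    wildlife_combine: str = "mean",
    seed: int = 0,
    wildlife: GoalSuitability | None = None,
) -> AreaSummary:
    """Full pipeline rerun with one factor group removed (base if None)."""
    if group is None or not group.members:
        reduced = hierarchies
    else:
        reduced = {
            goal: remove_factor_group(tree, group, goal)
            for goal, tree in hierarchies.items()
        }
    return _conflict_areas(scene, units, reduced, wildlife_combine, seed, wildlife)


# ---------------------------------------------------------------------------
# Change metrics and report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangeRecord:
    scenario: str
    conflict_class: str
    area_km2: float
    change_km2: float | None  # None for base rows
    pct_change: float | None  # None for base rows or undefined (base area 0)


def change_metrics(
    base: AreaSummary, scenario: AreaSummary, scenario_name: str = "scenario"
) -> list[ChangeRecord]:
    """Per-class area change (km^2, whole-km reporting) and percent change
    (one decimal) of a scenario against the base run."""
    if abs(base.total_area_km2 - scenario.total_area_km2) > 1e-6:
        raise ValidationError("base and scenario total areas differ")
    records = []
    for cls in CLASSES:
        b, s = base.area(cls), scenario.area(cls)
        change = s - b
        pct = None if b == 0 else 100.0 * change / b
        records.append(
            ChangeRecord(
                scenario=scenario_name,
                conflict_class=cls,
                area_km2=s,
                change_km2=change,
                pct_change=pct,
            )
        )
    return records


@dataclass
class SensitivityReport:
    """Base plus one row-set per removed factor (per-class areas + changes)."""

    base: AreaSummary
    records: list[ChangeRecord] = field(default_factory=list)

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        rows = []
        for cls in CLASSES:
            rows.append(
                {
                    "scenario": "base",
                    "conflict_class": cls,
                    "area_km2": round(self.base.area(cls), decimals),
                    "change_km2": 0.0,
                    "pct_change": 0.0,
                }
            )
        for rec in self.records:
            rows.append(
                {
                    "scenario": rec.scenario,
                    "conflict_class": rec.conflict_class,
                    "area_km2": round(rec.area_km2, decimals),
                    "change_km2": None if rec.change_km2 is None else round(rec.change_km2),
                    "pct_change": None if rec.pct_change is None else round(rec.pct_change, 1),
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self, decimals: int = 1) -> str:
        df = self.to_frame(decimals)
        return df.to_markdown(index=False)


def run_sensitivity(
    scene: SyntheticScene,
    units: DecisionUnitGrid,
    hierarchies: dict[str, HierarchyNode],
    groups: list[FactorGroup] | None = None,
    wildlife_combine: str = "mean",
    seed: int = 0,
) -> SensitivityReport:
    """Base run plus one full OAT rerun per factor group."""
    groups = groups if groups is not None else load_factor_groups()
    wildlife = build_goal_suitability(
        "wildlife", scene, units, wildlife_combine=wildlife_combine
    )
    base = run_oat_scenario(
        scene, units, hierarchies, None, wildlife_combine, seed, wildlife
    )
    report = SensitivityReport(base=base)
    for group in groups:
        summary = run_oat_scenario(
            scene, units, hierarchies, group, wildlife_combine, seed, wildlife
        )
        report.records.extend(change_metrics(base, summary, group.name))
    return report
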