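"""Conflict identification by preference overlay.

Goal suitability (continuous 1-9) is rebinned into three preference levels
with Jenks natural breaks (1 low, 2 medium, 3 high).  Conflict then follows
the literal matched-level overlay rules:

* high conflict:      WL=3 and (AG=3 or HS=3)
* moderate conflict:  WL=2 and (AG=2 or HS=2)
* low conflict:       WL=1 and (AG=1 or HS=1)

Any triple matching no rule — including every mixed-level overlap such as
WL=3 with AG=2 — classifies as *none*.  This is deliberate and follows the
rules exactly as stated; the matched-level formulation means only units
where wildlife and a human use sit at the *same* preference level register
as conflict.  A unit with no wildlife preference (nodata) can never be in
conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geoprimitives import DecisionUnitGrid
from .mce import jenks_breaks
from .suitability import GoalSuitability

#: Conflict classes in severity order; integer codes 0..3 for rasterization.
CLASSES = ("none", "low", "moderate", "high")

#: Preference level marking nodata (no preference information).
NO_LEVEL = 0


@dataclass(frozen=True)
class PreferenceTriple:
    """Per-unit wildlife / agriculture / settlement preference levels (1-3)."""

    WL: int
    AG: int
    HS: int


def bin_preferences(
    goal: GoalSuitability, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Jenks k=3 rebinning of a goal's suitability scores to levels 1-3.

    Level 1 is the lowest-score class.  Nodata units get level 0.
    Requires at least three distinct valid scores.
    """
    scores = goal.scores
    nodata = goal.units.nodata
    valid = scores != nodata
    if len(np.unique(scores[valid])) < 3:
        raise ValidationError("preference binning needs >= 3 distinct suitability values")
    result = jenks_breaks(scores[valid], k=3, rng=rng)
    levels = np.full(len(scores), NO_LEVEL, dtype=int)
    levels[valid] = result.assignments
    return levels


def classify_conflict(triple: PreferenceTriple) -> str:
    """Literal overlay rule for one preference triple."""
    return classify_conflict_levels(
        np.array([triple.WL]), np.array([triple.AG]), np.array([triple.HS])
    )[0]


def classify_conflict_levels(
    wl: np.ndarray, ag: np.ndarray, hs: np.ndarray
) -> np.ndarray:
    """Vectorized conflict classification; returns class names per unit."""
    wl, ag, hs = (np.asarray(a, dtype=int) for a in (wl, ag, hs))
    for name, arr in (("WL", wl), ("AG", ag), ("HS", hs)):
        if ((arr < 0) | (arr > 3)).any():
            raise ValidationError(f"{name} levels must be in {{1,2,3}} (0 = nodata)")
    out = np.full(wl.shape, "none", dtype=object)
    for level, cls in ((1, "low"), (2, "moderate"), (3, "high")):
        hit = (wl == level) & ((ag == level) | (hs == level))
        out[hit] = cls
    return out.astype(str)


@dataclass
class ConflictMap:
    """Per-unit conflict class over a decision-unit grid."""

    units: DecisionUnitGrid
    classes: np.ndarray  # str array over units

    def __post_init__(self) -> None:
        bad = set(np.unique(self.classes)) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown conflict classes {sorted(bad)}")

    def codes(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(CLASSES)}
        return np.array([lookup[c] for c in self.classes], dtype=int)


def overlay_conflict(
    wl_levels: np.ndarray,
    ag_levels: np.ndarray,
    hs_levels: np.ndarray,
    units: DecisionUnitGrid,
) -> ConflictMap:
    classes = classify_conflict_levels(wl_levels, ag_levels, hs_levels)
    return ConflictMap(units=units, classes=classes)


@dataclass
class AreaSummary:
    """Per-class areas (km^2) and shares (% of total study area)."""

    areas_km2: dict[str, float]
    total_area_km2: float

    def __post_init__(self) -> None:
        if self.total_area_km2 <= 0:
            raise ValidationError("total_area_km2 must be positive")

    def area(self, cls: str) -> float:
        return self.areas_km2.get(cls, 0.0)

    def share_pct(self, cls: str, decimals: int | None = None) -> float:
        share = 100.0 * self.area(cls) / self.total_area_km2
        return share if decimals is None else round(share, decimals)

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "area_km2": round(self.area(cls), decimals),
                "share_pct": self.share_pct(cls, decimals),
            }
            for cls in CLASSES
        ]
        return pd.DataFrame(rows)


def summarize_areas(
    conflict: ConflictMap | None = None,
    units: DecisionUnitGrid | None = None,
    total_area_km2: float | None = None,
    areas_km2: dict[str, float] | None = None,
) -> AreaSummary:
    """Account per-class areas from unit polygons (or supplied area figures).

    Either pass a :class:`ConflictMap` (areas summed from the true unit
    polygon areas) or a prepared ``areas_km2`` mapping (e.g. printed report
    figures).  ``total_area_km2`` defaults to the tessellated area.
    """
    if areas_km2 is None:
        if conflict is None:
            raise ValidationError("need a ConflictMap or explicit areas_km2")
        units = units or conflict.units
        unit_areas = units.df["area_km2"].to_numpy(dtype=float)
        areas_km2 = {
            cls: float(unit_areas[conflict.classes == cls].sum()) for cls in CLASSES
        }
        if total_area_km2 is None:
            total_area_km2 = units.total_area_km2()
    if total_area_km2 is None:
        raise ValidationError("total_area_km2 required with explicit areas_km2")
    return AreaSummary(areas_km2=dict(areas_km2), total_area_km2=float(total_area_km2))
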