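"""End-to-end run orchestration: stages, artifacts, manifest, provenance.

A run is driven by a YAML configuration (scene source, decision-unit
parameters, hierarchy/factor-group overrides, seed) and executes any subset
of the stages ``simulate -> suitability -> conflict -> sensitivity``, each
persisting text artifacts into the output directory:

* ``scene/``                 rasters (.asc), vectors (.geojson), scene.yaml
* ``units_scores.csv``       decision units with per-goal suitability
* ``units.geojson``          unit polygons with scores
* ``preferences.csv``        per-unit 1-3 preference levels per goal
* ``conflict.csv`` / ``conflict.geojson``  per-unit conflict class
* ``areas.csv``              per-class area accounting
* ``sensitivity.csv`` / ``sensitivity.md`` OAT map-removal report
* ``manifest.yaml``          config hash, seed, stage timings, checksums

Reruns with the identical config and seed reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .conflict import CLASSES, bin_preferences, overlay_conflict, summarize_areas
from .geoprimitives import DecisionUnitGrid, build_decision_units
from .raster import FeatureSet
from .sensitivity import load_factor_groups, run_sensitivity
from .suitability import build_goal_suitability, load_hierarchies
from .synthetic import LandscapeConfig, SyntheticScene, generate_scene

log = logging.getLogger(__name__)

STAGES = ("simulate", "suitability", "conflict", "sensitivity")


@dataclass
class RunConfig:
    """Validated run configuration."""

    scene_synthetic: LandscapeConfig | None
    scene_manifest: Path | None
    fine_m: float = 250.0
    coarse_m: float = 1000.0
    developed_buffer_m: float = 2000.0
    hierarchies_path: Path | None = None
    factor_groups_path: Path | None = None
    wildlife_combine: str = "mean"
    seed: int = 0
    report_precision: int = 1
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path | None, seed: int | None = None) -> "RunConfig":
        if path is None:
            text = resources.files("lucis.defaults").joinpath("demo_scene.yaml").read_text()
        else:
            path = Path(path)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            text = path.read_text()
        try:
            doc = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML config: {exc}") from exc

        scene = doc.get("scene") or {}
        synth = None
        manifest = None
        if "synthetic" in scene:
            params = dict(scene["synthetic"])
            params.setdefault("seed", doc.get("seed", 0))
            try:
                synth = LandscapeConfig.from_dict(params)
            except Exception as exc:
                raise ConfigError(f"invalid synthetic scene config: {exc}") from exc
        elif "manifest" in scene:
            manifest = Path(scene["manifest"])
            if not manifest.exists():
                raise ConfigError(f"scene manifest not found: {manifest}")
        else:
            raise ConfigError("config must define scene.synthetic or scene.manifest")

        units = doc.get("decision_units") or {}
        for key in ("hierarchies", "factor_groups"):
            p = doc.get(key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{key} config not found: {p}")
        cfg = cls(
            scene_synthetic=synth,
            scene_manifest=manifest,
            fine_m=float(units.get("fine_m", 250.0)),
            coarse_m=float(units.get("coarse_m", 1000.0)),
            developed_buffer_m=float(units.get("developed_buffer_m", 2000.0)),
            hierarchies_path=Path(doc["hierarchies"]) if doc.get("hierarchies") else None,
            factor_groups_path=Path(doc["factor_groups"]) if doc.get("factor_groups") else None,
            wildlife_combine=str(doc.get("wildlife_combine", "mean")),
            seed=int(doc.get("seed", 0)),
            report_precision=int(doc.get("report_precision", 1)),
            raw=doc,
        )
        if seed is not None:
            cfg.seed = int(seed)
            cfg.raw = dict(cfg.raw, seed=int(seed))
            if cfg.scene_synthetic is not None:
                cfg.scene_synthetic.seed = int(seed)
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_scene(config: RunConfig, outdir: Path) -> SyntheticScene:
    scene_dir = outdir / "scene"
    if (scene_dir / "scene.yaml").exists():
        return SyntheticScene.read(scene_dir)
    if config.scene_manifest is not None:
        return SyntheticScene.read(config.scene_manifest.parent
                                   if config.scene_manifest.name == "scene.yaml"
                                   else config.scene_manifest)
    if config.scene_synthetic is not None:
        return generate_scene(config.scene_synthetic)
    raise ConfigError("no scene available: run the simulate stage or point to a manifest")


def _build_units(config: RunConfig, scene: SyntheticScene) -> DecisionUnitGrid:
    developed = FeatureSet(
        geometries=(
            scene.vectors["settlements"].geometries + scene.vectors["farms"].geometries
        ),
        crs_id=scene.config.crs_id,
    )
    return build_decision_units(
        extent=scene.config.extent,
        developed=developed,
        protected=scene.vectors["protected_areas"],
        fine_m=config.fine_m,
        coarse_m=config.coarse_m,
        developed_buffer_m=config.developed_buffer_m,
    )


def run_pipeline(
    config: RunConfig, stages: list[str], outdir: str | Path
) -> dict[str, Path]:
    """Run the requested stages in canonical order; returns written artifacts.

    Raises :class:`ConfigError` when a stage's inputs are missing (e.g.
    conflict without persisted suitability scores).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    scene: SyntheticScene | None = None
    units: DecisionUnitGrid | None = None

    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)

        if stage == "simulate":
            if config.scene_synthetic is None:
                raise ConfigError("simulate stage requires scene.synthetic in the config")
            scene = generate_scene(config.scene_synthetic)
            scene.write(outdir / "scene")
            artifacts["scene"] = outdir / "scene" / "scene.yaml"

        elif stage == "suitability":
            scene = scene or _load_scene(config, outdir)
            units = _build_units(config, scene)
            hierarchies = load_hierarchies(config.hierarchies_path)
            for goal in ("agriculture", "settlement"):
                suit = build_goal_suitability(goal, scene, units, hierarchies[goal])
                units = units.with_score(f"suit_{goal}", suit.scores)
            wl = build_goal_suitability(
                "wildlife", scene, units, wildlife_combine=config.wildlife_combine
            )
            units = units.with_score("suit_wildlife", wl.scores)
            units.write_csv(outdir / "units_scores.csv")
            units.write_geojson(outdir / "units.geojson")
            artifacts["units_scores"] = outdir / "units_scores.csv"
            artifacts["units"] = outdir / "units.geojson"

        elif stage == "conflict":
            if units is None:
                scores_path = outdir / "units_scores.csv"
                if not scores_path.exists():
                    raise ConfigError(
                        f"conflict stage requires {scores_path} (run suitability first)"
                    )
                scene = scene or _load_scene(config, outdir)
                units = DecisionUnitGrid.read_csv(
                    scores_path,
                    origin_x=scene.config.extent[0],
                    origin_y=scene.config.extent[3],
                    fine_m=config.fine_m,
                    crs_id=scene.config.crs_id,
                )
            from .suitability import GoalSuitability

            levels = {}
            for i, goal in enumerate(("wildlife", "agriculture", "settlement")):
                gs = GoalSuitability(goal=goal, units=units, scores=units.scores(f"suit_{goal}"))
                levels[goal] = bin_preferences(
                    gs, rng=np.random.default_rng((config.seed + i) % 2**31)
                )
            prefs = pd.DataFrame(
                {
                    "uid": units.df["uid"],
                    "WL": levels["wildlife"],
                    "AG": levels["agriculture"],
                    "HS": levels["settlement"],
                }
            )
            prefs.to_csv(outdir / "preferences.csv", index=False)
            cmap = overlay_conflict(
                levels["wildlife"], levels["agriculture"], levels["settlement"], units
            )
            out_units = units.with_score("conflict_code", cmap.codes().astype(float))
            out_units.df["conflict_class"] = cmap.classes
            out_units.write_geojson(outdir / "conflict.geojson")
            out_units.df[["uid", "conflict_class"]].to_csv(outdir / "conflict.csv", index=False)
            summary = summarize_areas(cmap, units)
            summary.to_frame(config.report_precision).to_csv(outdir / "areas.csv", index=False)
            artifacts["preferences"] = outdir / "preferences.csv"
            artifacts["conflict"] = outdir / "conflict.csv"
            artifacts["areas"] = outdir / "areas.csv"

        elif stage == "sensitivity":
            scene = scene or _load_scene(config, outdir)
            units_base = _build_units(config, scene)
            hierarchies = load_hierarchies(config.hierarchies_path)
            groups = load_factor_groups(config.factor_groups_path)
            report = run_sensitivity(
                scene,
                units_base,
                hierarchies,
                groups,
                wildlife_combine=config.wildlife_combine,
                seed=config.seed,
            )
            df = report.to_frame(config.report_precision)
            df.to_csv(outdir / "sensitivity.csv", index=False, float_format="%.10g")
            (outdir / "sensitivity.md").write_text(report.to_markdown(config.report_precision) + "\n")
            artifacts["sensitivity"] = outdir / "sensitivity.csv"
            artifacts["sensitivity_md"] = outdir / "sensitivity.md"

        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])

    checksums = {}
    for name, path in artifacts.items():
        if path.exists():
            checksums[str(path.relative_to(outdir))] = _checksum(path)
    if (outdir / "scene" / "scene.yaml").exists():
        for p in sorted((outdir / "scene").rglob("*")):
            if p.is_file():
                checksums[str(p.relative_to(outdir))] = _checksum(p)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "timings_s": timings,
        "checksums": checksums,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    artifacts["manifest"] = outdir / "manifest.yaml"
    return artifacts
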