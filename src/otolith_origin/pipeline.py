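"""Pipeline orchestration: simulate → reduce → calibrate → classify → compare.

A :class:`RunConfig` names the working directory, the scenario (for the
simulate stage) and the analysis knobs (window percentiles, vaterite
thresholds, weighting scheme, alpha, seed). ``run_pipeline`` executes the
requested stages against that directory and writes a ``manifest.yaml``
recording the configuration hash, seed and SHA-256 checksums of every
output, so a rerun with the same config is verifiably byte-identical.

All randomness flows from the single root seed, split per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as oio
from .assemblage_stats import run_comparison_suite
from .calibration import (
    CalibrationModel,
    build_calibration_observations,
    calibrate_families,
)
from .classification import classify_assemblage
from .config import (
    KIND_LINEAR,
    KIND_PARTITION,
    KIND_PUBLISHED,
    ScenarioConfig,
    default_scenario,
)
from .errors import ConfigError
from .origin_windows import build_windows
from .synthetic_data import generate_dataset
from .transect_processing import reduce_dataset

STAGES = ("simulate", "reduce", "calibrate", "classify", "compare")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    scenario: ScenarioConfig | None = None
    percentiles: tuple[float, float] = (5.0, 95.0)
    vaterite_srca_max: float = 150.0
    vaterite_mgca_min: float = 1000.0
    alpha: float = 0.05
    weight_scheme: str = "equal_location"
    truncate_windows: bool = True
    min_group_n: int = 5
    wisconsin_id: str = "WI"
    ca_internal_pct: float = 38.8
    enumeration_limit: int = 100_000
    n_reps: int = 100_000
    published_models: dict = field(default_factory=dict)

    def validate(self) -> None:
        lo, hi = self.percentiles
        if not lo < hi:
            raise ConfigError("percentile lo must be < hi")
        if self.vaterite_srca_max <= 0 or self.vaterite_mgca_min <= 0:
            raise ConfigError("vaterite thresholds must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "scenario" in d and d["scenario"] is not None:
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict() if self.scenario else None
        d["percentiles"] = list(self.percentiles)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _scenario_published(scenario: ScenarioConfig) -> dict[str, CalibrationModel]:
    out = {}
    for ft in scenario.families:
        if ft.calibration_kind == KIND_PUBLISHED:
            out[ft.family] = CalibrationModel.published(
                ft.family, ft.true_slope, ft.true_intercept,
                ft.published_domain_water,
            )
    return out


def run_pipeline(
    cfg: RunConfig, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the selected stages; returns (and writes) the run manifest."""
    cfg.validate()
    d = cfg.out_dir
    os.makedirs(d, exist_ok=True)
    scenario = cfg.scenario or default_scenario(cfg.seed)
    outputs: list[str] = []

    if "simulate" in stages:
        paths = generate_dataset(scenario, d, seed=_stage_seed(cfg.seed, "simulate"))
        outputs += [paths[k] for k in ("water", "fish", "truth", "standards", "blanks")]

    if "reduce" in stages:
        fish = oio.read_fish(os.path.join(d, "fish.csv"))
        standards = oio.read_standards(os.path.join(d, "standards.csv"))
        blanks = oio.read_blanks(os.path.join(d, "blanks.csv"))
        summaries = reduce_dataset(
            os.path.join(d, "transects"), fish, standards, blanks,
            ca_internal_pct=cfg.ca_internal_pct,
            vaterite_srca_max=cfg.vaterite_srca_max,
            vaterite_mgca_min=cfg.vaterite_mgca_min,
        )
        oio.write_csv(summaries, os.path.join(d, "summaries.csv"))
        outputs.append(os.path.join(d, "summaries.csv"))

    if "calibrate" in stages:
        summaries = oio.read_summaries(os.path.join(d, "summaries.csv"))
        fish = oio.read_fish(os.path.join(d, "fish.csv"))
        water = oio.read_water(os.path.join(d, "water.csv"))
        obs = build_calibration_observations(summaries, fish, water)
        fit_fams = [f.family for f in scenario.families
                    if f.calibration_kind == KIND_LINEAR]
        part_fams = [f.family for f in scenario.families
                     if f.calibration_kind == KIND_PARTITION]
        published = dict(_scenario_published(scenario))
        published.update({
            fam: CalibrationModel.from_dict(m) if isinstance(m, dict) else m
            for fam, m in cfg.published_models.items()
        })
        models = calibrate_families(obs, fit_fams, part_fams, published,
                                    weight_scheme=cfg.weight_scheme)
        with open(os.path.join(d, "calibration.yaml"), "w", encoding="utf-8") as fh:
            yaml.safe_dump({fam: m.to_dict() for fam, m in models.items()}, fh,
                           sort_keys=True)
        outputs.append(os.path.join(d, "calibration.yaml"))

    if "classify" in stages:
        with open(os.path.join(d, "calibration.yaml"), "r", encoding="utf-8") as fh:
            models = {fam: CalibrationModel.from_dict(md)
                      for fam, md in yaml.safe_load(fh).items()}
        water = oio.read_water(os.path.join(d, "water.csv"))
        summaries = oio.read_summaries(os.path.join(d, "summaries.csv"))
        fish = oio.read_fish(os.path.join(d, "fish.csv"))
        candidate_ids = {wb.id for wb in scenario.candidate_bodies}
        windows = build_windows(models, water[water["body_id"].isin(candidate_ids)],
                                *cfg.percentiles, truncate=cfg.truncate_windows)
        oio.write_csv(windows, os.path.join(d, "windows.csv"))
        bodies = {wb.id: wb for wb in scenario.water_bodies}
        assignments = classify_assemblage(
            summaries, windows, models, fish, bodies, scenario.mainstem_id,
            cfg.wisconsin_id,
        )
        oio.write_csv(assignments, os.path.join(d, "assignments.csv"))
        outputs += [os.path.join(d, "windows.csv"), os.path.join(d, "assignments.csv")]

    if "compare" in stages:
        assignments = oio.read_assignments(os.path.join(d, "assignments.csv"))
        ext_path = os.path.join(d, "external.csv")
        external = oio.read_assignments(ext_path) if os.path.exists(ext_path) else None
        tests = run_comparison_suite(
            assignments, external, alpha=cfg.alpha, min_group_n=cfg.min_group_n,
            enumeration_limit=cfg.enumeration_limit, n_reps=cfg.n_reps,
            seed=_stage_seed(cfg.seed, "compare"),
        )
        oio.write_csv(tests, os.path.join(d, "tests.csv"))
        _write_summary_md(tests, os.path.join(d, "tests_summary.md"))
        outputs += [os.path.join(d, "tests.csv"), os.path.join(d, "tests_summary.md")]

    manifest = dict(
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        stages=list(stages),
        package_version=_package_version(),
        checksums={os.path.relpath(p, d): _sha256(p) for p in outputs},
    )
    with open(os.path.join(d, "manifest.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("otolith-origin")
    except PackageNotFoundError:
        return "unknown"


def _write_summary_md(tests: pd.DataFrame, path: str) -> None:
    lines = ["# Origin-distribution comparisons", ""]
    run = tests[~tests["skipped"]]
    if not run.empty:
        alpha_adj = run["alpha_adjusted"].iloc[0]
        lines.append(f"Tests run: {len(run)}; Bonferroni-adjusted alpha: "
                     f"{alpha_adj:.5g}")
        lines.append("")
        lines.append("| comparison | p | method | significant |")
        lines.append("|---|---|---|---|")
        for r in run.itertuples():
            lines.append(
                f"| {r.comparison} | {r.p_value:.4g} | {r.method} | "
                f"{'yes' if r.significant else 'no'} |"
            )
    skipped = tests[tests["skipped"]]
    if not skipped.empty:
        lines += ["", f"Skipped: {len(skipped)} (insufficient group sizes)."]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
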