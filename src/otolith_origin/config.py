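"""Scenario and run configuration.

A :class:`ScenarioConfig` describes a synthetic river network: the candidate
recruitment sources (one mainstem plus tributaries, each with a water Sr:Ca
distribution), the fish families with their true water→otolith mappings, and
the acquisition settings (drift, standard-block spacing, measurement noise)
that the reduction stage must undo.

The default scenario mirrors the study design this package emulates: one
high-Sr:Ca large tributary, several low-Sr:Ca tributaries whose chemistry
partially overlaps, and an intermediate mainstem river sampled over three
navigation reaches and two years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigError

MAINSTEM = "mainstem"
TRIBUTARY = "tributary"

#: calibration kinds a family can declare
KIND_LINEAR = "linear"  # fit a random-intercept linear model from the data
KIND_PARTITION = "partition"  # per-water-body partition coefficients
KIND_PUBLISHED = "published"  # coefficients supplied by configuration


@dataclass(frozen=True)
class WaterBody:
    """A candidate recruitment source.

    Parameters
    ----------
    id :
        Short unique label (e.g. ``"UMR"``, ``"MN"``); used as the refined
        classification label for single-body matches.
    role :
        ``"mainstem"`` or ``"tributary"``.
    confluence_reach :
        Study reach at which a tributary joins the mainstem (``"P4"`` ...),
        or ``"multiple"`` for the mainstem itself / multi-reach tributaries.
    water_srca_median, water_srca_cv :
        Median (mmol:mol) and coefficient of variation of the body's water
        Sr:Ca, modelled log-normally.
    candidate_source :
        Whether the body is a candidate recruitment source (gets an origin
        window). Calibration-only anchor sites (closed ponds extending the
        water-chemistry range of the water-otolith models) set this False.
    """

    id: str
    name: str
    role: str
    confluence_reach: str
    water_srca_median: float
    water_srca_cv: float
    candidate_source: bool = True

    def validate(self) -> None:
        if self.role not in (MAINSTEM, TRIBUTARY):
            raise ConfigError(f"water body {self.id}: unknown role {self.role!r}")
        if not self.water_srca_median > 0:
            raise ConfigError(f"water body {self.id}: median must be > 0")
        if self.water_srca_cv < 0:
            raise ConfigError(f"water body {self.id}: CV must be >= 0")


@dataclass(frozen=True)
class FamilyTruth:
    """True water→otolith Sr:Ca mapping for one fish family.

    ``linear``/``published`` kinds use ``otolith = slope * water + intercept``
    (μmol:mol per mmol:mol); ``partition`` kinds use a per-body otolith:water
    ratio drawn uniformly from ``[k_lo, k_hi]``. ``site_sd`` is the SD of the
    per-(family, water body) random intercept; ``residual_sd`` is the
    per-fish SD, both μmol:mol.
    """

    family: str
    calibration_kind: str
    true_slope: float = 0.0
    true_intercept: float = 0.0
    site_sd: float = 0.0
    residual_sd: float = 0.0
    k_lo: float = 0.0
    k_hi: float = 0.0
    published_domain_water: tuple[float, float] = (0.4, 4.0)

    def validate(self) -> None:
        if self.calibration_kind not in (KIND_LINEAR, KIND_PARTITION, KIND_PUBLISHED):
            raise ConfigError(
                f"family {self.family}: unknown calibration kind "
                f"{self.calibration_kind!r}"
            )
        if self.residual_sd < 0 or self.site_sd < 0:
            raise ConfigError(f"family {self.family}: SDs must be >= 0")
        if self.calibration_kind == KIND_PARTITION:
            if not (0 < self.k_lo <= self.k_hi):
                raise ConfigError(
                    f"family {self.family}: need 0 < k_lo <= k_hi, "
                    f"got ({self.k_lo}, {self.k_hi})"
                )

    def predict(self, water_srca: float, k: float | None = None) -> float:
        """Noise-free otolith Sr:Ca (μmol:mol) for a water value (mmol:mol)."""
        if self.calibration_kind == KIND_PARTITION:
            if k is None:
                k = 0.5 * (self.k_lo + self.k_hi)
            return k * water_srca
        return self.true_slope * water_srca + self.true_intercept


@dataclass(frozen=True)
class SpeciesSpec:
    """A species in the sampling design (role: predator|prey)."""

    species: str
    family: str
    role: str
    source: str  # "sampled" (independently collected) or "stomach" (consumed)


@dataclass
class ScenarioConfig:
    """Full synthetic-study description; see module docstring."""

    water_bodies: list[WaterBody]
    families: list[FamilyTruth]
    species: list[SpeciesSpec]
    pools: list[str] = field(default_factory=lambda: ["P4", "P8", "P13"])
    years: list[int] = field(default_factory=lambda: [2019, 2020])
    n_fish_per_group: int = 10
    n_reference_fish_per_body: int = 4
    n_water_samples: int = 40
    origin_proportions: dict[str, float] | None = None
    vaterite_fraction: float = 0.0
    drift_slope: float = 0.0
    count_noise_cv: float = 0.0
    block_interval: int = 15
    transect_length_um: float = 400.0
    step_um: float = 5.0
    seed: int = 0

    # -- derived helpers ---------------------------------------------------
    def body(self, body_id: str) -> WaterBody:
        for wb in self.water_bodies:
            if wb.id == body_id:
                return wb
        raise ConfigError(f"unknown water body id {body_id!r}")

    @property
    def mainstem_id(self) -> str:
        ids = [wb.id for wb in self.water_bodies if wb.role == MAINSTEM]
        if len(ids) != 1:
            raise ConfigError(f"expected exactly one mainstem, found {ids}")
        return ids[0]

    def family_truth(self, family: str) -> FamilyTruth:
        for ft in self.families:
            if ft.family == family:
                return ft
        raise ConfigError(f"unknown family {family!r}")

    @property
    def candidate_bodies(self) -> list[WaterBody]:
        return [wb for wb in self.water_bodies if wb.candidate_source]

    def resolved_origin_proportions(self) -> dict[str, float]:
        if self.origin_proportions is None:
            cand = self.candidate_bodies
            p = 1.0 / len(cand)
            return {wb.id: p for wb in cand}
        return dict(self.origin_proportions)

    def validate(self) -> None:
        if not self.water_bodies:
            raise ConfigError("at least one water body is required")
        ids = [wb.id for wb in self.water_bodies]
        if len(set(ids)) != len(ids):
            raise ConfigError("water body ids must be unique")
        for wb in self.water_bodies:
            wb.validate()
        _ = self.mainstem_id
        for ft in self.families:
            ft.validate()
        fams = {ft.family for ft in self.families}
        for sp in self.species:
            if sp.family not in fams:
                raise ConfigError(f"species {sp.species}: family {sp.family} undefined")
        if self.n_fish_per_group < 1:
            raise ConfigError("n_fish_per_group must be >= 1")
        if self.n_water_samples < 2:
            raise ConfigError("n_water_samples must be >= 2")
        if not (0.0 <= self.vaterite_fraction <= 1.0):
            raise ConfigError("vaterite_fraction must be in [0, 1]")
        if not self.candidate_bodies:
            raise ConfigError("at least one candidate recruitment source is required")
        props = self.resolved_origin_proportions()
        cand_ids = {wb.id for wb in self.candidate_bodies}
        unknown = set(props) - cand_ids
        if unknown:
            raise ConfigError(
                f"origin proportions name non-candidate bodies: {sorted(unknown)}"
            )
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"origin proportions sum to {total}, expected 1")
        if any(p < 0 for p in props.values()):
            raise ConfigError("origin proportions must be non-negative")
        if self.transect_length_um < 150.0:
            raise ConfigError(
                "transect_length_um must be >= 150 (core and edge windows overlap)"
            )
        if self.block_interval < 1:
            raise ConfigError("block_interval must be >= 1")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for ft in d["families"]:
            ft["published_domain_water"] = list(ft["published_domain_water"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        d["water_bodies"] = [WaterBody(**wb) for wb in d["water_bodies"]]
        fams = []
        for ft in d["families"]:
            ft = dict(ft)
            if "published_domain_water" in ft:
                ft["published_domain_water"] = tuple(ft["published_domain_water"])
            fams.append(FamilyTruth(**ft))
        d["families"] = fams
        d["species"] = [SpeciesSpec(**sp) for sp in d["species"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Reference scenarios
# ---------------------------------------------------------------------------

def _default_bodies() -> list[WaterBody]:
    # One high-Sr:Ca large tributary (MN), several low-Sr:Ca tributaries,
    # intermediate mainstem; medians are scenario constants, not estimates
    # of the real rivers. The two ponds are closed calibration-only sites
    # that extend the water-otolith model domain past every origin window.
    return [
        WaterBody("UMR", "Upper Mississippi", MAINSTEM, "multiple", 1.6, 0.12),
        WaterBody("MN", "Minnesota", TRIBUTARY, "P4", 3.4, 0.10),
        WaterBody("CAN", "Cannon", TRIBUTARY, "P4", 0.85, 0.10),
        WaterBody("CHP", "Chippewa", TRIBUTARY, "P4", 0.80, 0.12),
        WaterBody("ZMB", "Zumbro", TRIBUTARY, "P4", 0.75, 0.10),
        WaterBody("BLK", "Black", TRIBUTARY, "P8", 0.70, 0.10),
        WaterBody("WI", "Wisconsin", TRIBUTARY, "P8", 0.65, 0.10),
        WaterBody("MAQ", "Maquoketa", TRIBUTARY, "P13", 0.78, 0.10),
        WaterBody("PONDLO", "Low-Sr pond", TRIBUTARY, "P4", 0.50, 0.05,
                  candidate_source=False),
        WaterBody("PONDHI", "High-Sr pond", TRIBUTARY, "P4", 4.2, 0.05,
                  candidate_source=False),
    ]


_DEFAULT_PROPORTIONS = {
    "UMR": 0.45,
    "MN": 0.15,
    "WI": 0.08,
    "CHP": 0.07,
    "BLK": 0.07,
    "CAN": 0.06,
    "ZMB": 0.06,
    "MAQ": 0.06,
}

_DEFAULT_SPECIES = [
    SpeciesSpec("largemouth bass", "Centrarchidae", "predator", "sampled"),
    SpeciesSpec("bowfin", "Amiidae", "predator", "sampled"),
    SpeciesSpec("freshwater drum", "Sciaenidae", "prey", "stomach"),
    SpeciesSpec("channel catfish", "Ictaluridae", "prey", "stomach"),
    SpeciesSpec("bluegill", "Centrarchidae", "prey", "stomach"),
]


def default_scenario(seed: int = 0, n_fish_per_group: int = 10) -> ScenarioConfig:
    """Reference noisy scenario.

    Otolith-side noise (``site_sd``/``residual_sd``) is set to 10% of each
    family's mainstem window width; measurement-side noise (count CV, drift)
    is small relative to the chemistry signal.
    """
    # mainstem window widths at cv=0.12 (5th-95th of the log-normal spans
    # a factor exp(2*1.645*sigma) ~ 1.48): Sciaenidae ~213, Ictaluridae
    # ~124, Centrarchidae ~165, Amiidae (partition) ~130 umol:mol.
    families = [
        FamilyTruth("Sciaenidae", KIND_LINEAR, 337.04, -131.55, 21.0, 21.0),
        FamilyTruth("Ictaluridae", KIND_LINEAR, 196.04, 71.30, 12.0, 12.0),
        FamilyTruth("Centrarchidae", KIND_PUBLISHED, 260.0, -10.0, 16.0, 16.0),
        FamilyTruth("Amiidae", KIND_PARTITION, residual_sd=13.0, k_lo=96.9, k_hi=178.0),
    ]
    cfg = ScenarioConfig(
        water_bodies=_default_bodies(),
        families=families,
        species=list(_DEFAULT_SPECIES),
        n_fish_per_group=n_fish_per_group,
        origin_proportions=dict(_DEFAULT_PROPORTIONS),
        vaterite_fraction=0.04,
        drift_slope=0.02,
        count_noise_cv=0.002,
        seed=seed,
    )
    cfg.validate()
    return cfg


def noise_free_scenario(seed: int = 0, n_fish_per_group: int = 6) -> ScenarioConfig:
    """Zero-otolith-noise scenario with mutually separated origin windows.

    Otolith-side SDs, vaterite, drift and count noise are all zero; water
    CVs are small (4-5%) and medians spaced so that every linear-family
    window is disjoint from every other and no partition-family tributary
    window touches the mainstem window (k range [96.9, 178] forces a
    median ratio > 2.1 between the highest low tributary, the mainstem,
    and the high tributary). Classification must then recover the latent
    coarse origin category exactly.
    """
    bodies = [
        WaterBody("UMR", "Upper Mississippi", MAINSTEM, "multiple", 2.1, 0.04),
        WaterBody("MN", "Minnesota", TRIBUTARY, "P4", 4.6, 0.04),
        WaterBody("CAN", "Cannon", TRIBUTARY, "P4", 0.96, 0.04),
        WaterBody("CHP", "Chippewa", TRIBUTARY, "P8", 0.80, 0.04),
        WaterBody("ZMB", "Zumbro", TRIBUTARY, "P4", 0.66, 0.04),
        WaterBody("WI", "Wisconsin", TRIBUTARY, "P8", 0.55, 0.04),
        WaterBody("PONDLO", "Low-Sr pond", TRIBUTARY, "P4", 0.45, 0.05,
                  candidate_source=False),
        WaterBody("PONDHI", "High-Sr pond", TRIBUTARY, "P4", 5.5, 0.05,
                  candidate_source=False),
    ]
    families = [
        FamilyTruth("Sciaenidae", KIND_LINEAR, 337.04, -131.55, 0.0, 0.0),
        FamilyTruth("Ictaluridae", KIND_LINEAR, 196.04, 71.30, 0.0, 0.0),
        FamilyTruth("Centrarchidae", KIND_PUBLISHED, 260.0, -10.0, 0.0, 0.0,
                    published_domain_water=(0.3, 6.0)),
        FamilyTruth("Amiidae", KIND_PARTITION, residual_sd=0.0, k_lo=96.9, k_hi=178.0),
    ]
    cfg = ScenarioConfig(
        water_bodies=bodies,
        families=families,
        species=list(_DEFAULT_SPECIES),
        n_fish_per_group=n_fish_per_group,
        origin_proportions={
            "UMR": 0.45, "MN": 0.15, "WI": 0.10, "CHP": 0.10,
            "CAN": 0.10, "ZMB": 0.10,
        },
        vaterite_fraction=0.0,
        drift_slope=0.0,
        count_noise_cv=0.0,
        seed=seed,
    )
    cfg.validate()
    return cfg
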