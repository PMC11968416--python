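"""Synthetic water chemistry, fish cohorts and raw LA-ICPMS transects.

Everything downstream of field sampling is emulated here with the exact
statistical structure the analysis assumes, so the full pipeline is testable
without any external data:

* water Sr:Ca per body is log-normal (positive, right-skewed) parameterised
  by median and CV, so the 5th/95th percentile window has a closed form;
* otolith core Sr:Ca reflects the natal water through the family's true
  mapping plus a per-(family, body) site intercept and per-fish residual;
  the edge reflects the capture water the same way;
* raw counts carry an argon-blank offset, a multiplicative linear drift in
  standard-block index, and bracketing standard-block measurements that the
  reduction stage must invert;
* a configurable fraction of fish are vateritic: core Sr:Ca uniform on
  [50, 140] μmol:mol and core Mg:Ca uniform on [1100, 3000] μmol:mol, so the
  combination quality filter is unambiguous.

Latent truth (natal body, noise-free core value, vaterite flag) is emitted
alongside the fixtures for parameter-recovery tests.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as oio
from .config import KIND_PARTITION, FamilyTruth, ScenarioConfig
from .errors import ConfigError, GenerationError
from .transect_processing import (
    CA_ASSUMED_UGG,
    CHANNELS,
    MACS3_CERTIFIED_UGG,
    ratio_to_ugg,
)

# fixture instrument constants: per-channel sensitivity (counts per ug/g),
# argon-blank mean/SD (counts), and a per-channel drift multiplier so the
# three channels drift at slightly different rates.
SENSITIVITY = {"sr": 50.0, "mg": 30.0, "ca": 0.1}
BLANK_MEAN = {"sr": 100.0, "mg": 80.0, "ca": 200.0}
BLANK_SD = {"sr": 4.0, "mg": 3.0, "ca": 6.0}
DRIFT_CHANNEL_FACTOR = {"sr": 1.0, "mg": 0.9, "ca": 1.1}

VATERITE_SRCA_RANGE = (50.0, 140.0)
VATERITE_MGCA_RANGE = (1100.0, 3000.0)

#: core Mg:Ca for normal (aragonitic) otoliths, well below the 1000 cutoff
NORMAL_MGCA_RANGE = (200.0, 600.0)

N_STANDARD_REPLICATES = 3


def _lognormal_params(median: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and CV."""
    if cv < 0:
        raise ConfigError(f"CV must be >= 0, got {cv}")
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.log(median), sigma


def water_window_quantiles(
    median: float, cv: float, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> tuple[float, float]:
    """Closed-form (p_lo, p_hi) quantiles of the configured log-normal."""
    from scipy.stats import norm

    mu, sigma = _lognormal_params(median, cv)
    return (
        math.exp(mu + sigma * norm.ppf(lo_pct / 100.0)),
        math.exp(mu + sigma * norm.ppf(hi_pct / 100.0)),
    )


def generate_water_samples(
    config: ScenarioConfig, seed: int | np.random.Generator | None = None,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Draw per-body water Sr:Ca samples (mmol:mol).

    Returns a frame with columns ``body_id`` and ``srca_mmol_mol``; per body
    the samples are log-normal with the configured median and CV (a zero CV
    yields the median exactly).
    """
    rng = np.random.default_rng(seed)
    n = config.n_water_samples if n_samples is None else n_samples
    if n < 2:
        raise ConfigError("need at least 2 water samples per body")
    frames = []
    for wb in config.water_bodies:
        mu, sigma = _lognormal_params(wb.water_srca_median, wb.water_srca_cv)
        if sigma == 0.0:
            vals = np.full(n, wb.water_srca_median)
        else:
            vals = rng.lognormal(mean=mu, sigma=sigma, size=n)
        frames.append(pd.DataFrame({"body_id": wb.id, "srca_mmol_mol": vals}))
    return pd.concat(frames, ignore_index=True)


def generate_fish(
    config: ScenarioConfig, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the fish table and its latent truth.

    One group per (species × pool), ``n_fish_per_group`` fish each, years
    cycling through the configured list; natal origins are drawn from the
    configured origin proportions. A further ``n_reference_fish_per_body``
    resident fish per (data-calibrated family × body) provide the
    water-otolith calibration observations (``source="reference"``; their
    natal body equals their capture body).
    """
    rng = np.random.default_rng(seed)
    props = config.resolved_origin_proportions()
    body_ids = list(props)
    p = np.asarray([props[b] for b in body_ids], dtype=float)
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"origin proportions sum to {total}, expected 1")
    p = p / total

    fish_rows, truth_rows = [], []
    i = 0
    for sp in config.species:
        for pool in config.pools:
            for j in range(config.n_fish_per_group):
                fid = f"F{i:05d}"
                natal = body_ids[rng.choice(len(body_ids), p=p)]
                year = config.years[j % len(config.years)]
                fish_rows.append(
                    dict(fish_id=fid, species=sp.species, family=sp.family,
                         role=sp.role, source=sp.source, pool=pool, year=year,
                         capture_body=config.mainstem_id)
                )
                truth_rows.append(
                    dict(fish_id=fid, natal_body=natal,
                         capture_body=config.mainstem_id)
                )
                i += 1
    # reference (calibration) fish: residents spread across all bodies
    for ft in config.families:
        for wb in config.water_bodies:
            for _ in range(config.n_reference_fish_per_body):
                fid = f"F{i:05d}"
                fish_rows.append(
                    dict(fish_id=fid, species=f"{ft.family} reference",
                         family=ft.family, role="reference", source="reference",
                         pool="REF", year=config.years[0], capture_body=wb.id)
                )
                truth_rows.append(
                    dict(fish_id=fid, natal_body=wb.id, capture_body=wb.id)
                )
                i += 1
    return pd.DataFrame(fish_rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class _FishChemistry:
    core_srca: float  # noisy truth, umol:mol
    core_srca_nf: float  # noise-free counterpart (no site/residual noise)
    edge_srca: float
    core_mgca: float
    edge_mgca: float
    vaterite: bool


def _draw_site_effects(
    config: ScenarioConfig, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    eff = {}
    for ft in config.families:
        for wb in config.water_bodies:
            eff[(ft.family, wb.id)] = (
                rng.normal(0.0, ft.site_sd) if ft.site_sd > 0 else 0.0
            )
    return eff


def _draw_partition_ks(
    config: ScenarioConfig, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    ks = {}
    for ft in config.families:
        if ft.calibration_kind != KIND_PARTITION:
            continue
        for wb in config.water_bodies:
            ks[(ft.family, wb.id)] = rng.uniform(ft.k_lo, ft.k_hi)
    return ks


class _WaterProfiles:
    """Per-body central statistics of the generated water samples.

    A fish's otolith core/edge integrates weeks-to-months of exposure, so
    the chemistry a fish records is drawn from the central 80% (10th-90th
    percentile) of its body's water profile rather than from single grab
    samples; calibration reference fish, resident for life, record the
    body's mean.
    """

    def __init__(self, water: pd.DataFrame):
        g = water.groupby("body_id")["srca_mmol_mol"]
        self.q10 = g.quantile(0.10).to_dict()
        self.q90 = g.quantile(0.90).to_dict()
        self.mean = g.mean().to_dict()

    def draw(self, body_id: str, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.q10[body_id], self.q90[body_id]))


def synthesize_transect(
    chem: _FishChemistry,
    config: ScenarioConfig,
    position: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw counts for one ablation transect.

    The transect starts 100 μm before the core, so the core sits at
    distance 100 μm; Sr:Ca is held at the core value through 130 μm, ramps
    linearly to the edge value, and holds that over the final 50 μm. Counts
    are ``ablation_yield × concentration × sensitivity × drift`` plus the
    argon blank, with optional multiplicative measurement noise.
    """
    length = config.transect_length_um
    if length < 150.0:
        raise GenerationError(
            f"transect of {length} um cannot hold disjoint core and edge windows"
        )
    d = np.arange(0.0, length + 0.5 * config.step_um, config.step_um)

    def _profile(core: float, edge: float) -> np.ndarray:
        ramp_lo, ramp_hi = 130.0, length - 50.0
        vals = np.empty_like(d)
        vals[d <= ramp_lo] = core
        vals[d >= ramp_hi] = edge
        mid = (d > ramp_lo) & (d < ramp_hi)
        frac = (d[mid] - ramp_lo) / (ramp_hi - ramp_lo)
        vals[mid] = core + frac * (edge - core)
        return vals

    srca = _profile(chem.core_srca, chem.edge_srca)
    mgca = _profile(chem.core_mgca, chem.edge_mgca)

    ca_ugg = CA_ASSUMED_UGG
    sr_ugg = ratio_to_ugg(srca, "sr", ca_ugg)
    mg_ugg = ratio_to_ugg(mgca, "mg", ca_ugg)
    conc = {"sr": sr_ugg, "mg": mg_ugg, "ca": np.full_like(d, ca_ugg)}

    ablation_yield = 1.0 + 0.08 * np.sin(d / 40.0)  # spatially varying mass removal
    out = {"distance_um": d}
    for ch in CHANNELS:
        drift = 1.0 + config.drift_slope * DRIFT_CHANNEL_FACTOR[ch] * position
        counts = ablation_yield * conc[ch] * SENSITIVITY[ch] * drift
        if config.count_noise_cv > 0:
            counts = counts * (1.0 + rng.normal(0.0, config.count_noise_cv, d.size))
        out[ch] = counts + BLANK_MEAN[ch]
    return pd.DataFrame(out)


def _standards_table(
    n_blocks: int, drift_slope: float, count_noise_cv: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for b in range(n_blocks + 1):
        for rep in range(N_STANDARD_REPLICATES):
            row = {"block_index": b, "position": float(b), "replicate": rep}
            for ch in CHANNELS:
                drift = 1.0 + drift_slope * DRIFT_CHANNEL_FACTOR[ch] * b
                counts = MACS3_CERTIFIED_UGG[ch] * SENSITIVITY[ch] * drift
                if count_noise_cv > 0:
                    counts *= 1.0 + rng.normal(0.0, count_noise_cv)
                row[ch] = counts + BLANK_MEAN[ch]
            rows.append(row)
    return pd.DataFrame(rows)


def _blanks_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": list(CHANNELS),
            "mean": [BLANK_MEAN[c] for c in CHANNELS],
            "sd": [BLANK_SD[c] for c in CHANNELS],
        }
    )


def generate_dataset(
    config: ScenarioConfig, out_dir: str, seed: int | None = None
) -> dict[str, str]:
    """Write the full fixture set for one scenario; returns the file map.

    Files: ``water.csv``, ``fish.csv``, ``truth.csv``, ``standards.csv``,
    ``blanks.csv`` and one raw transect per fish under ``transects/``.
    Identical (config, seed) pairs produce byte-identical files.
    """
    config.validate()
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    rng_water, rng_fish, rng_chem, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    os.makedirs(os.path.join(out_dir, "transects"), exist_ok=True)
    water = generate_water_samples(config, rng_water)
    fish, truth = generate_fish(config, rng_fish)

    site = _draw_site_effects(config, rng_chem)
    part_k = _draw_partition_ks(config, rng_chem)
    profiles = _WaterProfiles(water)
    n_fish = len(fish)
    vaterite_flags = rng_chem.random(n_fish) < config.vaterite_fraction

    chem_rows = []
    for idx, (frow, trow) in enumerate(zip(fish.itertuples(), truth.itertuples())):
        ft: FamilyTruth = config.family_truth(frow.family)
        natal = config.body(trow.natal_body)
        capture = config.body(trow.capture_body)
        if frow.source == "reference":
            # life-long residents: otolith chemistry reflects the body mean
            w_natal = w_capture = profiles.mean[capture.id]
        else:
            w_natal = profiles.draw(natal.id, rng_chem)
            w_capture = profiles.draw(capture.id, rng_chem)
        k_natal = part_k.get((ft.family, natal.id))
        k_capture = part_k.get((ft.family, capture.id))
        core_nf = ft.predict(w_natal, k_natal)
        edge_nf = ft.predict(w_capture, k_capture)
        resid = rng_chem.normal(0.0, ft.residual_sd, 2) if ft.residual_sd > 0 else (0.0, 0.0)
        core = core_nf + site[(ft.family, natal.id)] + resid[0]
        edge = edge_nf + site[(ft.family, capture.id)] + resid[1]
        core_mg = rng_chem.uniform(*NORMAL_MGCA_RANGE)
        edge_mg = rng_chem.uniform(*NORMAL_MGCA_RANGE)
        if vaterite_flags[idx]:
            core = rng_chem.uniform(*VATERITE_SRCA_RANGE)
            core_mg = rng_chem.uniform(*VATERITE_MGCA_RANGE)
        chem_rows.append(
            _FishChemistry(core_srca=max(core, 1.0), core_srca_nf=core_nf,
                           edge_srca=max(edge, 1.0), core_mgca=core_mg,
                           edge_mgca=edge_mg, vaterite=bool(vaterite_flags[idx]))
        )

    n_blocks = max(1, math.ceil(n_fish / config.block_interval))
    paths = {
        "water": os.path.join(out_dir, "water.csv"),
        "fish": os.path.join(out_dir, "fish.csv"),
        "truth": os.path.join(out_dir, "truth.csv"),
        "standards": os.path.join(out_dir, "standards.csv"),
        "blanks": os.path.join(out_dir, "blanks.csv"),
        "transects": os.path.join(out_dir, "transects"),
    }

    positions = (np.arange(n_fish) + 0.5) / config.block_interval
    fish = fish.assign(block_position=positions)
    for idx, frow in enumerate(fish.itertuples()):
        tdf = synthesize_transect(chem_rows[idx], config, positions[idx], rng_counts)
        oio.write_csv(tdf, os.path.join(paths["transects"], f"{frow.fish_id}.csv"))

    truth = truth.assign(
        natal_water_srca=[np.nan] * n_fish,  # filled below
        core_srca_true=[c.core_srca for c in chem_rows],
        core_srca_noise_free=[c.core_srca_nf for c in chem_rows],
        edge_srca_true=[c.edge_srca for c in chem_rows],
        vaterite=[c.vaterite for c in chem_rows],
    )
    # noise-free core back-solved through the truth map is the natal water
    # signal; store the core-level value, the water draw itself is internal
    truth = truth.drop(columns=["natal_water_srca"])

    oio.write_csv(water, paths["water"])
    oio.write_csv(fish, paths["fish"])
    oio.write_csv(truth, paths["truth"])
    oio.write_csv(
        _standards_table(n_blocks, config.drift_slope, config.count_noise_cv, rng_counts),
        paths["standards"],
    )
    oio.write_csv(_blanks_table(), paths["blanks"])
    return paths
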