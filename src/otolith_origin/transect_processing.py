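"""Reduce raw LA-ICPMS transects to Sr:Ca / Mg:Ca profiles and summaries.

The reduction chain is: argon-blank subtraction → drift correction against
bracketing CaCO₃ standard blocks → quantification with Ca as the
pseudo-internal standard → molar-ratio conversion → core/edge summaries
with a vaterite quality flag. All steps are per-channel linear, so the
whole chain is scale-invariant: multiplying every raw channel by c > 0
leaves the ratio outputs unchanged.

Conventions (configurable where noted):

* the transect starts 100 μm before the core, so the core window is the
  closed interval [75, 125] μm and the edge window is the final 50 μm;
* assumed otolith Ca content is 38.8 wt% (aragonite) for the
  pseudo-internal standard;
* drift is interpolated linearly in standard-block index with constant
  extrapolation outside the bracketing blocks;
* limit of detection is 3×SD of the gas blank divided by sensitivity;
  points below LOD are retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ReductionError, SummaryError

CHANNELS = ("sr", "mg", "ca")

#: atomic weights (g/mol)
MW = {"sr": 87.62, "mg": 24.305, "ca": 40.078}

#: MACS-3 certified concentrations used by the fixtures (μg/g)
MACS3_CERTIFIED_UGG = {"sr": 6700.0, "mg": 1755.0, "ca": 379000.0}

#: assumed otolith Ca content: 38.8 wt%
CA_ASSUMED_PCT = 38.8
CA_ASSUMED_UGG = CA_ASSUMED_PCT * 1e4

#: vaterite thresholds, strict inequalities, applied in combination
VATERITE_SRCA_MAX = 150.0
VATERITE_MGCA_MIN = 1000.0


def to_molar_ratio(elem_ugg, ca_ugg, element: str = "sr"):
    """Element:Ca molar ratio in μmol:mol from mass concentrations.

    ratio = (elem/MW_elem) / (ca/MW_ca) × 1e6.
    """
    elem_ugg = np.asarray(elem_ugg, dtype=float)
    ca_ugg = np.asarray(ca_ugg, dtype=float)
    if np.any(ca_ugg <= 0):
        raise ReductionError("nonpositive Ca concentration in molar-ratio conversion")
    return (elem_ugg / MW[element]) / (ca_ugg / MW["ca"]) * 1e6


def ratio_to_ugg(ratio_umol_mol, element: str, ca_ugg):
    """Inverse of :func:`to_molar_ratio` (used by the synthetic generator)."""
    ratio = np.asarray(ratio_umol_mol, dtype=float)
    return ratio * 1e-6 * MW[element] * (np.asarray(ca_ugg, dtype=float) / MW["ca"])


def flag_vaterite(
    core_srca: float,
    core_mgca: float,
    srca_max: float = VATERITE_SRCA_MAX,
    mgca_min: float = VATERITE_MGCA_MIN,
) -> bool:
    """True iff core Sr:Ca < ``srca_max`` AND core Mg:Ca > ``mgca_min``.

    Both conditions are required in combination; boundary values do not
    trigger the flag.
    """
    if core_srca < 0 or core_mgca < 0:
        raise ReductionError("molar ratios must be >= 0")
    return (core_srca < srca_max) and (core_mgca > mgca_min)


class StandardSeries:
    """Bracketing standard-block measurements for one session.

    Built from the replicate standard table (columns ``block_index``,
    ``position``, ``replicate``, one column per channel) and the blank
    means; exposes per-channel sensitivity (counts per μg/g) interpolated
    linearly in block position, with constant extrapolation outside the
    measured blocks.
    """

    def __init__(
        self,
        standards: pd.DataFrame,
        blank_means: dict[str, float],
        certified_ugg: dict[str, float] | None = None,
    ):
        certified = dict(certified_ugg or MACS3_CERTIFIED_UGG)
        for ch in CHANNELS:
            if certified.get(ch, 0) <= 0:
                raise ReductionError(f"certified concentration for {ch} must be > 0")
        if standards.empty:
            raise ReductionError("at least one standard block is required")
        means = standards.groupby("position", sort=True)[list(CHANNELS)].mean()
        self.positions = means.index.to_numpy(dtype=float)
        self.sensitivity = {}
        for ch in CHANNELS:
            net = means[ch].to_numpy(dtype=float) - blank_means[ch]
            if np.any(net <= 0):
                raise ReductionError(f"zero/negative net standard counts for {ch}")
            self.sensitivity[ch] = net / certified[ch]
        self.certified = certified

    def sensitivity_at(self, channel: str, position: float) -> float:
        return float(
            np.interp(position, self.positions, self.sensitivity[channel])
        )

    def relative_sensitivity(self, channel: str, position: float) -> float:
        """Sensitivity at ``position`` relative to the first block."""
        return self.sensitivity_at(channel, position) / self.sensitivity[channel][0]

    def reference_count_ratio(self, num: str, den: str) -> float:
        """Net count ratio num/den of the first (reference) block."""
        return float(self.sensitivity[num][0] * self.certified[num]) / float(
            self.sensitivity[den][0] * self.certified[den]
        )


def subtract_blank(points: pd.DataFrame, blank_means: dict[str, float]) -> pd.DataFrame:
    """Subtract per-channel gas-blank means, flooring at zero."""
    out = points.copy()
    for ch in CHANNELS:
        if ch not in blank_means:
            raise ReductionError(f"missing blank mean for channel {ch!r}")
        if blank_means[ch] < 0:
            raise ReductionError(f"blank mean for {ch!r} must be >= 0")
        out[ch] = np.maximum(points[ch].to_numpy(dtype=float) - blank_means[ch], 0.0)
    return out


def correct_drift(
    points: pd.DataFrame, standards: StandardSeries, position: float
) -> pd.DataFrame:
    """Divide each channel by its relative sensitivity at ``position``.

    With identical standard blocks the relative sensitivity is 1 and the
    transect is returned unchanged.
    """
    out = points.copy()
    for ch in CHANNELS:
        out[ch] = points[ch].to_numpy(dtype=float) / standards.relative_sensitivity(
            ch, position
        )
    return out


def quantify(
    points: pd.DataFrame,
    standards: StandardSeries,
    ca_internal_pct: float = CA_ASSUMED_PCT,
) -> pd.DataFrame:
    """Convert blank/drift-corrected counts to concentrations (μg/g).

    Ratio method with Ca as the pseudo-internal standard::

        conc_e = (counts_e / counts_Ca) / R_std(e:Ca) × (cert_e / cert_Ca)
                 × assumed otolith Ca

    Points with non-positive Ca counts are flagged ``invalid`` and excluded
    from downstream summaries rather than raising.
    """
    if not 0 < ca_internal_pct <= 100:
        raise ReductionError("ca_internal_pct must be in (0, 100]")
    ca_assumed = ca_internal_pct * 1e4
    ca = points["ca"].to_numpy(dtype=float)
    invalid = ca <= 0
    safe_ca = np.where(invalid, np.nan, ca)
    out = pd.DataFrame({"distance_um": points["distance_um"].to_numpy(dtype=float)})
    for ch in ("sr", "mg"):
        r_sample = points[ch].to_numpy(dtype=float) / safe_ca
        r_std = standards.reference_count_ratio(ch, "ca")
        cert_ratio = standards.certified[ch] / standards.certified["ca"]
        out[f"{ch}_ugg"] = r_sample / r_std * cert_ratio * ca_assumed
    out["ca_ugg"] = np.where(invalid, np.nan, ca_assumed)
    out["invalid"] = invalid
    return out


def detection_limits(
    blank_sd: dict[str, float], standards: StandardSeries, position: float
) -> dict[str, float]:
    """Per-channel LOD in μg/g: 3×SD(blank) / sensitivity."""
    return {
        ch: 3.0 * blank_sd[ch] / standards.sensitivity_at(ch, position)
        for ch in CHANNELS
    }


def reduce_transect(
    raw: pd.DataFrame,
    blanks: pd.DataFrame,
    standards: StandardSeries,
    position: float,
    ca_internal_pct: float = CA_ASSUMED_PCT,
) -> pd.DataFrame:
    """Full reduction of one raw transect to molar-ratio profiles.

    Returns distance, ``srca_umol_mol``, ``mgca_umol_mol``, the ``invalid``
    flag (non-positive Ca counts) and ``below_lod`` flags per element.
    """
    d = raw["distance_um"].to_numpy(dtype=float)
    if d.size < 2 or np.any(np.diff(d) <= 0):
        raise ReductionError("transect distances must be strictly increasing")
    blank_means = dict(zip(blanks["channel"], blanks["mean"].astype(float)))
    blank_sd = dict(zip(blanks["channel"], blanks["sd"].astype(float)))
    pts = subtract_blank(raw, blank_means)
    pts = correct_drift(pts, standards, position)
    conc = quantify(pts, standards, ca_internal_pct)
    lod = detection_limits(blank_sd, standards, position)
    with np.errstate(invalid="ignore"):
        conc["srca_umol_mol"] = (
            conc["sr_ugg"] / MW["sr"] / (conc["ca_ugg"] / MW["ca"]) * 1e6
        )
        conc["mgca_umol_mol"] = (
            conc["mg_ugg"] / MW["mg"] / (conc["ca_ugg"] / MW["ca"]) * 1e6
        )
        conc["sr_below_lod"] = conc["sr_ugg"] < lod["sr"]
        conc["mg_below_lod"] = conc["mg_ugg"] < lod["mg"]
    return conc


@dataclass(frozen=True)
class OtolithSummary:
    """Core/edge summary of one reduced transect."""

    fish_id: str
    core_srca: float
    core_mgca: float
    edge_srca: float
    vaterite: bool
    n_core_points: int
    n_edge_points: int


def summarize(
    profile: pd.DataFrame,
    fish_id: str,
    core_position_um: float = 100.0,
    window_um: float = 50.0,
    vaterite_srca_max: float = VATERITE_SRCA_MAX,
    vaterite_mgca_min: float = VATERITE_MGCA_MIN,
) -> OtolithSummary:
    """Core and edge means of a reduced profile.

    Core = mean over the closed interval ``core_position ± window/2``;
    edge = mean over the final ``window_um`` of the transect. The transect
    must span the core window and leave at least ``window_um`` of tail
    beyond it.
    """
    d = profile["distance_um"].to_numpy(dtype=float)
    half = window_um / 2.0
    lo, hi = core_position_um - half, core_position_um + half
    if d.min() > lo or d.max() < hi + window_um:
        raise SummaryError(
            f"transect [{d.min()}, {d.max()}] um too short for core window "
            f"[{lo}, {hi}] um plus a {window_um} um edge window"
        )
    ok = ~profile["invalid"].to_numpy(dtype=bool)
    core_mask = (d >= lo) & (d <= hi) & ok
    edge_mask = (d >= d.max() - window_um) & ok
    if not core_mask.any():
        raise SummaryError(f"empty core window [{lo}, {hi}] um")
    if not edge_mask.any():
        raise SummaryError(f"empty edge window (last {window_um} um)")
    core_srca = float(profile.loc[core_mask, "srca_umol_mol"].mean())
    core_mgca = float(profile.loc[core_mask, "mgca_umol_mol"].mean())
    edge_srca = float(profile.loc[edge_mask, "srca_umol_mol"].mean())
    return OtolithSummary(
        fish_id=fish_id,
        core_srca=core_srca,
        core_mgca=core_mgca,
        edge_srca=edge_srca,
        vaterite=flag_vaterite(core_srca, core_mgca, vaterite_srca_max, vaterite_mgca_min),
        n_core_points=int(core_mask.sum()),
        n_edge_points=int(edge_mask.sum()),
    )


def reduce_dataset(
    transect_dir: str,
    fish: pd.DataFrame,
    standards_df: pd.DataFrame,
    blanks: pd.DataFrame,
    ca_internal_pct: float = CA_ASSUMED_PCT,
    vaterite_srca_max: float = VATERITE_SRCA_MAX,
    vaterite_mgca_min: float = VATERITE_MGCA_MIN,
) -> pd.DataFrame:
    """Reduce every fish's raw transect to a summary row.

    Returns a frame with columns fish_id, core_srca, core_mgca, edge_srca,
    vaterite, n_core_points, n_edge_points (ratios in μmol:mol).
    """
    import os

    from . import io as oio

    blank_means = dict(zip(blanks["channel"], blanks["mean"].astype(float)))
    standards = StandardSeries(standards_df, blank_means)
    rows = []
    for frow in fish.itertuples():
        raw = oio.read_transect(os.path.join(transect_dir, f"{frow.fish_id}.csv"))
        position = float(getattr(frow, "block_position", 0.0))
        profile = reduce_transect(raw, blanks, standards, position, ca_internal_pct)
        s = summarize(
            profile, frow.fish_id,
            vaterite_srca_max=vaterite_srca_max,
            vaterite_mgca_min=vaterite_mgca_min,
        )
        rows.append(dataclass_to_row(s))
    return pd.DataFrame(rows)


def dataclass_to_row(s: OtolithSummary) -> dict:
    return dict(
        fish_id=s.fish_id, core_srca=s.core_srca, core_mgca=s.core_mgca,
        edge_srca=s.edge_srca, vaterite=s.vaterite,
        n_core_points=s.n_core_points, n_edge_points=s.n_edge_points,
    )
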