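"""Predicted otolith-core Sr:Ca intervals per water body and family.

Each water body's water-chemistry distribution is reduced to its empirical
5th/95th percentiles and pushed through the family's calibration:

* linear kinds: ``[slope·p5 + intercept, slope·p95 + intercept]``;
* partition kinds: ``[k_lo·p5, k_hi·p95]`` (lowest coefficient times the
  lower percentile, highest times the upper).

Windows are intersected with the family's model limits (predictions at the
calibration domain endpoints); a window that only partially fits is
truncated and flagged, one wholly outside is dropped. Percentiles use
linear interpolation between closest order statistics (the type-7
convention, numpy's default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .errors import ConfigError


@dataclass(frozen=True)
class OriginWindow:
    """Predicted otolith-core Sr:Ca interval for one body and family."""

    water_body_id: str
    family: str
    lo: float
    hi: float
    truncated: bool = False
    dropped: bool = False

    def contains(self, value: float) -> bool:
        return (not self.dropped) and self.lo <= value <= self.hi


def water_percentiles(
    samples, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> tuple[float, float]:
    """Empirical (p_lo, p_hi) of water Sr:Ca samples, type-7 interpolation."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ConfigError("need >= 2 water samples for percentiles")
    if not lo_pct < hi_pct:
        raise ConfigError("lower percentile must be below upper")
    p = np.percentile(arr, [lo_pct, hi_pct])  # linear interpolation
    return float(p[0]), float(p[1])


def _truncate(
    body_id: str, family: str, lo: float, hi: float,
    limits: tuple[float, float], truncate: bool = True,
) -> OriginWindow:
    mn, mx = limits
    new_lo, new_hi = max(lo, mn), min(hi, mx)
    if new_lo > new_hi:  # entirely outside the model's validity domain
        return OriginWindow(body_id, family, lo, hi, truncated=False, dropped=True)
    was_truncated = (new_lo > lo) or (new_hi < hi)
    if was_truncated and not truncate:
        return OriginWindow(body_id, family, lo, hi, truncated=False, dropped=True)
    return OriginWindow(body_id, family, new_lo, new_hi, truncated=was_truncated)


def predict_window_linear(
    model: CalibrationModel, p5: float, p95: float,
    body_id: str = "", truncate: bool = True,
) -> OriginWindow:
    """Window from a linear calibration, clipped to the model limits."""
    if model.kind != "linear":
        raise ConfigError(f"model for {model.family} is not linear")
    lo = model.slope * p5 + model.intercept
    hi = model.slope * p95 + model.intercept
    lo, hi = min(lo, hi), max(lo, hi)
    return _truncate(body_id, model.family, lo, hi, model.model_limits(), truncate)


def predict_window_partition(
    k_lo: float, k_hi: float, p5: float, p95: float,
    body_id: str = "", family: str = "",
    limits: tuple[float, float] | None = None, truncate: bool = True,
) -> OriginWindow:
    """Window from partition coefficients: [k_lo·p5, k_hi·p95]."""
    if not 0 < k_lo <= k_hi:
        raise ConfigError("need 0 < k_lo <= k_hi")
    lo, hi = k_lo * p5, k_hi * p95
    if limits is None:
        return OriginWindow(body_id, family, lo, hi)
    return _truncate(body_id, family, lo, hi, limits, truncate)


def predict_window(
    model: CalibrationModel, p5: float, p95: float,
    body_id: str, truncate: bool = True,
) -> OriginWindow:
    if model.kind == "partition":
        return predict_window_partition(
            model.k_lo, model.k_hi, p5, p95, body_id=body_id,
            family=model.family, limits=model.model_limits(), truncate=truncate,
        )
    return predict_window_linear(model, p5, p95, body_id=body_id, truncate=truncate)


def build_windows(
    models: dict[str, CalibrationModel],
    water: pd.DataFrame,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    truncate: bool = True,
) -> pd.DataFrame:
    """One window per (family, water body).

    ``water`` holds per-body samples (columns ``body_id``,
    ``srca_mmol_mol``). Returns a frame with columns family,
    water_body_id, lo, hi, truncated, dropped.
    """
    rows = []
    for fam, model in sorted(models.items()):
        for body_id, sub in water.groupby("body_id", sort=True):
            p5, p95 = water_percentiles(sub["srca_mmol_mol"], lo_pct, hi_pct)
            w = predict_window(model, p5, p95, body_id=str(body_id), truncate=truncate)
            rows.append(
                dict(family=fam, water_body_id=w.water_body_id, lo=w.lo, hi=w.hi,
                     truncated=w.truncated, dropped=w.dropped)
            )
    return pd.DataFrame(rows)


def windows_from_frame(df: pd.DataFrame, family: str) -> list[OriginWindow]:
    sub = df[df["family"] == family]
    return [
        OriginWindow(r.water_body_id, family, float(r.lo), float(r.hi),
                     bool(r.truncated), bool(r.dropped))
        for r in sub.itertuples()
    ]
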