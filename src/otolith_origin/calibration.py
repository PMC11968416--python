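"""Family-specific water→otolith Sr:Ca calibrations.

Two calibration kinds are supported:

* a weighted random-intercept linear model — otolith edge Sr:Ca (μmol:mol)
  regressed on mean water Sr:Ca (mmol:mol) with sampling location as a
  random intercept, fit by REML. Locations enter with variance weights
  inversely proportional to their sample share so that no single heavily
  sampled location dominates the fit;
* a partition-coefficient pair — for families whose capture sites span too
  narrow a water Sr:Ca range to regress, the per-body ratio of mean otolith
  edge Sr:Ca to mean water Sr:Ca, summarised by its minimum and maximum
  over bodies.

Pre-published families enter as supplied coefficients (no refit).

The REML fitter is written here because the per-location variance-weight
structure is not expressible in the standard mixed-model APIs; it profiles
the fixed effects by GLS and optimises the two variance components with a
Woodbury-form marginal covariance per location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CalibrationError

WEIGHT_EQUAL_LOCATION = "equal_location"
WEIGHT_NONE = "none"


@dataclass
class CalibrationModel:
    """A fitted (or supplied) water→otolith Sr:Ca relation.

    ``kind`` is ``"linear"`` (slope/intercept in μmol:mol per mmol:mol and
    μmol:mol) or ``"partition"`` (k_lo/k_hi otolith:water ratios).
    ``domain_water`` is the water Sr:Ca range the relation is valid over;
    predictions at its endpoints define the model limits used by
    classification.
    """

    family: str
    kind: str
    slope: float = float("nan")
    intercept: float = float("nan")
    site_intercept_sd: float = float("nan")
    residual_sd: float = float("nan")
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    f_stat: float = float("nan")
    df_num: int = 1
    df_den: int = 0
    domain_water: tuple[float, float] = (float("nan"), float("nan"))
    k_lo: float = float("nan")
    k_hi: float = float("nan")
    k_per_body: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    n_locations: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "partition"):
            raise CalibrationError(f"unknown calibration kind {self.kind!r}")
        lo, hi = self.domain_water
        if not (math.isnan(lo) or math.isnan(hi)) and not lo < hi:
            raise CalibrationError(f"domain lo must be < hi, got {self.domain_water}")
        if self.kind == "partition" and not (
            math.isnan(self.k_lo) or 0 < self.k_lo <= self.k_hi
        ):
            raise CalibrationError("partition kind needs 0 < k_lo <= k_hi")

    def predict(self, water_srca) -> np.ndarray:
        """Predicted otolith Sr:Ca (μmol:mol); partition kind uses midpoint k."""
        x = np.asarray(water_srca, dtype=float)
        if self.kind == "partition":
            return 0.5 * (self.k_lo + self.k_hi) * x
        return self.slope * x + self.intercept

    def model_limits(self) -> tuple[float, float]:
        """Otolith-chemistry validity bounds (μmol:mol).

        Linear kinds: predictions at the water-domain endpoints; partition
        kinds: [k_lo × domain lo, k_hi × domain hi].
        """
        lo, hi = self.domain_water
        if self.kind == "partition":
            return (self.k_lo * lo, self.k_hi * hi)
        a, b = self.slope * lo + self.intercept, self.slope * hi + self.intercept
        return (min(a, b), max(a, b))

    def to_dict(self) -> dict:
        d = dict(
            family=self.family, kind=self.kind, slope=self.slope,
            intercept=self.intercept, site_intercept_sd=self.site_intercept_sd,
            residual_sd=self.residual_sd, r2_marginal=self.r2_marginal,
            r2_conditional=self.r2_conditional, f_stat=self.f_stat,
            df_num=self.df_num, df_den=self.df_den,
            domain_water=list(self.domain_water), k_lo=self.k_lo, k_hi=self.k_hi,
            k_per_body=dict(self.k_per_body), n_obs=self.n_obs,
            n_locations=self.n_locations,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["domain_water"] = tuple(d["domain_water"])
        return cls(**d)

    @classmethod
    def published(
        cls, family: str, slope: float, intercept: float,
        domain_water: tuple[float, float],
    ) -> "CalibrationModel":
        """A prior-study linear relation supplied by configuration."""
        return cls(family=family, kind="linear", slope=slope, intercept=intercept,
                   domain_water=tuple(domain_water))


def location_weights(locations: np.ndarray, scheme: str = WEIGHT_EQUAL_LOCATION) -> np.ndarray:
    """Per-observation variance weights.

    ``equal_location``: w_i = (N/L)/n_loc(i) — inverse of the location's
    sample share, so each location contributes equally; normalised to mean
    one. ``none``: all ones.
    """
    locations = np.asarray(locations)
    n = locations.size
    if scheme == WEIGHT_NONE:
        return np.ones(n)
    if scheme != WEIGHT_EQUAL_LOCATION:
        raise CalibrationError(f"unknown weight scheme {scheme!r}")
    uniq, counts = np.unique(locations, return_counts=True)
    per_loc = {u: (n / uniq.size) / c for u, c in zip(uniq, counts)}
    return np.asarray([per_loc[loc] for loc in locations], dtype=float)


def _reml_criterion(
    log_s2: float, log_t2: float, groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
) -> tuple[float, np.ndarray, np.ndarray]:
    """REML deviance plus GLS pieces for variance components (σ², τ²).

    Each group carries (X_j, y_j, w_j); V_j = σ² diag(1/w) + τ² 11'. Uses
    the Woodbury identity so only scalars are inverted.
    """
    s2, t2 = math.exp(log_s2), math.exp(log_t2)
    p = groups[0][0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for X, y, w in groups:
        # V^{-1} = W/s2 - (t2/s2) * (W1)(1'W) / (s2 + t2 * s_w)
        sw = float(w.sum())
        c = t2 / (s2 * (s2 + t2 * sw))
        Xw = X * w[:, None]
        yw = y * w
        x1 = Xw.sum(axis=0)  # X' W 1
        y1 = float(yw.sum())  # 1' W y
        xtvx += (X.T @ Xw) / s2 - c * np.outer(x1, x1)
        xtvy += (X.T @ yw) / s2 - c * x1 * y1
        ytvy += float(y @ yw) / s2 - c * y1 * y1
        logdet += y.size * math.log(s2) - float(np.log(w).sum()) + math.log1p(
            t2 * sw / s2
        )
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - float(beta @ xtvy)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise CalibrationError("singular design in mixed-model fit")
    crit = logdet + logdet_xtvx + max(quad, 0.0)
    return crit, beta, np.linalg.inv(xtvx)


def fit_linear_mixed(
    data: pd.DataFrame,
    x: str = "water_srca",
    y: str = "edge_srca",
    group: str = "location",
    family: str = "",
    weight_scheme: str = WEIGHT_EQUAL_LOCATION,
) -> CalibrationModel:
    """REML fit of the weighted random-intercept calibration.

    ``data`` has one row per fish: its sampling location, the location's
    mean water Sr:Ca (mmol:mol) and the fish's otolith edge Sr:Ca
    (μmol:mol). Requires ≥3 locations spanning a non-zero water range.

    Returns a :class:`CalibrationModel` with the fixed-effect slope and
    intercept, variance components, Nakagawa marginal/conditional R², the
    Wald F statistic for the water effect (denominator df = locations − 2)
    and ``domain_water`` set to the observed water range.
    """
    df = data[[group, x, y]].dropna()
    locs = df[group].to_numpy()
    uniq = np.unique(locs)
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if uniq.size < 3:
        raise CalibrationError(
            f"need >= 3 sampling locations, got {uniq.size}"
        )
    if np.ptp(xv) <= 0:
        raise CalibrationError("water Sr:Ca range is zero; fit is singular")
    w = location_weights(locs, weight_scheme)
    X = np.column_stack([np.ones_like(xv), xv])
    groups = []
    for u in uniq:
        m = locs == u
        groups.append((X[m], yv[m], w[m]))

    # initial values from an OLS fit
    beta0, res0, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid0 = yv - X @ beta0
    v0 = max(float(np.var(resid0)), 1e-8)
    start = np.log([v0 * 0.7, v0 * 0.3 + 1e-10])

    def objective(theta):
        ls2, lt2 = np.clip(theta, -40.0, 40.0)
        try:
            crit, _, _ = _reml_criterion(ls2, lt2, groups)
        except np.linalg.LinAlgError:
            return 1e12
        return crit

    opt = optimize.minimize(
        objective, start, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    ls2, lt2 = np.clip(opt.x, -40.0, 40.0)
    _, beta, cov = _reml_criterion(ls2, lt2, groups)
    s2, t2 = math.exp(ls2), math.exp(lt2)

    intercept, slope = float(beta[0]), float(beta[1])
    se_slope = math.sqrt(max(cov[1, 1], 0.0))
    f_stat = (slope / se_slope) ** 2 if se_slope > 0 else float("inf")
    df_den = int(uniq.size - 2)

    # Nakagawa R^2: variance explained by fixed effects vs. total
    var_fixed = float(np.var(slope * xv))
    s2_mean = s2 * float(np.mean(1.0 / w))
    denom = var_fixed + t2 + s2_mean
    r2m = var_fixed / denom if denom > 0 else float("nan")
    r2c = (var_fixed + t2) / denom if denom > 0 else float("nan")

    return CalibrationModel(
        family=family, kind="linear", slope=slope, intercept=intercept,
        site_intercept_sd=math.sqrt(t2), residual_sd=math.sqrt(s2),
        r2_marginal=r2m, r2_conditional=r2c, f_stat=f_stat,
        df_num=1, df_den=df_den,
        domain_water=(float(xv.min()), float(xv.max())),
        n_obs=int(len(df)), n_locations=int(uniq.size),
    )


def compute_partition_coefficients(
    data: pd.DataFrame,
    body: str = "location",
    water: str = "water_srca",
    edge: str = "edge_srca",
    family: str = "",
) -> CalibrationModel:
    """Per-body partition coefficients k = mean otolith edge / mean water.

    ``k_lo``/``k_hi`` are the minimum and maximum over bodies;
    ``domain_water`` spans the observed per-body mean water values.
    Invariant to fish ordering and to duplicating a body's fish list.
    """
    df = data[[body, water, edge]].dropna()
    if df.empty:
        raise CalibrationError("no observations for partition coefficients")
    ks: dict[str, float] = {}
    waters: dict[str, float] = {}
    for b, sub in df.groupby(body, sort=True):
        mean_water = float(sub[water].mean())
        if mean_water <= 0:
            raise CalibrationError(f"body {b}: mean water Sr:Ca must be > 0")
        ks[str(b)] = float(sub[edge].mean()) / mean_water
        waters[str(b)] = mean_water
    k_lo, k_hi = min(ks.values()), max(ks.values())
    wlo, whi = min(waters.values()), max(waters.values())
    if not wlo < whi:
        # single body: widen degenerately so the domain invariant holds
        wlo, whi = wlo * (1 - 1e-9) - 1e-12, whi * (1 + 1e-9) + 1e-12
    return CalibrationModel(
        family=family, kind="partition", k_lo=k_lo, k_hi=k_hi, k_per_body=ks,
        domain_water=(wlo, whi), n_obs=int(len(df)), n_locations=len(ks),
    )


def build_calibration_observations(
    summaries: pd.DataFrame,
    fish: pd.DataFrame,
    water: pd.DataFrame,
    sources: tuple[str, ...] = ("reference",),
) -> pd.DataFrame:
    """Join summaries to capture locations and mean water chemistry.

    One row per non-vateritic fish of the calibration collection (by
    default the ``reference`` source — fish of known residence, mirroring
    a calibration set from closed water bodies plus the mainstem):
    location (capture body), the body's mean water Sr:Ca and the fish's
    edge Sr:Ca, plus family. Falls back to all fish when no source
    matches.
    """
    mean_water = water.groupby("body_id")["srca_mmol_mol"].mean()
    cols = ["fish_id", "family", "capture_body", "source"]
    df = summaries.merge(fish[[c for c in cols if c in fish.columns]], on="fish_id")
    if "source" in df.columns and df["source"].isin(sources).any():
        df = df[df["source"].isin(sources)]
    df = df[~df["vaterite"].astype(bool)]
    df = df.assign(
        location=df["capture_body"],
        water_srca=df["capture_body"].map(mean_water),
    )
    return df[["fish_id", "family", "location", "water_srca", "edge_srca"]]


def calibrate_families(
    observations: pd.DataFrame,
    fit_families: list[str],
    partition_families: list[str],
    published: dict[str, CalibrationModel],
    weight_scheme: str = WEIGHT_EQUAL_LOCATION,
) -> dict[str, CalibrationModel]:
    """Fit/collect one CalibrationModel per family."""
    models: dict[str, CalibrationModel] = {}
    for fam in fit_families:
        sub = observations[observations["family"] == fam]
        models[fam] = fit_linear_mixed(sub, family=fam, weight_scheme=weight_scheme)
    for fam in partition_families:
        sub = observations[observations["family"] == fam]
        models[fam] = compute_partition_coefficients(sub, family=fam)
    for fam, model in published.items():
        models[fam] = model
    return models
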