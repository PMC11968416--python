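"""Rule-based natal-origin assignment from otolith-core Sr:Ca.

Every non-vateritic fish is compared against its family's origin windows
(closed intervals) and assigned

* a coarse category: ``tributary`` (matches tributaries only),
  ``potential_resident`` (matches the mainstem, possibly with tributaries),
  ``unclassifiable_above``/``unclassifiable_below`` (core outside the
  family's model limits), or ``low_srca``/``high_srca`` (core inside the
  model limits but in no window);
* a refined label: the single matched body's id; ``"small tributary or
  Wisconsin River"`` for tributary-only matches of the Wisconsin River plus
  one or two others; ``"TRIB"`` for three or more tributaries whose
  confluences span multiple reaches; ``"TRIB or UMR"`` for potential
  residents matching three or more tributaries; ``"UMR or <names>"`` for
  potential residents matching one or two tributaries; otherwise a
  canonical alphabetical "or"-joined label.

Interior gaps (core inside model limits, between windows, neither below
all nor above all of them) are labelled relative to the mainstem window
— below its lower bound → ``low_srca``, above its upper bound →
``high_srca`` — and flagged for audit. Cores matching the mainstem window
only are counted as potential residents with refined label ``"UMR"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import WaterBody
from .errors import ClassificationError
from .origin_windows import OriginWindow

TRIBUTARY_CAT = "tributary"
POTENTIAL_RESIDENT = "potential_resident"
UNCLASSIFIABLE_ABOVE = "unclassifiable_above"
UNCLASSIFIABLE_BELOW = "unclassifiable_below"
LOW_SRCA = "low_srca"
HIGH_SRCA = "high_srca"
VATERITE_EXCLUDED = "vaterite_excluded"

COARSE_CATEGORIES = (
    TRIBUTARY_CAT, POTENTIAL_RESIDENT, UNCLASSIFIABLE_ABOVE,
    UNCLASSIFIABLE_BELOW, LOW_SRCA, HIGH_SRCA,
)

SMALL_TRIB_OR_WI = "small tributary or Wisconsin River"
TRIB_LABEL = "TRIB"
TRIB_OR_UMR = "TRIB or UMR"


@dataclass(frozen=True)
class OriginAssignment:
    fish_id: str
    matched_bodies: frozenset[str]
    coarse: str
    refined: str
    excluded_vaterite: bool = False
    interior_gap: bool = False
    error: str = ""


def match_windows(core_srca: float, windows: list[OriginWindow]) -> set[str]:
    """Ids of non-dropped windows whose closed interval contains the core."""
    return {w.water_body_id for w in windows if w.contains(core_srca)}


def assign_coarse(
    core_srca: float,
    matches: set[str],
    model_limits: tuple[float, float],
    all_windows: list[OriginWindow],
    mainstem_id: str,
) -> tuple[str, bool]:
    """Coarse category for one fish; returns (category, interior_gap_flag)."""
    mn, mx = model_limits
    if core_srca < mn:
        return UNCLASSIFIABLE_BELOW, False
    if core_srca > mx:
        return UNCLASSIFIABLE_ABOVE, False
    if matches:
        if mainstem_id in matches:
            return POTENTIAL_RESIDENT, False
        return TRIBUTARY_CAT, False
    live = [w for w in all_windows if not w.dropped]
    if live:
        if core_srca < min(w.lo for w in live):
            return LOW_SRCA, False
        if core_srca > max(w.hi for w in live):
            return HIGH_SRCA, False
    # interior gap: between windows; label relative to the mainstem window
    main = next((w for w in live if w.water_body_id == mainstem_id), None)
    if main is not None and core_srca < main.lo:
        return LOW_SRCA, True
    if main is not None and core_srca > main.hi:
        return HIGH_SRCA, True
    # no usable mainstem window; fall back to nearest-side labelling
    if live:
        mid = 0.5 * (min(w.lo for w in live) + max(w.hi for w in live))
        return (LOW_SRCA if core_srca < mid else HIGH_SRCA), True
    return LOW_SRCA, True


def _spans_multiple_reaches(body_ids: set[str], bodies: dict[str, WaterBody]) -> bool:
    reaches = set()
    for b in body_ids:
        reach = bodies[b].confluence_reach
        if reach == "multiple":
            return True
        reaches.add(reach)
    return len(reaches) > 1


def refine_category(
    matches: set[str],
    coarse: str,
    bodies: dict[str, WaterBody],
    mainstem_id: str,
    wisconsin_id: str | None = "WI",
) -> str:
    """Deterministic refined label for a classified fish."""
    if coarse not in (TRIBUTARY_CAT, POTENTIAL_RESIDENT):
        raise ClassificationError(
            f"refine_category called with coarse={coarse!r}"
        )
    if not matches:
        raise ClassificationError("refine_category called with no matches")
    unknown = matches - set(bodies)
    if unknown:
        raise ClassificationError(f"matched unknown water bodies: {sorted(unknown)}")
    if len(matches) == 1:
        return next(iter(matches))
    tribs = sorted(m for m in matches if m != mainstem_id)
    if coarse == TRIBUTARY_CAT:
        if wisconsin_id in matches and 2 <= len(matches) <= 3:
            return SMALL_TRIB_OR_WI
        if len(tribs) >= 3 and _spans_multiple_reaches(set(tribs), bodies):
            return TRIB_LABEL
        return " or ".join(tribs)
    # potential resident
    if len(tribs) >= 3:
        return TRIB_OR_UMR
    if not tribs:
        return mainstem_id
    return f"{mainstem_id} or " + " or ".join(tribs)


def classify_fish(
    fish_id: str,
    core_srca: float,
    vaterite: bool,
    windows: list[OriginWindow],
    model_limits: tuple[float, float],
    bodies: dict[str, WaterBody],
    mainstem_id: str,
    wisconsin_id: str | None = "WI",
) -> OriginAssignment:
    if vaterite:
        return OriginAssignment(fish_id, frozenset(), VATERITE_EXCLUDED, "",
                                excluded_vaterite=True)
    matches = match_windows(core_srca, windows)
    coarse, gap = assign_coarse(core_srca, matches, model_limits, windows, mainstem_id)
    if coarse in (TRIBUTARY_CAT, POTENTIAL_RESIDENT):
        refined = refine_category(matches, coarse, bodies, mainstem_id, wisconsin_id)
    else:
        refined = coarse
    return OriginAssignment(fish_id, frozenset(matches), coarse, refined,
                            interior_gap=gap)


def classify_assemblage(
    summaries: pd.DataFrame,
    windows_df: pd.DataFrame,
    models: dict,
    fish: pd.DataFrame,
    bodies: dict[str, WaterBody],
    mainstem_id: str,
    wisconsin_id: str | None = "WI",
) -> pd.DataFrame:
    """Classify every fish; order follows the input summaries.

    Vateritic fish are carried through with ``excluded_vaterite=True`` and
    no category. Fish whose family lacks a calibration/windows get a
    per-fish error record rather than raising.
    """
    from .origin_windows import windows_from_frame

    fam_of = dict(zip(fish["fish_id"], fish["family"]))
    window_cache: dict[str, list[OriginWindow]] = {}
    rows = []
    for s in summaries.itertuples():
        fam = fam_of.get(s.fish_id)
        if fam is None or fam not in models:
            rows.append(dict(
                fish_id=s.fish_id, coarse="", refined="", matched_bodies="",
                excluded_vaterite=False, interior_gap=False,
                error=f"no calibration for family {fam!r}",
            ))
            continue
        if fam not in window_cache:
            window_cache[fam] = windows_from_frame(windows_df, fam)
        a = classify_fish(
            s.fish_id, float(s.core_srca), bool(s.vaterite), window_cache[fam],
            models[fam].model_limits(), bodies, mainstem_id, wisconsin_id,
        )
        rows.append(dict(
            fish_id=a.fish_id, coarse=a.coarse, refined=a.refined,
            matched_bodies=";".join(sorted(a.matched_bodies)),
            excluded_vaterite=a.excluded_vaterite, interior_gap=a.interior_gap,
            error=a.error,
        ))
    out = pd.DataFrame(rows)
    meta_cols = ["fish_id", "species", "family", "role", "source", "pool", "year"]
    have = [c for c in meta_cols if c in fish.columns]
    return out.merge(fish[have], on="fish_id", how="left")[
        have + [c for c in out.columns if c != "fish_id"]
    ]
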