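"""Hand-built window set and fixture fish exercising every assignment rule."""

from otolith_origin.config import WaterBody
from otolith_origin.origin_windows import OriginWindow

MODEL_LIMITS = (150.0, 1500.0)
MAINSTEM_ID = "UMR"
FAMILY = "Sciaenidae"

BODIES = {
    "UMR": WaterBody("UMR", "Upper Mississippi", "mainstem", "multiple", 1.6, 0.1),
    "MN": WaterBody("MN", "Minnesota", "tributary", "P4", 3.4, 0.1),
    "CAN": WaterBody("CAN", "Cannon", "tributary", "P4", 0.9, 0.1),
    "CHP": WaterBody("CHP", "Chippewa", "tributary", "P8", 0.8, 0.1),
    "ZMB": WaterBody("ZMB", "Zumbro", "tributary", "P4", 0.75, 0.1),
    "WI": WaterBody("WI", "Wisconsin", "tributary", "P8", 0.65, 0.1),
    "MAQ": WaterBody("MAQ", "Maquoketa", "tributary", "P13", 0.78, 0.1),
    "BLK": WaterBody("BLK", "Black", "tributary", "P8", 0.7, 0.1),
    "ROT": WaterBody("ROT", "Root", "tributary", "P13", 0.72, 0.1),
}

WINDOWS = [
    OriginWindow("UMR", FAMILY, 400.0, 900.0),
    OriginWindow("MN", FAMILY, 950.0, 1100.0),
    OriginWindow("CAN", FAMILY, 300.0, 430.0),
    OriginWindow("CHP", FAMILY, 320.0, 390.0),
    OriginWindow("ZMB", FAMILY, 310.0, 370.0),
    OriginWindow("WI", FAMILY, 200.0, 280.0),
    OriginWindow("MAQ", FAMILY, 260.0, 330.0),
    OriginWindow("BLK", FAMILY, 380.0, 460.0),
    OriginWindow("ROT", FAMILY, 390.0, 450.0),
]

# (fish_id, core_srca, core_mgca, expected coarse, expected refined)
RULE_CASES = [
    ("vaterite", 100.0, 1500.0, "vaterite_excluded", ""),
    ("below_limits", 50.0, 400.0, "unclassifiable_below", "unclassifiable_below"),
    ("above_limits", 1600.0, 400.0, "unclassifiable_above", "unclassifiable_above"),
    ("low_srca", 180.0, 400.0, "low_srca", "low_srca"),
    ("high_srca", 1300.0, 400.0, "high_srca", "high_srca"),
    ("single_tributary", 1000.0, 400.0, "tributary", "MN"),
    ("umr_only_resident", 850.0, 400.0, "potential_resident", "UMR"),
    ("resident_with_tribs", 440.0, 400.0, "potential_resident", "UMR or BLK or ROT"),
    ("small_trib_or_wisconsin", 270.0, 400.0, "tributary",
     "small tributary or Wisconsin River"),
    ("multi_trib_spanning_reaches", 330.0, 400.0, "tributary", "TRIB"),
    ("trib_or_umr", 410.0, 400.0, "potential_resident", "TRIB or UMR"),
]
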