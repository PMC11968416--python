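"""CSV readers/writers for the pipeline's file formats.

All files are UTF-8 CSV with a header row and '.' decimals. Writing uses a
fixed float format so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigError

FLOAT_FORMAT = "%.10g"

_REQUIRED = {
    "water": ["body_id", "srca_mmol_mol"],
    "fish": ["fish_id", "species", "family", "role", "source", "pool", "year",
             "capture_body"],
    "truth": ["fish_id", "natal_body", "capture_body"],
    "standards": ["block_index", "position", "replicate", "sr", "mg", "ca"],
    "blanks": ["channel", "mean", "sd"],
    "transect": ["distance_um", "sr", "mg", "ca"],
    "summaries": ["fish_id", "core_srca", "core_mgca", "edge_srca", "vaterite"],
    "windows": ["family", "water_body_id", "lo", "hi", "truncated", "dropped"],
    "assignments": ["fish_id", "coarse", "refined", "matched_bodies",
                    "excluded_vaterite"],
}


def write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _read(path: str, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise ConfigError(f"missing input file: {path}") from exc
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    return df


def read_water(path: str) -> pd.DataFrame:
    return _read(path, "water")


def read_fish(path: str) -> pd.DataFrame:
    return _read(path, "fish")


def read_truth(path: str) -> pd.DataFrame:
    return _read(path, "truth")


def read_standards(path: str) -> pd.DataFrame:
    return _read(path, "standards")


def read_blanks(path: str) -> pd.DataFrame:
    return _read(path, "blanks")


def read_transect(path: str) -> pd.DataFrame:
    return _read(path, "transect")


def read_summaries(path: str) -> pd.DataFrame:
    return _read(path, "summaries")


def read_windows(path: str) -> pd.DataFrame:
    return _read(path, "windows")


def read_assignments(path: str) -> pd.DataFrame:
    df = _read(path, "assignments")
    if "error" in df.columns:
        df["error"] = df["error"].fillna("")
    if "refined" in df.columns:
        df["refined"] = df["refined"].fillna("")
    return df
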