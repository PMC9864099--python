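"""Electrode manufacturing catalogue.

Seventeen electrode types: 8 spun-steel 1/15-sateen patches sweeping surface
area, 8 fixed-area patches sweeping yarn (silver-coated nylon vs spun steel)
and weave pattern, and 1 clinical adhesive Ag/AgCl reference whose interface
circuit parameters are treated as known rather than fitted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["ADHESIVE_ID", "default_catalog", "load_catalog", "write_catalog"]

ADHESIVE_ID = 17

_ROWS = [
    # id, label, width_cm, height_cm, yarn, pattern
    (1, "Area1", 1.27, 2.54, "steel spun", "1/15 sateen"),
    (2, "Area2", 1.27, 3.38, "steel spun", "1/15 sateen"),
    (3, "Area3", 2.54, 4.22, "steel spun", "1/15 sateen"),
    (4, "Area4", 2.54, 5.08, "steel spun", "1/15 sateen"),
    (5, "Area5", 2.54, 5.92, "steel spun", "1/15 sateen"),
    (6, "Area6", 3.81, 6.76, "steel spun", "1/15 sateen"),
    (7, "Area7", 3.81, 7.62, "steel spun", "1/15 sateen"),
    (8, "Area8", 3.81, 8.46, "steel spun", "1/15 sateen"),
    (9, "1Si", 1.68, 3.38, "silver nylon", "1/15 sateen"),
    (10, "2Si", 1.68, 3.38, "silver nylon", "broken twill"),
    (11, "3Si", 1.68, 3.38, "silver nylon", "twill"),
    (12, "4Si", 1.68, 3.38, "silver nylon", "birds eye"),
    (13, "1St", 1.68, 3.38, "steel spun", "1/15 sateen"),
    (14, "2St", 1.68, 3.38, "steel spun", "broken twill"),
    (15, "3St", 1.68, 3.38, "steel spun", "twill"),
    (16, "4St", 1.68, 3.38, "steel spun", "birds eye"),
    (17, "Adh", 5.0, 3.9226, "adhesive", "n/a"),  # 19.61 cm^2 circular pad
]

_COLUMNS = ["id", "label", "width_cm", "height_cm", "yarn", "pattern"]


def default_catalog() -> pd.DataFrame:
    """The built-in 17-type catalogue with a derived ``area_cm2`` column."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df["area_cm2"] = df["width_cm"] * df["height_cm"]
    return df


def load_catalog(path) -> pd.DataFrame:
    """Read a catalogue CSV (columns id, label, width_cm, height_cm, yarn,
    pattern); ids must be unique and dimensions positive."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} lacks columns {missing}")
    if df["id"].duplicated().any():
        raise ValueError(f"catalog {path} has duplicate electrode ids")
    if (df["width_cm"] <= 0).any() or (df["height_cm"] <= 0).any():
        raise ValueError(f"catalog {path} has non-positive dimensions")
    df["area_cm2"] = df["width_cm"] * df["height_cm"]
    return df


def write_catalog(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[_COLUMNS].to_csv(path, index=False)
    return path
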