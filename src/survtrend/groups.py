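"""Shared categorical groupings for demographic and regional variables.

The adjustment-weighting scheme cross-classifies the sample on three
different age groupings, a collapsed ISCED education variable, Nielsen
marketing areas, combined federal-state groups, and municipality-size
classes.  The definitions live here so the weighting, modelling and
simulation code all agree on category names and order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEXES = ["female", "male"]

#: fine age grouping used for sex x age adjustment and for the regressions
AGE7 = ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
#: coarse grouping used with education
AGE3A = ["18-29", "30-59", "60+"]
#: coarse grouping used with federal-state groups
AGE3B = ["18-39", "40-59", "60+"]

EDUCATION = ["low", "medium", "high"]

NIELSEN_AREAS = [
    "Northwest", "North Rhine-Westphalia", "Center", "East (North)",
    "East (South)", "Bavaria", "Baden-Wuerttemberg",
]

#: combined federal-state groups: five merged groups covering the smaller
#: states plus five states kept on their own.
STATE_GROUPS = [
    "SH+HH", "NI+HB", "NW", "HE", "RP+SL",
    "BW", "BY", "BE", "BB+MV", "ST+SN+TH",
]

MUNICIPALITY_SIZES = ["rural", "small-town", "medium-town", "metropolitan"]

_AGE7_EDGES = [18, 30, 40, 50, 60, 70, 80, 200]
_AGE3A_EDGES = [18, 30, 60, 200]
_AGE3B_EDGES = [18, 40, 60, 200]


def _cut(age, edges, labels):
    a = pd.to_numeric(age, errors="coerce")
    out = pd.cut(a, bins=edges, labels=labels, right=False)
    return out.astype(object).where(a.notna(), other=np.nan)


def age_group7(age) -> pd.Series:
    return _cut(age, _AGE7_EDGES, AGE7)


def age_group3a(age) -> pd.Series:
    return _cut(age, _AGE3A_EDGES, AGE3A)


def age_group3b(age) -> pd.Series:
    return _cut(age, _AGE3B_EDGES, AGE3B)


def coarse_of_age7(group7: str) -> str:
    """Map a fine age group to the coarse 18-29 / 30-59 / 60+ grouping."""
    if group7 == "18-29":
        return "18-29"
    if group7 in ("30-39", "40-49", "50-59"):
        return "30-59"
    return "60+"


def derive_group_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``age7``, ``age3a``, ``age3b`` columns derived from ``age``."""
    out = records.copy()
    out["age7"] = age_group7(out["age"])
    out["age3a"] = age_group3a(out["age"])
    out["age3b"] = age_group3b(out["age"])
    return out
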