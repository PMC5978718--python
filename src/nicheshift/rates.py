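"""Rates of phenotypic change in darwins.

One darwin is a change in a (positive) trait value by a factor *e* per
million years:

    rate = |ln(x2 / x1)| / (t / 1e6)   for elapsed time t in years.

The trait summary used here is the group-mean proportion of bleached
thalli at a treatment level, floored at a small epsilon so a fully
tolerant group does not produce ln 0. Rates are computed per coastline
invasion and treatment level and averaged per stressor.
"""

from __future__ import annotations

import math

import pandas as pd

from .ordinal import proportion_bleached

DEFAULT_YEARS = 100.0       # the invasion is about a century old
DEFAULT_EPSILON = 0.01


def darwin_rate(x1: float, x2: float, years: float) -> float:
    """|ln(x2/x1)| per million years; x1, x2, years must be positive."""
    if x1 <= 0 or x2 <= 0:
        raise ValueError("trait values must be positive")
    if years <= 0:
        raise ValueError("elapsed time must be positive")
    return abs(math.log(x2 / x1)) / (years / 1e6)


def rate_summary(estimates: pd.DataFrame) -> pd.Series:
    """Mean darwin rate per stressor across coastline x level cells.

    ``estimates`` needs columns ``stressor, coastline, level, rate``.
    """
    if len(estimates) == 0:
        raise ValueError("no rate estimates to summarize")
    return estimates.groupby("stressor")["rate"].mean()


def assay_darwin_rates(assays: pd.DataFrame, years: float = DEFAULT_YEARS,
                       epsilon: float = DEFAULT_EPSILON,
                       native_label: str = "native_source") -> pd.DataFrame:
    """Per coastline x treatment-level darwin rates from bleaching assays.

    The trait is the proportion bleached (SBS > 0), native-source mean as
    x1 and each non-native coastline's mean as x2, floored at ``epsilon``.
    """
    rows = []
    native = assays[assays["range_class"] == native_label]
    for (stressor, level), nat_sub in native.groupby(["stressor", "level"], sort=False):
        x1 = max(proportion_bleached(nat_sub["sbs"]), epsilon)
        inv = assays[(assays["range_class"] != native_label)
                     & (assays["stressor"] == stressor)
                     & (assays["level"] == level)]
        for coast, sub in inv.groupby("coastline", sort=False):
            x2 = max(proportion_bleached(sub["sbs"]), epsilon)
            rows.append([stressor, coast, level, x1, x2,
                         darwin_rate(x1, x2, years)])
    out = pd.DataFrame(rows, columns=["stressor", "coastline", "level",
                                      "trait_native", "trait_invaded", "rate"])
    if len(out) == 0:
        raise ValueError("no native/non-native pairs found in assays")
    return out
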