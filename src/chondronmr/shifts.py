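"""Chemical-shift table arithmetic.

Assignment tables (one row per ring/reporter/anomer) are plain DataFrames;
"n/d" marks resonances that could not be determined (overlap).  On top of
them this module provides the comparisons used to interpret the spectra:
absolute shift differences between oligosaccharide species, amide-proton
temperature coefficients with their hydrogen-bond reading, and the
empirical +0.5 ppm downfield sulfation-shift rule for H-4/H-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InputError

#: |slope| above this (ppb/degC) argues against a persistent intramolecular
#: hydrogen bond for an amide proton
HBOND_COEF_THRESHOLD = 3.0
#: typical coefficient for an amide proton in free exchange with water
FREE_EXCHANGE_COEF = -11.0
SULFATION_DOWNFIELD_SHIFT = 0.5  # ppm, 4-O/6-O sulfation of GalNAc


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("chondronmr.data").joinpath(name).open() as fh:
        # keep "n/d"/"n/a" markers as literal strings rather than NaN
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def load_table(name: str) -> pd.DataFrame:
    """Packaged assignment/comparison tables, e.g. load_table("table1_shifts")."""
    return _read_fixture(f"{name}.csv")


def _numeric(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col, errors="coerce")


def abs_shift_difference(table_a: pd.DataFrame, table_b: pd.DataFrame,
                         keys=("ring", "reporter", "anomer"),
                         value="delta_ppm") -> pd.DataFrame:
    """Per-atom |delta_a - delta_b| over matched assignment keys.

    Rows where either side is missing/non-numeric are kept and flagged "n/d";
    keys present on only one side appear with status "unmatched".
    """
    keys = [k for k in keys if k in table_a.columns and k in table_b.columns]
    merged = table_a.merge(table_b, on=keys, how="outer",
                           suffixes=("_a", "_b"), indicator=True)
    va = _numeric(merged[f"{value}_a"])
    vb = _numeric(merged[f"{value}_b"])
    merged["abs_diff"] = (va - vb).abs()
    merged["status"] = np.where(
        merged["_merge"] != "both", "unmatched",
        np.where(merged["abs_diff"].notna(), "ok", "n/d"),
    )
    return merged.drop(columns="_merge")


@dataclass
class ShiftSeries:
    """One reporter's chemical shift across temperatures."""

    key: str  # e.g. "CN6 N3 HN"
    points: list  # of (temperature_C, delta_ppm)

    def __post_init__(self):
        temps = {t for t, _ in self.points}
        if len(temps) < 2:
            raise InputError("a shift series needs >= 2 distinct temperatures")


def temperature_coefficient(series) -> tuple:
    """(slope ppb/degC, R^2) of shift vs temperature by least squares.

    Negative slopes mean upfield movement on warming. Accepts a ShiftSeries
    or a plain sequence of (temperature_C, delta_ppm).
    """
    points = series.points if isinstance(series, ShiftSeries) else list(series)
    if len(points) < 2:
        raise InputError("need at least two temperature points")
    t = np.array([p[0] for p in points], dtype=float)
    d = np.array([p[1] for p in points], dtype=float)
    if np.ptp(t) == 0:
        raise InputError("temperatures are all identical")
    if np.allclose(d, d[0]):
        return 0.0, 1.0
    fit = linregress(t, d)
    return float(fit.slope * 1000.0), float(fit.rvalue ** 2)


@dataclass
class HbondClassification:
    label: str  # "persistent-hbond-consistent" | "no-persistent-hbond"
    slope_ppb_per_C: float
    delta_to_free_exchange: float  # |slope - (-11)| ppb/degC


def classify_hbond_from_coefficient(slope_ppb_per_C: float) -> HbondClassification:
    """Hydrogen-bond reading of an amide temperature coefficient.

    |slope| <= 3 ppb/degC is consistent with a persistent intramolecular
    hydrogen bond; larger magnitudes indicate its absence.  The distance to
    the free-exchange reference (~ -11 ppb/degC) is reported alongside.
    """
    if not np.isfinite(slope_ppb_per_C):
        raise InputError("slope must be finite")
    label = (
        "persistent-hbond-consistent"
        if abs(slope_ppb_per_C) <= HBOND_COEF_THRESHOLD
        else "no-persistent-hbond"
    )
    return HbondClassification(
        label=label,
        slope_ppb_per_C=float(slope_ppb_per_C),
        delta_to_free_exchange=abs(slope_ppb_per_C - FREE_EXCHANGE_COEF),
    )


def predict_sulfation_shift(delta_unsulfated_ppm: float, site: str) -> float:
    """Predicted 1H shift after 4-O or 6-O sulfation: +0.5 ppm downfield."""
    if site not in ("4-O", "6-O"):
        raise InputError(f"unknown sulfation site {site!r} (use '4-O' or '6-O')")
    return float(delta_unsulfated_ppm + SULFATION_DOWNFIELD_SHIFT)
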