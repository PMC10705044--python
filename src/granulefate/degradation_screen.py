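"""Suspect screening of degradation-product peaks against a compound database.

A peak observation (candidate compound, observed m/z, area, S/N) is accepted
as a degradation-product detection when its mass error against the
candidate's theoretical adduct m/z is strictly below 5 ppm in magnitude and
its signal-to-noise ratio is at least 10. Accepted peaks are tracked over
time as *corrected peak areas* — relative concentration proxies normalized
to the parent compound's 100 μg/L standard:

    aqueous corrected area = area * concentration_factor / standard_area
    solid corrected area   = area / (standard_area * dry_weight_g)

The screen is deliberately minimal: no isotope-pattern scoring, no
retention-time prediction — presence of products is used as an indicator of
biodegradation, not for absolute quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import (  # noqa: F401  (re-exported screening primitives)
    adduct_mz,
    average_mass,
    mass_error_ppm,
    monoisotopic_mass,
    parse_formula,
)
from .compounds import load_compound_db, validate_compound_db
from .errors import DataError, ScreenError

#: Reporting filter defaults: |mass error| < 5 ppm (strict) and S/N >= 10.
MAX_PPM_DEFAULT = 5.0
MIN_SNR_DEFAULT = 10.0

PEAK_COLUMNS = [
    "sample_id", "day", "phase", "compound", "observed_mz", "area", "snr",
    "concentration_factor", "dry_weight_g", "standard_area_100",
]


def aqueous_corrected_area(
    area: float,
    concentration_factor: float,
    standard_area_100: float,
    divide_by_cf: bool = False,
) -> float:
    """Aqueous corrected peak area (unitless, relative).

    Literal form: ``area * concentration_factor / standard_area_100``.
    ``divide_by_cf=True`` switches the concentration factor to the
    denominator for users who prefer concentrations on the original
    (pre-extraction) sample basis.
    """
    if standard_area_100 <= 0:
        raise ScreenError("standard area must be positive")
    if area < 0:
        raise ScreenError("peak area must be >= 0")
    if divide_by_cf:
        if concentration_factor <= 0:
            raise ScreenError("concentration factor must be positive")
        return area / (concentration_factor * standard_area_100)
    return area * concentration_factor / standard_area_100


def solid_corrected_area(
    area: float, standard_area_100: float, dry_weight_g: float
) -> float:
    """Solid corrected peak area per gram dry granules.

    ``area / (standard_area_100 * dry_weight_g)``.
    """
    if standard_area_100 <= 0:
        raise ScreenError("standard area must be positive")
    if dry_weight_g <= 0:
        raise ScreenError("dry weight must be positive")
    if area < 0:
        raise ScreenError("peak area must be >= 0")
    return area / (standard_area_100 * dry_weight_g)


def theoretical_mz_table(
    db: pd.DataFrame, adduct: str = "[M+H]+"
) -> pd.Series:
    """Theoretical adduct m/z per compound code in the database."""
    db = validate_compound_db(db)
    return pd.Series(
        {
            row["code"]: adduct_mz(monoisotopic_mass(row["formula"]), adduct)
            for _, row in db.iterrows()
        },
        name="theoretical_mz",
    )


def screen_peaks(
    peaks: pd.DataFrame,
    db: pd.DataFrame | None = None,
    max_ppm: float = MAX_PPM_DEFAULT,
    min_snr: float = MIN_SNR_DEFAULT,
    adduct: str = "[M+H]+",
    divide_by_cf: bool = False,
) -> pd.DataFrame:
    """Screen a peak table against the compound database.

    Returns one hit row per peak with ``theoretical_mz``,
    ``mass_error_ppm``, ``passed`` (strict ``< max_ppm`` on |error|,
    inclusive ``>= min_snr`` on S/N), and ``corrected_area`` (aqueous or
    solid form chosen from the ``phase`` column). Peaks with no usable
    parent standard area are kept but flagged ``normalizable=False`` with
    NaN corrected area rather than dropped.

    Raises
    ------
    ScreenError
        If any ``compound`` code in ``peaks`` is absent from the database.
    """
    if db is None:
        db = load_compound_db()
    missing_cols = [c for c in ("compound", "observed_mz", "area", "snr", "phase")
                    if c not in peaks.columns]
    if missing_cols:
        raise DataError(f"peak table missing columns: {missing_cols}")
    theo = theoretical_mz_table(db, adduct)
    unknown = sorted(set(peaks["compound"]) - set(theo.index))
    if unknown:
        raise ScreenError(f"peaks reference unknown compound codes: {unknown}")

    hits = peaks.copy()
    hits["theoretical_mz"] = hits["compound"].map(theo)
    hits["mass_error_ppm"] = 1e6 * (
        hits["observed_mz"] - hits["theoretical_mz"]
    ) / hits["theoretical_mz"]
    hits["passed"] = (
        (hits["mass_error_ppm"].abs() < max_ppm) & (hits["snr"] >= min_snr)
    )

    std = hits.get("standard_area_100", pd.Series(np.nan, index=hits.index))
    std = pd.to_numeric(std, errors="coerce")
    hits["normalizable"] = std.notna() & (std > 0)

    is_solid = hits["phase"].eq("solid")
    corrected = np.full(len(hits), np.nan)
    ok = hits["normalizable"].to_numpy()
    solid_rows = ok & is_solid.to_numpy()
    aq_rows = ok & ~is_solid.to_numpy()
    if solid_rows.any():
        dw = pd.to_numeric(hits.loc[solid_rows, "dry_weight_g"])
        corrected[solid_rows] = (
            hits.loc[solid_rows, "area"].to_numpy()
            / (std[solid_rows].to_numpy() * dw.to_numpy())
        )
    if aq_rows.any():
        cf = pd.to_numeric(hits.loc[aq_rows, "concentration_factor"])
        if divide_by_cf:
            corrected[aq_rows] = hits.loc[aq_rows, "area"].to_numpy() / (
                cf.to_numpy() * std[aq_rows].to_numpy()
            )
        else:
            corrected[aq_rows] = (
                hits.loc[aq_rows, "area"].to_numpy()
                * cf.to_numpy()
                / std[aq_rows].to_numpy()
            )
    hits["corrected_area"] = corrected
    return hits


def product_timeseries(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-compound, per-phase time series of corrected areas.

    Restricted to hits that passed the reporting filter. Non-detections are
    explicit gaps — days with no passing hit simply have no row (a missing
    observation is not a measured zero). Replicate passing hits within one
    (compound, phase, day) cell are averaged.
    """
    passed = hits[hits["passed"]]
    if passed.empty:
        return pd.DataFrame(
            columns=["compound", "phase", "day", "corrected_area", "n_peaks"]
        )
    series = (
        passed.groupby(["compound", "phase", "day"], as_index=False)
        .agg(corrected_area=("corrected_area", "mean"),
             n_peaks=("corrected_area", "size"))
        .sort_values(["compound", "phase", "day"], ignore_index=True)
    )
    return series
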