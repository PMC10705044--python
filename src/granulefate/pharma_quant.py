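"""Pharmaceutical quantification, recovery correction, and removal mass balance.

Concentrations are determined from peak areas via an ordinary-least-squares
calibration curve, corrected for solid-phase-extraction losses using spike
recovery (prespiked / unspiked / postspiked replicates), and expressed as
percent removal by a per-timepoint mass balance on influent and effluent
concentrations. The same mass balance serves the conventional analytes
(NH3-N, NO2-N, NO3-N, PO4-P, DOC).

Sign convention: removal may be negative; an effluent concentration twice
the influent one gives -100 % removal (the desorption-spike regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, RecoveryError, DataError


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line relating peak area to nominal concentration (μg/L)."""

    compound: str
    slope: float            # area per (μg/L)
    intercept: float        # area
    r_squared: float
    standards: tuple = field(default_factory=tuple, repr=False)

    def area(self, conc: float) -> float:
        """Predicted peak area at a nominal concentration."""
        return self.slope * conc + self.intercept


def fit_calibration(
    standards: Sequence[tuple[float, float]], compound: str = ""
) -> CalibrationCurve:
    """Fit a calibration line to (nominal μg/L, peak area) standards.

    Requires at least two distinct nominal levels and a positive slope
    (areas must increase with concentration for the curve to be invertible).
    """
    pts = [(float(x), float(a)) for x, a in standards]
    if any(a < 0 for _, a in pts):
        raise CalibrationError("negative peak area in standards")
    xs = np.array([x for x, _ in pts])
    ys = np.array([a for _, a in pts])
    if len(np.unique(xs)) < 2:
        raise CalibrationError(
            "calibration needs >= 2 distinct nominal levels"
        )
    res = stats.linregress(xs, ys)
    if res.slope <= 0:
        raise CalibrationError(
            f"non-positive calibration slope ({res.slope:g}) for "
            f"{compound or 'compound'}: curve not invertible"
        )
    return CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=tuple(pts),
    )


class Quantified(NamedTuple):
    """Result of inverting a calibration curve for one peak area."""

    conc: float
    below_range: bool


def quantify(area: float, curve: CalibrationCurve) -> Quantified:
    """Concentration (μg/L) from a peak area via the calibration curve.

    ``(area - intercept) / slope``; a value below zero (area under the
    intercept) is clipped to 0 and flagged ``below_range``.
    """
    if curve.slope <= 0:
        raise CalibrationError("calibration curve has non-positive slope")
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        return Quantified(0.0, True)
    return Quantified(float(conc), False)


def concentration_factor(loaded_volume_ml: float, extract_volume_ml: float) -> float:
    """Solid-phase-extraction concentration factor: loaded / extract volume.

    A 100 mL sample concentrated to a 1 mL extract has factor 100.
    """
    if loaded_volume_ml <= 0 or extract_volume_ml <= 0:
        raise DataError("volumes must be positive")
    return loaded_volume_ml / extract_volume_ml


# ---------------------------------------------------------------------------
# spike recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeRecoverySet:
    """Concentrations from one spike-recovery triplet (μg/L).

    prespike: sample spiked before extraction; unspiked: plain duplicate;
    postspike: unspiked extract spiked after extraction (extraction-loss
    free reference). The nominal spike level in the study design is
    100 μg/L.
    """

    prespike_conc: float
    unspiked_conc: float
    postspike_conc: float
    nominal_spike: float = 100.0

    def __post_init__(self):
        for name in ("prespike_conc", "unspiked_conc", "postspike_conc"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def compute_recovery(s: SpikeRecoverySet) -> float:
    """Recovery fraction: (prespike - unspiked) / (postspike - unspiked).

    May exceed 1 (over-recovery is real and propagated, not clipped).
    Raises RecoveryError when postspike <= unspiked (denominator <= 0).
    """
    denom = s.postspike_conc - s.unspiked_conc
    if denom <= 0:
        raise RecoveryError(
            "recovery undefined: postspike concentration must exceed "
            f"unspiked ({s.postspike_conc} <= {s.unspiked_conc})"
        )
    return (s.prespike_conc - s.unspiked_conc) / denom


def correct_for_recovery(raw_conc, recovery: float):
    """Divide a measured concentration by its recovery fraction.

    Accepts scalars or array-likes. Recovery must be in (0, 2]; values
    above 1 (over-recovery) scale concentrations down accordingly.
    """
    if not (0 < recovery <= 2):
        raise RecoveryError(f"recovery must be in (0, 2], got {recovery}")
    arr = np.asarray(raw_conc, dtype=float)
    out = arr / recovery
    return float(out) if np.isscalar(raw_conc) else out


@dataclass
class ConcentrationMeasurement:
    """One recovery-corrected concentration measurement."""

    sample_id: str
    reactor: str
    day: float
    phase: str            # influent | effluent | solid
    compound: str
    raw_conc: float       # μg/L aqueous, μg/g solid
    recovery: float | None = None
    corrected_conc: float | None = None

    def correct(self) -> "ConcentrationMeasurement":
        if self.recovery is None:
            raise RecoveryError("no recovery set on measurement")
        self.corrected_conc = correct_for_recovery(self.raw_conc, self.recovery)
        return self


def correct_measurements(
    conc: pd.DataFrame, recoveries: pd.DataFrame
) -> pd.DataFrame:
    """Apply per-(compound, matrix) recovery correction to a tidy table.

    ``conc`` needs columns compound, phase, raw_conc; ``recoveries`` needs
    compound, phase (``aqueous`` or ``solid``), recovery_mean. Influent and
    effluent rows use the aqueous recovery. Adds ``recovery`` and
    ``corrected_conc`` columns.
    """
    out = conc.copy()
    matrix = out["phase"].map(
        lambda p: "solid" if p == "solid" else "aqueous"
    )
    key = pd.MultiIndex.from_arrays([out["compound"], matrix])
    rec_map = recoveries.set_index(["compound", "phase"])["recovery_mean"]
    rec = pd.Series(rec_map.reindex(key).to_numpy(), index=out.index)
    if rec.isna().any():
        missing = sorted(set(map(tuple, key[rec.isna()].to_list())))
        raise DataError(f"no recovery for {missing}")
    bad = rec[(rec <= 0) | (rec > 2)]
    if len(bad):
        raise RecoveryError(f"recoveries outside (0, 2]: {bad.unique()}")
    out["recovery"] = rec
    out["corrected_conc"] = out["raw_conc"] / rec
    return out


# ---------------------------------------------------------------------------
# removal mass balance
# ---------------------------------------------------------------------------

def removal_percent(influent, effluent):
    """Percent removal from a per-timepoint influent/effluent mass balance.

    ``100 * (influent - effluent) / influent``. Negative values mean the
    effluent carried more than the influent supplied (e.g. desorption).
    Timepoints with non-positive influent are undefined and returned as NaN.
    Vectorized over array-likes.
    """
    inf = np.asarray(influent, dtype=float)
    eff = np.asarray(effluent, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(inf > 0, 100.0 * (inf - eff) / inf, np.nan)
    if inf.ndim == 0:
        return float(out)
    return out


def removal_series(
    conc: pd.DataFrame,
    value_col: str = "corrected_conc",
    by: str = "compound",
) -> pd.DataFrame:
    """Per-(compound, day) removal from a tidy concentration table.

    ``conc`` must hold influent and effluent rows (column ``phase``) with a
    numeric ``day`` column. Replicates within a (day, compound, phase) cell
    are averaged before the mass balance. Rows where the influent is
    missing or non-positive get NaN removal and ``defined=False``.
    """
    aq = conc[conc["phase"].isin(["influent", "effluent"])]
    wide = (
        aq.pivot_table(
            index=[by, "day"], columns="phase", values=value_col,
            aggfunc="mean",
        )
        .reindex(columns=["influent", "effluent"])
        .reset_index()
    )
    wide["removal_percent"] = removal_percent(
        wide["influent"].to_numpy(), wide["effluent"].to_numpy()
    )
    wide["defined"] = wide["influent"].to_numpy() > 0
    wide.columns.name = None
    return wide.rename(
        columns={"influent": "influent_conc", "effluent": "effluent_conc"}
    )


NITROGEN_SPECIES = ("NH3-N", "NO2-N", "NO3-N")


def total_nitrogen_removal(influent_n, effluent_n) -> float:
    """Percent total-nitrogen removal from per-species as-N concentrations.

    ``influent_n``/``effluent_n`` are mappings or sequences of the three
    as-N species concentrations (NH3-N, NO2-N, NO3-N), all in the same
    units. TN is summed per phase and passed through the mass balance.
    """
    def _tn(values) -> float:
        if isinstance(values, dict):
            missing = [s for s in NITROGEN_SPECIES if s not in values]
            if missing:
                raise DataError(f"missing nitrogen species: {missing}")
            return float(sum(values[s] for s in NITROGEN_SPECIES))
        vals = list(values)
        if len(vals) != 3:
            raise DataError("expected three as-N species concentrations")
        return float(sum(vals))

    return removal_percent(_tn(influent_n), _tn(effluent_n))


def total_nitrogen_removal_series(analytes: pd.DataFrame) -> pd.DataFrame:
    """Per-(reactor, day) TN removal from a tidy analyte table.

    ``analytes`` columns: reactor, day, phase (influent|effluent), analyte,
    value. Only the three as-N species are used.
    """
    n = analytes[analytes["analyte"].isin(NITROGEN_SPECIES)]
    tn = (
        n.groupby(["reactor", "day", "phase"])["value"].sum().unstack("phase")
        .reindex(columns=["influent", "effluent"])
        .reset_index()
    )
    tn["removal_percent"] = removal_percent(
        tn["influent"].to_numpy(), tn["effluent"].to_numpy()
    )
    tn.columns.name = None
    return tn.rename(
        columns={"influent": "influent_tn", "effluent": "effluent_tn"}
    )


def solid_phase_concentration(
    extract_conc: float, extract_volume_ml: float, dry_weight_g: float
) -> float:
    """Solid-phase concentration in μg/g dry granules.

    ``extract_conc`` (μg/L) in an extract of ``extract_volume_ml`` obtained
    from ``dry_weight_g`` of dry biomass.
    """
    if dry_weight_g <= 0:
        raise DataError("dry weight must be positive")
    if extract_volume_ml <= 0:
        raise DataError("extract volume must be positive")
    return extract_conc * (extract_volume_ml / 1000.0) / dry_weight_g
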