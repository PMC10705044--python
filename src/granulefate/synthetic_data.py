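"""Seeded synthetic data emulating a paired-SBR pharmaceutical exposure study.

The generator stands in for the study's raw data so every downstream stage
is testable with known ground truth. It emulates:

* two sequencing batch reactors (control and test) sampled irregularly over
  ~80 days, the test reactor dosed with three pharmaceuticals (DCF, ERY,
  GEM) at ~150 μg/L each;
* a three-phase pharmaceutical fate trajectory — partial removal by sorption
  plus biodegradation (days 0-12), a desorption spike with effluent at about
  twice influent concentration (days 12-23), then negligible removal;
* mass-spectral peak observations for degradation products with known
  presence/absence, plus parent calibration standards and spike-recovery
  tables;
* paired DNA (rRNA gene) and cDNA (transcript) ZOTU count matrices with a
  known truly-active subset (elevated transcript:gene concentration ratio),
  inactive taxa, and phantom taxa (structurally zero DNA, nonzero cDNA);
* conventional analyte (NH3-N, NO2-N, NO3-N, PO4-P, DOC) time series with
  configurable removal trajectories.

Measurement noise is multiplicative lognormal (concentrations and peak
areas are positive; the emulated study's reported spreads are ~10-20 %).
Identical configurations (including the seed) give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .active_community import CountMatrix
from .chem import adduct_mz, monoisotopic_mass
from .compounds import PARENTS, PRODUCTS, default_compound_db
from .errors import ConfigurationError

__all__ = [
    "SimConfig", "SimTruth", "PharmaSim", "CommunitySim",
    "simulate_pharma_series", "simulate_community", "simulate_analytes",
    "simulate_ordination", "call_accuracy",
]

#: Aqueous and solid spike recoveries used to distort raw measurements,
#: matching the magnitudes a solid-phase-extraction workflow reports.
DEFAULT_RECOVERY = {
    ("DCF", "aqueous"): (0.97, 0.09),
    ("ERY", "aqueous"): (1.17, 0.17),
    ("GEM", "aqueous"): (0.98, 0.11),
    ("DCF", "solid"): (0.75, 0.08),
    ("ERY", "solid"): (0.56, 0.22),
    ("GEM", "solid"): (0.68, 0.08),
}

#: Influent concentrations of conventional analytes (mg/L; N and P as-element).
DEFAULT_ANALYTE_INFLUENT = {
    "NH3-N": 50.0, "NO2-N": 0.0, "NO3-N": 0.0, "PO4-P": 10.0, "DOC": 650.0,
}

_FAMILIES = [
    ("Rhodocyclaceae", "Pseudomonadota", "Gammaproteobacteria", "Burkholderiales"),
    ("Competibacteraceae", "Pseudomonadota", "Gammaproteobacteria", "Competibacterales"),
    ("Methylophilaceae", "Pseudomonadota", "Gammaproteobacteria", "Burkholderiales"),
    ("Nitrosomonadaceae", "Pseudomonadota", "Gammaproteobacteria", "Burkholderiales"),
    ("Nitrospiraceae", "Nitrospirota", "Nitrospiria", "Nitrospirales"),
    ("Chitinophagaceae", "Bacteroidota", "Bacteroidia", "Chitinophagales"),
    ("Xanthomonadaceae", "Pseudomonadota", "Gammaproteobacteria", "Xanthomonadales"),
    ("Saprospiraceae", "Bacteroidota", "Bacteroidia", "Chitinophagales"),
]

_DEFAULT_PHARMA_DAYS = (
    0, 2, 5, 7, 10, 12, 14, 17, 19, 23, 27, 31, 34, 38, 42, 47, 51, 56,
    59, 63, 67, 71, 75, 80,
)
_DEFAULT_COMMUNITY_DAYS = (0, 5, 12, 17, 23, 34, 56, 80)


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the synthetic study.

    Defaults encode the emulated study conditions: 80 days of dosing at
    150 μg/L per compound, removal phase ending at day 12, desorption
    spike (effluent ~2x influent) ending at day 23, and negligible removal
    after. Community parameters control the paired count matrices.
    """

    n_days: int = 80
    dose_day: int = 0
    influent_level: float = 150.0
    removal_end: int = 12
    desorption_end: int = 23
    desorption_multiplier: float = 2.0
    phase1_removal: Mapping[str, float] = field(
        default_factory=lambda: {"DCF": 0.50, "ERY": 0.18, "GEM": 0.40}
    )
    post_desorption_removal: float = 0.0
    noise_cv: float = 0.10
    sampling_days: tuple | None = None
    community_days: tuple | None = None
    n_zotus: int = 60
    n_samples_per_reactor: int = 8
    active_fraction: float = 0.30
    phantom_fraction: float = 0.05
    active_multiplier: float = 3.0
    inactive_multiplier: float = 0.3
    depth_dna: int = 20000
    depth_cdna: int = 20000
    dirichlet_alpha: float = 5.0
    dirichlet_overdispersion: float = 300.0
    undersampled_phantoms: bool = False
    include_decoys: bool = True
    concentration_factor: float = 100.0
    solid_extract_ml: float = 10.0
    dry_weight_g: float = 0.5
    analyte_influent: Mapping[str, float] | None = None
    analyte_removal: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if not (0 <= self.removal_end < self.desorption_end <= self.n_days):
            raise ConfigurationError(
                "phase breaks must satisfy 0 <= removal_end < desorption_end"
                f" <= n_days, got {self.removal_end}, {self.desorption_end},"
                f" {self.n_days}"
            )
        if not 1.0 <= self.desorption_multiplier <= 2.5:
            raise ConfigurationError(
                "desorption_multiplier must be in [1, 2.5] (true removal is"
                " bounded in [-1.5, 1] by construction)"
            )
        for c, r in self.phase1_removal.items():
            if not 0 <= r <= 1:
                raise ConfigurationError(
                    f"phase-1 removal for {c} must be in [0, 1], got {r}"
                )
        for name in ("active_fraction", "phantom_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.active_fraction + self.phantom_fraction > 1:
            raise ConfigurationError(
                "active_fraction + phantom_fraction must be <= 1"
            )
        if self.depth_dna <= 0 or self.depth_cdna <= 0:
            raise ConfigurationError("library depths must be positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.influent_level <= 0:
            raise ConfigurationError("influent_level must be positive")
        if self.n_zotus < 2:
            raise ConfigurationError("n_zotus must be >= 2")
        if self.active_multiplier <= 0 or self.inactive_multiplier <= 0:
            raise ConfigurationError("activity multipliers must be positive")
        if self.analyte_influent is not None:
            for a, v in self.analyte_influent.items():
                if v < 0:
                    raise ConfigurationError(
                        f"negative influent concentration for {a}: {v}"
                    )
        if self.analyte_removal is not None:
            for a, r in self.analyte_removal.items():
                if not 0 <= r <= 1:
                    raise ConfigurationError(
                        f"analyte removal for {a} must be in [0, 1], got {r}"
                    )

    @property
    def phase_breaks(self) -> tuple[int, int]:
        return (self.removal_end, self.desorption_end)

    def pharma_days(self) -> tuple[int, ...]:
        if self.sampling_days is not None:
            days = tuple(sorted(set(int(d) for d in self.sampling_days)))
            if days and (days[0] < 0 or days[-1] > self.n_days):
                raise ConfigurationError("sampling days outside [0, n_days]")
            return days
        return tuple(d for d in _DEFAULT_PHARMA_DAYS if d <= self.n_days)

    def community_sample_days(self) -> tuple[int, ...]:
        if self.community_days is not None:
            days = tuple(sorted(set(int(d) for d in self.community_days)))
            if days and (days[0] < 0 or days[-1] > self.n_days):
                raise ConfigurationError("community days outside [0, n_days]")
            return days
        default = tuple(d for d in _DEFAULT_COMMUNITY_DAYS if d <= self.n_days)
        if self.n_samples_per_reactor == len(default):
            return default
        # even grid when a non-default sample count is requested
        return tuple(
            int(round(x))
            for x in np.linspace(0, self.n_days, self.n_samples_per_reactor)
        )


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    removal: pd.DataFrame | None = None          # compound, day, true_removal
    product_presence: pd.DataFrame | None = None  # compound, day, matrix, present
    true_active_zotus: frozenset = frozenset()
    phantom_zotus: frozenset = frozenset()

    def merge(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            removal=self.removal if other.removal is None else other.removal,
            product_presence=(
                self.product_presence
                if other.product_presence is None
                else other.product_presence
            ),
            true_active_zotus=self.true_active_zotus | other.true_active_zotus,
            phantom_zotus=self.phantom_zotus | other.phantom_zotus,
        )

    def zotu_table(self) -> pd.DataFrame:
        zotus = sorted(self.true_active_zotus | self.phantom_zotus)
        return pd.DataFrame(
            {
                "zotu_id": zotus,
                "truly_active": [z in self.true_active_zotus for z in zotus],
                "phantom": [z in self.phantom_zotus for z in zotus],
            }
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    )


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# pharmaceutical fate
# ---------------------------------------------------------------------------

def true_removal_fraction(config: SimConfig, compound: str, day: float) -> float:
    """Ground-truth removal fraction for one compound on one day."""
    if day < config.dose_day:
        return 0.0
    if day < config.removal_end:
        return float(config.phase1_removal.get(compound, 0.4))
    if day < config.desorption_end:
        return 1.0 - config.desorption_multiplier
    return float(config.post_desorption_removal)


def _phase_label(config: SimConfig, day: float) -> str:
    if day < config.removal_end:
        return "removal"
    if day < config.desorption_end:
        return "desorption"
    return "post"


def _solid_true_conc(config: SimConfig, day: float) -> float:
    """Solid-phase concentration trajectory (μg/g): rise then desorb."""
    s_max = config.influent_level * 0.10
    if day < config.removal_end:
        return s_max * (day + 1) / config.removal_end
    tail = s_max * np.exp(-(day - config.removal_end) / 4.0)
    if day < config.desorption_end:
        return float(tail)
    residual = s_max * np.exp(-(config.desorption_end - config.removal_end) / 4.0)
    return float(residual * np.exp(-(day - config.desorption_end) / 20.0))


def _product_intensity(config: SimConfig, day: float, matrix: str) -> float:
    """Relative degradation-product signal; zero means truly absent."""
    if matrix == "aqueous":
        if day < config.removal_end:
            return 0.3
        if day < config.desorption_end:
            return 0.6  # primary products wash out during the spike
        return 0.0
    if day < config.desorption_end:
        return 0.2
    return 0.0


@dataclass
class PharmaSim:
    """Tables produced by :func:`simulate_pharma_series`."""

    concentrations: pd.DataFrame
    recoveries: pd.DataFrame
    standards: pd.DataFrame
    peaks: pd.DataFrame
    truth: SimTruth


def simulate_pharma_series(config: SimConfig) -> PharmaSim:
    """Simulate influent/effluent/solid pharmaceutical measurements and peaks.

    Raw concentrations are the *measured* values: true concentration times
    the compound's extraction recovery times lognormal noise, so the
    recovery-correction stage must invert the distortion. Effluent truth is
    ``influent * (1 - true_removal)`` per phase. Degradation-product peaks
    are emitted only on days the product is truly present, with areas
    proportional to the biodegradation signal; when ``include_decoys`` is
    set, additional peaks that must fail the screening filter (mass error
    above 5 ppm or S/N below 10) are interleaved.
    """
    rng = _rng(config.seed, 0)
    days = config.pharma_days()
    db = default_compound_db()
    slope = {c: 1000.0 + 200.0 * i for i, c in enumerate(PARENTS)}

    conc_rows, peak_rows, removal_rows, presence_rows = [], [], [], []
    for day in days:
        phase = _phase_label(config, day)
        sample = f"test_d{day:03d}"
        for compound in PARENTS:
            r = true_removal_fraction(config, compound, day)
            removal_rows.append((compound, day, r))
            true_inf = config.influent_level if day >= config.dose_day else 0.0
            true_eff = true_inf * (1.0 - r)
            true_solid = _solid_true_conc(config, day) if day >= config.dose_day else 0.0
            rec_aq = DEFAULT_RECOVERY[(compound, "aqueous")][0]
            rec_sol = DEFAULT_RECOVERY[(compound, "solid")][0]
            for ph, true_val, rec, units in (
                ("influent", true_inf, rec_aq, "ug/L"),
                ("effluent", true_eff, rec_aq, "ug/L"),
                ("solid", true_solid, rec_sol, "ug/g"),
            ):
                raw = true_val * rec * _noise(rng, config.noise_cv)
                conc_rows.append(
                    (sample, "test", day, ph, compound, raw, units)
                )
            # control reactor receives no pharmaceuticals
            for ph, units in (("influent", "ug/L"), ("effluent", "ug/L"),
                              ("solid", "ug/g")):
                conc_rows.append(
                    (f"control_d{day:03d}", "control", day, ph, compound,
                     0.0, units)
                )
            # degradation-product peaks
            std_area = slope[compound] * 100.0
            for code in PRODUCTS[compound]:
                theo = adduct_mz(
                    monoisotopic_mass(
                        db.loc[db["code"] == code, "formula"].iloc[0]
                    )
                )
                for matrix, ph in (("aqueous", "effluent"), ("solid", "solid")):
                    intensity = _product_intensity(config, day, matrix)
                    presence_rows.append((code, day, matrix, intensity > 0))
                    if intensity <= 0:
                        continue
                    ppm = float(np.clip(rng.normal(0.0, 1.2), -4.0, 4.0))
                    area = std_area * intensity * _noise(rng, config.noise_cv)
                    peak_rows.append(
                        (sample, "test", day, ph, code,
                         theo * (1 + ppm * 1e-6), area,
                         float(rng.uniform(15, 60)),
                         config.concentration_factor if matrix == "aqueous" else np.nan,
                         config.dry_weight_g if matrix == "solid" else np.nan,
                         std_area)
                    )
                    if config.include_decoys and rng.random() < 0.25:
                        if rng.random() < 0.5:  # mass-error decoy
                            dppm = float(rng.uniform(6, 20)) * (
                                1 if rng.random() < 0.5 else -1
                            )
                            dsnr = float(rng.uniform(15, 60))
                        else:  # signal-to-noise decoy
                            dppm = float(np.clip(rng.normal(0.0, 1.2), -4, 4))
                            dsnr = float(rng.uniform(1, 9.5))
                        peak_rows.append(
                            (sample, "test", day, ph, code,
                             theo * (1 + dppm * 1e-6),
                             std_area * 0.05 * _noise(rng, config.noise_cv),
                             dsnr,
                             config.concentration_factor if matrix == "aqueous" else np.nan,
                             config.dry_weight_g if matrix == "solid" else np.nan,
                             std_area)
                        )

    concentrations = pd.DataFrame(
        conc_rows,
        columns=["sample_id", "reactor", "day", "phase", "compound",
                 "raw_conc", "units"],
    )
    peaks = pd.DataFrame(
        peak_rows,
        columns=["sample_id", "reactor", "day", "phase", "compound",
                 "observed_mz", "area", "snr", "concentration_factor",
                 "dry_weight_g", "standard_area_100"],
    )
    recoveries = pd.DataFrame(
        [
            (c, m, mean, sd)
            for (c, m), (mean, sd) in DEFAULT_RECOVERY.items()
        ],
        columns=["compound", "phase", "recovery_mean", "recovery_sd"],
    )
    nominal = np.array([0.0, 10.0, 25.0, 50.0, 100.0, 200.0])
    std_rows = []
    for compound in PARENTS:
        for solvent in ("methanol", "water"):
            areas = slope[compound] * nominal * _noise(
                rng, config.noise_cv, size=len(nominal)
            )
            for x, a in zip(nominal, areas):
                std_rows.append((compound, solvent, x, a))
    standards = pd.DataFrame(
        std_rows, columns=["compound", "solvent", "nominal_ugL", "area"]
    )
    truth = SimTruth(
        removal=pd.DataFrame(
            removal_rows, columns=["compound", "day", "true_removal"]
        ).drop_duplicates(ignore_index=True),
        product_presence=pd.DataFrame(
            presence_rows, columns=["compound", "day", "matrix", "present"]
        ).drop_duplicates(ignore_index=True),
    )
    return PharmaSim(concentrations, recoveries, standards, peaks, truth)


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------

@dataclass
class CommunitySim:
    """Paired count matrices and taxonomy from :func:`simulate_community`."""

    dna: dict[str, CountMatrix]
    cdna: dict[str, CountMatrix]
    taxonomy: pd.DataFrame
    truth: SimTruth


def _taxonomy(zotus: list[str]) -> pd.DataFrame:
    rows = []
    for i, z in enumerate(zotus):
        fam, phylum, cls, order = _FAMILIES[i % len(_FAMILIES)]
        rows.append(
            ("Bacteria", phylum, cls, order, fam, f"genus_{i % 17}", z)
        )
    return pd.DataFrame(
        rows,
        columns=["domain", "phylum", "class", "order", "family", "genus",
                 "zotu_id"],
    )[["zotu_id", "domain", "phylum", "class", "order", "family", "genus"]]


def simulate_community(config: SimConfig) -> CommunitySim:
    """Simulate paired DNA/cDNA ZOTU count matrices for both reactors.

    Per sample a latent DNA composition is drawn from a Dirichlet centred
    on the reactor's (time-drifting, for the test reactor) base
    composition; DNA counts are multinomial at ``depth_dna``. The cDNA
    composition reweights the same latent composition by each taxon's
    activity multiplier (``active_multiplier`` for truly active taxa,
    ``inactive_multiplier`` otherwise); cDNA counts are multinomial at
    ``depth_cdna``. Phantom taxa have structurally zero DNA concentration
    but positive cDNA concentration, so the phantom rule is exercised at
    any depth. ``undersampled_phantoms`` instead gives phantoms a tiny
    nonzero DNA concentration, producing phantoms by undersampling.
    """
    rng = _rng(config.seed, 1)
    n = config.n_zotus
    zotus = [f"ZOTU{i + 1:04d}" for i in range(n)]
    n_phantom = int(round(config.phantom_fraction * n))
    n_active = int(round(config.active_fraction * n))
    if n_active + n_phantom > n:
        raise ConfigurationError(
            "active_fraction + phantom_fraction leaves no inactive taxa"
        )
    phantom_ids = frozenset(zotus[n - n_phantom:]) if n_phantom else frozenset()
    elevated_ids = frozenset(zotus[:n_active])
    activity = np.where(
        np.isin(zotus, list(elevated_ids)),
        config.active_multiplier, config.inactive_multiplier,
    ).astype(float)
    activity[n - n_phantom:] = config.active_multiplier if n_phantom else 1.0

    base = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    dna_base = base.copy()
    if n_phantom:
        if config.undersampled_phantoms:
            dna_base[n - n_phantom:] = base[n - n_phantom:] * 1e-4
        else:
            dna_base[n - n_phantom:] = 0.0
    dna_base = dna_base / dna_base.sum()

    days = config.community_sample_days()
    dna_mats, cdna_mats = {}, {}
    taxonomy = _taxonomy(zotus)
    meta_rows = []
    for reactor in ("control", "test"):
        dna_cols, cdna_cols, sample_ids = {}, {}, []
        for day in days:
            sid = f"{reactor}_d{day:03d}"
            sample_ids.append(sid)
            meta_rows.append((sid, reactor, day))
            drift = np.ones(n)
            if reactor == "test":
                # pharmaceutical effect: some active taxa decline, some bloom
                k = min(3, n_active)
                drift[:k] = np.exp(-0.06 * day)
                if n_active > k:
                    k2 = min(n_active, k + 2)
                    drift[k:k2] = np.exp(0.05 * day)
            mean = dna_base * drift
            mean = mean / mean.sum()
            alpha = mean * config.dirichlet_overdispersion
            q = rng.dirichlet(np.where(alpha > 0, alpha, 1e-12))
            q = np.where(mean > 0, q, 0.0)
            q = q / q.sum()
            dna_cols[sid] = rng.multinomial(config.depth_dna, q)
            m = q * activity
            if n_phantom and not config.undersampled_phantoms:
                m[n - n_phantom:] = (
                    base[n - n_phantom:] * config.active_multiplier
                )
            m = m / m.sum()
            cdna_cols[sid] = rng.multinomial(config.depth_cdna, m)
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "reactor", "day"]
        ).set_index("sample_id")
        dna_mats[reactor] = CountMatrix(
            pd.DataFrame(dna_cols, index=zotus), "DNA",
            meta.loc[sample_ids].copy(),
        )
        cdna_mats[reactor] = CountMatrix(
            pd.DataFrame(cdna_cols, index=zotus), "cDNA",
            meta.loc[sample_ids].copy(),
        )

    truth = SimTruth(
        true_active_zotus=elevated_ids | phantom_ids,
        phantom_zotus=phantom_ids,
    )
    return CommunitySim(dna_mats, cdna_mats, taxonomy, truth)


def call_accuracy(calls: pd.DataFrame, truth: SimTruth) -> dict[str, float]:
    """Sensitivity and specificity of active calls against simulation truth.

    Evaluated over (ZOTU, sample) pairs for which the caller produced a
    defined mean ratio (taxa absent from both libraries carry no call).
    """
    scored = calls[calls["mean_ratio"].notna()]
    is_true = scored["zotu_id"].isin(truth.true_active_zotus)
    called = scored["active"].astype(bool)
    tp = int((is_true & called).sum())
    fn = int((is_true & ~called).sum())
    tn = int((~is_true & ~called).sum())
    fp = int((~is_true & called).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_scored": float(len(scored)),
    }


# ---------------------------------------------------------------------------
# conventional analytes and ordination
# ---------------------------------------------------------------------------

def _analyte_removal(config: SimConfig, analyte: str, reactor: str,
                     day: float) -> float:
    if config.analyte_removal is not None and analyte in config.analyte_removal:
        return (
            float(config.analyte_removal[analyte])
            if reactor == "test" else 1.0 if analyte.endswith("-N")
            else 0.95
        )
    if analyte in ("NH3-N", "NO2-N", "NO3-N"):
        if reactor == "control":
            return 1.0
        # drop to ~0.70, brief recovery peaking at 0.93 around day 13
        base = 0.70
        if 6 <= day <= 20:
            peak = 0.93
            frac = 1.0 - abs(day - 13.0) / 7.0
            return base + (peak - base) * max(frac, 0.0)
        return base
    if analyte == "PO4-P":
        if reactor == "control":
            return 0.95
        return 0.63 if day >= 3 else 0.95
    if analyte == "DOC":
        return 0.92
    return 0.5


def simulate_analytes(config: SimConfig) -> pd.DataFrame:
    """Tidy influent/effluent time series for the conventional analytes.

    Nitrogen enters as ammonia; effluent nitrogen is split between residual
    ammonia (85 %) and nitrate (15 %) so that total-nitrogen removal equals
    the configured trajectory exactly in the noise-free limit.
    """
    rng = _rng(config.seed, 2)
    influent = dict(DEFAULT_ANALYTE_INFLUENT)
    if config.analyte_influent:
        influent.update(config.analyte_influent)
    rows = []
    for reactor in ("control", "test"):
        for day in config.pharma_days():
            sid = f"{reactor}_d{day:03d}"
            for analyte, inf_level in influent.items():
                if analyte in ("NO2-N", "NO3-N"):
                    continue  # handled with ammonia below
                r = _analyte_removal(config, analyte, reactor, day)
                inf = inf_level * _noise(rng, config.noise_cv)
                if analyte == "NH3-N":
                    residual = inf_level * (1.0 - r)
                    eff = {
                        "NH3-N": residual * 0.85,
                        "NO2-N": 0.0,
                        "NO3-N": residual * 0.15,
                    }
                    rows.append((sid, reactor, day, "influent", "NH3-N", inf,
                                 "mg/L"))
                    rows.append((sid, reactor, day, "influent", "NO2-N", 0.0,
                                 "mg/L"))
                    rows.append((sid, reactor, day, "influent", "NO3-N", 0.0,
                                 "mg/L"))
                    for sp, val in eff.items():
                        rows.append(
                            (sid, reactor, day, "effluent", sp,
                             val * _noise(rng, config.noise_cv), "mg/L")
                        )
                else:
                    rows.append((sid, reactor, day, "influent", analyte, inf,
                                 "mg/L"))
                    rows.append(
                        (sid, reactor, day, "effluent", analyte,
                         inf_level * (1.0 - r) * _noise(rng, config.noise_cv),
                         "mg/L")
                    )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "reactor", "day", "phase", "analyte", "value",
                 "units"],
    )


def simulate_ordination(sample_meta: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic two-axis ordination coordinates for community samples.

    A stand-in for an externally computed NMDS: axis 1 tracks time (so
    effluent concentrations that change over the run correlate with it),
    axis 2 is noise. ``sample_meta`` must be indexed by sample_id with a
    ``day`` column.
    """
    rng = _rng(seed, 3)
    day = sample_meta["day"].to_numpy(dtype=float)
    scale = max(day.std(), 1.0)
    axis1 = (day - day.mean()) / scale + rng.normal(0, 0.25, len(day))
    axis2 = rng.normal(0, 0.5, len(day))
    return pd.DataFrame(
        {"axis1": axis1, "axis2": axis2}, index=sample_meta.index
    )
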