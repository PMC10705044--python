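"""Active-microbiome calling from paired rRNA gene (DNA) and transcript (cDNA) libraries.

The active community is the set of ZOTUs whose 16S rRNA transcript to rRNA
gene abundance ratio, averaged over repeated paired rarefaction trials, is
at least a threshold (1 by default). Both libraries of a sample are rarefied
without replacement to fixed depths in each trial; the ratio is taken on
rarefied relative abundances, so unequal DNA and cDNA depths remain
comparable. A *phantom* taxon — transcripts observed, gene reads absent in
the rarefied pair — is assigned a fixed large ratio of 100 in that trial, so
phantoms are always classified active. A ZOTU absent from both rarefied
libraries contributes no value to that trial's mean.

Downstream, relative abundances of the active community are computed from
unrarefied DNA read numbers (transcript counts can carry reverse-
transcription bias), as are richness and Shannon diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, PairingError, RarefactionError

PHANTOM_RATIO = 100.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer ZOTU-by-sample count matrix with per-sample metadata.

    ``counts``: DataFrame, ZOTU rows x sample columns, nonnegative ints.
    ``sample_meta``: DataFrame indexed by sample_id with at least
    ``reactor`` and ``day`` columns.
    """

    counts: pd.DataFrame
    library_type: str = "DNA"
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.library_type not in ("DNA", "cDNA"):
            raise DataError(f"library_type must be DNA or cDNA, got {self.library_type!r}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be >= 0")
        if self.counts.columns.duplicated().any():
            raise DataError("duplicate sample ids")
        if len(self.sample_meta) and not set(self.counts.columns) <= set(
            self.sample_meta.index
        ):
            raise DataError("sample metadata incomplete")

    @property
    def zotu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


class PairedLibraries(NamedTuple):
    """Matched DNA and cDNA count vectors over one ZOTU index for one sample."""

    sample_id: str
    dna_counts: pd.Series
    cdna_counts: pd.Series


def pair_samples(dna: CountMatrix, cdna: CountMatrix) -> Iterator[PairedLibraries]:
    """Iterate samples shared by both matrices as PairedLibraries.

    Raises PairingError when sample sets or ZOTU indices differ.
    """
    if set(dna.sample_ids) != set(cdna.sample_ids):
        raise PairingError(
            "DNA and cDNA matrices hold different samples: "
            f"{sorted(set(dna.sample_ids) ^ set(cdna.sample_ids))}"
        )
    if not dna.zotu_ids.equals(cdna.zotu_ids):
        if set(dna.zotu_ids) != set(cdna.zotu_ids):
            raise PairingError("DNA and cDNA matrices hold different ZOTUs")
        cdna = CountMatrix(
            cdna.counts.reindex(dna.zotu_ids), "cDNA", cdna.sample_meta
        )
    for sid in dna.sample_ids:
        d, c = dna.counts[sid], cdna.counts[sid]
        if d.sum() <= 0 or c.sum() <= 0:
            raise PairingError(f"sample {sid!r} has an empty library")
        yield PairedLibraries(sid, d, c)


# ---------------------------------------------------------------------------
# rarefaction and per-trial ratios
# ---------------------------------------------------------------------------

def rarefy(counts, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth`` reads.

    Equivalent to drawing ``depth`` reads from the library's read pool; the
    marginal distribution of each ZOTU's rarefied count is (multivariate)
    hypergeometric. Deterministic given ``seed`` (an int, SeedSequence, or
    Generator).
    """
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise DataError("rarefy expects a single library vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise DataError("counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise DataError("counts must be >= 0")
    total = int(arr.sum())
    depth = int(depth)
    if depth <= 0:
        raise RarefactionError("depth must be positive")
    if depth > total:
        raise RarefactionError(
            f"depth {depth} exceeds library total {total}"
        )
    if depth == total:
        return arr.astype(np.int64).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr.astype(np.int64), depth)


def ratio_one_trial(
    pair: PairedLibraries,
    depth_dna: int,
    depth_cdna: int,
    seed=None,
    phantom_value: float = PHANTOM_RATIO,
) -> pd.Series:
    """Transcript:gene ratio per ZOTU from one paired rarefaction trial.

    Both libraries are rarefied, then per ZOTU:

    * both rarefied counts zero -> NaN (taxon absent; contributes no value);
    * cDNA > 0 and DNA == 0 -> ``phantom_value`` (100);
    * otherwise cDNA relative abundance / DNA relative abundance
      (0 when the taxon has gene reads but no transcripts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = rarefy(pair.dna_counts.to_numpy(), depth_dna, rng)
    c = rarefy(pair.cdna_counts.to_numpy(), depth_cdna, rng)
    d_rel = d / depth_dna
    c_rel = c / depth_cdna
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, c_rel / np.where(d > 0, d_rel, 1.0), np.nan)
    ratio = np.where((d == 0) & (c > 0), phantom_value, ratio)
    # both zero stays NaN
    return pd.Series(ratio, index=pair.dna_counts.index, name=pair.sample_id)


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

def call_active(
    dna: CountMatrix,
    cdna: CountMatrix,
    n_trials: int = 100,
    threshold: float = 1.0,
    depth: int | None = None,
    depth_dna: int | None = None,
    depth_cdna: int | None = None,
    seed=None,
    phantom_value: float = PHANTOM_RATIO,
    absent_as_zero: bool = False,
) -> pd.DataFrame:
    """Classify ZOTUs as active from paired DNA/cDNA matrices.

    Runs ``n_trials`` paired rarefaction trials per sample, averages each
    ZOTU's per-trial ratios over the trials in which it had a value, and
    calls ``active = (mean_ratio >= threshold)``. Structural phantoms —
    zero total DNA reads but positive cDNA reads in the unrarefied sample —
    are assigned ``mean_ratio = phantom_value`` outright and are therefore
    active at any default threshold.

    The rarefaction depth defaults to the minimum library size across both
    pools and all samples; ``depth_dna``/``depth_cdna`` override per pool.
    A master ``seed`` spawns one child stream per (sample, trial), so each
    sample's result is independent of processing order.

    Returns a long DataFrame: sample_id, zotu_id, mean_ratio,
    phantom_frequency (fraction of trials the ZOTU was a trial-level
    phantom), active, dna_reads (unrarefied).
    """
    if n_trials < 1:
        raise DataError("n_trials must be >= 1")
    pairs = list(pair_samples(dna, cdna))
    if depth is None:
        depth = int(
            min(dna.library_sizes().min(), cdna.library_sizes().min())
        )
    d_dna = int(depth_dna if depth_dna is not None else depth)
    d_cdna = int(depth_cdna if depth_cdna is not None else depth)

    master = np.random.SeedSequence(seed)
    sample_seqs = master.spawn(len(pairs))

    records = []
    for pair, sseq in zip(pairs, sample_seqs):
        trial_seqs = sseq.spawn(n_trials)
        n_z = len(pair.dna_counts)
        ratios = np.empty((n_trials, n_z))
        phantom = np.zeros((n_trials, n_z), dtype=bool)
        for t, tseq in enumerate(trial_seqs):
            r = ratio_one_trial(
                pair, d_dna, d_cdna, np.random.default_rng(tseq),
                phantom_value,
            ).to_numpy()
            ratios[t] = r
            phantom[t] = r == phantom_value
        if absent_as_zero:
            mean_ratio = np.nanmean(np.nan_to_num(ratios, nan=0.0), axis=0)
        else:
            with np.errstate(invalid="ignore"):
                n_obs = np.sum(~np.isnan(ratios), axis=0)
                mean_ratio = np.where(
                    n_obs > 0, np.nansum(ratios, axis=0) / np.maximum(n_obs, 1),
                    np.nan,
                )
        dna_tot = pair.dna_counts.to_numpy()
        cdna_tot = pair.cdna_counts.to_numpy()
        structural = (dna_tot == 0) & (cdna_tot > 0)
        mean_ratio = np.where(structural, phantom_value, mean_ratio)
        active = np.where(
            np.isnan(mean_ratio), False, mean_ratio >= threshold
        )
        records.append(
            pd.DataFrame(
                {
                    "sample_id": pair.sample_id,
                    "zotu_id": pair.dna_counts.index,
                    "mean_ratio": mean_ratio,
                    "phantom_frequency": phantom.mean(axis=0),
                    "active": active.astype(bool),
                    "dna_reads": dna_tot,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# active-community composition and diversity
# ---------------------------------------------------------------------------

def active_relative_abundance(
    calls: pd.DataFrame, dna: CountMatrix
) -> pd.DataFrame:
    """Per-sample relative abundances within the active community.

    For each sample, abundance_i = dna_reads_i / sum over active ZOTUs of
    dna_reads, using unrarefied DNA read numbers. Phantom taxa are part of
    the active set and contribute their DNA reads (possibly zero). Samples
    with no active ZOTU, or whose active set carries zero DNA reads, yield
    an all-NaN column (flagged empty composition).

    Returns a ZOTU x sample DataFrame; non-active ZOTUs have abundance 0.
    """
    comp = pd.DataFrame(
        0.0, index=dna.zotu_ids, columns=dna.sample_ids
    )
    for sid, sub in calls.groupby("sample_id"):
        if sid not in comp.columns:
            raise PairingError(f"calls reference unknown sample {sid!r}")
        active = sub.loc[sub["active"], "zotu_id"]
        reads = dna.counts.loc[active, sid].astype(float)
        total = reads.sum()
        if len(active) == 0 or total <= 0:
            comp[sid] = np.nan
            continue
        comp.loc[active, sid] = (reads / total).to_numpy()
    return comp


class FamilyTables(NamedTuple):
    """Family-level aggregation: the full table and the reporting view."""

    full: pd.DataFrame
    reporting: pd.DataFrame


def aggregate_family(
    composition: pd.DataFrame,
    taxonomy: pd.DataFrame,
    min_plot_abundance: float = 0.01,
) -> FamilyTables:
    """Sum ZOTU abundances to family level.

    ``taxonomy`` must carry a ``family`` column indexed (or keyed by a
    ``zotu_id`` column) by ZOTU; missing labels fall back to
    ``"unclassified"``. The full table preserves column sums exactly; the
    reporting view keeps only families reaching ``min_plot_abundance`` in
    at least one sample (inclusive).
    """
    tax = taxonomy.set_index("zotu_id") if "zotu_id" in taxonomy.columns else taxonomy
    family = tax["family"].reindex(composition.index).fillna("unclassified")
    full = composition.groupby(family.to_numpy()).sum()
    full.index.name = "family"
    keep = (full >= min_plot_abundance).any(axis=1)
    return FamilyTables(full=full, reporting=full[keep])


def diversity_indices(dna: CountMatrix) -> pd.DataFrame:
    """Observed-ZOTU richness and Shannon entropy (natural log) per sample.

    Computed from DNA read numbers. Empty samples (zero reads) are flagged
    with NaN indices rather than dropped.
    """
    out = []
    for sid in dna.sample_ids:
        counts = dna.counts[sid].to_numpy()
        total = counts.sum()
        if total <= 0:
            out.append((sid, np.nan, np.nan))
            continue
        nz = counts[counts > 0]
        shannon = float(stats.entropy(nz))  # natural log
        out.append((sid, int((counts > 0).sum()), shannon))
    return pd.DataFrame(out, columns=["sample_id", "richness", "shannon"]).set_index(
        "sample_id"
    )
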