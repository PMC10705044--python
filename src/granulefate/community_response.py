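"""Between-timepoint response ratios and environmental vector fitting.

The response of an active ZOTU between two sampling days is summarized by
the bounded, symmetric response ratio

    rr = (b - a) / (b + a)

for relative abundances ``a`` (first timepoint) and ``b`` (second). The
statistic lives in [-1, 1]: +1 when a taxon appears from nothing, -1 when
it vanishes, 0 when unchanged. Values with |rr| <= 0.5 are classified
neutral; only taxa exceeding 0.1 % relative abundance at either timepoint
are scored.

Environmental vectors (e.g. effluent pharmaceutical concentrations) are
fitted onto externally supplied ordination coordinates by least squares,
with significance from a permutation test — the same construction as
vegan's ``envfit``. The ordination itself (NMDS) is an input, not computed
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


# ---------------------------------------------------------------------------
# response ratios
# ---------------------------------------------------------------------------

def response_ratio(a: float, b: float) -> float:
    """Bounded response ratio (b - a) / (b + a) for abundances a, b >= 0.

    Returns NaN (undefined) when both abundances are zero.
    """
    if a < 0 or b < 0:
        raise DataError("abundances must be >= 0")
    if a + b == 0:
        return float("nan")
    return (b - a) / (b + a)


def classify_response(rr: float, band: float = 0.5) -> str:
    """Classify a response ratio as negative / neutral / positive.

    The neutral band is inclusive: |rr| <= band is neutral, so the three
    categories partition [-1, 1] with deterministic boundaries.
    """
    if not -1.0 <= rr <= 1.0:
        raise DataError(f"response ratio out of [-1, 1]: {rr}")
    if abs(rr) <= band:
        return "neutral"
    return "positive" if rr > 0 else "negative"


def filter_min_abundance(
    abundance_t1: pd.Series,
    abundance_t2: pd.Series,
    min_abundance: float = 0.001,
) -> pd.Index:
    """ZOTUs exceeding ``min_abundance`` (strictly) at either timepoint.

    The filter retains taxa that appear or vanish between the timepoints —
    a taxon at 5 % then 0 passes, one at exactly the threshold at both
    timepoints does not.
    """
    if not abundance_t1.index.equals(abundance_t2.index):
        raise DataError("abundance vectors must share one ZOTU index")
    keep = (abundance_t1 > min_abundance) | (abundance_t2 > min_abundance)
    return abundance_t1.index[keep]


def response_table(
    composition: pd.DataFrame,
    sample_t1: str,
    sample_t2: str,
    min_abundance: float = 0.001,
    band: float = 0.5,
) -> pd.DataFrame:
    """Response ratios between two samples of an active-composition table.

    ``composition`` is ZOTU x sample (relative abundances within the
    active community). Returns one row per ZOTU passing the abundance
    filter: zotu_id, abundance_t1, abundance_t2, response_ratio, category.
    """
    for s in (sample_t1, sample_t2):
        if s not in composition.columns:
            raise DataError(f"sample {s!r} not in composition table")
    a = composition[sample_t1].fillna(0.0)
    b = composition[sample_t2].fillna(0.0)
    keep = filter_min_abundance(a, b, min_abundance)
    rows = []
    for z in keep:
        rr = response_ratio(float(a[z]), float(b[z]))
        rows.append((z, float(a[z]), float(b[z]), rr, classify_response(rr, band)))
    return pd.DataFrame(
        rows,
        columns=["zotu_id", "abundance_t1", "abundance_t2",
                 "response_ratio", "category"],
    )


# ---------------------------------------------------------------------------
# vector fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VectorFitResult:
    """A fitted environmental vector in ordination space."""

    variable: str
    direction: np.ndarray   # unit vector over ordination axes
    r_squared: float
    p_value: float
    n_perm: int


def vector_fit(
    ordination_scores,
    values,
    n_perm: int = 999,
    seed=None,
    variable: str = "",
) -> VectorFitResult:
    """Fit an environmental variable onto ordination coordinates.

    Ordinary least squares of the centered variable on the centered
    sample scores gives the arrow direction (normalized coefficient
    vector) and r² (fraction of variance explained). The p-value is a
    permutation test: values are randomly permuted across samples
    ``n_perm`` times and p = (1 + #{permuted r² >= observed}) / (1 + n_perm).
    """
    X = np.asarray(ordination_scores, dtype=float)
    y = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataError("ordination scores must be samples x >=2 axes")
    if X.shape[0] < 3:
        raise DataError("vector fitting needs >= 3 samples")
    if y.shape != (X.shape[0],):
        raise DataError("one value per sample required")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("non-finite inputs to vector_fit")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        raise DataError(f"constant variable {variable!r}: fit undefined")
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    norm = np.linalg.norm(beta)
    if norm == 0:
        direction = np.zeros_like(beta)
    else:
        direction = beta / norm
    # projection onto the column space of Xc -> r2 via the hat matrix
    hat = Xc @ np.linalg.pinv(Xc)
    fitted = hat @ yc
    r2 = float(fitted @ fitted) / ss_tot

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
        fitted_p = perms @ hat.T
        r2_perm = np.einsum("ij,ij->i", fitted_p, perms) / ss_tot
        p = (1 + int(np.sum(r2_perm >= r2))) / (1 + n_perm)
    else:
        p = float("nan")
    return VectorFitResult(
        variable=variable, direction=direction, r_squared=r2,
        p_value=p, n_perm=n_perm,
    )


def fit_environment(
    ordination: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Fit every column of ``env`` onto ``ordination`` (shared sample index).

    Returns a tidy table: variable, r_squared, p_value, and one
    ``axis_<name>`` column per ordination axis with the unit direction.
    Independent permutation streams are derived per variable from ``seed``.
    """
    common = ordination.index.intersection(env.index)
    if len(common) < 3:
        raise DataError("fewer than 3 shared samples between tables")
    X = ordination.loc[common]
    master = np.random.SeedSequence(seed)
    rows = []
    for child, col in zip(master.spawn(env.shape[1]), env.columns):
        res = vector_fit(
            X.to_numpy(), env.loc[common, col].to_numpy(),
            n_perm=n_perm, seed=np.random.default_rng(child), variable=col,
        )
        row = {"variable": col, "r_squared": res.r_squared,
               "p_value": res.p_value}
        for ax, d in zip(ordination.columns, res.direction):
            row[f"axis_{ax}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
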