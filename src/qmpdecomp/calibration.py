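"""Spike-in standard curves: raw reads -> absolute copies per gram (QMP).

Synthetic internal-standard sequences of known input copy number are added
to each DNA extract before amplification.  For every sample a standard
curve ``log10(R_s) = a * log10(C_s) + b`` is fitted by ordinary least
squares between spike read counts ``R_s`` and spike input copies ``C_s``;
inverting the curve converts any taxon's read count into absolute copies,
and dividing by the documented extract mass yields copies per gram.  The
companion relative pipeline (RMP) rarefies spike-free read counts to a
common depth.

Log base is 10 throughout: any base gives identical copies, but the
reported intercept is base-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix

logger = logging.getLogger("qmpdecomp")


@dataclass
class SpikeInDesign:
    """Spike-in manifest: input copy number per spike per sample.

    ``table`` is spike_id rows x sample columns, strictly positive, with at
    least two distinct copy levels per sample (a line needs two points).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.to_numpy() <= 0).any():
            raise ValueError("spike input copies must be strictly positive")
        n_levels = self.table.nunique(axis=0)
        if (n_levels < 2).any():
            bad = list(n_levels.index[n_levels < 2])
            raise ValueError(f"samples with fewer than 2 distinct spike copy levels: {bad[:5]}")

    @property
    def spike_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class StandardCurveFit:
    """Per-sample fit of log10(reads) on log10(input copies)."""

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def usable(self) -> bool:
        return self.n_points >= 2 and np.isfinite(self.slope) and self.slope > 0


class CalibrationError(ValueError):
    """Raised when a sample cannot be calibrated."""


def fit_standard_curve(
    spike_reads: pd.Series | np.ndarray,
    spike_copies: pd.Series | np.ndarray,
    sample_id: str = "",
) -> StandardCurveFit:
    """OLS of log10 spike reads on log10 spike input copies.

    Spikes with zero reads are dropped (the log is undefined there) and
    ``n_points`` decremented accordingly; fewer than two positive-read
    spikes is a calibration failure.
    """
    reads = np.asarray(spike_reads, dtype=float)
    copies = np.asarray(spike_copies, dtype=float)
    if reads.shape != copies.shape:
        raise ValueError("spike_reads and spike_copies must align")
    if (copies <= 0).any():
        raise ValueError("spike input copies must be strictly positive")
    if (reads < 0).any():
        raise ValueError("spike read counts must be nonnegative")
    keep = reads > 0
    if keep.sum() < 2 or len(np.unique(copies[keep])) < 2:
        raise CalibrationError(
            f"sample {sample_id or '<unnamed>'}: need >= 2 spikes with positive reads at distinct copy levels"
        )
    x, y = np.log10(copies[keep]), np.log10(reads[keep])
    res = stats.linregress(x, y)
    return StandardCurveFit(
        sample_id=sample_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(keep.sum()),
    )


def reads_to_copies(reads: np.ndarray | pd.Series | float, fit: StandardCurveFit) -> np.ndarray | float:
    """Invert the standard curve: copies = 10**((log10(reads) - b) / a).

    Zero reads map to zero copies (the curve is undefined at 0; absence of
    evidence maps to absence).  Strictly increasing in reads.
    """
    if not fit.usable:
        raise CalibrationError(f"sample {fit.sample_id}: standard-curve fit is unusable")
    arr = np.asarray(reads, dtype=float)
    if (arr < 0).any():
        raise ValueError("read counts must be nonnegative")
    out = np.zeros_like(arr, dtype=float)
    pos = arr > 0
    out[pos] = 10.0 ** ((np.log10(arr[pos]) - fit.intercept) / fit.slope)
    if np.isscalar(reads) or arr.ndim == 0:
        return float(out)
    if isinstance(reads, pd.Series):
        return pd.Series(out, index=reads.index)
    return out


def fit_sample_curves(
    counts: AbundanceMatrix,
    spikes: SpikeInDesign,
    r2_warn: float = 0.8,
) -> tuple[dict[str, StandardCurveFit], pd.DataFrame]:
    """Fit a standard curve for every sample; report a calibration table.

    Samples failing calibration (< 2 positive-read spikes) are flagged in
    the report (``usable = False``) and excluded from QMP downstream.
    Fits with R^2 below ``r2_warn`` are kept but logged as warnings.
    """
    if counts.mode != "raw_reads":
        raise ValueError("standard curves are fitted on raw read counts")
    missing = spikes.spike_ids.difference(counts.taxa)
    if len(missing):
        raise ValueError(f"spike rows absent from count matrix: {list(missing)}")
    fits: dict[str, StandardCurveFit] = {}
    rows = []
    for sample in counts.samples:
        rec = {"sample_id": sample, "slope": np.nan, "intercept": np.nan, "r_squared": np.nan, "n_points": 0}
        try:
            fit = fit_standard_curve(
                counts.data.loc[spikes.spike_ids, sample],
                spikes.table.loc[spikes.spike_ids, sample],
                sample_id=sample,
            )
        except CalibrationError as err:
            logger.warning("calibration failure: %s", err)
            rec["usable"] = False
        else:
            fits[sample] = fit
            rec.update(
                slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared,
                n_points=fit.n_points, usable=fit.usable,
            )
            if fit.r_squared < r2_warn:
                logger.warning("sample %s: standard-curve R^2 = %.3f < %.2f", sample, fit.r_squared, r2_warn)
        rows.append(rec)
    report = pd.DataFrame(rows).set_index("sample_id")
    return fits, report


def remove_spikeins(matrix: AbundanceMatrix, spike_ids) -> AbundanceMatrix:
    """Drop spike-in rows; idempotent, other rows untouched."""
    keep = ~matrix.taxa.isin(pd.Index(spike_ids))
    return matrix.with_data(matrix.data.loc[keep])


def copies_per_gram(copies: pd.DataFrame, masses: pd.Series) -> AbundanceMatrix:
    """Divide each sample column of absolute copies by its extract mass (g).

    Samples with missing or nonpositive mass are excluded with a log entry.
    """
    masses = masses.reindex(copies.columns)
    bad = masses.index[~(masses > 0)]
    if len(bad):
        logger.warning("dropping %d samples with missing/invalid mass: %s", len(bad), list(bad)[:5])
    keep = masses.index[masses > 0]
    return AbundanceMatrix(copies[keep] / masses[keep], mode="copies_per_gram")


def qmp_profile(
    counts: AbundanceMatrix,
    spikes: SpikeInDesign,
    masses: pd.Series,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Full QMP path: fit curves, invert reads, remove spikes, per gram.

    Returns the copies-per-gram matrix (calibratable samples only) and the
    per-sample calibration report.
    """
    fits, report = fit_sample_curves(counts, spikes)
    taxa_counts = remove_spikeins(counts, spikes.spike_ids)
    cols = {}
    for sample, fit in fits.items():
        if fit.usable:
            cols[sample] = reads_to_copies(taxa_counts.data[sample], fit)
    if not cols:
        raise CalibrationError("no sample could be calibrated")
    copies = pd.DataFrame(cols).reindex(columns=[s for s in counts.samples if s in cols])
    out = copies_per_gram(copies, masses)
    out.domain = counts.domain
    return out, report


def rarefy(matrix: AbundanceMatrix, depth: int | None = None, seed: int = 0) -> AbundanceMatrix:
    """Subsample reads without replacement to a common depth (RMP basis).

    Spike rows must already be removed.  ``depth`` defaults to the minimum
    sample total; samples with totals below ``depth`` are dropped with a
    log entry.  Every retained column sums exactly to ``depth``;
    deterministic given ``seed`` (multivariate hypergeometric draws).
    """
    if matrix.mode != "raw_reads":
        raise ValueError("rarefaction applies to raw read counts")
    totals = matrix.data.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    drop = totals.index[totals < depth]
    if len(drop):
        logger.warning("rarefaction drops %d samples below depth %d: %s", len(drop), depth, list(drop)[:5])
    keep = [s for s in matrix.samples if totals[s] >= depth]
    rng = np.random.default_rng(seed)
    cols = {}
    for sample in keep:
        counts = matrix.data[sample].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            cols[sample] = counts
        else:
            cols[sample] = rng.multivariate_hypergeometric(counts, depth)
    data = pd.DataFrame(cols, index=matrix.taxa, columns=keep)
    return AbundanceMatrix(data=data, mode="rarefied_reads", domain=matrix.domain)


def rmp_profile(
    counts: AbundanceMatrix,
    spike_ids,
    depth: int | None = None,
    seed: int = 0,
) -> AbundanceMatrix:
    """Full RMP path: remove spikes, rarefy to a common depth."""
    return rarefy(remove_spikeins(counts, spike_ids), depth=depth, seed=seed)
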