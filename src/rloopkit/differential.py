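"""Restriction-fragment count matrix and differential R-loop testing.

Peaks are intersected with the restriction-fragment tiling of the genome;
fragments overlapping at least one sample's significant peaks form the rows
of a count matrix whose entries are overlap-weighted sums of binned
coverage. Samples are normalized with median-of-ratios size factors and
rows are tested for differential abundance between two conditions with a
negative-binomial Wald test: dispersions are estimated by the method of
moments, pooled across rows of similar mean (a trend of bins), and the
log fold change is tested with a delta-method standard error. A fragment is
called differential when |log2FC| > 1 and the BH-adjusted p value is below
0.05.

This is a transparent reimplementation of the standard normalization /
NB-testing approach for count matrices; it deliberately trades the full
dispersion-shrinkage machinery of dedicated tools for an auditable
moment-based estimate, and is validated on simulations (type-I control and
power at planted fold changes).

The module also houses the low-count filter rule reused for expression
matrices: a gene is removed when at least half of the samples have fewer
than 20 normalized reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import CoverageTrack
from .peaks import Peak
from .restriction import RestrictionFragment
from .stats import bh_adjust

__all__ = [
    "FragmentCountMatrix",
    "build_count_matrix",
    "size_factors_median_of_ratios",
    "nb_test",
    "low_count_filter",
]

LOG2FC_GATE = 1.0
ALPHA = 0.05


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


@dataclass
class FragmentCountMatrix:
    """Integer counts per restriction fragment (rows) and sample (columns)."""

    counts: pd.DataFrame
    fragments: dict[str, RestrictionFragment]
    condition: pd.Series  # sample -> condition label
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            raise ValueError("every sample column needs a condition label")


def _fragment_counts(
    frag: RestrictionFragment, track: CoverageTrack
) -> float:
    """Overlap-weighted sum of bin counts inside the fragment."""
    bin_bp = track.bin_bp
    b0 = frag.start // bin_bp
    b1 = (frag.end - 1) // bin_bp
    b1 = min(b1, track.n_bins - 1)
    total = 0.0
    for b in range(b0, b1 + 1):
        bin_start = b * bin_bp
        bin_end = bin_start + bin_bp
        overlap = min(frag.end, bin_end) - max(frag.start, bin_start)
        if overlap > 0:
            total += track.counts[b] * overlap / bin_bp
    return total


def build_count_matrix(
    fragments: Sequence[RestrictionFragment],
    tracks: Mapping[str, CoverageTrack],
    condition: Mapping[str, str],
    peaks_by_sample: Mapping[str, Sequence[Peak]] | None = None,
) -> FragmentCountMatrix:
    """Count coverage per fragment and sample.

    When ``peaks_by_sample`` is given, rows are restricted to fragments
    overlapping (>= 1 bp) at least one sample's peaks ("empty frame" is an
    error); otherwise all fragments are counted, which is the appropriate
    frame for size-factor estimation because it is dominated by background
    fragments. Bin counts are apportioned by bin/fragment overlap fraction
    and rounded half-up so the totals are integers.
    """
    fragments = list(fragments)
    if peaks_by_sample is not None:
        intervals = sorted(
            (p.chrom, p.start, p.end)
            for peaks in peaks_by_sample.values()
            for p in peaks
        )
        kept: list[RestrictionFragment] = []
        for frag in fragments:
            if any(
                chrom == frag.chrom and start < frag.end and frag.start < end
                for chrom, start, end in intervals
            ):
                kept.append(frag)
        fragments = kept
        if not fragments:
            raise ValueError("empty frame: no fragment overlaps any peak")

    data = {
        sample: _round_half_up(
            np.array([_fragment_counts(f, track) for f in fragments])
        )
        for sample, track in tracks.items()
    }
    counts = pd.DataFrame(data, index=[f.id for f in fragments])
    cond = pd.Series({s: condition[s] for s in counts.columns})
    return FragmentCountMatrix(counts, {f.id: f for f in fragments}, cond)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (rows containing a zero are excluded
    from the geometric-mean reference)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no zero-free rows; cannot estimate size factors")
    logs = np.log(mat[positive])
    log_ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trend_dispersions(
    norm: np.ndarray, groups: list[np.ndarray], n_bins: int = 20, floor: float = 1e-8
) -> np.ndarray:
    """Moment dispersion per row, pooled across rows of similar mean.

    Per row, alpha is solved from the pooled within-group variance
    (var = mu + alpha mu^2); rows are then binned by overall mean and each
    row inherits the mean alpha of its bin, floored at ``floor``. The mean
    (not the median) keeps the pooled estimate unbiased: the per-row moment
    estimator is strongly right-skewed at few replicates, so its median
    underestimates the dispersion and inflates the Wald statistic.
    """
    n_rows = norm.shape[0]
    overall_mean = norm.mean(axis=1)
    alpha_raw = np.full(n_rows, np.nan)
    num = np.zeros(n_rows)
    den = np.zeros(n_rows)
    for idx in groups:
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += (var[ok] - mu[ok]) / mu[ok] ** 2 * (idx.size - 1)
        den[ok] += idx.size - 1
    ok = den > 0
    alpha_raw[ok] = num[ok] / den[ok]

    order = np.argsort(overall_mean, kind="mergesort")
    alpha = np.full(n_rows, floor)
    edges = np.linspace(0, n_rows, min(n_bins, max(1, n_rows)) + 1).astype(int)
    for i in range(len(edges) - 1):
        rows = order[edges[i] : edges[i + 1]]
        if rows.size == 0:
            continue
        vals = alpha_raw[rows]
        vals = vals[np.isfinite(vals)]
        pooled = float(np.mean(vals)) if vals.size else floor
        alpha[rows] = max(pooled, floor)
    return alpha


def nb_test(
    matrix: FragmentCountMatrix,
    reference: str,
    treatment: str,
    size_factors: pd.Series | None = None,
    n_trend_bins: int = 20,
) -> pd.DataFrame:
    """Negative-binomial Wald test of treatment vs reference per fragment.

    Returns a data frame with baseMean, log2FC (treatment over reference),
    p value, BH-adjusted p and the called flag (|log2FC| > 1 and adjusted
    p < 0.05). ``size_factors`` defaults to median-of-ratios factors of the
    matrix itself; in a pipeline they are usually estimated on the full
    (unrestricted) fragment frame and passed in.
    """
    counts = matrix.counts
    cond = matrix.condition
    ref_cols = np.flatnonzero((cond == reference).to_numpy())
    trt_cols = np.flatnonzero((cond == treatment).to_numpy())
    if ref_cols.size < 2 or trt_cols.size < 2:
        raise ValueError("each condition needs at least two samples")

    if size_factors is None:
        size_factors = matrix.size_factors
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors must be positive for every sample")

    norm = counts.to_numpy(dtype=float) / sf[None, :]
    alpha = _trend_dispersions(norm, [ref_cols, trt_cols], n_bins=n_trend_bins)

    pseudo = 0.5 / sf.mean()
    mu_ref = norm[:, ref_cols].mean(axis=1)
    mu_trt = norm[:, trt_cols].mean(axis=1)
    log2fc = np.log2((mu_trt + pseudo) / (mu_ref + pseudo))

    # delta-method variance of log(mean + pseudo) per group
    def se2_log(mu: np.ndarray, n: int) -> np.ndarray:
        var_mean = (mu + alpha * mu**2) / n
        return var_mean / (mu + pseudo) ** 2

    se = np.sqrt(se2_log(mu_ref, ref_cols.size) + se2_log(mu_trt, trt_cols.size))
    delta = np.log(mu_trt + pseudo) - np.log(mu_ref + pseudo)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * _sps.norm.sf(np.abs(z))
    p = np.clip(p, 5e-324, 1.0)
    padj = bh_adjust(p)
    called = (np.abs(log2fc) > LOG2FC_GATE) & (padj < ALPHA)

    return pd.DataFrame(
        {
            "fragment": counts.index,
            "baseMean": norm.mean(axis=1),
            "log2FC": log2fc,
            "p_value": p,
            "bh_adjusted_p": padj,
            "called": called,
        }
    ).set_index("fragment")


def low_count_filter(
    normalized: pd.DataFrame, min_reads: float = 20.0
) -> pd.Index:
    """Genes kept after the low-count rule.

    A gene is removed when at least half of the samples ("at least half"
    read inclusively, i.e. >= n/2) have fewer than ``min_reads`` normalized
    reads. Returns the index of kept genes.
    """
    if normalized.empty:
        raise ValueError("empty expression matrix")
    n = normalized.shape[1]
    below = (normalized < min_reads).sum(axis=1)
    return normalized.index[below < n / 2.0]
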