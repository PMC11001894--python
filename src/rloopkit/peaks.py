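"""Broad enrichment-peak calling against dual controls.

DRIP coverage is tested bin-by-bin against a local Poisson background whose
rate is the maximum of the depth-scaled input control, the depth-scaled
RNase H1-treated control, and the genome-wide scaled control mean, plus a
pseudocount. Candidate bins are merged across short gaps into broad peaks,
each peak is re-scored as a Poisson upper-tail test of its summed counts
against its summed background rate, and Benjamini-Hochberg q values are
computed over the candidate peak list. Using the maximum of the two controls
makes the returned peak set a subset of what either control alone would give
(on identical binning), and the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as _sps

from .io import CoverageTrack
from .stats import bh_adjust

__all__ = ["PeakCallParams", "Peak", "call_broad_peaks"]


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning knobs of the broad-peak caller.

    bin_bp: width of the coverage bins (all three tracks must agree).
    merge_gap_bp: candidate bin runs closer than this are merged into one
        peak (R-loops are broad; 1 kb bridges dips inside one structure).
    q_threshold: BH q-value cut-off on returned peaks (0.1 by convention
        for discovery-oriented broad calling).
    min_peak_bp: minimum peak span; 300 bp mirrors the span of large
        R-loop structures (300 bp - 1 kb).
    pseudocount: added to the background rate so zero-control bins cannot
        produce infinite enrichment.
    seed_p: per-bin Poisson p value below which a bin seeds a candidate
        peak (loose on purpose; the peak-level test and BH do the gating).
    """

    bin_bp: int = 200
    merge_gap_bp: int = 1000
    q_threshold: float = 0.1
    min_peak_bp: int = 300
    pseudocount: float = 0.5
    seed_p: float = 1e-3

    def __post_init__(self) -> None:
        if self.bin_bp < 1:
            raise ValueError("bin_bp must be >= 1")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class Peak:
    """A called (or consensus-annotated) enrichment interval."""

    chrom: str
    start: int
    end: int
    p_value: float
    q_value: Optional[float] = None
    fold_enrichment: float = float("nan")
    replicate_id: Optional[str] = None
    category: Optional[str] = None  # background / weak / stringent
    status: str = "candidate"  # candidate / confirmed / discarded / true_positive
    combined_p: Optional[float] = None
    bh_adjusted_p: Optional[float] = None
    rescued: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _poisson_sf(counts: np.ndarray | float, lam: np.ndarray | float) -> np.ndarray:
    """Upper tail P(X >= counts) for X ~ Poisson(lam)."""
    counts = np.ceil(np.asarray(counts, dtype=float))
    return _sps.poisson.sf(counts - 1.0, np.asarray(lam, dtype=float))


def call_broad_peaks(
    drip: CoverageTrack,
    input_track: CoverageTrack,
    rnh1_track: CoverageTrack,
    params: PeakCallParams | None = None,
    replicate_id: str | None = None,
) -> list[Peak]:
    """Call broad DRIP peaks against input and RNase H1 controls.

    Returns peaks with q value below ``params.q_threshold``, sorted by
    position. Raises on mismatched bin grids or empty tracks.
    """
    params = params or PeakCallParams()
    tracks = (drip, input_track, rnh1_track)
    if any(t.n_bins == 0 for t in tracks):
        raise ValueError("empty coverage track")
    if len({t.chrom for t in tracks}) != 1:
        raise ValueError("tracks are on different chromosomes")
    if len({t.bin_bp for t in tracks}) != 1 or len({t.n_bins for t in tracks}) != 1:
        raise ValueError("tracks are on mismatched bin grids")
    if params.bin_bp != drip.bin_bp:
        raise ValueError(
            f"params.bin_bp={params.bin_bp} does not match track bin {drip.bin_bp}"
        )
    if input_track.total <= 0 or rnh1_track.total <= 0 or drip.total <= 0:
        raise ValueError("library sizes must be positive")

    # depth scaling: counts-per-million ratio treatment / control
    scaled_input = input_track.counts * (drip.total / input_track.total)
    scaled_rnh1 = rnh1_track.counts * (drip.total / rnh1_track.total)
    genome_lambda = max(scaled_input.mean(), scaled_rnh1.mean())
    lam = np.maximum(np.maximum(scaled_input, scaled_rnh1), genome_lambda)
    lam = lam + params.pseudocount

    p_bin = _poisson_sf(drip.counts, lam)
    seeds = np.flatnonzero(p_bin < params.seed_p)
    if seeds.size == 0:
        return []

    # merge seed bins whose gaps are within merge_gap_bp
    gap_bins = params.merge_gap_bp // params.bin_bp
    runs: list[tuple[int, int]] = []
    run_start = prev = int(seeds[0])
    for b in seeds[1:]:
        if b - prev - 1 <= gap_bins:
            prev = int(b)
        else:
            runs.append((run_start, prev))
            run_start = prev = int(b)
    runs.append((run_start, prev))

    candidates: list[Peak] = []
    for b0, b1 in runs:
        start = b0 * params.bin_bp
        end = (b1 + 1) * params.bin_bp
        if end - start < params.min_peak_bp:
            continue
        total = float(drip.counts[b0 : b1 + 1].sum())
        expected = float(lam[b0 : b1 + 1].sum())
        p = float(_poisson_sf(total, expected))
        p = max(p, 5e-324)
        candidates.append(
            Peak(
                chrom=drip.chrom,
                start=start,
                end=end,
                p_value=p,
                fold_enrichment=total / expected,
                replicate_id=replicate_id,
            )
        )
    if not candidates:
        return []

    q = bh_adjust([p.p_value for p in candidates])
    kept: list[Peak] = []
    for peak, qv in zip(candidates, q):
        peak.q_value = float(qv)
        if peak.q_value < params.q_threshold:
            kept.append(peak)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept
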