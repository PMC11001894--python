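"""Multi-replicate peak confirmation and group shared-peak derivation.

Replicate peak sets are combined with a categorize / rescue / combine /
correct procedure:

1. each peak is categorized by its p value as background (p > tau_weak),
   weak (tau_stringent < p <= tau_weak) or stringent (p <= tau_stringent);
2. background peaks are discarded; the remaining peaks from all replicates
   are grouped into overlap components (>= 1 bp intersection, closed
   transitively);
3. a weak peak is flagged rescued when its component contains a stringent
   peak from another replicate;
4. a peak is confirmed when its component contains peaks from at least
   ``min_supporting_replicates`` other replicates AND the Fisher-combined
   p value over the component's peaks is at most ``gamma_combined``;
5. confirmed peaks undergo Benjamini-Hochberg correction of the combined
   p values at ``alpha_bh``; survivors are true positives, the rest are
   discarded.

Consensus intervals are the union spans of components that retain at least
one true-positive peak. A group's *shared peaks* are merged consensus
intervals supported by a true-positive peak in every sample of the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .peaks import Peak
from .stats import bh_adjust, fisher_combine

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "categorize",
    "confirm_across_replicates",
    "shared_peaks",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the replicate-confirmation procedure.

    tau_weak / tau_stringent: p-value cut-offs (1e-4 and 1e-8) separating
        background, weak and stringent peaks.
    gamma_combined: ceiling (1e-8) on the Fisher-combined p value of an
        overlap component for confirmation.
    alpha_bh: FDR level (0.05) of the final BH pass over confirmed peaks.
    min_supporting_replicates: how many *other* replicates must contribute
        an overlapping non-background peak.
    """

    tau_weak: float = 1e-4
    tau_stringent: float = 1e-8
    gamma_combined: float = 1e-8
    alpha_bh: float = 0.05
    min_supporting_replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("tau_weak", "tau_stringent", "gamma_combined", "alpha_bh"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.tau_stringent > self.tau_weak:
            raise ValueError("tau_stringent must not exceed tau_weak")
        if self.min_supporting_replicates < 0:
            raise ValueError("min_supporting_replicates must be >= 0")


def categorize(peaks: Sequence[Peak], params: ConsensusParams | None = None) -> list[Peak]:
    """Assign background / weak / stringent categories in place (and return)."""
    params = params or ConsensusParams()
    for peak in peaks:
        if peak.p_value is None:
            raise ValueError("peak without p value cannot be categorized")
        if peak.p_value <= params.tau_stringent:
            peak.category = "stringent"
        elif peak.p_value <= params.tau_weak:
            peak.category = "weak"
        else:
            peak.category = "background"
    return list(peaks)


def _overlap_components(peaks: list[tuple[int, Peak]]) -> list[list[tuple[int, Peak]]]:
    """Group (replicate_index, peak) records into transitive overlap components."""
    by_chrom: dict[str, list[tuple[int, Peak]]] = {}
    for rec in peaks:
        by_chrom.setdefault(rec[1].chrom, []).append(rec)
    components: list[list[tuple[int, Peak]]] = []
    for chrom_peaks in by_chrom.values():
        chrom_peaks.sort(key=lambda rec: (rec[1].start, rec[1].end))
        current: list[tuple[int, Peak]] = []
        max_end = -1
        for rec in chrom_peaks:
            if current and rec[1].start < max_end:
                current.append(rec)
            else:
                if current:
                    components.append(current)
                current = [rec]
            max_end = max(max_end, rec[1].end)
        if current:
            components.append(current)
    return components


@dataclass
class ConsensusResult:
    """Annotated per-replicate peaks plus deduplicated consensus intervals."""

    peaks_by_replicate: list[list[Peak]]
    consensus_intervals: list[tuple[str, int, int]]
    params: ConsensusParams = field(default_factory=ConsensusParams)

    def true_positives(self, replicate: int) -> list[Peak]:
        return [p for p in self.peaks_by_replicate[replicate] if p.status == "true_positive"]

    def audit_table(self) -> pd.DataFrame:
        rows = []
        for rep, peaks in enumerate(self.peaks_by_replicate):
            for p in peaks:
                rows.append(
                    {
                        "replicate": rep,
                        "chrom": p.chrom,
                        "start": p.start,
                        "end": p.end,
                        "p_value": p.p_value,
                        "category": p.category,
                        "rescued": p.rescued,
                        "combined_p": p.combined_p,
                        "bh_adjusted_p": p.bh_adjusted_p,
                        "status": p.status,
                    }
                )
        return pd.DataFrame(rows)


def confirm_across_replicates(
    peaksets: Sequence[Sequence[Peak]],
    params: ConsensusParams | None = None,
) -> ConsensusResult:
    """Run the categorize / rescue / combine / BH procedure over replicates.

    ``peaksets`` holds one peak list per biological replicate. Peaks are
    categorized if they do not carry a category yet. Every peak leaves with
    a status of true_positive or discarded; consensus intervals are the
    union spans of components containing a true positive.
    """
    params = params or ConsensusParams()
    if len(peaksets) == 0:
        raise ValueError("need at least one replicate peak set")

    annotated: list[list[Peak]] = [list(ps) for ps in peaksets]
    for peaks in annotated:
        for p in peaks:
            if p.category is None:
                categorize([p], params)

    surviving: list[tuple[int, Peak]] = []
    for rep, peaks in enumerate(annotated):
        for p in peaks:
            if p.category == "background":
                p.status = "discarded"
            else:
                surviving.append((rep, p))

    components = _overlap_components(surviving)
    confirmed: list[Peak] = []
    component_of: dict[int, list[tuple[int, Peak]]] = {}
    for comp in components:
        reps = {rep for rep, _ in comp}
        combined = fisher_combine([p.p_value for _, p in comp])
        for rep, p in comp:
            p.combined_p = combined
            component_of[id(p)] = comp
            other_reps = reps - {rep}
            if p.category == "weak":
                p.rescued = any(
                    q.category == "stringent" for r, q in comp if r != rep
                )
            supported = len(other_reps) >= params.min_supporting_replicates
            if supported and combined <= params.gamma_combined:
                p.status = "confirmed"
                confirmed.append(p)
            else:
                p.status = "discarded"

    if confirmed:
        adj = bh_adjust([p.combined_p for p in confirmed])
        for p, a in zip(confirmed, adj):
            p.bh_adjusted_p = float(a)
            p.status = "true_positive" if a <= params.alpha_bh else "discarded"

    intervals: set[tuple[str, int, int]] = set()
    for p in confirmed:
        if p.status == "true_positive":
            comp = component_of[id(p)]
            chrom = comp[0][1].chrom
            intervals.add(
                (chrom, min(q.start for _, q in comp), max(q.end for _, q in comp))
            )
    consensus = sorted(intervals)
    return ConsensusResult(annotated, consensus, params)


def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def shared_peaks(
    true_positive_sets: Sequence[Sequence[Peak]],
) -> tuple[list[tuple[str, int, int]], int]:
    """Merged intervals detected in *every* sample of a group.

    ``true_positive_sets`` holds, per sample of the group, that sample's
    true-positive peaks. All peaks are merged into candidate intervals; an
    interval is *shared* when it overlaps (>= 1 bp) at least one peak from
    every sample. Returns (shared intervals, count).
    """
    if len(true_positive_sets) == 0:
        raise ValueError("group must contain at least one sample")
    all_intervals = [
        (p.chrom, p.start, p.end) for peaks in true_positive_sets for p in peaks
    ]
    shared: list[tuple[str, int, int]] = []
    for chrom, start, end in _merge_intervals(all_intervals):
        hit_in_all = all(
            any(
                p.chrom == chrom and p.start < end and start < p.end
                for p in sample_peaks
            )
            for sample_peaks in true_positive_sets
        )
        if hit_in_all:
            shared.append((chrom, start, end))
    return shared, len(shared)
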