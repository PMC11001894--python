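"""Peak-to-gene-feature annotation and integrative overlap analyses.

Peaks are assigned a single gene-feature class from the position of their
midpoint, with a fixed priority: promoter-TSS window > 5'UTR > 3'UTR > TTS
window > gene body > intergenic. Windows are strand-aware: the promoter
window spans 1000 bp upstream to 100 bp downstream of the TSS, the TTS
window 100 bp upstream to 1000 bp downstream of the TTS. Midpoint
assignment makes the classes a partition, so class proportions and
mutant-vs-wild-type shares are well defined.

The module also quantifies how R-loop losses co-locate with intron
retention reduction (IRR) splicing events, and compares gene expression
between conditions stratified by where the lost R-loop sat on the gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .peaks import Peak
from .stats import wilcoxon_signed_rank_one_sample

__all__ = [
    "GeneModel",
    "SpliceEvent",
    "FeatureAnnotation",
    "FEATURE_CLASSES",
    "annotate_peak",
    "annotate_peaks",
    "feature_distribution",
    "group_feature_share",
    "irr_rloop_overlap",
    "class_loss_gene_sets",
    "expression_by_rloop_location",
]

FEATURE_CLASSES = (
    "promoter-TSS",
    "5'UTR",
    "gene body",
    "TTS",
    "3'UTR",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon/UTR structure on a chromosome (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.start >= self.end:
            raise ValueError("gene span must be non-empty")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class SpliceEvent:
    """A differential splicing event (delta PSI = mutant - reference)."""

    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    delta_psi: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if abs(self.delta_psi) > 1:
            raise ValueError("|delta_psi| cannot exceed 1")

    @property
    def is_irr(self) -> bool:
        """Intron retention reduction: retention event with delta PSI below
        -0.10 at adjusted p < 0.05."""
        return (
            self.event_type == "intron_retention"
            and self.delta_psi < -0.10
            and self.adjusted_p < 0.05
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    peak_id: str
    feature_class: str
    gene_id: Optional[str]


def _windows(
    gene: GeneModel,
    promoter_upstream: int,
    promoter_downstream: int,
    tts_upstream: int,
    tts_downstream: int,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(promoter window, TTS window) in genomic coordinates, strand-aware."""
    if gene.strand == "+":
        prom = (gene.tss - promoter_upstream, gene.tss + promoter_downstream)
        tts = (gene.tts - tts_upstream, gene.tts + tts_downstream)
    else:
        prom = (gene.tss - promoter_downstream, gene.tss + promoter_upstream)
        tts = (gene.tts - tts_downstream, gene.tts + tts_upstream)
    return prom, tts


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
    tts_upstream: int = 100,
    tts_downstream: int = 1000,
    peak_id: str | None = None,
) -> FeatureAnnotation:
    """Classify one peak by its midpoint with the fixed feature priority."""
    chroms = {g.chrom for g in genes}
    if peak.chrom not in chroms:
        raise ValueError(f"peak on unknown chromosome {peak.chrom!r}")
    mid = peak.midpoint
    pid = peak_id or f"{peak.chrom}:{peak.start}-{peak.end}"

    def hit(lo: int, hi: int) -> bool:
        return lo <= mid < hi

    candidates = [g for g in genes if g.chrom == peak.chrom]

    for g in candidates:
        prom, _ = _windows(
            g, promoter_upstream, promoter_downstream, tts_upstream, tts_downstream
        )
        if hit(*prom):
            return FeatureAnnotation(pid, "promoter-TSS", g.gene_id)
    for g in candidates:
        if g.utr5 and hit(*g.utr5):
            return FeatureAnnotation(pid, "5'UTR", g.gene_id)
    for g in candidates:
        if g.utr3 and hit(*g.utr3):
            return FeatureAnnotation(pid, "3'UTR", g.gene_id)
    for g in candidates:
        _, tts = _windows(
            g, promoter_upstream, promoter_downstream, tts_upstream, tts_downstream
        )
        if hit(*tts):
            return FeatureAnnotation(pid, "TTS", g.gene_id)
    for g in candidates:
        if hit(g.start, g.end):
            return FeatureAnnotation(pid, "gene body", g.gene_id)
    return FeatureAnnotation(pid, "intergenic", None)


def annotate_peaks(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], **kwargs
) -> list[FeatureAnnotation]:
    return [
        annotate_peak(p, genes, peak_id=f"peak_{i}", **kwargs)
        for i, p in enumerate(peaks)
    ]


def feature_distribution(
    annotations: Sequence[FeatureAnnotation],
) -> dict[str, float]:
    """Proportion of peaks per feature class (sums to 1)."""
    if not annotations:
        raise ValueError("no annotations")
    n = len(annotations)
    return {
        cls: sum(a.feature_class == cls for a in annotations) / n
        for cls in FEATURE_CLASSES
    }


def group_feature_share(
    annotations_by_group: Mapping[str, Sequence[FeatureAnnotation]],
    numerator_group: str,
) -> dict[str, float]:
    """Per-class share of the numerator group among all groups' peaks.

    With groups {MUT, WT}, share(class) = n_MUT / (n_MUT + n_WT); classes
    with no peak in any group are omitted.
    """
    if not annotations_by_group or all(
        len(v) == 0 for v in annotations_by_group.values()
    ):
        raise ValueError("no annotations")
    if numerator_group not in annotations_by_group:
        raise ValueError(f"unknown group {numerator_group!r}")
    shares: dict[str, float] = {}
    for cls in FEATURE_CLASSES:
        totals = {
            grp: sum(a.feature_class == cls for a in anns)
            for grp, anns in annotations_by_group.items()
        }
        denom = sum(totals.values())
        if denom:
            shares[cls] = totals[numerator_group] / denom
    return shares


def _percent_half_up(fraction: float) -> int:
    return int(math.floor(fraction * 100 + 0.5))


def irr_rloop_overlap(
    lost_rloop_genes: Iterable[str],
    events: Sequence[SpliceEvent],
) -> tuple[int, int, float, int]:
    """Overlap of IRR events with genes that lost an R-loop.

    Events are restricted to IRRs and deduplicated by (gene, intron
    interval). An IRR is overlapped when its gene carries at least one lost
    R-loop (at any of UTRs, TSS, TTS or gene body). Returns
    (overlapped, total, fraction, percent rounded half-up).
    """
    lost = set(lost_rloop_genes)
    seen: set[tuple[str, str, int, int]] = set()
    irrs: list[SpliceEvent] = []
    for ev in events:
        if not ev.is_irr:
            continue
        key = (ev.gene_id, ev.chrom, ev.start, ev.end)
        if key not in seen:
            seen.add(key)
            irrs.append(ev)
    if not irrs:
        raise ValueError("empty IRR set")
    overlapped = sum(ev.gene_id in lost for ev in irrs)
    fraction = overlapped / len(irrs)
    return overlapped, len(irrs), fraction, _percent_half_up(fraction)


def class_loss_gene_sets(
    reference_annotations: Sequence[FeatureAnnotation],
    mutant_annotations: Sequence[FeatureAnnotation],
    classes: Sequence[str] = ("promoter-TSS", "gene body", "TTS", "3'UTR"),
) -> dict[str, set[str]]:
    """Genes with a reference R-loop at each class and none there in mutant."""
    mut_by_class: dict[str, set[str]] = {}
    for a in mutant_annotations:
        if a.gene_id:
            mut_by_class.setdefault(a.feature_class, set()).add(a.gene_id)
    out: dict[str, set[str]] = {}
    for cls in classes:
        ref_genes = {
            a.gene_id
            for a in reference_annotations
            if a.feature_class == cls and a.gene_id
        }
        out[cls] = ref_genes - mut_by_class.get(cls, set())
    return out


def expression_by_rloop_location(
    expr_ref: pd.DataFrame,
    expr_mut: pd.DataFrame,
    gene_sets_by_class: Mapping[str, Iterable[str]],
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-class reference-minus-mutant expression differences.

    For each class, the per-gene difference of mean expression (reference
    minus mutant) is computed over the class's gene set, and a two-sided
    one-sample Wilcoxon signed-rank test compares the differences to a
    theoretical mean of 0. Classes with fewer than ``min_n`` genes are
    reported with a missing p value; empty classes are skipped with a
    warning. Identical matrices give difference 0 and p = 1.
    """
    common = expr_ref.index.intersection(expr_mut.index)
    rows = []
    for cls, genes in gene_sets_by_class.items():
        genes = [g for g in genes if g in common]
        if not genes:
            warnings.warn(f"class {cls!r} has no genes with expression; skipped")
            continue
        diffs = (
            expr_ref.loc[genes].mean(axis=1) - expr_mut.loc[genes].mean(axis=1)
        ).to_numpy()
        if len(genes) < min_n:
            p = float("nan")
        elif np.all(diffs == 0):
            p = 1.0
        else:
            p = wilcoxon_signed_rank_one_sample(diffs, mu0=0.0).p_value
        rows.append(
            {
                "feature_class": cls,
                "n_genes": len(genes),
                "mean_difference": float(np.mean(diffs)),
                "median_difference": float(np.median(diffs)),
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows)
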