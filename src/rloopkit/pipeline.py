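"""End-to-end synthetic study: simulate, call, confirm, test, integrate.

This module wires the whole analysis together on generated data with
planted truth, so the recovery of lost R-loop loci, the group contrast in
shared-peak counts, and the IRR/expression integration can all be measured
against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotate, consensus, differential, peaks, restriction, simulate
from .annotate import FeatureAnnotation
from .peaks import Peak, PeakCallParams
from .simulate import CONDITIONS, RLoopTruth, SimulationDesign

__all__ = ["StudyResult", "run_synthetic_study", "evaluate_lost_locus_recovery"]


@dataclass
class StudyResult:
    """All intermediate and final products of one synthetic study run."""

    design: SimulationDesign
    genes: list
    truth: list[RLoopTruth]
    peaks_by_sample: dict[str, list[Peak]]
    consensus_by_group: dict[str, consensus.ConsensusResult]
    shared_by_group: dict[str, list[tuple[str, int, int]]]
    shared_counts: dict[str, int]
    size_factors: pd.Series
    differential_table: pd.DataFrame
    recovery: dict[str, float]
    irr_overlap: tuple[int, int, float, int] | None
    expression_comparison: pd.DataFrame | None
    annotations_by_group: dict[str, list[FeatureAnnotation]] = field(
        default_factory=dict
    )


def _sample_name(condition: str, replicate: int) -> str:
    return f"{condition}_{replicate + 1}"


def evaluate_lost_locus_recovery(
    truth: list[RLoopTruth],
    fragments,
    diff_table: pd.DataFrame,
) -> dict[str, float]:
    """Recall/precision of lost-locus recovery from called-down fragments.

    A planted locus counts as *recovered* when it overlaps at least one
    fragment called differential with negative log2FC (down in mutant).
    Recall is measured over truly lost loci; precision over all recovered
    loci.
    """
    frag_by_id = {f.id: f for f in fragments}
    down = [
        frag_by_id[fid]
        for fid, row in diff_table.iterrows()
        if row["called"] and row["log2FC"] < 0 and fid in frag_by_id
    ]
    recovered: set[int] = set()
    for i, locus in enumerate(truth):
        for frag in down:
            if (
                frag.chrom == locus.chrom
                and frag.start < locus.end
                and locus.start < frag.end
            ):
                recovered.add(i)
                break
    true_lost = {i for i, t in enumerate(truth) if t.lost_in_mutant}
    tp = len(recovered & true_lost)
    recall = tp / len(true_lost) if true_lost else float("nan")
    precision = tp / len(recovered) if recovered else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_recovered": float(len(recovered)),
        "n_true_lost": float(len(true_lost)),
    }


def run_synthetic_study(
    design: SimulationDesign | None = None,
    peak_params: PeakCallParams | None = None,
    consensus_params: consensus.ConsensusParams | None = None,
    with_irr_expression: bool = True,
) -> StudyResult:
    """Run the full pipeline on one synthetic design.

    Steps: genome + truth generation; per-sample coverage (DRIP, input,
    RNase H1); per-sample broad peak calling; per-group replicate
    confirmation and shared-peak counting; restriction digestion; count
    matrix over peak-overlapping fragments with size factors estimated on
    the full fragment frame; NB differential test (MUT vs WT); lost-locus
    recovery against the planted truth; IRR overlap and expression
    stratification from the confirmed peak annotations.
    """
    design = design or SimulationDesign()
    peak_params = peak_params or PeakCallParams(bin_bp=design.bin_bp)
    consensus_params = consensus_params or consensus.ConsensusParams()

    genome, genes = simulate.make_genome(design)
    truth = simulate.plant_rloops(design, genes)

    tracks: dict[str, dict[str, object]] = {}
    peaks_by_sample: dict[str, list[Peak]] = {}
    for condition in CONDITIONS:
        for rep in range(design.n_replicates_per_group):
            sample = _sample_name(condition, rep)
            roles = {
                role: simulate.simulate_coverage(truth, design, condition, rep, role)
                for role in simulate.ROLES
            }
            tracks[sample] = roles
            peaks_by_sample[sample] = peaks.call_broad_peaks(
                roles["drip"],
                roles["input"],
                roles["rnh1"],
                peak_params,
                replicate_id=sample,
            )

    consensus_by_group: dict[str, consensus.ConsensusResult] = {}
    shared_by_group: dict[str, list[tuple[str, int, int]]] = {}
    shared_counts: dict[str, int] = {}
    for condition in CONDITIONS:
        samples = [
            _sample_name(condition, rep)
            for rep in range(design.n_replicates_per_group)
        ]
        result = consensus.confirm_across_replicates(
            [peaks_by_sample[s] for s in samples], consensus_params
        )
        consensus_by_group[condition] = result
        tp_sets = [result.true_positives(i) for i in range(len(samples))]
        shared, count = consensus.shared_peaks(tp_sets)
        shared_by_group[condition] = shared
        shared_counts[condition] = count

    fragments = restriction.digest(genome, restriction.builtin_enzymes())
    drip_tracks = {s: roles["drip"] for s, roles in tracks.items()}
    condition_of = {s: s.split("_")[0] for s in drip_tracks}

    full_matrix = differential.build_count_matrix(
        fragments, drip_tracks, condition_of, peaks_by_sample=None
    )
    size_factors = differential.size_factors_median_of_ratios(full_matrix.counts)
    peak_matrix = differential.build_count_matrix(
        fragments, drip_tracks, condition_of, peaks_by_sample=peaks_by_sample
    )
    diff_table = differential.nb_test(
        peak_matrix, reference="WT", treatment="MUT", size_factors=size_factors
    )
    recovery = evaluate_lost_locus_recovery(truth, fragments, diff_table)

    # annotate each group's shared peaks for the feature analyses
    annotations_by_group: dict[str, list[FeatureAnnotation]] = {}
    for condition, shared in shared_by_group.items():
        shared_as_peaks = [
            Peak(chrom=c, start=s, end=e, p_value=1e-12) for c, s, e in shared
        ]
        annotations_by_group[condition] = annotate.annotate_peaks(
            shared_as_peaks, genes
        )

    irr_overlap = None
    expression_comparison = None
    if with_irr_expression:
        events_df, expr_wt, expr_mut = simulate.simulate_irr_and_expression(
            truth, design, genes
        )
        events = [
            annotate.SpliceEvent(
                gene_id=row.gene_id,
                event_type=row.event_type,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                delta_psi=float(row.delta_psi),
                adjusted_p=float(row.adjusted_p),
            )
            for row in events_df.itertuples()
        ]
        lost_genes = {
            t.linked_gene for t in truth if t.lost_in_mutant and t.linked_gene
        }
        if events:
            irr_overlap = annotate.irr_rloop_overlap(lost_genes, events)
        gene_sets = annotate.class_loss_gene_sets(
            annotations_by_group["WT"], annotations_by_group["MUT"]
        )
        expression_comparison = annotate.expression_by_rloop_location(
            expr_wt, expr_mut, gene_sets
        )

    return StudyResult(
        design=design,
        genes=genes,
        truth=truth,
        peaks_by_sample=peaks_by_sample,
        consensus_by_group=consensus_by_group,
        shared_by_group=shared_by_group,
        shared_counts=shared_counts,
        size_factors=size_factors,
        differential_table=diff_table,
        recovery=recovery,
        irr_overlap=irr_overlap,
        expression_comparison=expression_comparison,
        annotations_by_group=annotations_by_group,
    )
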