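"""Synthetic study generator with planted ground truth.

Everything the analysis consumes can be generated here: a linear synthetic
chromosome ("chrS") with non-overlapping gene models, planted R-loop loci
(promoter-proximal and gene-body classes) of which a stated fraction is
absent in the "mutant" condition, negative-binomial binned coverage for
DRIP / input / RNase H1 roles per replicate, intron-retention-reduction
(IRR) splice events co-located with lost loci at a stated rate, expression
matrices with a shift tied to TSS R-loop loss, lognormal fiber speeds, and
qPCR Ct tables consistent with stated recoveries.

Every generator is a pure function of (design, seed): a fixed stream key
per generator keeps outputs byte-identical across runs and independent of
call order. Negative-binomial noise is parameterized by mean mu and
dispersion alpha with variance mu + alpha * mu^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .io import CoverageTrack

__all__ = [
    "SimulationDesign",
    "RLoopTruth",
    "make_genome",
    "plant_rloops",
    "simulate_coverage",
    "simulate_irr_and_expression",
    "simulate_fibers",
    "simulate_qpcr",
    "write_truth_bed",
]

CONDITIONS = ("WT", "MUT")
ROLES = ("drip", "input", "rnh1")

# fixed stream keys so each generator draws from its own reproducible stream
_STREAM_GENOME = 0
_STREAM_RLOOPS = 1
_STREAM_COVERAGE = 2
_STREAM_IRR_EXPR = 3

# R-loop widths span the large, stable structures (300 bp to 1 kb)
RLOOP_WIDTH_RANGE = (300, 1000)
# minimum separation between planted loci so neighbouring peaks cannot be
# bridged by the caller's merge gap (1 kb) plus one bin on each side
MIN_LOCUS_SEPARATION = 1400
# promoter loci reach at most this far upstream of the TSS, keeping loci of
# adjacent genes separable given the intergenic gaps below
MAX_PROMOTER_UPSTREAM = 400


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a synthetic two-condition DRIP study.

    The defaults describe the standard benchmark: a 1 Mb chromosome with
    210 genes, 200 planted R-loops of which 60% are lost in the mutant
    condition, three replicates per group, 20x locus enrichment over a
    background of 5 reads per 200 bp bin, and NB dispersion 0.05 (typical
    for replicate count data).
    """

    seed: int = 0
    genome_length_bp: int = 1_000_000
    n_genes: int = 210
    n_rloops: int = 200
    promoter_fraction: float = 0.3
    loss_fraction: float = 0.6
    n_replicates_per_group: int = 3
    mean_depth: float = 100.0
    dispersion: float = 0.05
    irr_link_rate: float = 0.69
    expr_shift: float = 1.0
    bin_bp: int = 200
    background_depth: float = 5.0
    irr_background_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "promoter_fraction",
            "loss_fraction",
            "irr_link_rate",
            "irr_background_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if self.genome_length_bp % self.bin_bp != 0:
            raise ValueError("bin_bp must divide genome_length_bp")
        if self.n_rloops > self.n_genes:
            raise ValueError("n_rloops cannot exceed n_genes (one locus per gene)")

    def rng(self, stream: int, *subkeys: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *subkeys])


@dataclass(frozen=True)
class RLoopTruth:
    """A planted R-loop locus with its condition membership."""

    chrom: str
    start: int
    end: int
    feature_class: str
    present_in: frozenset[str]
    linked_gene: str | None

    @property
    def lost_in_mutant(self) -> bool:
        return "MUT" not in self.present_in


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

_GENE_LENGTH_RANGE = (2000, 2400)
_GAP_RANGE = (2300, 2600)
_UTR5_RANGE = (100, 200)
_UTR3_RANGE = (200, 300)
_N_EXONS = 3


def make_genome(
    design: SimulationDesign, chrom: str = "chrS"
) -> tuple[dict[str, str], list[GeneModel]]:
    """One linear chromosome plus non-overlapping gene models.

    Gene spans are laid out left to right with randomized lengths and gaps
    (the leftover genome length is distributed over the gaps), each gene
    getting a 5'UTR, three exons with introns, and a 3'UTR. Promoter
    regions carry GC skew (excess G on the coding strand just downstream of
    the TSS), the sequence feature characteristic of R-loop-forming
    promoters. Raises when the genome is too short to place the genes.
    """
    if design.genome_length_bp < 50_000:
        raise ValueError("genome_length_bp must be at least 50,000")
    rng = design.rng(_STREAM_GENOME)
    L = design.genome_length_bp
    n = design.n_genes

    lengths = rng.integers(*_GENE_LENGTH_RANGE, size=n, endpoint=True)
    gaps = rng.integers(*_GAP_RANGE, size=n + 1, endpoint=True)
    required = int(lengths.sum() + gaps.sum())
    if required > L:
        raise ValueError(
            f"genome too short to place {n} genes: need at least "
            f"{required} bp, got {L}"
        )
    # spread the leftover across the gaps so genes cover the chromosome
    extra = L - required
    bonus = np.zeros(n + 1, dtype=int)
    if extra > 0:
        per, rem = divmod(extra, n + 1)
        bonus[:] = per
        bonus[: rem] += 1
    gaps = gaps + bonus

    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L).astype("U1")

    genes: list[GeneModel] = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = pos + int(lengths[i])
        pos = end
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(*_UTR5_RANGE, endpoint=True))
        u3 = int(rng.integers(*_UTR3_RANGE, endpoint=True))
        if strand == "+":
            utr5 = (start, start + u5)
            utr3 = (end - u3, end)
        else:
            utr5 = (end - u5, end)
            utr3 = (start, start + u3)
        # three exons: split the span at two intron blocks inside the CDS
        inner_lo = start + (u5 if strand == "+" else u3) + 100
        inner_hi = end - (u3 if strand == "+" else u5) - 100
        cuts = np.sort(rng.integers(inner_lo, inner_hi, size=4))
        while cuts[1] - cuts[0] < 50 or cuts[3] - cuts[2] < 50 or cuts[2] - cuts[1] < 100:
            cuts = np.sort(rng.integers(inner_lo, inner_hi, size=4))
        exons = (
            (start, int(cuts[0])),
            (int(cuts[1]), int(cuts[2])),
            (int(cuts[3]), end),
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
        # GC skew downstream of the TSS: G-rich on the coding strand
        if strand == "+":
            lo, hi = start, min(start + 300, end)
            skewed = rng.choice(list("ACGT"), size=hi - lo, p=[0.25, 0.12, 0.38, 0.25])
        else:
            lo, hi = max(end - 300, start), end
            # coding-strand G excess maps to C excess on the top strand
            skewed = rng.choice(list("ACGT"), size=hi - lo, p=[0.25, 0.38, 0.12, 0.25])
        seq[lo:hi] = skewed

    return {chrom: "".join(seq.tolist())}, genes


# ---------------------------------------------------------------------------
# R-loop truth
# ---------------------------------------------------------------------------

_MAX_PLACEMENT_TRIES = 200


def plant_rloops(
    design: SimulationDesign, genes: Sequence[GeneModel]
) -> list[RLoopTruth]:
    """Plant ``n_rloops`` non-overlapping loci, one per chosen gene.

    round(promoter_fraction * n) loci are placed so their midpoints fall in
    the promoter-TSS window; the rest sit inside the gene body (clear of
    UTRs and the TSS/TTS windows). round(loss_fraction * n) loci are marked
    absent in the mutant condition. Placement keeps a minimum separation of
    1600 bp between loci; when a locus cannot be placed after bounded
    retries an error is raised.
    """
    n = design.n_rloops
    if n == 0:
        return []
    if n > len(genes):
        raise ValueError("not enough genes to host the requested loci")
    rng = design.rng(_STREAM_RLOOPS)

    n_prom = round(design.promoter_fraction * n)
    order = rng.permutation(len(genes))
    hosts = [genes[i] for i in order[:n]]

    placed: list[tuple[int, int]] = []

    def fits(start: int, end: int) -> bool:
        return all(
            end + MIN_LOCUS_SEPARATION <= s or e + MIN_LOCUS_SEPARATION <= start
            for s, e in placed
        )

    loci: list[tuple[GeneModel, str, int, int]] = []
    for idx, gene in enumerate(hosts):
        is_promoter = idx < n_prom
        ok = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            width = int(rng.integers(*RLOOP_WIDTH_RANGE, endpoint=True))
            if is_promoter:
                # midpoint inside the promoter-TSS window [-1000, +100],
                # kept close to the TSS so the locus stays clear of the
                # neighbouring gene's loci
                if gene.strand == "+":
                    mid = int(rng.integers(gene.tss - 150, gene.tss + 51))
                    max_w = 2 * (mid - (gene.tss - MAX_PROMOTER_UPSTREAM))
                else:
                    mid = int(rng.integers(gene.tss - 50, gene.tss + 151))
                    max_w = 2 * ((gene.tss + MAX_PROMOTER_UPSTREAM) - mid)
                width = min(width, max_w)
                cls = "promoter-TSS"
            else:
                # midpoint clear of UTRs, promoter and TTS windows
                u5 = gene.utr5[1] - gene.utr5[0]
                u3 = gene.utr3[1] - gene.utr3[0]
                if gene.strand == "+":
                    lo = gene.start + u5 + 500
                    hi = gene.end - u3 - 500
                else:
                    lo = gene.start + u3 + 500
                    hi = gene.end - u5 - 500
                if hi <= lo:
                    continue
                mid = int(rng.integers(lo, hi))
                cls = "gene body"
            start = max(0, mid - width // 2)
            end = min(design.genome_length_bp, start + width)
            if fits(start, end):
                placed.append((start, end))
                loci.append((gene, cls, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place R-loop in {gene.gene_id} after "
                f"{_MAX_PLACEMENT_TRIES} tries; relax the design"
            )

    n_lost = round(design.loss_fraction * n)
    lost_idx = set(rng.choice(n, size=n_lost, replace=False).tolist())
    truth: list[RLoopTruth] = []
    for i, (gene, cls, start, end) in enumerate(loci):
        present = frozenset(["WT"]) if i in lost_idx else frozenset(CONDITIONS)
        truth.append(
            RLoopTruth(
                chrom=gene.chrom,
                start=start,
                end=end,
                feature_class=cls,
                present_in=present,
                linked_gene=gene.gene_id,
            )
        )
    truth.sort(key=lambda t: t.start)
    return truth


def write_truth_bed(truth: Iterable[RLoopTruth], path) -> None:
    """BED6 with the feature class and condition membership in the name."""
    with open(path, "w") as fh:
        for t in truth:
            name = f"{t.feature_class}|{'+'.join(sorted(t.present_in))}|{t.linked_gene}"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t.\n")


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + alpha mu^2."""
    r = 1.0 / alpha
    p = r / (r + np.maximum(mu, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_coverage(
    truth: Sequence[RLoopTruth],
    design: SimulationDesign,
    condition: str,
    replicate: int,
    role: str,
    chrom: str = "chrS",
) -> CoverageTrack:
    """Binned NB coverage for one sample track.

    DRIP bins over loci present in ``condition`` have mean background +
    mean_depth (scaled by bin overlap); input and RNase H1 tracks are
    background everywhere, which encodes the abolition of true DRIP signal
    by RNase H1.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if design.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")

    n_bins = design.genome_length_bp // design.bin_bp
    mu = np.full(n_bins, design.background_depth, dtype=float)
    if role == "drip":
        for locus in truth:
            if condition not in locus.present_in:
                continue
            b0 = locus.start // design.bin_bp
            b1 = (locus.end - 1) // design.bin_bp
            for b in range(b0, min(b1 + 1, n_bins)):
                bin_start = b * design.bin_bp
                overlap = min(locus.end, bin_start + design.bin_bp) - max(
                    locus.start, bin_start
                )
                mu[b] += design.mean_depth * overlap / design.bin_bp

    rng = design.rng(
        _STREAM_COVERAGE,
        CONDITIONS.index(condition),
        replicate,
        ROLES.index(role),
    )
    counts = _nb_draw(rng, mu, design.dispersion)
    return CoverageTrack(
        chrom,
        design.bin_bp,
        counts.astype(float),
        meta={
            "condition": condition,
            "replicate": replicate,
            "role": role,
            "seed": design.seed,
        },
    )


# ---------------------------------------------------------------------------
# IRR events and expression
# ---------------------------------------------------------------------------

def simulate_irr_and_expression(
    truth: Sequence[RLoopTruth],
    design: SimulationDesign,
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Splice-event table plus WT and MUT expression matrices.

    IRR events (intron retention with delta PSI < -0.10 and adjusted
    p < 0.05 in the mutant) are planted in round(irr_link_rate * n_lost)
    genes that lost an R-loop and round(irr_background_rate * n_other) of
    the remaining genes. Genes losing a promoter-TSS R-loop have their
    mutant log2 expression shifted down by ``expr_shift``.
    """
    rng = design.rng(_STREAM_IRR_EXPR)
    by_id = {g.gene_id: g for g in genes}

    lost_genes = sorted(
        {t.linked_gene for t in truth if t.lost_in_mutant and t.linked_gene}
    )
    other_genes = sorted(set(by_id) - set(lost_genes))
    tss_loss_genes = sorted(
        {
            t.linked_gene
            for t in truth
            if t.lost_in_mutant and t.feature_class == "promoter-TSS" and t.linked_gene
        }
    )

    n_linked = round(design.irr_link_rate * len(lost_genes))
    n_bg = round(design.irr_background_rate * len(other_genes))
    linked = rng.choice(lost_genes, size=n_linked, replace=False) if n_linked else []
    background = rng.choice(other_genes, size=n_bg, replace=False) if n_bg else []

    rows = []
    for gene_id in list(linked) + list(background):
        gene = by_id[gene_id]
        introns = gene.introns
        if not introns:
            continue
        s, e = introns[int(rng.integers(len(introns)))]
        rows.append(
            {
                "gene_id": gene_id,
                "event_type": "intron_retention",
                "chrom": gene.chrom,
                "start": s,
                "end": e,
                "delta_psi": -float(rng.uniform(0.15, 0.5)),
                "adjusted_p": float(10 ** -rng.uniform(2.0, 6.0)),
            }
        )
    events = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "event_type",
            "chrom",
            "start",
            "end",
            "delta_psi",
            "adjusted_p",
        ],
    )

    gene_ids = [g.gene_id for g in genes]
    base = rng.normal(8.0, 1.5, size=len(gene_ids))
    n_rep = design.n_replicates_per_group
    noise_wt = rng.normal(0.0, 0.3, size=(len(gene_ids), n_rep))
    noise_mut = rng.normal(0.0, 0.3, size=(len(gene_ids), n_rep))
    shift = np.array(
        [design.expr_shift if g in set(tss_loss_genes) else 0.0 for g in gene_ids]
    )
    expr_wt = pd.DataFrame(
        base[:, None] + noise_wt,
        index=gene_ids,
        columns=[f"WT_{i + 1}" for i in range(n_rep)],
    )
    expr_mut = pd.DataFrame(
        (base - shift)[:, None] + noise_mut,
        index=gene_ids,
        columns=[f"MUT_{i + 1}" for i in range(n_rep)],
    )
    return events, expr_wt, expr_mut


# ---------------------------------------------------------------------------
# Fibers and qPCR
# ---------------------------------------------------------------------------

def simulate_fibers(
    n: int,
    mean_speed_kb_min: float = 0.75,
    cv: float = 0.45,
    seed: int = 0,
    t_label: float = 30.0,
) -> pd.DataFrame:
    """Fibers whose implied speeds are lognormal with the given mean and CV.

    Each fiber carries 30-min IdU and CldU pulses; the total labelled
    length is split between the two analogs with a mildly noisy symmetry
    ratio around 1.
    """
    if n < 1:
        raise ValueError("need at least one fiber")
    if mean_speed_kb_min <= 0:
        raise ValueError("mean speed must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng([seed, 11])
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean_speed_kb_min) - sigma2 / 2.0
    speeds = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    ratio = rng.lognormal(0.0, 0.08, size=n)  # IdU/CldU symmetry noise
    total = speeds * 2 * t_label
    d_idu = total * ratio / (1.0 + ratio)
    d_cldu = total - d_idu
    return pd.DataFrame(
        {
            "fiber_id": [f"fiber_{i + 1}" for i in range(n)],
            "d_idu_kb": d_idu,
            "d_cldu_kb": d_cldu,
            "t_idu_min": t_label,
            "t_cldu_min": t_label,
        }
    )


def simulate_qpcr(
    loci_spec: Sequence[dict],
    seed: int = 0,
    baseline_ct: float = 14.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Ct plate table for a list of loci.

    Each spec entry gives ``locus``, the DRIP ``recovery`` (fraction of
    template immunoprecipitated), optionally ``rnh1_recovery`` and the
    input ``dilution`` (default 10). Ct values follow
    Ct = baseline - log2(template quantity) + Gaussian noise, so with zero
    noise the %input computation inverts the planted recovery exactly.
    """
    rng = np.random.default_rng([seed, 13])
    rows = []
    for spec in loci_spec:
        locus = spec["locus"]
        recovery = float(spec["recovery"])
        if not (0 < recovery <= 1):
            raise ValueError("recovery must lie in (0, 1]")
        dilution = float(spec.get("dilution", 10.0))
        rnh1 = spec.get("rnh1_recovery")
        quantities = {"input": 1.0 / dilution, "drip": recovery}
        if rnh1 is not None:
            quantities["drip_rnh1"] = float(rnh1)
        for role, q in quantities.items():
            ct = baseline_ct - math.log2(q)
            if noise_sd > 0:
                ct += float(rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "locus": locus,
                    "role": role,
                    "ct": ct,
                    "input_dilution_factor": dilution,
                }
            )
    return pd.DataFrame(rows)
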