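# Methods

This note records the models, parameter choices and numerical decisions
behind rloopkit, and what the synthetic benchmarks do and do not establish.

## Peak calling

DRIP enrichment is tested per fixed-width bin (default 200 bp) with a
one-sided Poisson upper-tail test. The background rate of a bin is

    λ = max(input · s_in, RNase H1 · s_rn, genome-wide scaled control mean) + c

where `s` are counts-per-million depth ratios (treatment total over control
total), the genome-wide term guards against control dropouts, and the
pseudocount `c = 0.5` prevents infinite enrichment over empty control bins.
Taking the maximum over both controls makes the dual-control peak set a
subset of what either control alone would admit; the RNase H1 arm encodes
the biochemical specificity control (RNase H1 degrades the RNA strand of
RNA:DNA hybrids, so genuine R-loop signal must disappear under it).

Bins below a loose seed p value (1e-3) are merged across gaps up to
`merge_gap_bp = 1000`; each merged span is re-scored as Poisson on its
summed counts versus summed λ, so broad, dip-containing R-loops are scored
as single units. Peaks shorter than `min_peak_bp = 300` are dropped — large,
stable R-loops span roughly 300 bp to 1 kb, which also motivates the
simulated locus widths (uniform 300–1000 bp). BH q values are computed over
the candidate peaks and the q < 0.1 set is returned. The procedure is
deterministic; it is a transparent local-λ test of the same family as the
broad mode of general-purpose peak callers, not a bit-compatible
reimplementation of any of them.

Exact scale invariance of the peak set under an integer depth factor holds
for the deterministic part of the procedure; on noisy backgrounds, scaled
Poisson noise is overdispersed relative to a Poisson of the scaled mean, so
borderline bins can enter or leave the seed set. The test suite pins the
invariance on a noise-free background.

## Replicate consensus

Peaks are categorized by their p value: stringent (p ≤ 1e-8), weak
(1e-8 < p ≤ 1e-4), background (p > 1e-4). Background peaks are discarded.
Remaining peaks from all replicates are grouped into transitive overlap
components (≥ 1 bp intersection, pairwise chains closed). A weak peak is
flagged *rescued* when its component holds a stringent peak from another
replicate. A peak is confirmed when (i) its component contains peaks from
at least `min_supporting_replicates` other replicates (default 1 — the
requirement that a peak be supported elsewhere; exposed because the precise
count is a tool parameter rather than a biological constant) and (ii) the
Fisher-combined p value over the component's peaks is ≤ 1e-8. Fisher's
statistic X² = −2 Σ ln pᵢ is referred to χ² with 2k degrees of freedom; for
even df the survival function has the closed form
exp(−x/2) Σ_{i<k} (x/2)ⁱ/i!, which is evaluated in log space. Confirmed
peaks undergo one BH pass (over all confirmed peaks of the replicate set,
not per chromosome) at 0.05; survivors are true positives. Rescue is
recorded as an annotation; confirmation is decided by support count plus
the combined test, so the procedure is monotone: adding a supporting
replicate can only promote peaks.

Group *shared peaks* merge all true-positive intervals of a group's samples
and keep the merged intervals that overlap a true positive in every sample,
which avoids double counting when replicate peaks fragment differently.

## Restriction-fragment frame and differential testing

The five-enzyme digestion panel (HindIII AAGCTT/1, EcoRI GAATTC/1, BsrGI
TGTACA/1, XbaI TCTAGA/1, SspI AATATT/3) uses REBASE recognition sites and
top-strand cut offsets; all five sites are palindromic, so a top-strand
scan finds every cut (asserted at panel construction). Overlapping motif
occurrences each cut; coincident cuts collapse; ambiguous bases never
match; chromosomes are linear. Fragments are identified as
"chrom:start-end" and tile each chromosome exactly.

Counting apportions bin counts to fragments by overlap fraction and rounds
half-up to integers so NB machinery applies. The analysis frame is the set
of fragments overlapping at least one sample's significant peaks. Size
factors are median-of-ratios (geometric-mean reference over zero-free
rows). In the end-to-end pipeline the factors are estimated on the **full**
fragment frame and passed to the test over the peak frame: with a large
planted loss fraction the peak frame is mostly truly differential rows,
which violates the "most features unchanged" assumption of median-of-ratios
and would absorb the biological signal into normalization, whereas the full
frame is dominated by unchanged background fragments.

The per-fragment test is a Wald test on the log ratio of normalized group
means with delta-method variance, var(mean) = (μ + αμ²)/n per group.
Dispersions α are method-of-moments estimates from the pooled within-group
variance, pooled across rows of similar overall mean (20 equal-count trend
bins, floor 1e-8). Pooling uses the bin **mean** of per-row estimates: the
per-row moment estimator is strongly right-skewed at 2–5 replicates, so a
median pools low and inflates the Wald statistic; with mean pooling the
empirical type-I error on all-null NB data (μ = 100, α = 0.05, 5 vs 5) sits
at the nominal 0.05 (the suite requires [0.035, 0.065] on 2000 rows). The
log2 fold change uses a pseudocount of 0.5 divided by the mean size factor
to avoid infinite values at zeros, and the differential call requires
|log₂FC| > 1 and BH-adjusted p < 0.05. The full shrinkage machinery of
dedicated count-model packages is deliberately not reproduced; calibration
and power (≥ 85/100 planted log₂FC = 2 rows recovered) are demonstrated by
simulation instead.

The expression low-count rule removes a gene when at least half of the
samples (inclusive: ≥ n/2) have fewer than 20 normalized reads.

## Annotation and integration

A peak's feature class is decided by its midpoint with a fixed priority:
promoter-TSS window > 5'UTR > 3'UTR > TTS window > gene body > intergenic.
Windows are strand-aware: promoter = TSS −1000/+100 bp, TTS window = TTS
−100/+1000 bp — common annotation-tool conventions. Midpoint assignment
makes the classes a partition, which pie-chart proportions and group shares
require; a peak overlapping several genes takes the highest-priority hit.

IRR (intron retention reduction) events are retention events with
ΔPSI < −0.10 (mutant minus reference) at adjusted p < 0.05; events are
deduplicated by (gene, intron interval) before overlap counting, and an IRR
counts as overlapped when its gene carries at least one lost R-loop at any
feature. Percentages are reported rounded half-up to whole percent. A
"lost R-loop" can be defined by either route the pipeline supports —
differential fragments called down, or reference shared peaks with no
overlapping mutant peak (the expression analysis defaults to the
shared-peak definition; both routes are exposed).

The expression comparison takes, per feature class, the genes whose
reference-condition R-loop at that class is absent in the mutant, computes
per-gene reference-minus-mutant mean expression differences, and applies
the two-sided one-sample Wilcoxon signed-rank test against 0. Classes with
fewer than 5 genes report a missing p value (the exact two-sided test
cannot reach 0.05 below n = 5); empty classes are skipped with a warning;
all-zero differences (identical matrices) report p = 1.

## Replication assays

Fork speed is (d_I + d_Cl)/(t_I + t_Cl) in kb/min with 30-min pulses by
default; symmetry is d_I/d_Cl. Fibers missing one analog track are excluded
from both statistics, not imputed. Lengths are accepted in kb, or in µm via
the combing convention of 2 kb/µm. Group comparisons use the two-sided
Mann–Whitney test and warn below 200 fibers per group, the conventional
minimum.

qPCR: %input = 100 · 2^(Ct_input − log₂(dilution) − Ct_DRIP) with the input
dilution factor defaulting to 10; fold enrichment is the ratio of positive-
to negative-locus recoveries and equals the ratio of %input values
algebraically (asserted to 1e-12 relative in the suite). QC flags mark
%input outside 1–15% and fold enrichment outside 20–300.

## Statistical primitives

All tests are implemented in `rloopkit.stats` from first principles;
scipy supplies only distribution tail functions. Fisher's exact 2×2 sums
hypergeometric point probabilities ≤ the observed one (1e-7 relative tie
tolerance). Mann–Whitney is exact by enumeration when n_x + n_y ≤ 12
without ties, otherwise normal with tie and continuity corrections; the
one-sample Wilcoxon is exact via the dynamic-programming null distribution
when n ≤ 25 without tied magnitudes, otherwise normal with the standard
corrections; the unpaired t test is Student's pooled-variance form (Welch
behind a flag). BH is a single step-up pass; note it is not idempotent
(re-adjusting adjusted values inflates them), so it is applied exactly once
per family.

## Synthetic data

The generator is a pure function of (design, seed): each generator draws
from its own fixed-key RNG stream, so outputs are byte-identical across
runs and independent of call order, and seeds are recorded in track
headers.

The default design is the benchmark the end-to-end tests use: one linear
1 Mb chromosome ("chrS", 0-based half-open coordinates), 210 genes of
2.0–2.4 kb with 5'UTR, three exons and 3'UTR, intergenic gaps ≥ 2.3 kb;
200 planted R-loop loci (30% promoter-proximal, the rest in gene bodies,
one per gene, ≥ 1.4 kb apart so the caller's merge gap cannot bridge
neighbours); loss fraction 0.6 in the mutant; 3 replicates per group; NB
counts with background 5 reads per 200-bp bin, 20× enrichment
(mean_depth = 100) over present loci and dispersion α = 0.05 (variance
μ + αμ²), typical of replicate count data. Promoter sequences carry GC skew
(G-rich coding strand just downstream of the TSS), the composition feature
of R-loop-forming promoters, so digestion and annotation see realistic
sequence. Sequencing depth per library is a free design parameter (no
published per-sample depth constrains it); 20× locus enrichment represents
a strong DRIP signal.

IRR planting is deterministic: round(irr_link_rate · n_lost) of the genes
that lost an R-loop and round(irr_background_rate · n_other) of the
remaining genes receive one retention event each (ΔPSI uniform on
[−0.5, −0.15], adjusted p between 1e-6 and 1e-2). Exact counts rather than
per-gene Bernoulli draws make configured overlap ratios reproducible — the
345-of-498 (69%) configuration is hit exactly — and the recovered linked
fraction equals the configured rate by construction. Expression matrices
are Gaussian in log scale (base N(8, 1.5), replicate noise SD 0.3) with the
mutant mean of TSS-loss genes shifted down by `expr_shift` (default 1).
Fiber speeds are lognormal with specified mean and coefficient of
variation; symmetry noise is lognormal with σ = 0.08. qPCR Ct values follow
Ct = baseline − log₂(template) + Gaussian noise, so the zero-noise plate is
inverted exactly by the %input formula.

What the synthetic benchmark does **not** emulate: mappability and GC
biases, copy-number structure, fragment-length effects, partially penetrant
losses (loci are fully present or fully absent per condition), R-loops
shared across neighbouring genes, and genome-scale sequence composition.
Passing the round trip therefore demonstrates the correctness and
calibration of the statistical machinery under the stated noise model, not
performance on patient data; cohort-scale results (tens of thousands of
differential fragments, thousands of differentially expressed genes) are
outside desk-scale reproduction by design.

## Problem sizes

The default test and acceptance runs use a 1 Mb genome (5,000 bins per
track, ~1,200 restriction fragments, ~380 peak-frame fragments), 2,000-row
null calibrations, and a 6 Mb genome for the 1,000-locus IRR configuration;
these sizes keep every check well-powered while the full suite runs in
about a minute on one CPU.
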