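# rloopkit

A Python toolkit for analysing R-loop maps from DRIP-seq (DNA:RNA
immunoprecipitation sequencing) in two-condition study designs, built for
studies of splicing-factor-mutated myelodysplastic syndromes where the
mutant condition *loses* R-loops genome-wide. It is aimed at computational
biologists who have per-sample binned coverage for DRIP libraries, their
input controls and RNase H1-treated controls, and who want a transparent,
fully testable route from coverage to confirmed peaks, differential
R-loops, and the downstream integrative statistics.

## What it does

- **Broad peak calling with dual controls** (`rloopkit.peaks`): each bin of
  DRIP coverage is tested against a Poisson background whose rate is
  λ = max(scaled input, scaled RNase H1, genome-wide scaled control mean) +
  pseudocount; enriched bins are merged across ≤ 1 kb gaps, each peak is
  re-scored on its summed counts, and Benjamini–Hochberg q < 0.1 peaks are
  returned. Using the maximum of both controls means a peak must beat the
  input *and* survive RNase H1, the specificity control that abolishes true
  RNA:DNA-hybrid signal.
- **Multi-replicate consensus** (`rloopkit.consensus`): peaks are
  categorized as background / weak / stringent at p cut-offs 1e-4 and 1e-8,
  weak peaks are rescued when a stringent peak overlaps them in another
  replicate, overlapping peaks are combined with Fisher's probability test
  (X² = −2 Σ ln pᵢ ~ χ²₂ₖ) against a 1e-8 ceiling, and confirmed peaks pass
  BH at 0.05 to become true positives. A group's *shared peaks* are the
  merged intervals supported in every sample of the group.
- **Restriction-fragment differential testing** (`rloopkit.restriction`,
  `rloopkit.differential`): the genome is digested in silico with the
  five-enzyme DRIP panel (HindIII, EcoRI, BsrGI, XbaI, SspI); fragments
  overlapping peaks form a count matrix, normalized with median-of-ratios
  size factors and tested per fragment with a negative-binomial Wald test
  (variance μ + αμ², moment-estimated trend dispersion). A fragment is
  differential when |log₂FC| > 1 and BH-adjusted p < 0.05.
- **Integration** (`rloopkit.annotate`): midpoint-based peak annotation to
  promoter-TSS / 5'UTR / gene body / TTS / 3'UTR / intergenic, feature
  distributions and mutant-vs-total shares, overlap of lost R-loops with
  intron-retention-reduction (IRR) splicing events, and expression
  comparison of gene sets stratified by where the lost R-loop sat
  (one-sample Wilcoxon signed-rank against 0).
- **Replication assays** (`rloopkit.assays`): DNA-combing fork speed
  (d_I + d_Cl)/(t_I + t_Cl) and symmetry d_I/d_Cl with Mann–Whitney group
  comparison; DRIP-qPCR %input = 100·2^(Ct_input − log₂(dilution) − Ct_DRIP)
  and fold enrichment over an R-loop-free locus, with the 1–15% and 20–300
  QC windows.
- **Self-contained statistics** (`rloopkit.stats`): Fisher's exact 2×2,
  Fisher's combined probability, BH adjustment, exact/approximate
  Mann–Whitney and one-sample Wilcoxon, and the unpaired t test — all
  implemented from first principles and checked against enumeration
  oracles.
- **Synthetic data with planted truth** (`rloopkit.simulate`): a generator
  for every input above — synthetic chromosome with GC-skewed promoters,
  planted promoter/gene-body R-loop loci with a configurable loss fraction,
  NB coverage per role and replicate, IRR events linked to lost loci,
  expression shifts tied to TSS R-loop loss, lognormal fiber speeds, and Ct
  plates — so the whole pipeline is testable end to end without any
  external download.

## Worked example

`examples/differential_rloops.py` runs the complete pipeline on the default
benchmark design — a 1 Mb chromosome, 200 planted R-loops of which 60% are
absent in the mutant condition, three replicates per group:

```text
shared peaks per group: {'WT': 191, 'MUT': 80}
mutant/wild-type shared-peak ratio: 0.42 (planted: 0.40)
lost-locus recovery: recall=1.00 precision=0.98
differential fragments called: 214, 100% down in mutant
feature_class  n_genes  mean_difference  median_difference  wilcoxon_p
 promoter-TSS       28         0.975461           0.998169    0.000004
    gene body       84         0.031554           0.042612    0.118017
```

The shared-peak ratio recovers the planted 40% retention; every truly lost
locus overlaps a fragment called down in the mutant (recall 1.00) and
almost nothing else is called (precision 0.98). Genes that lost their
promoter-TSS R-loop show the planted ≈1-unit drop of mutant expression
(positive wild-type-minus-mutant difference, Wilcoxon p ≈ 4e-6), while
gene-body losses leave expression unchanged — the expected location
dependence of R-loop effects on transcription.

The other scripts in `examples/` each demonstrate one capability: peak
calling, replicate consensus, in-silico digestion, and the combing/qPCR
statistics. A thin command line mirrors them
(`rloopkit simulate|digest|callpeaks|consensus|combing|qpcr|roundtrip`).

## Scope notes

Read-level processing (trimming, alignment, deduplication) and the
internals of splicing-event callers are out of scope: the toolkit consumes
binned coverage and event tables. The peak caller and the differential test
are transparent reimplementations of the standard approaches (Poisson local
background; median-of-ratios + NB Wald) and are validated by oracle and
simulation tests rather than being bit-compatible with any external tool.
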