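"""Confirm peaks across replicates: categorize, rescue, combine, correct.

Three replicate peak lists are combined: peaks are binned into background /
weak / stringent by p value (1e-4 and 1e-8 cut-offs), overlapping peaks are
combined with Fisher's probability test against a 1e-8 ceiling, and the
confirmed peaks pass Benjamini-Hochberg at 0.05 to become true positives.
"""

from rloopkit import ConsensusParams, Peak, confirm_across_replicates

rep1 = [
    Peak("chrS", 1000, 1800, p_value=1e-5),    # weak, supported below
    Peak("chrS", 9000, 9600, p_value=1e-5),    # weak, unsupported
]
rep2 = [Peak("chrS", 1400, 2200, p_value=1e-9)]  # stringent, rescues rep1's weak
rep3 = [Peak("chrS", 30_000, 30_400, p_value=0.2)]  # background, discarded

result = confirm_across_replicates([rep1, rep2, rep3], ConsensusParams())
for rep, peaks in enumerate(result.peaks_by_replicate, start=1):
    for p in peaks:
        print(
            f"replicate {rep} {p.start}-{p.end}: category={p.category} "
            f"rescued={p.rescued} combined_p={p.combined_p} status={p.status}"
        )
print("consensus intervals:", result.consensus_intervals)
# The overlapping weak+stringent pair is confirmed (combined p ~ 4e-13);
# the lone weak peak lacks support in any other replicate and is discarded.
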