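"""Replicate confirmation against an exhaustive independent rule oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from rloopkit.consensus import (
    ConsensusParams,
    categorize,
    confirm_across_replicates,
    shared_peaks,
)
from rloopkit.peaks import Peak

P = ConsensusParams()


def peak(start, end, p, rep=None):
    return Peak(chrom="chrS", start=start, end=end, p_value=p, replicate_id=rep)


class TestCategorize:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (1e-9, "stringent"),
            (1e-8, "stringent"),
            (1e-5, "weak"),
            (1e-4, "weak"),
            (0.5, "background"),
            (1.1e-4, "background"),
        ],
    )
    def test_thresholds(self, p, expected):
        (pk,) = categorize([peak(0, 100, p)], P)
        assert pk.category == expected


class TestConfirmExamples:
    def test_two_overlapping_weak_peaks_confirmed(self):
        # Fisher combination of (1e-5, 1e-5) ~ 2.40e-9 <= 1e-8
        res = confirm_across_replicates(
            [[peak(0, 500, 1e-5)], [peak(300, 800, 1e-5)]], P
        )
        statuses = [ps[0].status for ps in res.peaks_by_replicate]
        assert statuses == ["true_positive", "true_positive"]
        assert res.peaks_by_replicate[0][0].combined_p == pytest.approx(
            2.4026e-9, rel=1e-4
        )
        assert res.consensus_intervals == [("chrS", 0, 800)]

    def test_unsupported_weak_peak_discarded(self):
        res = confirm_across_replicates(
            [[peak(0, 500, 1e-5)], [peak(5000, 5500, 1e-9)]], P
        )
        assert res.peaks_by_replicate[0][0].status == "discarded"

    def test_single_stringent_peak_confirmed_when_no_support_required(self):
        params = ConsensusParams(min_supporting_replicates=0)
        res = confirm_across_replicates([[peak(0, 500, 1e-12)]], params)
        assert res.peaks_by_replicate[0][0].status == "true_positive"
        assert res.peaks_by_replicate[0][0].combined_p == pytest.approx(1e-12)

    def test_weak_peak_rescue_flag(self):
        res = confirm_across_replicates(
            [[peak(0, 500, 1e-5)], [peak(300, 800, 1e-12)]], P
        )
        assert res.peaks_by_replicate[0][0].rescued
        assert not res.peaks_by_replicate[1][0].rescued

    def test_background_discarded_before_combination(self):
        res = confirm_across_replicates(
            [[peak(0, 500, 0.5)], [peak(300, 800, 1e-12)]],
            ConsensusParams(min_supporting_replicates=0),
        )
        assert res.peaks_by_replicate[0][0].status == "discarded"
        # stringent peak is evaluated without the background one
        assert res.peaks_by_replicate[1][0].combined_p == pytest.approx(1e-12)

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            confirm_across_replicates([], P)

    def test_rescue_monotonicity(self):
        base = [[peak(0, 500, 1e-5)], [peak(300, 800, 1e-5)]]
        res1 = confirm_across_replicates(
            [[peak(*((p.start, p.end)), p.p_value) for p in ps] for ps in base], P
        )
        with_stringent = base + [[peak(100, 600, 1e-12)]]
        res2 = confirm_across_replicates(
            [[peak(p.start, p.end, p.p_value) for p in ps] for ps in with_stringent],
            P,
        )
        rank = {"discarded": 0, "confirmed": 1, "true_positive": 2}
        for rep in range(2):
            before = rank[res1.peaks_by_replicate[rep][0].status]
            after = rank[res2.peaks_by_replicate[rep][0].status]
            assert after >= before


def oracle_confirm(peaksets, params):
    """Independent plain-loop implementation of the confirmation rules."""
    records = []
    for rep, peaks in enumerate(peaksets):
        for start, end, p in peaks:
            if p <= params.tau_stringent:
                cat = "stringent"
            elif p <= params.tau_weak:
                cat = "weak"
            else:
                cat = "background"
            records.append(
                {"rep": rep, "start": start, "end": end, "p": p, "cat": cat}
            )
    alive = [r for r in records if r["cat"] != "background"]
    # transitive overlap closure by repeated merging
    comp_id = list(range(len(alive)))
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(alive):
            for j, b in enumerate(alive):
                if comp_id[i] != comp_id[j] and a["start"] < b["end"] and b["start"] < a["end"]:
                    tgt, src = min(comp_id[i], comp_id[j]), max(comp_id[i], comp_id[j])
                    comp_id = [tgt if c == src else c for c in comp_id]
                    changed = True
    statuses = {}
    combined_ps = {}
    confirmed = []
    for i, rec in enumerate(alive):
        comp = [alive[j] for j in range(len(alive)) if comp_id[j] == comp_id[i]]
        x = -2 * sum(np.log(r["p"]) for r in comp)
        combined = float(sps.chi2.sf(x, 2 * len(comp))) if len(comp) > 1 else comp[0]["p"]
        combined_ps[i] = combined
        other_reps = {r["rep"] for r in comp} - {rec["rep"]}
        if len(other_reps) >= params.min_supporting_replicates and combined <= params.gamma_combined:
            statuses[i] = "confirmed"
            confirmed.append(i)
        else:
            statuses[i] = "discarded"
    if confirmed:
        ps = [combined_ps[i] for i in confirmed]
        m = len(ps)
        order = sorted(range(m), key=lambda k: ps[k])
        adj = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            k = order[rank - 1]
            running = min(running, ps[k] * m / rank)
            adj[k] = running
        for k, i in enumerate(confirmed):
            statuses[i] = "true_positive" if adj[k] <= params.alpha_bh else "discarded"
    out = {}
    for rep, peaks in enumerate(peaksets):
        for start, end, p in peaks:
            key = (rep, start, end, p)
            match = [
                i
                for i, r in enumerate(alive)
                if (r["rep"], r["start"], r["end"], r["p"]) == key
            ]
            out[key] = statuses[match[0]] if match else "discarded"
    return out


class TestExhaustiveOracle:
    # three replicates, up to five peaks over a fixed slot geometry:
    # slots 0/1 overlap, slots 2/3 overlap, slot 4 is isolated
    SLOTS = [(0, 1000), (500, 1500), (3000, 4000), (3500, 4500), (8000, 9000)]
    P_LEVELS = [0.5, 1e-5, 1e-12]

    def test_matches_oracle_on_all_configurations(self):
        params = ConsensusParams()
        rng = np.random.default_rng(7)
        n_checked = 0
        for placement in itertools.product([None, 0, 1, 2], repeat=5):
            if all(rep is None for rep in placement):
                continue
            occupied = [i for i, rep in enumerate(placement) if rep is not None]
            # deterministic p patterns cycling through the levels
            for offset in range(3):
                peaksets = [[], [], []]
                config = []
                for k, slot_idx in enumerate(occupied):
                    p = self.P_LEVELS[(k + offset) % 3]
                    rep = placement[slot_idx]
                    start, end = self.SLOTS[slot_idx]
                    peaksets[rep].append((start, end, p))
                    config.append((rep, start, end, p))
                expected = oracle_confirm(peaksets, params)
                res = confirm_across_replicates(
                    [
                        [peak(s, e, p, rep=str(r)) for s, e, p in ps]
                        for r, ps in enumerate(peaksets)
                    ],
                    params,
                )
                for rep, peaks in enumerate(res.peaks_by_replicate):
                    for pk in peaks:
                        key = (rep, pk.start, pk.end, pk.p_value)
                        assert pk.status == expected[key], (
                            f"mismatch at {key}: {pk.status} vs {expected[key]}"
                        )
                n_checked += 1
        assert n_checked > 1000


class TestSharedPeaks:
    def test_peak_in_all_samples_is_shared(self):
        tp = [
            [peak(0, 500, 1e-12)],
            [peak(100, 600, 1e-12)],
            [peak(200, 700, 1e-12)],
        ]
        shared, count = shared_peaks(tp)
        assert count == 1
        assert shared == [("chrS", 0, 700)]

    def test_missing_in_one_sample_not_shared(self):
        tp = [[peak(0, 500, 1e-12)], [peak(100, 600, 1e-12)], []]
        _, count = shared_peaks(tp)
        assert count == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            shared_peaks([])

    def test_end_to_end_shared_count(self, study):
        # 80 retained loci with strong enrichment across 3 mutant replicates
        n_retained = sum(not t.lost_in_mutant for t in study.truth)
        assert study.shared_counts["MUT"] >= 0.9 * n_retained
        assert study.shared_counts["MUT"] <= n_retained + 5
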