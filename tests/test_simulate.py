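"""Synthetic-data generator contracts: determinism, planting, noise models."""

import numpy as np
import pandas as pd
import pytest

from rloopkit.annotate import annotate_peak
from rloopkit.peaks import Peak
from rloopkit.simulate import (
    SimulationDesign,
    make_genome,
    plant_rloops,
    simulate_coverage,
    simulate_fibers,
    simulate_irr_and_expression,
    simulate_qpcr,
)

SMALL = dict(genome_length_bp=200_000, n_genes=40, n_rloops=30)


class TestMakeGenome:
    def test_contract_100kb_10_genes(self):
        d = SimulationDesign(seed=1, genome_length_bp=100_000, n_genes=10, n_rloops=5)
        genome, genes = make_genome(d)
        assert len(genome["chrS"]) == 100_000
        assert len(genes) == 10
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping

    def test_same_seed_identical_bytes(self):
        d = SimulationDesign(seed=7, **SMALL)
        g1, _ = make_genome(d)
        g2, _ = make_genome(d)
        assert g1["chrS"] == g2["chrS"]

    def test_different_seeds_differ(self):
        g1, _ = make_genome(SimulationDesign(seed=1, **SMALL))
        g2, _ = make_genome(SimulationDesign(seed=2, **SMALL))
        assert g1["chrS"] != g2["chrS"]

    def test_too_short_genome_names_required_length(self):
        with pytest.raises(ValueError, match="need at least"):
            make_genome(
                SimulationDesign(
                    seed=1, genome_length_bp=60_000, n_genes=40, n_rloops=10
                )
            )

    def test_gene_structure_valid(self):
        _, genes = make_genome(SimulationDesign(seed=3, **SMALL))
        for g in genes:
            assert g.utr5 is not None and g.utr3 is not None
            assert g.start <= g.utr5[0] < g.utr5[1] <= g.end
            assert len(g.exons) == 3
            assert len(g.introns) == 2


class TestPlantRloops:
    def test_loss_rounding_contract(self):
        d = SimulationDesign(seed=1, loss_fraction=0.6)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        assert len(truth) == 200
        assert sum(t.lost_in_mutant for t in truth) == 120

    def test_zero_loss_identical_conditions(self):
        d = SimulationDesign(seed=1, loss_fraction=0.0, **SMALL)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        assert all(t.present_in == frozenset({"WT", "MUT"}) for t in truth)

    def test_promoter_fraction_one_round_trips_through_annotation(self):
        d = SimulationDesign(seed=4, promoter_fraction=1.0, **SMALL)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        for t in truth:
            ann = annotate_peak(Peak(t.chrom, t.start, t.end, 1e-10), genes)
            assert ann.feature_class == "promoter-TSS"
            assert ann.gene_id == t.linked_gene

    def test_gene_body_class_round_trips(self):
        d = SimulationDesign(seed=4, promoter_fraction=0.0, **SMALL)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        for t in truth:
            ann = annotate_peak(Peak(t.chrom, t.start, t.end, 1e-10), genes)
            assert ann.feature_class == "gene body"

    def test_loci_non_overlapping(self):
        d = SimulationDesign(seed=5)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        for a, b in zip(truth, truth[1:]):
            assert a.end <= b.start


class TestCoverage:
    @pytest.fixture(scope="class")
    def setup(self):
        d = SimulationDesign(seed=6)
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        return d, truth

    def test_bin_count(self, setup):
        d, truth = setup
        for role in ("drip", "input", "rnh1"):
            track = simulate_coverage(truth, d, "WT", 0, role)
            assert track.n_bins == d.genome_length_bp // d.bin_bp

    def _locus_and_background_bins(self, d, truth):
        locus_bins = set()
        for t in truth:
            for b in range(t.start // d.bin_bp, (t.end - 1) // d.bin_bp + 1):
                locus_bins.add(b)
        n_bins = d.genome_length_bp // d.bin_bp
        # keep a margin of 2 bins around loci out of the background set
        margin = set()
        for b in locus_bins:
            margin.update(range(b - 2, b + 3))
        background = [b for b in range(n_bins) if b not in margin]
        full_locus = [
            b
            for t in truth
            if "WT" in t.present_in
            for b in range(t.start // d.bin_bp + 1, (t.end - 1) // d.bin_bp)
        ]
        return full_locus, background

    def test_rnh1_track_is_background_over_loci(self, setup):
        d, truth = setup
        track = simulate_coverage(truth, d, "WT", 0, "rnh1")
        locus_bins, bg_bins = self._locus_and_background_bins(d, truth)
        bg = track.counts[bg_bins]
        locus = track.counts[locus_bins]
        assert len(bg_bins) >= 200
        sd = bg.std(ddof=1)
        se_diff = sd * np.sqrt(1 / len(locus) + 1 / len(bg))
        assert abs(locus.mean() - bg.mean()) <= 3 * se_diff

    def test_drip_enrichment_over_present_loci(self, setup):
        d, truth = setup
        track = simulate_coverage(truth, d, "WT", 0, "drip")
        locus_bins, bg_bins = self._locus_and_background_bins(d, truth)
        assert track.counts[locus_bins].mean() > 5 * track.counts[bg_bins].mean()

    def test_lost_loci_background_in_mutant_drip(self, setup):
        d, truth = setup
        track = simulate_coverage(truth, d, "MUT", 0, "drip")
        lost_bins = [
            b
            for t in truth
            if t.lost_in_mutant
            for b in range(t.start // d.bin_bp + 1, (t.end - 1) // d.bin_bp)
        ]
        assert track.counts[lost_bins].mean() < 2 * d.background_depth

    def test_determinism_and_replicate_independence(self, setup):
        d, truth = setup
        t1 = simulate_coverage(truth, d, "WT", 0, "drip")
        t2 = simulate_coverage(truth, d, "WT", 0, "drip")
        t3 = simulate_coverage(truth, d, "WT", 1, "drip")
        assert np.array_equal(t1.counts, t2.counts)
        assert not np.array_equal(t1.counts, t3.counts)

    def test_unknown_role_rejected(self, setup):
        d, truth = setup
        with pytest.raises(ValueError):
            simulate_coverage(truth, d, "WT", 0, "chip")


class TestIrrAndExpression:
    def _make(self, **kwargs):
        d = SimulationDesign(seed=8, **{**SMALL, **kwargs})
        _, genes = make_genome(d)
        truth = plant_rloops(d, genes)
        return d, genes, truth

    def test_full_linkage_zero_background(self):
        d, genes, truth = self._make(irr_link_rate=1.0, irr_background_rate=0.0)
        events, _, _ = simulate_irr_and_expression(truth, d, genes)
        lost = {t.linked_gene for t in truth if t.lost_in_mutant}
        assert len(events) > 0
        assert set(events.gene_id) <= lost
        # every lost gene received an IRR (rate 1, deterministic counts)
        assert set(events.gene_id) == lost

    def test_link_rate_recovered_exactly(self):
        d, genes, truth = self._make(irr_link_rate=0.5, irr_background_rate=0.0)
        events, _, _ = simulate_irr_and_expression(truth, d, genes)
        lost = {t.linked_gene for t in truth if t.lost_in_mutant}
        assert len(events) == round(0.5 * len(lost))

    def test_zero_shift_null_expression(self):
        d, genes, truth = self._make(expr_shift=0.0)
        _, expr_wt, expr_mut = simulate_irr_and_expression(truth, d, genes)
        tss_loss = [
            t.linked_gene
            for t in truth
            if t.lost_in_mutant and t.feature_class == "promoter-TSS"
        ]
        diffs = expr_wt.loc[tss_loss].mean(axis=1) - expr_mut.loc[tss_loss].mean(axis=1)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se

    def test_planted_shift_present(self):
        d, genes, truth = self._make(expr_shift=1.0)
        _, expr_wt, expr_mut = simulate_irr_and_expression(truth, d, genes)
        tss_loss = [
            t.linked_gene
            for t in truth
            if t.lost_in_mutant and t.feature_class == "promoter-TSS"
        ]
        diffs = expr_wt.loc[tss_loss].mean(axis=1) - expr_mut.loc[tss_loss].mean(axis=1)
        assert diffs.mean() == pytest.approx(1.0, abs=0.3)

    def test_events_are_valid_irrs(self):
        d, genes, truth = self._make()
        events, _, _ = simulate_irr_and_expression(truth, d, genes)
        assert (events.delta_psi < -0.10).all()
        assert (events.adjusted_p < 0.05).all()
        assert (events.event_type == "intron_retention").all()


class TestFibersAndQpcr:
    def test_fiber_mean_speed(self):
        df = simulate_fibers(200, 0.75, 0.45, seed=1)
        speeds = (df.d_idu_kb + df.d_cldu_kb) / (df.t_idu_min + df.t_cldu_min)
        se = speeds.std(ddof=1) / np.sqrt(len(speeds))
        assert abs(speeds.mean() - 0.75) <= 2 * se

    def test_fiber_determinism(self):
        a = simulate_fibers(50, 0.6, 0.4, seed=9)
        b = simulate_fibers(50, 0.6, 0.4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_fiber_parameters(self):
        with pytest.raises(ValueError):
            simulate_fibers(0, 0.75, 0.45)
        with pytest.raises(ValueError):
            simulate_fibers(10, -1.0, 0.45)
        with pytest.raises(ValueError):
            simulate_fibers(10, 0.75, 0.0)

    def test_qpcr_determinism(self):
        spec = [{"locus": "A", "recovery": 0.05}]
        a = simulate_qpcr(spec, seed=3, noise_sd=0.2)
        b = simulate_qpcr(spec, seed=3, noise_sd=0.2)
        pd.testing.assert_frame_equal(a, b)

    def test_qpcr_rnh1_role(self):
        spec = [{"locus": "A", "recovery": 0.05, "rnh1_recovery": 0.001}]
        plate = simulate_qpcr(spec, seed=0)
        assert set(plate.role) == {"input", "drip", "drip_rnh1"}
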