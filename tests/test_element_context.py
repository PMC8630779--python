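"""Mechanism annotation: TAD verdicts vs interval oracle, hand-walked
derivative-chromosome fixtures, chi-square enrichment hand computation."""

import math

import numpy as np
import pandas as pd
import pytest

from cisbreak.element_context import (
    RETRO_WINDOW, classify_tad_disruption, context_enrichment,
    detect_translocated_element, enumerate_upstream_associations, hijack_calls,
)
from cisbreak.io_model import GeneModel, IntervalTrack, SvCall
from conftest import make_cohort


def tad_track():
    # tads of 1 Mb tiling chr1 [0, 10 Mb) with a deliberate gap at [5, 6) Mb
    ivs = [("chr1", s * 1_000_000, (s + 1) * 1_000_000, "TAD")
           for s in range(10) if s != 5]
    return IntervalTrack("tads", ivs)


class TestTadDisruption:
    def test_both_ends_in_same_tad_not_disrupting(self):
        sv = SvCall("s", "chr1", 3_100_000, "+", "chr1", 3_900_000, "-", "DEL", "v")
        assert classify_tad_disruption(sv, tad_track()) is False

    def test_interchromosomal_always_disrupting(self):
        sv = SvCall("s", "chr1", 3_100_000, "+", "chr2", 3_200_000, "-", "TRA", "v")
        assert classify_tad_disruption(sv, tad_track()) is True

    def test_breakpoint_in_tad_gap_is_disrupting(self):
        sv = SvCall("s", "chr1", 5_100_000, "+", "chr1", 5_200_000, "-", "DEL", "v")
        assert classify_tad_disruption(sv, tad_track()) is True

    def test_random_svs_match_interval_oracle(self):
        track = tad_track()
        rng = np.random.default_rng(8)
        for _ in range(100):
            p1, p2 = sorted(int(x) for x in rng.integers(0, 10_000_000, 2))
            sv = SvCall("s", "chr1", p1, "+", "chr1", max(p2, p1 + 1), "-", "DEL", "v")
            shared = [
                iv for iv in track.intervals
                if iv[1] <= p1 < iv[2] and iv[1] <= max(p2, p1 + 1) < iv[2]
            ]
            assert classify_tad_disruption(sv, track) == (not shared)

    def test_verdict_invariant_to_end_order(self):
        a = SvCall("s", "chr1", 2_500_000, "+", "chr1", 7_100_000, "-", "DEL", "v")
        b = SvCall("s", "chr1", 7_100_000, "-", "chr1", 2_500_000, "+", "DEL", "v")
        assert classify_tad_disruption(a, tad_track()) == classify_tad_disruption(b, tad_track())


class TestUpstreamAssociations:
    def _cohort(self):
        gene = GeneModel("g", "chr1", 1_000_000, 1_020_000, "+")
        svs = [
            # two upstream breakpoints in the same sample: 5 kb and 300 kb
            SvCall("S", "chr1", 995_000, "-", "chr2", 100, "+", "TRA", "near"),
            SvCall("S", "chr1", 700_000, "-", "chr2", 200, "+", "TRA", "far"),
            # gene-body-only breakpoint in another sample
            SvCall("T", "chr1", 1_005_000, "-", "chr2", 300, "+", "TRA", "body"),
        ]
        return make_cohort([gene], svs, ["S", "T", "U"])

    def test_closest_upstream_breakpoint_selected(self):
        assoc = enumerate_upstream_associations(self._cohort(), 1_000_000)
        srows = assoc[assoc.sample_id == "S"]
        assert len(srows) == 1
        assert srows.iloc[0]["sv_id"] == "near" and srows.iloc[0]["d_gene"] == 5_000

    def test_gene_body_breakpoint_yields_no_upstream_association(self):
        assoc = enumerate_upstream_associations(self._cohort(), 1_000_000)
        assert "T" not in set(assoc["sample_id"])

    def test_enumeration_matches_brute_force(self, random_small_cohort):
        window = 1_000_000
        assoc = enumerate_upstream_associations(random_small_cohort, window)
        got = {(r.gene_id, r.sample_id): (r.d_gene, r.pos)
               for r in assoc.itertuples()}
        expected = {}
        for gene in random_small_cohort.genes:
            for sv in random_small_cohort.svs:
                for chrom, pos, _ in sv.breakpoints():
                    if chrom != gene.chrom:
                        continue
                    up = pos < gene.start if gene.strand == "+" else pos >= gene.end
                    if not up:
                        continue
                    d = abs(pos - gene.tss)
                    if d > window:
                        continue
                    key = (gene.gene_id, sv.sample_id)
                    if key not in expected or (d, pos) < expected[key]:
                        expected[key] = (d, pos)
        assert got == expected


def _assoc_row(gene_id="g", d_gene=10_000, pos=990_000, strand="-",
               mate=("chr5", 2_000_000, "-")):
    return pd.Series({
        "gene_id": gene_id, "sample_id": "S", "sv_id": "v", "local_end": 1,
        "chrom": "chr1", "pos": pos, "strand": strand,
        "mate_chrom": mate[0], "mate_pos": mate[1], "mate_strand": mate[2],
        "d_gene": d_gene, "altered": "overexpressed",
    })


class TestTranslocatedElement:
    GENE = GeneModel("g", "chr1", 1_000_000, 1_020_000, "+")

    def test_hand_walked_derivative_chromosome_hijack(self):
        # local bp 10 kb upstream retains the gene side ("-"); mate on chr5
        # retains rightward ("-"); LINE 5 kb beyond the mate; no native LINE
        track = IntervalTrack("rep", [("chr5", 2_005_000, 2_006_000, "LINE")])
        call = detect_translocated_element(
            _assoc_row(), self.GENE, track, "LINE", RETRO_WINDOW)
        assert call.is_hijack
        assert call.d_translocated == 15_000
        assert call.d_native == math.inf

    def test_native_element_closer_blocks_hijack(self):
        track = IntervalTrack("rep", [
            ("chr5", 2_005_000, 2_006_000, "LINE"),
            ("chr1", 997_000, 998_000, "LINE"),  # native 2 kb upstream of gene
        ])
        call = detect_translocated_element(
            _assoc_row(), self.GENE, track, "LINE", RETRO_WINDOW)
        assert not call.is_hijack
        assert call.d_native == 2_000 and call.d_translocated == 15_000

    def test_wrong_local_orientation_blocks_hijack(self):
        track = IntervalTrack("rep", [("chr5", 2_005_000, 2_006_000, "LINE")])
        call = detect_translocated_element(
            _assoc_row(strand="+"), self.GENE, track, "LINE", RETRO_WINDOW)
        assert not call.is_hijack and "gene side" in call.reason

    def test_mate_walk_respects_retained_direction(self):
        # mate retains leftward ("+"): element to the right is invisible
        track = IntervalTrack("rep", [("chr5", 2_005_000, 2_006_000, "LINE")])
        call = detect_translocated_element(
            _assoc_row(mate=("chr5", 2_000_000, "+")), self.GENE, track,
            "LINE", RETRO_WINDOW)
        assert not call.is_hijack
        # ... but an element to the left is reachable
        track2 = IntervalTrack("rep", [("chr5", 1_996_000, 1_997_000, "LINE")])
        call2 = detect_translocated_element(
            _assoc_row(mate=("chr5", 2_000_000, "+")), self.GENE, track2,
            "LINE", RETRO_WINDOW)
        assert call2.is_hijack and call2.d_translocated == 13_000

    def test_element_beyond_budget_not_reached(self):
        # budget is class_window - d_gene = 10 kb; element at 11 kb walk
        track = IntervalTrack("rep", [("chr5", 2_011_000, 2_012_000, "LINE")])
        call = detect_translocated_element(
            _assoc_row(), self.GENE, track, "LINE", RETRO_WINDOW)
        assert not call.is_hijack and call.d_translocated == math.inf

    def test_empty_mate_chromosome(self):
        track = IntervalTrack("rep", [("chr9", 0, 1_000, "LINE")])
        call = detect_translocated_element(
            _assoc_row(), self.GENE, track, "LINE", RETRO_WINDOW)
        assert not call.is_hijack

    def test_native_tie_is_not_a_hijack(self):
        # translocated and native both at effective 15 kb: strict < required
        track = IntervalTrack("rep", [
            ("chr5", 2_005_000, 2_006_000, "LINE"),
            ("chr1", 984_000, 985_000, "LINE"),  # native d = 15 kb exactly
        ])
        call = detect_translocated_element(
            _assoc_row(), self.GENE, track, "LINE", RETRO_WINDOW)
        assert call.d_native == call.d_translocated == 15_000
        assert not call.is_hijack


class TestContextEnrichment:
    def test_homogeneous_table_p_one(self):
        ctx = np.array([True] * 50 + [False] * 50 + [True] * 50 + [False] * 50)
        alt = np.array([True] * 100 + [False] * 100)
        stat, p, obs, exp = context_enrichment(ctx, alt)
        assert p == pytest.approx(1.0)
        assert obs == pytest.approx(exp)

    def test_hand_computed_chi_square_statistic(self):
        # table [[30,10],[10,30]]: E = 20 everywhere, sum (O-E)^2/E = 20
        ctx = np.array([True] * 30 + [False] * 10 + [True] * 10 + [False] * 30)
        alt = np.array([True] * 40 + [False] * 40)
        stat, p, obs, exp = context_enrichment(ctx, alt)
        assert stat == pytest.approx(20.0)
        assert obs.tolist() == [[30, 10], [10, 30]]
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(20.0, 1))

    def test_expected_counts_sum_to_table_total(self):
        rng = np.random.default_rng(0)
        ctx = rng.random(200) < 0.3
        alt = rng.random(200) < 0.5
        _, _, obs, exp = context_enrichment(ctx, alt)
        assert exp.sum() == pytest.approx(obs.sum())

    def test_zero_margin_table_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p, _, _ = context_enrichment(np.zeros(10, bool), np.ones(10, bool))
        assert p == 1.0

    def test_planted_enrichment_detected(self):
        # hijack probability 3x in the altered set: power check at n = 2000
        rng = np.random.default_rng(12)
        rejected = 0
        for _ in range(200):
            alt = rng.random(2000) < 0.5
            ctx = rng.random(2000) < np.where(alt, 0.15, 0.05)
            _, p, _, _ = context_enrichment(ctx, alt)
            rejected += p < 0.01
        assert rejected >= 190  # >= 95% of replicates


def test_hijack_calls_table_shape(random_small_cohort):
    track = IntervalTrack("rep", [("chrA", s, s + 500, "LINE")
                                  for s in range(0, 10_000_000, 400_000)])
    assoc = enumerate_upstream_associations(random_small_cohort, RETRO_WINDOW)
    calls = hijack_calls(random_small_cohort, assoc, track, "LINE", RETRO_WINDOW)
    assert len(calls) == len(assoc)
    hijacks = calls[calls.is_hijack]
    assert (hijacks.d_translocated < hijacks.d_native).all()
    assert (hijacks.d_translocated <= RETRO_WINDOW).all()
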