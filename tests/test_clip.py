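"""CLIP enrichment statistics, replicate filtering, region annotation and
hexamer motifs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poisonscan.clip import (
    ClipPeak,
    annotate_peak,
    bh_adjust,
    count_hexamers,
    hexamer_enrichment,
    peak_enrichment,
    reproducible_peaks,
    score_peaks,
)
from poisonscan.errors import ValidationError
from poisonscan.intervals import GenomicInterval


def _peak(start, end, ip, inp, ip_tot=10_000, inp_tot=10_000, contig="c"):
    return ClipPeak(GenomicInterval(contig, start, end, "+"), ip, inp, ip_tot, inp_tot)


class TestPeakEnrichment:
    def test_equal_proportions_give_zero_log2fc(self):
        log2fc, _ = peak_enrichment(10, 1000, 10, 1000)
        assert log2fc == 0.0

    def test_swapping_ip_and_input_negates_log2fc(self):
        a, _ = peak_enrichment(40, 1000, 5, 2000)
        b, _ = peak_enrichment(5, 2000, 40, 1000)
        assert a == pytest.approx(-b)

    def test_p_matches_enumerated_hypergeometric_tail(self):
        # one-sided exact test on [[8, 92], [1, 99]]: condition on 9 successes
        # among 200 draws and enumerate the tail directly
        _, p = peak_enrichment(8, 100, 1, 100)
        total = sum(math.comb(100, k) * math.comb(100, 9 - k) for k in range(0, 10))
        tail = sum(math.comb(100, k) * math.comb(100, 9 - k) for k in range(8, 10))
        assert p == pytest.approx(tail / total, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            peak_enrichment(-1, 100, 1, 100)
        with pytest.raises(ValidationError):
            peak_enrichment(1, 0, 1, 100)
        with pytest.raises(ValidationError):
            peak_enrichment(101, 100, 1, 100)

    def test_null_pvalues_are_super_uniform(self):
        # equal-rate IP/input counts: P(p <= a) must not exceed a (within MC noise)
        rng = np.random.default_rng(42)
        n = 3000
        ip = rng.binomial(2000, 0.01, size=n)
        inp = rng.binomial(2000, 0.01, size=n)
        ps = np.array([peak_enrichment(a, 2000, b, 2000)[1] for a, b in zip(ip, inp)])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = float(np.mean(ps <= alpha))
            assert frac <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n)


def _bh_brute(p):
    """Literal step-up rule: q_i = min_{j >= rank(i)} p_(j) * m / j, clipped."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_ties_map_to_themselves(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_step_up(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(_bh_brute(pvals), abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=40)
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_pvalue_order(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestReproduciblePeaks:
    def test_log2fc_exactly_at_threshold_is_excluded(self):
        # 8-fold pulldown with equal totals sits exactly at log2FC = 3
        pk = _peak(0, 50, ip=63, inp=7)
        [scored] = score_peaks([pk])
        assert scored.log2fc == pytest.approx(3.0)
        assert reproducible_peaks([scored], [scored], fdr_max=1.1, log2fc_min=3.0) == []

    def test_identical_passing_tables_are_idempotent(self):
        peaks = score_peaks([_peak(0, 50, 400, 5), _peak(100, 150, 300, 2)])
        kept = reproducible_peaks(peaks, peaks)
        assert len(kept) == len(peaks)
        assert reproducible_peaks(kept, kept) == kept

    def test_merged_interval_is_intersection(self):
        r1 = score_peaks([_peak(100, 200, 400, 5)])
        r2 = score_peaks([_peak(150, 250, 400, 5)])
        [kept] = reproducible_peaks(r1, r2)
        assert (kept.interval.start, kept.interval.end) == (150, 200)

    def test_non_overlapping_replicates_drop_out(self):
        r1 = score_peaks([_peak(0, 50, 400, 5)])
        r2 = score_peaks([_peak(60, 110, 400, 5)])
        assert reproducible_peaks(r1, r2) == []

    def test_disjoint_contig_namespaces_rejected(self):
        r1 = score_peaks([_peak(0, 50, 400, 5, contig="chrA")])
        r2 = score_peaks([_peak(0, 50, 400, 5, contig="chrB")])
        with pytest.raises(ValidationError, match="contig"):
            reproducible_peaks(r1, r2)


class TestAnnotatePeak:
    def test_priority_and_partition(self, toy_gene):
        genome, tx = toy_gene
        cases = {
            (20, 30): "CDS",  # mid-exon1 coding, > 10 nt from the donor at 40...
            (11, 16): "5'UTR",
            (90, 95): "CDS",
            (35, 45): "5'SS",  # straddles the donor at 40 despite touching CDS
            (75, 82): "3'SS",  # acceptor at 80
            (170, 200): "3'UTR",
        }
        for (s, e), expected in cases.items():
            label = annotate_peak(
                GenomicInterval("chrT", s, e, "+"), [tx], ss_window=5, proximal_window=8
            )
            assert label == expected, (s, e)

    def test_intron_distance_decides_proximal_vs_distal(self, toy_gene):
        _, tx = toy_gene
        # intron1 spans [40, 80); with tiny windows, its middle is distal
        assert (
            annotate_peak(GenomicInterval("chrT", 58, 62), [tx], ss_window=2, proximal_window=5)
            == "distal_intron"
        )
        assert (
            annotate_peak(GenomicInterval("chrT", 44, 48), [tx], ss_window=1, proximal_window=10)
            == "proximal_intron"
        )

    def test_unannotated_contig_is_intergenic(self, toy_gene):
        _, tx = toy_gene
        assert annotate_peak(GenomicInterval("chrZ", 0, 10), []) == "intergenic"


class TestHexamerEnrichment:
    def test_seven_nt_foreground_has_two_windows(self):
        assert count_hexamers(["GGGGGGG"]) == {"GGGGGG": 2}

    def test_windows_with_n_are_skipped(self):
        assert count_hexamers(["GGGGGGNGGGGGG"]) == {"GGGGGG": 2}

    def test_identical_fg_bg_has_zero_enrichment(self):
        seqs = ["ACGTACGTACGT", "GGGCCCAAATTT"]
        for r in hexamer_enrichment(seqs, seqs):
            assert r.log2_enrichment == pytest.approx(0.0)

    def test_planted_extreme_motif_ranks_first(self):
        rng = np.random.default_rng(0)
        bg = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(40)]
        fg = ["GGGGGG" * 5] * 10
        results = hexamer_enrichment(fg, bg)
        assert results[0].hexamer == "GGGGGG"
        assert results[0].z > 10

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValidationError):
            hexamer_enrichment([], ["ACGTACGT"])
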