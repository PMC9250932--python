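"""Isoform reconstruction, ORF scanning, the 50-nt NMD rule, domain-loss
accounting and consequence classification."""

import pytest

from poisonscan.consequence import (
    IncompatibleHostError,
    build_isoform_pair,
    call_domain_change,
    call_nmd,
    classify_consequence,
    scan_orf,
    summarize_consequences,
    ConsequenceCall,
)
from poisonscan.errors import ValidationError
from poisonscan.intervals import GenomicInterval
from poisonscan.splicing import SplicingEvent, read_event_table
from poisonscan.transcripts import DomainAnnotation, TranscriptModel


def _ce_event(s, e, dpsi=0.3, contig="chrT", strand="+",
              up=(10, 40), dn=(80, 110)):
    return SplicingEvent(
        "CE", "ev", "TOY", contig, strand,
        {
            "exonStart_0base": s, "exonEnd": e,
            "upstreamES": up[0], "upstreamEE": up[1],
            "downstreamES": dn[0], "downstreamEE": dn[1],
        },
        dpsi, 0.01,
    )


def _tx(exon_pairs, strand="+", contig="c", cds=None):
    return TranscriptModel(
        gene_id="g", transcript_id="t", contig=contig, strand=strand,
        exons=tuple(GenomicInterval(contig, s, e, strand) for s, e in exon_pairs),
        cds=cds,
    )


class TestBuildIsoformPair:
    def test_cassette_insertion_matches_hand_built_chain(self, toy_gene):
        _, tx = toy_gene
        pair = build_isoform_pair(_ce_event(50, 62), tx)
        assert [(e.start, e.end) for e in pair.inclusion.exons] == [
            (10, 40), (50, 62), (80, 110), (150, 210)
        ]
        assert pair.exclusion.exons == tx.exons
        assert pair.inclusion.spliced_length == pair.exclusion.spliced_length + 12

    def test_cassette_equal_to_host_exon_gives_host_inclusion(self, toy_gene):
        _, tx = toy_gene
        pair = build_isoform_pair(
            _ce_event(80, 110, up=(10, 40), dn=(150, 210)), tx
        )
        assert pair.inclusion.exons == tx.exons
        assert [(e.start, e.end) for e in pair.exclusion.exons] == [
            (10, 40), (150, 210)
        ]

    def test_retained_intron_merges_flanks_and_adds_intron_length(self, toy_gene):
        _, tx = toy_gene
        ev = SplicingEvent(
            "RI", "ri", "TOY", "chrT", "+",
            {
                "riExonStart_0base": 80, "riExonEnd": 210,
                "upstreamES": 80, "upstreamEE": 110,
                "downstreamES": 150, "downstreamEE": 210,
            },
            0.3, 0.01,
        )
        pair = build_isoform_pair(ev, tx)
        # intron2 spans [110, 150): 40 nt retained
        assert pair.inclusion.spliced_length == pair.exclusion.spliced_length + 40
        assert [(e.start, e.end) for e in pair.inclusion.exons] == [(10, 40), (80, 210)]

    def test_event_outside_host_span_is_incompatible(self, toy_gene):
        _, tx = toy_gene
        with pytest.raises(IncompatibleHostError):
            build_isoform_pair(_ce_event(500, 600, up=(400, 450), dn=(700, 750)), tx)


class TestScanOrf:
    def test_annotated_start_survives_and_matches_host_cds(self, toy_gene):
        genome, tx = toy_gene
        orf = scan_orf(tx, genome)
        assert orf == (9, 75)  # ATG after the 9-nt UTR; stop after 22 codons

    def test_first_aug_rule_when_annotation_absent(self):
        genome = {"c": "CCC" + "ATG" + "AAA" * 35 + "TAA"}
        tx = _tx([(0, len(genome["c"]))])
        assert scan_orf(tx, genome) == (3, 3 + 3 + 105)

    def test_min_codon_rule_relaxed_in_unit_fixture(self):
        genome = {"c": "AAAATGAAATAA"}
        tx = _tx([(0, 12)])
        assert scan_orf(tx, genome, min_orf_codons=1) == (3, 9)
        assert scan_orf(tx, genome, min_orf_codons=30) is None

    def test_no_aug_returns_none(self):
        genome = {"c": "A" * 60}
        assert scan_orf(_tx([(0, 60)]), genome) is None


class TestCallNmd:
    def test_stop_in_last_exon_is_immune(self):
        iso = _tx([(0, 30), (100, 130)])
        ptc, dist, nmd = call_nmd(iso, (0, 33))
        assert (ptc, nmd) == (False, False)

    def test_boundary_at_exactly_50_nt_triggers(self):
        iso = _tx([(0, 59), (100, 130)])  # junction at mRNA offset 59
        ptc, dist, nmd = call_nmd(iso, (0, 6))  # stop codon ends at 9
        assert (ptc, dist, nmd) == (True, 50, True)

    def test_49_nt_does_not_trigger(self):
        iso = _tx([(0, 58), (100, 130)])
        ptc, dist, nmd = call_nmd(iso, (0, 6))
        assert (ptc, dist, nmd) == (True, 49, False)

    def test_single_exon_isoforms_are_immune(self):
        iso = _tx([(0, 300)])
        assert call_nmd(iso, (0, 6)) == (False, None, False)

    def test_missing_stop_is_not_a_ptc(self):
        iso = _tx([(0, 59), (100, 130)])
        assert call_nmd(iso, (0, None)) == (False, None, False)


class TestCallDomainChange:
    DOMS = [DomainAnnotation("g", "D", 20, 30)]

    def test_identity_is_none(self):
        ref = "M" + "K" * 50
        assert call_domain_change(ref, ref, self.DOMS) == ("none", ())

    def test_truncation_before_domain_is_complete_loss(self):
        ref = "M" + "K" * 50
        assert call_domain_change(ref, "MK", self.DOMS) == ("domain_loss_complete", ("D",))

    def test_truncation_mid_domain_is_partial_loss(self):
        ref = "M" + "K" * 50
        alt = ref[:25]
        assert call_domain_change(ref, alt, self.DOMS) == ("domain_loss_partial", ("D",))

    def test_divergence_without_domain_overlap_is_frameshift(self):
        ref = "M" + "K" * 10
        alt = "M" + "K" * 5 + "RRRRR"
        cat, lost = call_domain_change(ref, alt, [])
        assert cat == "frameshift_no_domain" and lost == ()

    def test_domain_beyond_reference_rejected(self):
        with pytest.raises(ValidationError):
            call_domain_change("MKK", "MKK", [DomainAnnotation("g", "D", 2, 10)])


class TestClassifyConsequence:
    def test_poison_cassette_with_inframe_ptc_is_nmd(self, toy_gene):
        genome, tx = toy_gene
        seq = list(genome["chrT"])
        seq[50:53] = "TAA"  # in-frame stop inside a 24-nt cassette at (50, 74)
        genome = {"chrT": "".join(seq)}
        pair = build_isoform_pair(_ce_event(50, 74, dpsi=0.3), tx)
        call = classify_consequence(pair, genome, [], min_orf_codons=5)
        assert call.category == "NMD"
        assert call.ptc_present
        assert call.ptc_to_last_junction_nt == 51

    def test_inframe_cassette_without_ptc_hits_domain(self, toy_gene):
        genome, tx = toy_gene
        # 12-nt poly-C cassette: four proline codons inserted after residue 7
        pair = build_isoform_pair(_ce_event(50, 62, dpsi=0.3), tx)
        domains = [DomainAnnotation("TOY", "KDOM", 5, 10)]
        call = classify_consequence(pair, genome, domains, min_orf_codons=5)
        assert call.category == "domain_loss_partial"
        assert call.lost_domains == ("KDOM",)

    def test_promoting_the_host_isoform_is_none(self, toy_gene):
        genome, tx = toy_gene
        pair = build_isoform_pair(
            _ce_event(80, 110, dpsi=0.3, up=(10, 40), dn=(150, 210)), tx
        )
        call = classify_consequence(pair, genome, [], min_orf_codons=5)
        assert call.category == "none"


class TestSummaries:
    def test_single_nmd_call_is_100_pct(self):
        calls = [ConsequenceCall("e", "g", "NMD", True, 60, ())]
        s = summarize_consequences(calls)
        assert s["category_pct"]["NMD"] == 100.0

    def test_percentages_cover_all_calls(self):
        cats = ["NMD"] * 3 + ["none"] * 2 + ["domain_loss_partial"] * 2
        calls = [ConsequenceCall(f"e{i}", "g", c, False, None, ()) for i, c in enumerate(cats)]
        s = summarize_consequences(calls)
        assert sum(s["categories"].values()) == len(calls)
        assert sum(s["category_pct"].values()) == pytest.approx(100.0, abs=0.3)

    def test_empty_input_has_zero_denominator(self):
        s = summarize_consequences([])
        assert s["n_events"] == 0
        assert all(v == 0 for v in s["categories"].values())


class TestGeneratorConsistency:
    def test_every_planted_ptc_gene_is_called_nmd(self, sim_small):
        """The generator promises its poison isoforms satisfy the 50-nt rule;
        the caller must recover every one (recall 1.0)."""
        gt = sim_small.ground_truth
        ptc_genes = set(gt[gt.introduces_PTC].gene_id)
        genome = sim_small.genome
        hosts = {t.gene_id: t for t in sim_small.transcripts}
        events = []
        for t in sim_small.event_tables:
            events.extend(read_event_table(sim_small.paths[f"events_{t}"], t))
        called_nmd = set()
        for ev in events:
            if ev.gene_id not in ptc_genes:
                continue
            pair = build_isoform_pair(ev, hosts[ev.gene_id])
            call = classify_consequence(pair, genome, sim_small.domains)
            if call.category == "NMD":
                called_nmd.add(ev.gene_id)
        assert called_nmd == ptc_genes
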