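"""Per-event protein-consequence calling.

For each significant splicing event the inclusion and exclusion isoforms are
rebuilt on the host transcript, the open reading frame is located, the 50-nt
rule decides NMD sensitivity, and domain-level changes are scored against the
reference protein.

The 50-nt rule: a stop codon whose last base lies >= 50 nt upstream of the
last exon-exon junction of the spliced mRNA marks the transcript for
nonsense-mediated decay; stops in the last exon (or in single-exon mRNAs)
escape.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError
from .intervals import GenomicInterval
from .splicing import REPRESSED, SplicingEvent, classify_direction
from .transcripts import (
    START_CODON,
    STOP_CODONS,
    DomainAnnotation,
    TranscriptModel,
    spliced_sequence,
    translate_orf,
)

CATEGORIES = (
    "NMD",
    "processed_transcript",
    "domain_loss_complete",
    "domain_loss_partial",
    "frameshift_no_domain",
    "none",
)

#: grouping used for "altering coding potential" vs "altering protein domain"
SUPER_CATEGORY = {
    "NMD": "altering_coding_potential",
    "processed_transcript": "altering_coding_potential",
    "domain_loss_complete": "altering_protein_domain",
    "domain_loss_partial": "altering_protein_domain",
    "frameshift_no_domain": "altering_protein_domain",
    "none": "none",
}

NMD_RULE_NT = 50
MIN_ORF_CODONS = 30


class IncompatibleHostError(ValidationError):
    """Event coordinates cannot be embedded in the host exon chain."""


@dataclass(frozen=True)
class IsoformPair:
    host: TranscriptModel
    inclusion: TranscriptModel
    exclusion: TranscriptModel
    event: SplicingEvent


@dataclass(frozen=True)
class ConsequenceCall:
    event_id: str
    gene_id: str
    category: str
    ptc_present: bool
    ptc_to_last_junction_nt: int | None
    lost_domains: tuple[str, ...]

    @property
    def super_category(self) -> str:
        return SUPER_CATEGORY[self.category]


# ---------------------------------------------------------------------------
# isoform reconstruction


def _iv(tx: TranscriptModel, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(tx.contig, start, end, tx.strand)


def _remove_exon(exons, start, end):
    return [e for e in exons if not (e.start == start and e.end == end)]


def _insert_exon(tx: TranscriptModel, exons, start, end):
    new = sorted(exons + [_iv(tx, start, end)], key=lambda e: e.start)
    for a, b in zip(new, new[1:]):
        if a.end > b.start:
            raise IncompatibleHostError(
                f"exon [{start},{end}) collides with host chain of {tx.transcript_id}"
            )
    return new


def _replace_exon(tx, exons, old_start, old_end, new_start, new_end):
    kept = _remove_exon(exons, old_start, old_end)
    if len(kept) == len(exons):
        raise IncompatibleHostError(
            f"host {tx.transcript_id} lacks exon [{old_start},{old_end})"
        )
    return _insert_exon(tx, kept, new_start, new_end)


def build_isoform_pair(event: SplicingEvent, host: TranscriptModel) -> IsoformPair:
    """Rebuild the inclusion/exclusion isoforms of ``event`` on ``host``.

    CE: inclusion carries the cassette between the flanking exons.
    RI: inclusion merges the flanking exons across the retained intron.
    A3SS/A5SS: inclusion uses the long (extended) exon, exclusion the short.
    MXE: inclusion uses the first alternative exon, exclusion the second.
    The host's other exons are inherited unchanged.
    """
    if event.contig != host.contig:
        raise IncompatibleHostError(
            f"event on {event.contig} vs host on {host.contig}"
        )
    span = host.span
    fp = event.footprint
    if fp.start < span.start or fp.end > span.end:
        raise IncompatibleHostError(
            f"event footprint outside host span for {event.event_id}"
        )
    c = event.coords
    exons = list(host.exons)
    t = event.event_type
    if t == "CE":
        s, e = c["exonStart_0base"], c["exonEnd"]
        excl = _remove_exon(exons, s, e)
        incl = _insert_exon(host, excl, s, e)
    elif t == "RI":
        us, ue = c["upstreamES"], c["upstreamEE"]
        ds, de = c["downstreamES"], c["downstreamEE"]
        excl = list(exons)
        merged = _remove_exon(exons, us, ue)
        merged = _remove_exon(merged, ds, de)
        if len(merged) != len(exons) - 2:
            raise IncompatibleHostError(
                f"host {host.transcript_id} lacks the RI flanking exons"
            )
        incl = _insert_exon(host, merged, us, de)
    elif t in ("A3SS", "A5SS"):
        ls, le = c["longExonStart_0base"], c["longExonEnd"]
        ss, se = c["shortES"], c["shortEE"]
        has_long = any(e.start == ls and e.end == le for e in exons)
        has_short = any(e.start == ss and e.end == se for e in exons)
        if has_short:
            excl = exons
            incl = _replace_exon(host, exons, ss, se, ls, le)
        elif has_long:
            incl = exons
            excl = _replace_exon(host, exons, ls, le, ss, se)
        else:
            raise IncompatibleHostError(
                f"host {host.transcript_id} matches neither {t} exon form"
            )
    elif t == "MXE":
        s1, e1 = c["1stExonStart_0base"], c["1stExonEnd"]
        s2, e2 = c["2ndExonStart_0base"], c["2ndExonEnd"]
        has1 = any(e.start == s1 and e.end == e1 for e in exons)
        has2 = any(e.start == s2 and e.end == e2 for e in exons)
        if has2 and not has1:
            excl = exons
            incl = _replace_exon(host, exons, s2, e2, s1, e1)
        elif has1 and not has2:
            incl = exons
            excl = _replace_exon(host, exons, s1, e1, s2, e2)
        else:
            raise IncompatibleHostError(
                f"host {host.transcript_id} must carry exactly one MXE exon"
            )
    else:  # pragma: no cover - guarded by SplicingEvent validation
        raise ValidationError(f"unknown event type {t}")
    return IsoformPair(
        host=host,
        inclusion=host.with_exons(incl),
        exclusion=host.with_exons(excl),
        event=event,
    )


# ---------------------------------------------------------------------------
# ORF scan and NMD rule


def scan_orf(
    isoform: TranscriptModel,
    genome: dict[str, str],
    min_orf_codons: int = MIN_ORF_CODONS,
) -> tuple[int, int | None] | None:
    """Locate the ORF on the spliced isoform.

    If the host's annotated start codon survives splicing (its genomic
    position is exonic and still reads ATG), it is used; otherwise the first
    AUG opening an ORF of >= ``min_orf_codons`` codons is taken.  Returns
    ``(orf_start, stop_offset)`` in mRNA coordinates (``stop_offset`` is the
    first base of the stop codon, or ``None`` when translation runs off the
    end), or ``None`` when the isoform has no qualifying ORF.
    """
    mrna = spliced_sequence(isoform, genome)

    def stop_of(start: int) -> int | None:
        for i in range(start, len(mrna) - 2, 3):
            if mrna[i : i + 3] in STOP_CODONS:
                return i
        return None

    start_pos = isoform.annotated_start_genomic()
    if start_pos is not None:
        off = isoform.genomic_to_mrna(start_pos)
        if off is not None and mrna[off : off + 3] == START_CODON:
            return off, stop_of(off)

    search = 0
    while True:
        off = mrna.find(START_CODON, search)
        if off < 0:
            return None
        stop = stop_of(off)
        n_codons = ((stop if stop is not None else len(mrna) - (len(mrna) - off) % 3) - off) // 3
        if n_codons >= min_orf_codons:
            return off, stop
        search = off + 1


def call_nmd(
    isoform: TranscriptModel,
    orf: tuple[int, int | None],
    rule_nt: int = NMD_RULE_NT,
) -> tuple[bool, int | None, bool]:
    """Apply the 50-nt rule.  Returns (ptc_present, distance_nt, nmd_flag)
    where distance_nt = last-junction offset minus the stop codon's end."""
    _, stop_offset = orf
    if stop_offset is None:
        return False, None, False
    last_junction = isoform.last_junction_mrna_offset()
    if last_junction is None:  # single-exon mRNA: no downstream junction
        return False, None, False
    distance = last_junction - (stop_offset + 3)
    ptc_present = distance > 0
    return ptc_present, distance, distance >= rule_nt


# ---------------------------------------------------------------------------
# domain accounting


def call_domain_change(
    ref_protein: str,
    alt_protein: str,
    domains: list[DomainAnnotation],
) -> tuple[str, tuple[str, ...]]:
    """Compare proteins by shared prefix; every residue at or after the first
    divergent position counts as lost (a frameshifted tail cannot fold the
    reference domain).  Complete loss = no residue of the domain survives;
    partial = some but not all."""
    for d in domains:
        if d.aa_end > len(ref_protein):
            raise ValidationError(
                f"domain {d.domain_name} ({d.aa_start}-{d.aa_end}) exceeds "
                f"reference protein length {len(ref_protein)}"
            )
    prefix = 0
    for a, b in zip(ref_protein, alt_protein):
        if a != b:
            break
        prefix += 1
    lost_from = prefix + 1  # first lost residue, 1-based, in ref coordinates
    if lost_from > len(ref_protein):
        return "none", ()
    complete, partial = [], []
    for d in domains:
        if d.aa_start >= lost_from:
            complete.append(d.domain_name)
        elif d.aa_end >= lost_from:
            partial.append(d.domain_name)
    if complete:
        return "domain_loss_complete", tuple(complete + partial)
    if partial:
        return "domain_loss_partial", tuple(partial)
    return "frameshift_no_domain", ()


# ---------------------------------------------------------------------------
# classification


def classify_consequence(
    pair: IsoformPair,
    genome: dict[str, str],
    domains: list[DomainAnnotation],
    nmd_rule_nt: int = NMD_RULE_NT,
    min_orf_codons: int = MIN_ORF_CODONS,
) -> ConsequenceCall:
    """Classify the knockdown-promoted isoform against the factor-supported
    one.  Precedence: no qualifying ORF -> processed_transcript; 50-nt rule
    -> NMD; otherwise domain accounting on the translated proteins."""
    event = pair.event
    direction = event.direction or classify_direction(event)
    if direction == REPRESSED:
        promoted, reference = pair.inclusion, pair.exclusion
    else:
        promoted, reference = pair.exclusion, pair.inclusion

    orf = scan_orf(promoted, genome, min_orf_codons=min_orf_codons)
    if orf is None:
        return ConsequenceCall(
            event.event_id, event.gene_id, "processed_transcript", False, None, ()
        )
    ptc_present, distance, nmd = call_nmd(promoted, orf, rule_nt=nmd_rule_nt)
    if nmd:
        return ConsequenceCall(
            event.event_id, event.gene_id, "NMD", True, distance, ()
        )

    ref_orf = scan_orf(reference, genome, min_orf_codons=min_orf_codons)
    if ref_orf is None:
        return ConsequenceCall(
            event.event_id, event.gene_id, "none", ptc_present, distance, ()
        )
    mrna_p = spliced_sequence(promoted, genome)
    mrna_r = spliced_sequence(reference, genome)
    prot_p = translate_orf(mrna_p, orf[0])
    prot_r = translate_orf(mrna_r, ref_orf[0])
    gene_domains = [
        d
        for d in domains
        if d.gene_id == event.gene_id and d.aa_end <= len(prot_r)
    ]
    if prot_p == prot_r:
        return ConsequenceCall(
            event.event_id, event.gene_id, "none", ptc_present, distance, ()
        )
    category, lost = call_domain_change(prot_r, prot_p, gene_domains)
    return ConsequenceCall(
        event.event_id, event.gene_id, category, ptc_present, distance, lost
    )


# ---------------------------------------------------------------------------
# summaries


def _pct(k: int, n: int) -> float:
    """Percentage with one decimal, half-up (13.25 -> 13.3)."""
    if n == 0:
        return 0.0
    return float(
        (Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def summarize_consequences(calls: list[ConsequenceCall]) -> dict:
    """Counts and printed-style percentages per category and super-category."""
    n = len(calls)
    cat = Counter(c.category for c in calls)
    sup = Counter(c.super_category for c in calls)
    return {
        "n_events": n,
        "categories": {c: int(cat.get(c, 0)) for c in CATEGORIES},
        "category_pct": {c: _pct(cat.get(c, 0), n) for c in CATEGORIES},
        "super_categories": {
            s: int(sup.get(s, 0))
            for s in ("altering_coding_potential", "altering_protein_domain", "none")
        },
        "super_category_pct": {
            s: _pct(sup.get(s, 0), n)
            for s in ("altering_coding_potential", "altering_protein_domain", "none")
        },
    }
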