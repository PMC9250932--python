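"""Transcript models, spliced-sequence extraction and translation.

A :class:`TranscriptModel` stores its exons in genomic order regardless of
strand; strand is applied only when the spliced mRNA is extracted, which keeps
all interval algebra strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .errors import ValidationError
from .intervals import GenomicInterval

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain in 1-based inclusive amino-acid coordinates."""

    gene_id: str
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValidationError(
                f"invalid domain coordinates {self.aa_start}-{self.aa_end} "
                f"for {self.domain_name}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus an optional genomic CDS span.

    ``cds`` is the genomic span from the first base of the start codon to the
    last base of the stop codon (0-based half-open), irrespective of strand.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[int, int] | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0].start <= cs < ce <= self.exons[-1].end):
                raise ValidationError(
                    f"CDS ({cs},{ce}) outside exon span of {self.transcript_id}"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.contig, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        """Total exonic length inside the CDS span (0 for non-coding)."""
        if self.cds is None:
            return 0
        cs, ce = self.cds
        return sum(max(0, min(e.end, ce) - max(e.start, cs)) for e in self.exons)

    def with_exons(self, exons) -> "TranscriptModel":
        return replace(self, exons=tuple(exons))

    # -- coordinate mapping ----------------------------------------------

    def genomic_to_mrna(self, pos: int) -> int | None:
        """Map a genomic base position to its 0-based mRNA offset, or ``None``
        if the position is intronic / outside the transcript."""
        offset = 0
        if self.strand == "+":
            for e in self.exons:
                if e.start <= pos < e.end:
                    return offset + (pos - e.start)
                offset += len(e)
        else:
            for e in reversed(self.exons):
                if e.start <= pos < e.end:
                    return offset + (e.end - 1 - pos)
                offset += len(e)
        return None

    def last_junction_mrna_offset(self) -> int | None:
        """mRNA coordinate of the last exon-exon junction (the first base of
        the 3'-terminal exon); ``None`` for single-exon transcripts."""
        if len(self.exons) < 2:
            return None
        last = self.exons[-1] if self.strand == "+" else self.exons[0]
        return self.spliced_length - len(last)

    def annotated_start_genomic(self) -> int | None:
        """Genomic position of the first base of the start codon."""
        if self.cds is None:
            return None
        cs, ce = self.cds
        return cs if self.strand == "+" else ce - 1


def spliced_sequence(tx: TranscriptModel, genome: dict[str, str]) -> str:
    """Extract the 5'->3' mRNA of ``tx`` from a contig->sequence mapping."""
    if tx.contig not in genome:
        raise KeyError(f"contig {tx.contig!r} not in genome")
    contig_seq = genome[tx.contig]
    n = len(contig_seq)
    parts = []
    for e in tx.exons:
        if e.end > n:
            raise ValidationError(
                f"exon [{e.start},{e.end}) exceeds contig {tx.contig} length {n}"
            )
        parts.append(contig_seq[e.start : e.end])
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_orf(mrna: str, orf_start: int) -> str:
    """Translate from ``orf_start`` until the first in-frame stop (excluded)
    or the end of the sequence; a trailing partial codon is dropped.

    Requires a literal ATG at ``orf_start``; ambiguity codes never match the
    start codon and translate to ``X``.
    """
    mrna = mrna.upper()
    if mrna[orf_start : orf_start + 3] != START_CODON:
        raise ValidationError(f"no ATG at offset {orf_start}")
    aas = []
    for i in range(orf_start, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)
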