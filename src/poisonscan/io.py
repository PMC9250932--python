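"""Readers/writers for FASTA, GTF, BED6 and the package's tabular dialects.

The GTF reader is deliberately minimal: only ``exon``, ``CDS``,
``start_codon`` and ``stop_codon`` features carrying ``gene_id`` and
``transcript_id`` attributes are consumed.  GFF3 is out of scope.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .intervals import GenomicInterval, interval_from_external
from .transcripts import DomainAnnotation, TranscriptModel

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly line-wrapped, multi-contig) FASTA into a dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at 60; width kept for API stability


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')
_GTF_FEATURES = {"exon", "CDS", "start_codon", "stop_codon"}


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file (1-based closed coordinates)."""
    exons: dict[str, list[GenomicInterval]] = {}
    cds_bounds: dict[str, list[int]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in _GTF_FEATURES:
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            try:
                tid = attr["transcript_id"]
                gid = attr["gene_id"]
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: missing {exc} attribute") from exc
            iv = interval_from_external(contig, int(start), int(end), "GTF", strand)
            meta.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "contig": contig,
                    "strand": strand,
                    "biotype": attr.get("transcript_biotype", "protein_coding"),
                },
            )
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:  # CDS / start_codon / stop_codon all bound the coding span
                cds_bounds.setdefault(tid, []).extend((iv.start, iv.end))
    out = []
    for tid, exon_list in sorted(exons.items()):
        m = meta[tid]
        cds = None
        if tid in cds_bounds:
            cds = (min(cds_bounds[tid]), max(cds_bounds[tid]))
        out.append(
            TranscriptModel(
                gene_id=m["gene_id"],
                transcript_id=tid,
                contig=m["contig"],
                strand=m["strand"],
                exons=tuple(exon_list),
                cds=cds,
                biotype=m["biotype"],
            )
        )
    return out


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write exon/CDS/start_codon/stop_codon features (1-based closed)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )

            def row(feature: str, start0: int, end0: int) -> str:
                return (
                    f"{tx.contig}\tpoisonscan\t{feature}\t{start0 + 1}\t{end0}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )

            for e in tx.exons:
                fh.write(row("exon", e.start, e.end))
            if tx.cds is not None:
                cs, ce = tx.cds
                for e in tx.exons:
                    s, t = max(e.start, cs), min(e.end, ce)
                    if s < t:
                        fh.write(row("CDS", s, t))
                if tx.strand == "+":
                    fh.write(row("start_codon", cs, cs + 3))
                    fh.write(row("stop_codon", ce - 3, ce))
                else:
                    fh.write(row("start_codon", ce - 3, ce))
                    fh.write(row("stop_codon", cs, cs + 3))


# ---------------------------------------------------------------------------
# BED6


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed6(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tabular dialects (TSV via pandas)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Domain table columns: gene_id, domain_name, aa_start, aa_end."""
    df = read_tsv(path)
    required = {"gene_id", "domain_name", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing domain columns {sorted(missing)}")
    return [
        DomainAnnotation(r.gene_id, r.domain_name, int(r.aa_start), int(r.aa_end))
        for r in df.itertuples(index=False)
    ]
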