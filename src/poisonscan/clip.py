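"""Input-normalized CLIP peak enrichment, reproducibility filtering,
transcript-region annotation and hexamer motif enrichment.

Enrichment of an IP library over its size-matched input at a candidate site is
scored with a pseudocounted log2 fold change of library-normalized rates and a
one-sided exact test on the 2x2 read-count table.  Peaks are kept when they
overlap between biological replicates and pass ``FDR < 0.05`` and
``log2FC > 3`` (both strict) in each replicate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .intervals import GenomicInterval
from .transcripts import TranscriptModel

REGION_LABELS = (
    "5'SS",
    "3'SS",
    "CDS",
    "5'UTR",
    "3'UTR",
    "proximal_intron",
    "distal_intron",
    "noncoding_exon",
    "intergenic",
)

PSEUDOCOUNT = 1.0


@dataclass
class ClipPeak:
    """One candidate binding site in one replicate (IP vs size-matched input)."""

    interval: GenomicInterval
    ip_count: int
    input_count: int
    ip_total: int
    input_total: int
    log2fc: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    region_label: str | None = None
    passes_filter: bool = False


@dataclass(frozen=True)
class MotifResult:
    hexamer: str
    fg_count: int
    bg_count: int
    log2_enrichment: float
    z: float


# ---------------------------------------------------------------------------
# enrichment statistics


def peak_enrichment(
    ip_count: int, ip_total: int, input_count: int, input_total: int
) -> tuple[float, float]:
    """Return (log2 fold change, one-sided exact p) for IP vs input counts.

    log2FC uses a +1 pseudocount on both rates; the p-value is the upper tail
    of Fisher's exact test on ``[[ip, ip_total-ip], [input, input_total-input]]``
    with alternative "IP enriched".
    """
    if min(ip_count, input_count) < 0:
        raise ValidationError("negative read counts")
    if ip_total <= 0 or input_total <= 0:
        raise ValidationError("library totals must be positive")
    if ip_count > ip_total or input_count > input_total:
        raise ValidationError("count exceeds library total")
    log2fc = float(
        np.log2(
            ((ip_count + PSEUDOCOUNT) / ip_total)
            / ((input_count + PSEUDOCOUNT) / input_total)
        )
    )
    table = [
        [ip_count, ip_total - ip_count],
        [input_count, input_total - input_count],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return log2fc, float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# replicate reproducibility


def score_peaks(peaks: list[ClipPeak]) -> list[ClipPeak]:
    """Fill log2fc/p/fdr for one replicate's peak list (BH across the list)."""
    scored = []
    for pk in peaks:
        log2fc, p = peak_enrichment(pk.ip_count, pk.ip_total, pk.input_count, pk.input_total)
        scored.append(replace(pk, log2fc=log2fc, p=p))
    if scored:
        qs = bh_adjust([pk.p for pk in scored])
        scored = [replace(pk, fdr=float(q)) for pk, q in zip(scored, qs)]
    return scored


def reproducible_peaks(
    peaks_rep1: list[ClipPeak],
    peaks_rep2: list[ClipPeak],
    fdr_max: float = 0.05,
    log2fc_min: float = 3.0,
) -> list[ClipPeak]:
    """Peaks passing ``fdr < fdr_max`` and ``log2fc > log2fc_min`` in both
    replicates and overlapping by >= 1 nt; the merged interval is the
    intersection of the two replicate intervals."""
    c1 = {p.interval.contig for p in peaks_rep1}
    c2 = {p.interval.contig for p in peaks_rep2}
    if peaks_rep1 and peaks_rep2 and not (c1 & c2):
        raise ValidationError(
            f"replicate peak tables share no contigs: {sorted(c1 ^ c2)}"
        )

    def passes(pk: ClipPeak) -> bool:
        return pk.fdr < fdr_max and pk.log2fc > log2fc_min

    pass2 = [p for p in peaks_rep2 if passes(p)]
    merged: list[ClipPeak] = []
    for p1 in peaks_rep1:
        if not passes(p1):
            continue
        for p2 in pass2:
            inter = p1.interval.intersection(p2.interval)
            if inter is not None:
                merged.append(replace(p1, interval=inter, passes_filter=True))
                break
    return merged


# ---------------------------------------------------------------------------
# region annotation


def _canonical_transcript(candidates: list[TranscriptModel]) -> TranscriptModel:
    # longest CDS wins; deterministic lexicographic tie-break
    return max(candidates, key=lambda t: (t.cds_length, t.transcript_id))


def annotate_peak(
    peak: ClipPeak | GenomicInterval,
    transcripts: list[TranscriptModel],
    ss_window: int = 50,
    proximal_window: int = 500,
) -> str:
    """Assign exactly one region label with priority
    5'SS > 3'SS > CDS > 5'UTR > 3'UTR > proximal_intron > distal_intron >
    noncoding_exon > intergenic.

    Splice-site windows span ``ss_window`` nt on each side of a donor or
    acceptor; sidedness (donor vs acceptor) follows transcript strand.
    """
    iv = peak.interval if isinstance(peak, ClipPeak) else peak
    hits = [t for t in transcripts if t.contig == iv.contig and t.span.overlaps(iv)]
    if not hits:
        return "intergenic"
    tx = _canonical_transcript(hits)
    contig = tx.contig

    def window(center: int) -> GenomicInterval:
        return GenomicInterval(contig, max(0, center - ss_window), center + ss_window)

    donors, acceptors = [], []
    for intron in tx.introns:
        if tx.strand == "+":
            donors.append(intron.start)  # exon|intron boundary
            acceptors.append(intron.end)  # intron|exon boundary
        else:
            donors.append(intron.end)
            acceptors.append(intron.start)
    if any(iv.overlaps(window(d)) for d in donors):
        return "5'SS"
    if any(iv.overlaps(window(a)) for a in acceptors):
        return "3'SS"

    exonic = any(iv.overlaps(e) for e in tx.exons)
    if exonic:
        if tx.cds is None:
            return "noncoding_exon"
        cs, ce = tx.cds
        if iv.start < ce and cs < iv.end:
            return "CDS"
        upstream_of_cds = iv.end <= cs
        five_prime = upstream_of_cds if tx.strand == "+" else not upstream_of_cds
        return "5'UTR" if five_prime else "3'UTR"

    for intron in tx.introns:
        if iv.overlaps(intron):
            near = min(
                abs(iv.start - intron.start),
                abs(intron.end - iv.end),
                abs(iv.start - intron.end),
                abs(intron.start - iv.end),
            )
            if near <= proximal_window:
                return "proximal_intron"
            return "distal_intron"
    return "distal_intron"  # inside span but between annotated features


def annotate_peaks(
    peaks: list[ClipPeak],
    transcripts: list[TranscriptModel],
    ss_window: int = 50,
    proximal_window: int = 500,
) -> list[ClipPeak]:
    by_contig: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_contig.setdefault(t.contig, []).append(t)
    out = []
    for pk in peaks:
        label = annotate_peak(
            pk, by_contig.get(pk.interval.contig, []), ss_window, proximal_window
        )
        out.append(replace(pk, region_label=label))
    return out


# ---------------------------------------------------------------------------
# hexamer motif enrichment

K = 6
_N_KMERS = 4**K


def count_hexamers(sequences) -> Counter:
    """Overlapping 6-mer counts over {A,C,G,T}; windows containing other
    letters are skipped."""
    counts: Counter = Counter()
    valid = set("ACGT")
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - K + 1):
            kmer = s[i : i + K]
            if set(kmer) <= valid:
                counts[kmer] += 1
    return counts


def hexamer_enrichment(fg_sequences, bg_sequences) -> list[MotifResult]:
    """Rank all observed hexamers by smoothed log2 enrichment of foreground
    over background frequency; z is a normal approximation to the binomial
    count of each hexamer among foreground windows at the background rate."""
    fg = count_hexamers(fg_sequences)
    if not fg:
        raise ValidationError("foreground contains no scoreable hexamer windows")
    bg = count_hexamers(bg_sequences)
    fg_total = sum(fg.values())
    bg_total = sum(bg.values())
    results = []
    for kmer in sorted(set(fg) | set(bg)):
        fg_c, bg_c = fg.get(kmer, 0), bg.get(kmer, 0)
        fg_rate = (fg_c + 1) / (fg_total + _N_KMERS)
        bg_rate = (bg_c + 1) / (bg_total + _N_KMERS)
        log2_enr = float(np.log2(fg_rate / bg_rate))
        mu = fg_total * bg_rate
        sd = np.sqrt(fg_total * bg_rate * (1 - bg_rate))
        z = float((fg_c - mu) / sd) if sd > 0 else 0.0
        results.append(MotifResult(kmer, fg_c, bg_c, log2_enr, z))
    results.sort(key=lambda r: (-r.log2_enrichment, r.hexamer))
    return results


# ---------------------------------------------------------------------------
# tabular glue


def peaks_from_table(df: pd.DataFrame, replicate: int) -> list[ClipPeak]:
    """Build one replicate's peak list from the peak-table dialect
    (contig, start, end, strand, rep{i}_ip, rep{i}_input, rep{i}_ip_total,
    rep{i}_input_total)."""
    need = {
        "contig",
        "start",
        "end",
        "strand",
        f"rep{replicate}_ip",
        f"rep{replicate}_input",
        f"rep{replicate}_ip_total",
        f"rep{replicate}_input_total",
    }
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"peak table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ClipPeak(
                interval=GenomicInterval(r.contig, int(r.start), int(r.end), r.strand),
                ip_count=int(getattr(r, f"rep{replicate}_ip")),
                input_count=int(getattr(r, f"rep{replicate}_input")),
                ip_total=int(getattr(r, f"rep{replicate}_ip_total")),
                input_total=int(getattr(r, f"rep{replicate}_input_total")),
            )
        )
    return out


def peaks_to_table(peaks: list[ClipPeak]) -> pd.DataFrame:
    rows = []
    for pk in peaks:
        rows.append(
            {
                "contig": pk.interval.contig,
                "start": pk.interval.start,
                "end": pk.interval.end,
                "strand": pk.interval.strand,
                "ip_count": pk.ip_count,
                "input_count": pk.input_count,
                "log2fc": pk.log2fc,
                "p": pk.p,
                "fdr": pk.fdr,
                "region_label": pk.region_label,
            }
        )
    return pd.DataFrame(rows)
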