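"""Synthetic multi-omics dataset generator with planted poison exons.

Each simulated gene lives on its own contig and carries one multi-exon
protein-coding transcript whose stop codon sits in the last exon (so the
reference isoform escapes NMD).  Planted target genes receive

* an alternative-splicing event (CE / RI / A3SS / A5SS / MXE) whose
  knockdown-promoted isoform contains an in-frame stop >= 50 nt upstream of
  the final exon-exon junction (a poison exon / poison intron),
* a CLIP peak inside the event footprint with the configured IP/input
  pulldown fold and a planted hexamer motif, and
* a protein fold change below 0.9 with probability ``pi_down``.

PSI values in the emitted rMATS-dialect tables are computed from simulated
inclusion/skipping junction counts (beta-binomial per sample); event p-values
come from a two-proportion exact test on pooled counts and FDR from
Benjamini-Hochberg within each event type, emulating the output dialect
without claiming the rMATS likelihood model.

The IP libraries model immunoprecipitation: background coverage is depleted
``ip_background_depletion``-fold relative to the size-matched input, so the
input-normalized enrichment at a planted site exceeds the raw pulldown fold
while unbound decoy windows score near (or below) zero.

All randomness flows from a single seed; identical config + seed reproduces
the output files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import reverse_complement

from .clip import bh_adjust
from .errors import GenerationError, ValidationError
from .intervals import GenomicInterval
from .io import write_fasta, write_gtf, write_tsv
from .transcripts import (
    DomainAnnotation,
    TranscriptModel,
    spliced_sequence,
    translate_orf,
)

NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

UTR5_LEN = 60
UTR3_LEN = 150
PAD = 200
MIN_EXON = 60
PEAK_WIDTH = 50
CASSETTE_LEN = 108  # divisible by 3; carries one planted in-frame stop
MXE_SECOND_LEN = 102  # divisible by 3; A-free, hence stop-free in every frame

EVENT_TYPE_WEIGHTS = {"CE": 0.5, "RI": 0.2, "A3SS": 0.1, "A5SS": 0.1, "MXE": 0.1}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 8)
    fraction_planted_targets: float = 0.3
    fraction_bound_only: float = 0.1
    fraction_spliced_only: float = 0.1
    delta_psi: float = 0.3
    clip_fold: float = 8.0
    motif: str = "GGGGGG"
    pi_down: float = 0.9
    n_rnaseq_replicates: int = 2
    psi_overdispersion: float = 0.01
    psi_coverage: int = 100
    input_peak_reads: float = 50.0
    ip_background_depletion: float = 10.0
    protein_replicates: int = 4
    protein_log2_sd: float = 0.1
    protein_down_fc: float = 0.7
    min_aa: int = 150
    max_aa: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        for name in ("fraction_planted_targets", "fraction_bound_only",
                     "fraction_spliced_only", "pi_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        total = (self.fraction_planted_targets + self.fraction_bound_only
                 + self.fraction_spliced_only)
        if total > 1:
            raise ValidationError(f"planted fractions sum to {total} > 1")
        if not 0 <= self.delta_psi <= 0.5:
            raise ValidationError("delta_psi must lie in [0, 0.5]")
        if self.clip_fold < 1:
            raise ValidationError("clip_fold must be >= 1")
        if len(self.motif) != 6 or set(self.motif.upper()) - set("ACGT"):
            raise ValidationError("motif must be a hexamer over ACGT")
        lo, hi = self.exons_per_gene
        if not 4 <= lo <= hi:
            raise ValidationError("exons_per_gene must satisfy 4 <= lo <= hi")
        if not 0 < self.psi_overdispersion < 1:
            raise ValidationError("psi_overdispersion must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    """In-memory handles plus on-disk paths for one generated dataset."""

    config: SimulationConfig
    out_dir: Path
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    domains: list[DomainAnnotation]
    peak_table: pd.DataFrame
    event_tables: dict[str, pd.DataFrame]
    proteome: pd.DataFrame
    ground_truth: pd.DataFrame

    @property
    def paths(self) -> dict[str, Path]:
        p = {
            "genome": self.out_dir / "genome.fa",
            "gtf": self.out_dir / "annotation.gtf",
            "domains": self.out_dir / "domains.tsv",
            "peaks": self.out_dir / "clip_peaks.tsv",
            "proteome": self.out_dir / "proteome.tsv",
            "ground_truth": self.out_dir / "ground_truth.tsv",
        }
        for t in self.event_tables:
            p[f"events_{t}"] = self.out_dir / f"{t}.MATS.tsv"
        return p


# ---------------------------------------------------------------------------
# sequence helpers


def _rand_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _rand_nostop_segment(rng, n: int) -> str:
    # A-free sequence: cannot contain TAA/TAG/TGA or ATG in any frame
    return _rand_seq(rng, n, "CGT")


def _coding_segment_with_stop(rng, length: int, frame_offset: int) -> str:
    """A-free filler with one TAA planted at the first in-frame codon start
    at or after offset 30."""
    seg = list(_rand_nostop_segment(rng, length))
    o = frame_offset % 3
    pos = o + 3 * ((30 - o + 2) // 3)
    if pos + 3 > length:
        raise GenerationError(f"segment of {length} nt too short for planted stop")
    seg[pos : pos + 3] = "TAA"
    return "".join(seg)


def _mirror(start: int, end: int, contig_len: int) -> tuple[int, int]:
    return contig_len - end, contig_len - start


# ---------------------------------------------------------------------------
# per-gene construction


def _split_lengths(rng, total: int, parts: int, minimum: int) -> list[int]:
    extra = total - minimum * parts
    if extra < 0:
        raise GenerationError(f"cannot split {total} nt into {parts} exons")
    alloc = rng.multinomial(extra, np.full(parts, 1.0 / parts))
    return [minimum + int(a) for a in alloc]


def _build_gene(rng, idx: int, cfg: SimulationConfig, role: str, event_type: str | None):
    """Build one gene's contig, transcript, event/peak plan (sense layout,
    then optionally mirrored to the minus strand)."""
    gene_id = f"G{idx:04d}"
    contig = f"chr_{gene_id}"
    strand = "+" if rng.random() < 0.5 else "-"

    n_aa = int(rng.integers(cfg.min_aa, cfg.max_aa + 1))
    cds = "ATG" + "".join(rng.choice(NON_STOP_CODONS, size=n_aa - 1)) + "TAA"
    utr5 = _rand_seq(rng, UTR5_LEN, "CGT")  # A-free: no spurious upstream ATG
    utr3 = _rand_seq(rng, UTR3_LEN)
    mrna = utr5 + cds + utr3

    lo, hi = cfg.exons_per_gene
    n_ex = int(rng.integers(lo, hi + 1))
    tail_cds = int(rng.integers(30, 91))
    last_len = UTR3_LEN + 3 + tail_cds
    prefix = len(mrna) - last_len
    n_ex = min(n_ex, 1 + prefix // MIN_EXON)
    if n_ex < 4:
        raise GenerationError(f"{gene_id}: cannot fit 4 exons; increase min_aa")
    exon_lens = _split_lengths(rng, prefix, n_ex - 1, MIN_EXON) + [last_len]

    planted_intron = None
    if event_type is not None:
        planted_intron = int(rng.integers(1, n_ex - 2))  # intron i: exon i|i+1
    intron_lens = []
    for i in range(n_ex - 1):
        if i == planted_intron:
            intron_lens.append(800 + int(rng.integers(0, 101)))
        else:
            intron_lens.append(int(rng.integers(300, 601)))
    introns = ["GT" + _rand_seq(rng, L - 4) + "AG" for L in intron_lens]

    # --- genomic layout (sense space) ---
    pieces = [_rand_seq(rng, PAD)]
    exon_coords = []
    cursor = PAD
    mrna_cursor = 0
    intron_starts = []
    for i, elen in enumerate(exon_lens):
        exon_coords.append((cursor, cursor + elen))
        pieces.append(mrna[mrna_cursor : mrna_cursor + elen])
        mrna_cursor += elen
        cursor += elen
        if i < n_ex - 1:
            intron_starts.append(cursor)
            pieces.append(introns[i])
            cursor += intron_lens[i]
    pieces.append(_rand_seq(rng, PAD))
    layout = list("".join(pieces))
    contig_len = len(layout)

    cum = np.cumsum(exon_lens)
    # genomic (sense) position of an mRNA offset
    def sense_pos(off: int) -> int:
        for i, (s, e) in enumerate(exon_coords):
            start_off = cum[i] - exon_lens[i]
            if start_off <= off < cum[i]:
                return s + (off - start_off)
        raise GenerationError(f"{gene_id}: mRNA offset {off} not exonic")

    start_codon_pos = sense_pos(UTR5_LEN)
    stop_end_off = UTR5_LEN + len(cds)  # one past the stop codon
    cds_span = (start_codon_pos, sense_pos(stop_end_off - 1) + 1)

    # --- plant the alternative-splicing segment ---
    event_coords: dict[str, int] = {}
    extra_host_exon = None  # MXE second exon is part of the annotation
    peak_sense = None
    if event_type is not None:
        i = planted_intron
        istart = intron_starts[i]
        ilen = intron_lens[i]
        c = int(cum[i]) - UTR5_LEN  # coding offset at the intron's 5' junction
        o = (-c) % 3
        up, dn = exon_coords[i], exon_coords[i + 1]
        if event_type == "CE":
            seg = _coding_segment_with_stop(rng, CASSETTE_LEN, o)
            cs = istart + 100
            layout[cs : cs + CASSETTE_LEN] = seg
            event_coords = {
                "exonStart_0base": cs, "exonEnd": cs + CASSETTE_LEN,
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": dn[0], "downstreamEE": dn[1],
            }
            peak_sense = (istart + 20, istart + 20 + PEAK_WIDTH)
        elif event_type == "RI":
            # plant an in-frame stop inside the intron (past the GT donor)
            stop_at = istart + o + 3 * ((30 - o + 2) // 3)
            layout[stop_at : stop_at + 3] = "TAA"
            event_coords = {
                "riExonStart_0base": up[0], "riExonEnd": dn[1],
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": dn[0], "downstreamEE": dn[1],
            }
            peak_sense = (istart + 80, istart + 80 + PEAK_WIDTH)
        elif event_type == "A5SS":
            ext = 60
            seg = _coding_segment_with_stop(rng, ext, o)
            layout[istart : istart + ext] = seg
            event_coords = {
                "longExonStart_0base": up[0], "longExonEnd": up[1] + ext,
                "shortES": up[0], "shortEE": up[1],
                "flankingES": dn[0], "flankingEE": dn[1],
            }
            peak_sense = (istart + ext + 10, istart + ext + 10 + PEAK_WIDTH)
        elif event_type == "A3SS":
            ext = 60
            seg = _coding_segment_with_stop(rng, ext, o)
            layout[istart + ilen - ext : istart + ilen] = seg
            event_coords = {
                "longExonStart_0base": dn[0] - ext, "longExonEnd": dn[1],
                "shortES": dn[0], "shortEE": dn[1],
                "flankingES": up[0], "flankingEE": up[1],
            }
            peak_sense = (istart + 10, istart + 10 + PEAK_WIDTH)
        elif event_type == "MXE":
            segA = _coding_segment_with_stop(rng, CASSETTE_LEN, o)
            segB = _rand_nostop_segment(rng, MXE_SECOND_LEN)
            a_s = istart + 100
            b_s = istart + 400
            layout[a_s : a_s + CASSETTE_LEN] = segA
            layout[b_s : b_s + MXE_SECOND_LEN] = segB
            extra_host_exon = (b_s, b_s + MXE_SECOND_LEN)
            event_coords = {
                "1stExonStart_0base": a_s, "1stExonEnd": a_s + CASSETTE_LEN,
                "2ndExonStart_0base": b_s, "2ndExonEnd": b_s + MXE_SECOND_LEN,
                "upstreamES": up[0], "upstreamEE": up[1],
                "downstreamES": dn[0], "downstreamEE": dn[1],
            }
            peak_sense = (istart + 20, istart + 20 + PEAK_WIDTH)
        else:
            raise GenerationError(f"unknown planted event type {event_type}")
    else:
        # decoy window for unbound genes / peak site for bound-only genes
        peak_sense = (intron_starts[0] + 50, intron_starts[0] + 50 + PEAK_WIDTH)

    bound = role in ("target", "bound_only")
    if bound:
        ps, _pe = peak_sense
        m = cfg.motif.upper()
        for off in (5, 15, 25):
            layout[ps + off : ps + off + 6] = m

    seq = "".join(layout)
    host_exons = list(exon_coords)
    if extra_host_exon is not None:
        host_exons.append(extra_host_exon)
        host_exons.sort()

    # --- mirror to the minus strand if drawn ---
    if strand == "-":
        seq = reverse_complement(seq)
        host_exons = sorted(_mirror(s, e, contig_len) for s, e in host_exons)
        cds_span = _mirror(*cds_span, contig_len)
        if peak_sense is not None:
            peak_sense = _mirror(*peak_sense, contig_len)
        if event_coords:
            event_coords = _mirror_event(event_type, event_coords, contig_len)

    tx = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        contig=contig,
        strand=strand,
        exons=tuple(
            GenomicInterval(contig, s, e, strand) for s, e in host_exons
        ),
        cds=cds_span,
    )
    return {
        "gene_id": gene_id,
        "contig": contig,
        "strand": strand,
        "seq": seq,
        "transcript": tx,
        "event_type": event_type,
        "event_coords": event_coords,
        "peak": peak_sense,
        "role": role,
        "mirrored": strand == "-",
    }


def _mirror_event(event_type: str, coords: dict[str, int], L: int) -> dict[str, int]:
    """Mirror event coordinates and restore the dialect's genomic-order
    labels (upstream = lower coordinate, 1st exon = lower coordinate)."""
    pairs: dict[str, tuple[int, int]] = {}
    if event_type == "CE":
        keys = [("exonStart_0base", "exonEnd"), ("upstreamES", "upstreamEE"),
                ("downstreamES", "downstreamEE")]
    elif event_type == "RI":
        keys = [("riExonStart_0base", "riExonEnd"), ("upstreamES", "upstreamEE"),
                ("downstreamES", "downstreamEE")]
    elif event_type in ("A3SS", "A5SS"):
        keys = [("longExonStart_0base", "longExonEnd"), ("shortES", "shortEE"),
                ("flankingES", "flankingEE")]
    else:
        keys = [("1stExonStart_0base", "1stExonEnd"),
                ("2ndExonStart_0base", "2ndExonEnd"),
                ("upstreamES", "upstreamEE"), ("downstreamES", "downstreamEE")]
    for ks, ke in keys:
        pairs[(ks, ke)] = _mirror(coords[ks], coords[ke], L)
    out = {}
    for (ks, ke), (s, e) in pairs.items():
        out[ks], out[ke] = s, e
    # restore genomic-order semantics
    if event_type in ("CE", "RI", "MXE"):
        u = (out["upstreamES"], out["upstreamEE"])
        d = (out["downstreamES"], out["downstreamEE"])
        if u[0] > d[0]:
            out["upstreamES"], out["upstreamEE"] = d
            out["downstreamES"], out["downstreamEE"] = u
    if event_type == "MXE":
        a = (out["1stExonStart_0base"], out["1stExonEnd"])
        b = (out["2ndExonStart_0base"], out["2ndExonEnd"])
        if a[0] > b[0]:
            out["1stExonStart_0base"], out["1stExonEnd"] = b
            out["2ndExonStart_0base"], out["2ndExonEnd"] = a
            out["_swapped_mxe"] = 1  # PSI now tracks the clean (first) exon
    return out


# ---------------------------------------------------------------------------
# count simulation


def _beta_binomial_counts(rng, mean: float, coverage: int, rho: float, n: int):
    mean = min(max(mean, 0.02), 0.98)
    nu = (1 - rho) / rho
    a, b = mean * nu, (1 - mean) * nu
    ps = rng.beta(a, b, size=n)
    inc = rng.binomial(coverage, ps)
    return inc, coverage - inc


def _event_pvalue(inc_kd, skip_kd, inc_ctl, skip_ctl) -> float:
    table = [[int(np.sum(inc_kd)), int(np.sum(skip_kd))],
             [int(np.sum(inc_ctl)), int(np.sum(skip_ctl))]]
    _, p = stats.fisher_exact(table)
    return float(p)


# ---------------------------------------------------------------------------
# main entry points


def generate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate and write a complete synthetic dataset with planted effects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_genes
    n_target = round(cfg.fraction_planted_targets * n)
    n_bound = round(cfg.fraction_bound_only * n)
    n_spliced = round(cfg.fraction_spliced_only * n)
    roles = (["target"] * n_target + ["bound_only"] * n_bound
             + ["spliced_only"] * n_spliced)
    roles += ["null"] * (n - len(roles))

    type_names = list(EVENT_TYPE_WEIGHTS)
    type_p = np.array([EVENT_TYPE_WEIGHTS[t] for t in type_names])

    genes = []
    for idx, role in enumerate(roles):
        etype = None
        if role in ("target", "spliced_only"):
            etype = str(rng.choice(type_names, p=type_p))
        genes.append(_build_gene(rng, idx, cfg, role, etype))

    genome = {g["contig"]: g["seq"] for g in genes}
    transcripts = [g["transcript"] for g in genes]

    # domains on each host protein (consistent with the annotation by
    # construction: translated from the emitted genome + GTF)
    domains: list[DomainAnnotation] = []
    for g in genes:
        tx = g["transcript"]
        mrna = spliced_sequence(tx, genome)
        off = tx.genomic_to_mrna(tx.annotated_start_genomic())
        protein = translate_orf(mrna, off)
        P = len(protein)
        domains.append(DomainAnnotation(g["gene_id"], f"DOM_{g['gene_id']}_N", 10, min(50, P)))
        d2s = max(1, int(P * 0.6))
        domains.append(
            DomainAnnotation(g["gene_id"], f"DOM_{g['gene_id']}_C", d2s, min(d2s + 30, P))
        )

    # --- CLIP peak table -------------------------------------------------
    genome_len = sum(len(s) for s in genome.values())
    mu_in = cfg.input_peak_reads
    input_total = int(round(genome_len * mu_in / PEAK_WIDTH))
    n_bound_sites = sum(1 for g in genes if g["role"] in ("target", "bound_only"))
    ip_total = int(round(genome_len * mu_in / (PEAK_WIDTH * cfg.ip_background_depletion)
                         + n_bound_sites * mu_in * cfg.clip_fold))
    peak_rows = []
    for g in genes:
        s, e = g["peak"]
        is_bound = g["role"] in ("target", "bound_only")
        mu_ip = mu_in * cfg.clip_fold if is_bound else mu_in / cfg.ip_background_depletion
        row = {"contig": g["contig"], "start": s, "end": e, "strand": g["strand"]}
        for rep in (1, 2):
            row[f"rep{rep}_ip"] = int(rng.poisson(mu_ip))
            row[f"rep{rep}_input"] = int(rng.poisson(mu_in))
            row[f"rep{rep}_ip_total"] = ip_total
            row[f"rep{rep}_input_total"] = input_total
        peak_rows.append(row)
    peak_table = pd.DataFrame(peak_rows)

    # --- splicing event tables -------------------------------------------
    per_type_rows: dict[str, list[dict]] = {t: [] for t in type_names}
    truth_delta: dict[str, float] = {}
    for g in genes:
        role = g["role"]
        if g["event_type"] is not None:
            etype, coords = g["event_type"], dict(g["event_coords"])
            swapped = bool(coords.pop("_swapped_mxe", 0))
            p0 = float(rng.uniform(0.15, 0.45))
            p_kd = min(p0 + cfg.delta_psi, 0.97)
            if swapped:  # PSI tracks the clean first exon; poison exon is 2nd
                p0, p_kd = 1 - p0, 1 - p_kd
        else:
            # null event: an existing internal exon as a no-change cassette
            tx = g["transcript"]
            k = int(rng.integers(1, len(tx.exons) - 1))
            ex = tx.exons
            etype = "CE"
            coords = {
                "exonStart_0base": ex[k].start, "exonEnd": ex[k].end,
                "upstreamES": ex[k - 1].start, "upstreamEE": ex[k - 1].end,
                "downstreamES": ex[k + 1].start, "downstreamEE": ex[k + 1].end,
            }
            p0 = float(rng.uniform(0.5, 0.9))
            p_kd = p0
        nrep = cfg.n_rnaseq_replicates
        inc_kd, skip_kd = _beta_binomial_counts(
            rng, p_kd, cfg.psi_coverage, cfg.psi_overdispersion, nrep)
        inc_ctl, skip_ctl = _beta_binomial_counts(
            rng, p0, cfg.psi_coverage, cfg.psi_overdispersion, nrep)
        psi_kd = inc_kd / (inc_kd + skip_kd)
        psi_ctl = inc_ctl / (inc_ctl + skip_ctl)
        row = {
            "ID": len(per_type_rows[etype]),
            "GeneID": g["gene_id"],
            "geneSymbol": g["gene_id"],
            "chr": g["contig"],
            "strand": g["strand"],
            **coords,
            "IJC_SAMPLE_1": ",".join(map(str, inc_kd)),
            "SJC_SAMPLE_1": ",".join(map(str, skip_kd)),
            "IJC_SAMPLE_2": ",".join(map(str, inc_ctl)),
            "SJC_SAMPLE_2": ",".join(map(str, skip_ctl)),
            "IncFormLen": 100,
            "SkipFormLen": 100,
            "PValue": _event_pvalue(inc_kd, skip_kd, inc_ctl, skip_ctl),
            "IncLevel1": ",".join(f"{v:.6f}" for v in psi_kd),
            "IncLevel2": ",".join(f"{v:.6f}" for v in psi_ctl),
            "IncLevelDifference": round(float(psi_kd.mean() - psi_ctl.mean()), 6),
        }
        per_type_rows[etype].append(row)
        truth_delta[g["gene_id"]] = row["IncLevelDifference"]

    from .splicing import DIALECT_COORDS

    event_tables = {}
    for t in type_names:
        df = pd.DataFrame(per_type_rows[t])
        if not df.empty:
            df["FDR"] = bh_adjust(df["PValue"].to_numpy())
        else:
            df = pd.DataFrame(
                columns=["ID", "GeneID", "geneSymbol", "chr", "strand",
                         *DIALECT_COORDS[t], "PValue", "FDR",
                         "IncLevelDifference"]
            )
        event_tables[t] = df

    # --- proteome --------------------------------------------------------
    prot_rows = []
    for g in genes:
        is_ptc = g["role"] in ("target", "spliced_only")
        coupled = bool(is_ptc and rng.random() < cfg.pi_down)
        true_fc = cfg.protein_down_fc if coupled else 1.0
        reps = rng.normal(np.log2(true_fc), cfg.protein_log2_sd, cfg.protein_replicates)
        m = reps.mean()
        se = reps.std(ddof=1) / np.sqrt(cfg.protein_replicates)
        tstat = m / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(tstat), df=cfg.protein_replicates - 1)
        prot_rows.append({
            "gene_id": g["gene_id"],
            "mean_fc": float(2 ** m),
            "p": float(p),
            "_down": coupled,
        })
    prot = pd.DataFrame(prot_rows)
    prot["fdr"] = bh_adjust(prot["p"].to_numpy())
    proteome = prot[["gene_id", "mean_fc", "p", "fdr"]].copy()

    # --- ground truth ----------------------------------------------------
    gt_rows = []
    for g, pr in zip(genes, prot_rows):
        role = g["role"]
        gt_rows.append({
            "gene_id": g["gene_id"],
            "is_bound": role in ("target", "bound_only"),
            "is_mis_spliced": role in ("target", "spliced_only"),
            "event_type": g["event_type"] or "",
            "introduces_PTC": role in ("target", "spliced_only"),
            "protein_down": pr["_down"],
            "true_delta_psi": truth_delta[g["gene_id"]],
        })
    ground_truth = pd.DataFrame(gt_rows)

    ds = SimulatedDataset(
        config=cfg, out_dir=out_dir, genome=genome, transcripts=transcripts,
        domains=domains, peak_table=peak_table, event_tables=event_tables,
        proteome=proteome, ground_truth=ground_truth,
    )
    _write_dataset(ds)
    return ds


def _write_dataset(ds: SimulatedDataset) -> None:
    paths = ds.paths
    write_fasta(ds.genome, paths["genome"])
    write_gtf(ds.transcripts, paths["gtf"])
    dom = pd.DataFrame(
        [{"gene_id": d.gene_id, "domain_name": d.domain_name,
          "aa_start": d.aa_start, "aa_end": d.aa_end} for d in ds.domains]
    )
    write_tsv(dom, paths["domains"])
    write_tsv(ds.peak_table, paths["peaks"])
    for t, df in ds.event_tables.items():
        write_tsv(df, paths[f"events_{t}"])
    write_tsv(ds.proteome, paths["proteome"])
    write_tsv(ds.ground_truth, paths["ground_truth"])
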