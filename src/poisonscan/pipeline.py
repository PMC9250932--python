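"""End-to-end orchestration: CLIP -> splicing -> overlap -> consequence ->
proteome, producing the intersection funnel (significant -> bound ->
NMD-sensitive -> protein-down) and machine-readable summaries.

All thresholds default to the published cutoffs (peak FDR < 0.05 and
log2FC > 3; event FDR < 0.1 and |dPSI| > 0.05; protein FDR < 0.1 and
FC < 0.9 / > 1.1; 50-nt NMD rule), so a bare run reproduces the analysis
shape of the study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import reverse_complement

from . import clip as clipmod
from . import consequence as consmod
from . import proteome as protmod
from . import splicing as splmod
from .errors import ConfigurationError
from .io import read_domain_table, read_fasta, read_gtf, read_tsv, write_tsv
from .transcripts import TranscriptModel

log = logging.getLogger("poisonscan")


@dataclass
class PipelineConfig:
    genome: str = ""
    gtf: str = ""
    domains: str = ""
    peaks: str = ""
    events_dir: str = ""
    proteome: str = ""
    out_dir: str = "poisonscan_out"
    peak_fdr_max: float = 0.05
    peak_log2fc_min: float = 3.0
    ss_window: int = 50
    proximal_window: int = 500
    event_fdr_max: float = 0.1
    dpsi_min: float = 0.05
    protein_fdr_max: float = 0.1
    fc_down: float = 0.9
    fc_up: float = 1.1
    nmd_rule_nt: int = 50
    min_orf_codons: int = 30
    n_bootstrap_draws: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------


def _host_transcript(gene_id: str, transcripts: list[TranscriptModel]):
    """Canonical host per gene: longest annotated CDS, then transcript_id."""
    cands = [t for t in transcripts if t.gene_id == gene_id and t.cds is not None]
    if not cands:
        return None
    return max(cands, key=lambda t: (t.cds_length, t.transcript_id))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the funnel summary (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(cfg.genome)
    transcripts = read_gtf(cfg.gtf)
    domains = read_domain_table(cfg.domains)

    # -- stage 1: CLIP ----------------------------------------------------
    peak_df = read_tsv(cfg.peaks)
    rep1 = clipmod.score_peaks(clipmod.peaks_from_table(peak_df, 1))
    rep2 = clipmod.score_peaks(clipmod.peaks_from_table(peak_df, 2))
    peaks = clipmod.reproducible_peaks(
        rep1, rep2, fdr_max=cfg.peak_fdr_max, log2fc_min=cfg.peak_log2fc_min
    )
    peaks = clipmod.annotate_peaks(
        peaks, transcripts, ss_window=cfg.ss_window, proximal_window=cfg.proximal_window
    )
    write_tsv(clipmod.peaks_to_table(peaks), out / "reproducible_peaks.tsv")
    log.info("clip: %d candidate sites, %d reproducible peaks", len(rep1), len(peaks))

    # hexamer enrichment: strand-oriented peak sequences vs same-size
    # windows shifted 1 kb along the contig
    def oriented(contig: str, start: int, end: int, strand: str) -> str:
        seq = genome[contig][start:end]
        return str(reverse_complement(seq)) if strand == "-" else seq

    fg, bg = [], []
    for p in peaks:
        iv = p.interval
        fg.append(oriented(iv.contig, iv.start, iv.end, iv.strand))
        s = (iv.start + 1000) % max(1, len(genome[iv.contig]) - len(iv))
        bg.append(oriented(iv.contig, s, s + len(iv), iv.strand))
    motifs = clipmod.hexamer_enrichment(fg, bg) if fg else []
    motif_df = pd.DataFrame(
        [
            {"hexamer": m.hexamer, "fg_count": m.fg_count, "bg_count": m.bg_count,
             "log2_enrichment": m.log2_enrichment, "z": m.z}
            for m in motifs
        ]
    )
    write_tsv(motif_df, out / "hexamer_enrichment.tsv")

    # -- stage 2: splicing ------------------------------------------------
    events = []
    for t in splmod.EVENT_TYPES:
        path = Path(cfg.events_dir) / f"{t}.MATS.tsv"
        if path.exists():
            events.extend(splmod.read_event_table(path, t))
    events = splmod.collapse_duplicates(events)
    significant = splmod.filter_events(
        events, fdr_max=cfg.event_fdr_max, dpsi_min=cfg.dpsi_min
    )
    significant = splmod.with_directions(significant)
    significant = splmod.overlap_events_with_peaks(significant, peaks)
    write_tsv(splmod.events_to_table(significant), out / "significant_events.tsv")
    tally = splmod.tally_types(significant)
    tally.to_csv(out / "event_type_tally.tsv", sep="\t")
    bound_events = [e for e in significant if e.bound]
    log.info("splice: %d events, %d significant, %d bound",
             len(events), len(significant), len(bound_events))

    # -- stage 3: consequences (all significant events; bound subset noted)
    calls, skipped = [], 0
    for ev in significant:
        host = _host_transcript(ev.gene_id, transcripts)
        if host is None:
            skipped += 1
            continue
        try:
            pair = consmod.build_isoform_pair(ev, host)
        except consmod.IncompatibleHostError:
            skipped += 1
            continue
        calls.append(
            consmod.classify_consequence(
                pair, genome, domains,
                nmd_rule_nt=cfg.nmd_rule_nt, min_orf_codons=cfg.min_orf_codons,
            )
        )
    call_df = pd.DataFrame(
        [
            {"event_id": c.event_id, "gene_id": c.gene_id, "category": c.category,
             "ptc_present": c.ptc_present,
             "ptc_to_last_junction_nt": c.ptc_to_last_junction_nt,
             "lost_domains": ";".join(c.lost_domains)}
            for c in calls
        ]
    )
    write_tsv(call_df, out / "consequence_calls.tsv")
    summary = consmod.summarize_consequences(calls)
    bound_ids = {e.event_id for e in bound_events}
    nmd_calls = [c for c in calls if c.category == "NMD"]
    nmd_genes = sorted({c.gene_id for c in nmd_calls})
    bound_nmd_genes = sorted(
        {c.gene_id for c in nmd_calls if c.event_id in bound_ids}
    )
    log.info("consequence: %d calls (%d skipped), %d NMD genes", len(calls),
             skipped, len(nmd_genes))

    # -- stage 4: proteome ------------------------------------------------
    records = protmod.filter_protein_changes(
        protmod.read_proteome_table(cfg.proteome),
        fdr_max=cfg.protein_fdr_max, fc_down=cfg.fc_down, fc_up=cfg.fc_up,
    )
    measured, n_meas, k_down, unmeasured = protmod.map_and_count(nmd_genes, records)
    enrichment = None
    if n_meas > 0:
        flags = [r.change_flag == protmod.DOWN for r in records]
        enrichment = protmod.bootstrap_null(
            flags, n_meas, k_down, n_draws=cfg.n_bootstrap_draws, seed=cfg.seed
        )
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enrichment.to_dict(), fh, indent=2)

    funnel = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_candidate_sites": len(rep1),
        "n_reproducible_peaks": len(peaks),
        "n_events": len(events),
        "n_significant_events": len(significant),
        "n_bound_events": len(bound_events),
        "n_classified": len(calls),
        "n_skipped_incompatible": skipped,
        "consequence_summary": summary,
        "n_nmd_genes": len(nmd_genes),
        "nmd_genes": nmd_genes,
        "n_bound_nmd_genes": len(bound_nmd_genes),
        "bound_nmd_genes": bound_nmd_genes,
        "n_nmd_measured": n_meas,
        "n_nmd_unmeasured": len(unmeasured),
        "n_nmd_protein_down": k_down,
        "enrichment": enrichment.to_dict() if enrichment else None,
        "top_hexamers": [m.hexamer for m in motifs[:5]],
    }
    with open(out / "funnel_summary.json", "w") as fh:
        json.dump(funnel, fh, indent=2, sort_keys=True)
    return funnel
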