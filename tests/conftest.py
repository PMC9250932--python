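"""Shared fixtures: a small synthetic dataset, a pipeline run over it, and a
hand-built toy gene for isoform-reconstruction tests."""

from __future__ import annotations

import pytest

from poisonscan.intervals import GenomicInterval
from poisonscan.pipeline import PipelineConfig, run_pipeline
from poisonscan.simulate import SimulationConfig, generate_dataset
from poisonscan.transcripts import TranscriptModel


def run_on_dataset(ds, out_dir, seed=0, **overrides):
    p = ds.paths
    cfg = PipelineConfig(
        genome=str(p["genome"]),
        gtf=str(p["gtf"]),
        domains=str(p["domains"]),
        peaks=str(p["peaks"]),
        events_dir=str(ds.out_dir),
        proteome=str(p["proteome"]),
        out_dir=str(out_dir),
        seed=seed,
        **overrides,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    cfg = SimulationConfig(n_genes=30, seed=11)
    return generate_dataset(cfg, tmp_path_factory.mktemp("sim_small"))


@pytest.fixture(scope="session")
def funnel_small(sim_small, tmp_path_factory):
    return run_on_dataset(sim_small, tmp_path_factory.mktemp("out_small"), seed=11)


@pytest.fixture()
def toy_gene():
    """Three-exon plus-strand gene with a fully hand-checkable layout.

    contig: 10 nt pad | exon1 (30) | intron1 (40) | exon2 (30) | intron2 (40)
            | exon3 (60) | 10 nt pad
    exon1 carries 9 nt UTR then ATG; the stop codon TAA sits inside exon3.
    """
    pad = "C" * 10
    # mRNA layout: 9 nt UTR + ATG + 36 codons of AAA spread over the exons,
    # then TAA + 3' UTR inside exon3
    exon1 = "CCCCCCCCC" + "ATG" + "AAA" * 6  # 30 nt, CDS offset 9
    exon2 = "AAA" * 10  # 30 nt of lysine codons
    exon3 = "AAA" * 5 + "TAA" + "C" * 42  # 60 nt: 15 nt CDS + stop + UTR
    intron = "GT" + "C" * 36 + "AG"
    seq = pad + exon1 + intron + exon2 + intron + exon3 + pad
    genome = {"chrT": seq}
    e1 = (10, 40)
    e2 = (80, 110)
    e3 = (150, 210)
    tx = TranscriptModel(
        gene_id="TOY",
        transcript_id="TOY.t1",
        contig="chrT",
        strand="+",
        exons=(
            GenomicInterval("chrT", *e1, "+"),
            GenomicInterval("chrT", *e2, "+"),
            GenomicInterval("chrT", *e3, "+"),
        ),
        cds=(19, 168),  # ATG at 19, stop codon ends at 168
    )
    return genome, tx
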