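# poisonscan

Predicting the protein-level consequences of splicing-factor loss from
multi-omics evidence: CLIP binding, differential splicing, premature
termination codons (PTCs), nonsense-mediated decay (NMD), and proteome fold
changes.

## Scientific problem

Many RNA-binding splicing factors guard the transcriptome against
*poison exons* and *poison introns*: alternative regions whose inclusion
introduces an in-frame stop codon upstream of the last exon–exon junction.
By the 50-nt rule, such a premature stop marks the mRNA for nonsense-mediated
decay, so mis-splicing silently translates into protein loss. When a factor
such as RBM17 is depleted, poison inclusion rises at its direct binding
targets, and the affected genes are expected to lose protein.

Establishing that chain of causation requires integrating four assays that
live in different coordinate systems and statistical regimes:

1. **eCLIP** — where does the factor bind? Peaks are scored against a
   size-matched input (one-sided exact test on read counts, pseudocounted
   log2 fold change) and must reproduce in both replicates (FDR < 0.05 and
   log2FC > 3 in each); binding-site sequences are screened for enriched
   hexamers.
2. **RNA-seq splicing** — which events change on knockdown? rMATS-dialect
   tables for CE/RI/A3SS/A5SS/MXE events are filtered (FDR < 0.1,
   |ΔPSI| > 0.05) and split by direction: ΔPSI < 0 means the factor normally
   *supports* inclusion, ΔPSI > 0 means it *represses* it.
3. **Consequence calling** — does the knockdown-promoted isoform matter? The
   inclusion and exclusion isoforms are rebuilt on the host transcript, the
   ORF is located, and the event is classified as NMD (50-nt rule),
   processed transcript (no qualifying ORF), domain loss
   (complete/partial), frameshift without annotated-domain overlap, or none.
4. **Quantitative proteomics** — do the NMD-predicted targets actually lose
   protein? Targets are intersected with the measured proteome
   (down = mean FC < 0.9 and FDR < 0.1) and the observed down-fraction is
   compared against random same-size protein sets (bootstrap null) and the
   exact hypergeometric tail.

`poisonscan` implements this funnel end to end, together with a synthetic
data generator that plants poison events with known ground truth so the whole
pipeline can be validated for recall and precision.

## Worked example

Generate a 60-gene synthetic dataset (18 planted bound + mis-spliced + PTC
target genes, 8-fold CLIP enrichment, ΔPSI = 0.3) and run the full pipeline:

```bash
poisonscan simulate --out-dir demo --n-genes 60 --seed 4
cat > demo/config.yaml <<'YAML'
genome: demo/genome.fa
gtf: demo/annotation.gtf
domains: demo/domains.tsv
peaks: demo/clip_peaks.tsv
events_dir: demo
proteome: demo/proteome.tsv
out_dir: demo_out
seed: 4
YAML
poisonscan run --config demo/config.yaml
```

The log reports each funnel stage:

```
poisonscan clip: 60 candidate sites, 24 reproducible peaks
poisonscan splice: 60 events, 29 significant, 18 bound
poisonscan consequence: 29 calls (0 skipped), 24 NMD genes
```

and `demo_out/funnel_summary.json` contains (excerpt of the actual output):

```json
{
  "n_candidate_sites": 60,
  "n_reproducible_peaks": 24,
  "n_significant_events": 29,
  "n_bound_events": 18,
  "n_nmd_genes": 24,
  "n_bound_nmd_genes": 18,
  "n_nmd_measured": 24,
  "n_nmd_protein_down": 22,
  "top_hexamers": ["GGGGGG", "GGGGGC", "AGGGGG", "CGGGGG", "TGGGGG"]
}
```

All 18 planted targets are recovered in `bound_nmd_genes`, the planted
GGGGGG motif tops the hexamer ranking, and 22 of 24 measured NMD genes are
down at the protein level (the generator couples protein loss to PTC genes
with probability 0.9).

The deterministic count fixture reproduces the published-style worked
numbers through the same code paths:

```bash
poisonscan fixture --out-dir fix --seed 0
# build the 52-gene NMD target list from fix/fixture_events.tsv, then:
poisonscan proteome --proteome fix/fixture_proteome.tsv \
    --genes @fix/nmd_genes.txt --out fix/enrichment.json --seed 0
```

```
13/44 targets down; null mean 0.094
```

i.e. of 52 NMD-predicted genes, 44 are measured (8 are not), 13 of the 44
(29.5%) are significantly down, against a bootstrap null mean of 9.3% —
a ~3-fold enrichment with empirical p ≈ 2 × 10⁻⁴ (10,000 draws) and
hypergeometric p ≈ 1.2 × 10⁻⁴.

## Library use

```python
from poisonscan import (
    SimulationConfig, generate_dataset, PipelineConfig, run_pipeline
)
ds = generate_dataset(SimulationConfig(n_genes=60, seed=4), "demo")
funnel = run_pipeline(PipelineConfig(
    genome=str(ds.paths["genome"]), gtf=str(ds.paths["gtf"]),
    domains=str(ds.paths["domains"]), peaks=str(ds.paths["peaks"]),
    events_dir=str(ds.out_dir), proteome=str(ds.paths["proteome"]),
    out_dir="demo_out", seed=4,
))
```

Each stage is also importable on its own (`poisonscan.clip`,
`poisonscan.splicing`, `poisonscan.consequence`, `poisonscan.proteome`,
`poisonscan.simulate`).

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
pytest                      # full suite, ~10 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script (~2 s) recomputes the headline quantities at runtime:
the fixture worked-example numbers (32.9% NMD of 158 events, 13.3% annotated
domain loss, 44/52 NMD genes measured, 29.5% of them down vs a 9.3%
bootstrap null, the 107-nt poison exon length from its printed 1-based
region string) and planted-target recovery on a fresh 200-gene dataset
(precision and recall ≥ 0.9 at ΔPSI = 0.3, 8-fold CLIP enrichment,
π_down = 0.9). All randomness flows from the single `--seed`.

See `docs/methods.md` for statistical and design details, including the
coordinate conventions, the exact filter semantics, and the generator's
frame-arithmetic construction of poison exons.
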