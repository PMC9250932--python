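# Methods

Design rationale and statistical conventions for `poisonscan`. Everything
here is implemented in the package and exercised by the test suite.

## Coordinate conventions

Internally all intervals are 0-based, half-open (`GenomicInterval`). Two
external dialects are supported at the boundary only: GTF-style and printed
region strings (`chr3:186788310-186788416`) are 1-based, fully closed, and
BED is 0-based half-open. Under the closed convention that example region is
186788416 − 186788310 + 1 = 107 nt long; `parse_region_string` reproduces
exactly that arithmetic, and `interval_convert` performs the dialect shifts
in one place so off-by-one errors cannot spread.

Event tables use the rMATS column dialect: per-type coordinate columns
(`exonStart_0base`/`exonEnd` for cassette exons, `riExonStart_0base`/… for
retained introns, long/short/flanking for alternative splice sites,
1st/2nd for mutually exclusive exons) with `IncLevelDifference` and `FDR`.
Only the column *dialect* is emulated; no claim is made about the rMATS
likelihood model itself (the generator's p-values come from an exact
two-proportion test on pooled junction counts).

## CLIP statistics

Enrichment per peak and replicate is the input-normalized log2 fold change
with a +1 pseudocount on all four counts,
`log2((ip+1)/(ip_total+1) / ((input+1)/(input_total+1)))`, and a one-sided
Fisher exact test on the 2×2 count table (scipy), BH-adjusted per replicate
(statsmodels, wrapped by `bh_adjust`). A peak is *reproducible* when the
replicate intervals overlap and **both** replicates pass FDR < 0.05 and
log2FC > 3 (strict inequalities); the reported interval is the intersection,
the conservative choice when replicate boundaries disagree.

A deliberate modeling point: with equal library sizes, an 8-fold raw
pulldown sits at log2FC exactly 3 and a strict `> 3` cutoff would reject it.
Real IP libraries, however, are dominated by bound fragments — background
coverage is *depleted* relative to the size-matched input. The generator
models this with `ip_background_depletion` (default 10×), so a planted
8-fold site scores ≈ 6 input-normalized log2FC while decoy windows score
≈ −3. This is a property of the immunoprecipitation chemistry, not a tuned
constant; it is what makes "8-fold enrichment" and "log2FC > 3" mutually
consistent in real data too.

Peak annotation assigns one label per peak with fixed priority
5'SS > 3'SS > CDS > 5'UTR > 3'UTR > proximal intron (≤ 500 nt from a splice
site) > distal intron > noncoding exon > intergenic, using the longest-CDS
transcript per gene as canonical and a 50-nt splice-site window. Motif
analysis counts hexamers in strand-oriented peak sequences against
1-kb-shifted background windows with add-one smoothing; sequences from
minus-strand peaks are reverse-complemented first, since binding motifs live
in sense space.

## Splicing filters and direction

Significant events satisfy FDR < 0.1 **and** |ΔPSI| > 0.05, both strict.
ΔPSI = PSI(knockdown) − PSI(control). Direction follows the sign:
ΔPSI < 0 → the factor normally *supports* that inclusion
(`supported_by_RBM17`); ΔPSI > 0 → it *represses* it (`repressed_by_RBM17`).
Poison exons appear in the repressed class: their inclusion rises when the
factor is lost. Duplicate events (same type + coordinates) collapse to the
smallest FDR. An event is *bound* when a reproducible peak overlaps its
footprint (outermost flanking-exon boundary to outermost, same strand),
which covers the alternative region and both flanking introns — where
splicing-regulatory binding acts.

## Consequence calling

For each significant event the inclusion and exclusion isoform are rebuilt
on the host transcript's exon chain (cassette inserted/removed, retained
intron merging its flanks, short↔long splice-site forms, MXE exon swap). The
knockdown-*promoted* isoform (inclusion if repressed, exclusion if
supported) is then classified against the other:

1. **processed_transcript** — no qualifying ORF. The host's annotated start
   is reused when it survives splicing (still exonic, still reads ATG);
   otherwise the first AUG opening ≥ 30 codons.
2. **NMD** — 50-nt rule: the stop codon's last base lies ≥ 50 nt upstream of
   the last exon–exon junction. Stops in the last exon and single-exon
   mRNAs are immune. The ≥ at exactly 50 nt is asserted by a dedicated
   boundary test.
3. **Domain accounting** — otherwise both isoforms are translated and
   compared by shared prefix; every residue at or after the first divergence
   counts as lost (a frameshifted tail cannot fold the reference domain).
   Annotated domains (1-based amino-acid intervals) losing all residues give
   `domain_loss_complete`, some `domain_loss_partial`, none (but protein
   changed) `frameshift_no_domain`; identical proteins give `none`.

NMD + processed_transcript form the super-category *altering coding
potential*; the domain/frameshift classes form *altering protein domain*.
Percentages are reported half-up to one decimal.

## Proteome integration

A protein is *down* when mean FC < 0.9 and FDR < 0.1 (strict; up
symmetrically at > 1.1). Target genes map to proteins by case-insensitive
exact identifier match; duplicate protein rows keep the smallest FDR. The
observed down-fraction of the measured targets is tested two ways:

- **Bootstrap null** — 10,000 random target-sized protein sets drawn without
  replacement from the measured background. Because such draws are exactly
  hypergeometric, they are generated with `rng.hypergeometric`; the
  empirical p carries the +1 finite-sample correction
  (`(1 + #{null ≥ observed}) / (draws + 1)`) and can never be 0.
- **Hypergeometric tail** — the analytic twin `P(X ≥ k)` for
  `X ~ Hypergeom(N, K, n)`. The suite checks both agree within Monte-Carlo
  error on an (N, K, n) grid, and that the null mean equals K/N within 3
  standard errors.

## The paper-marginals fixture

`paper_marginals_fixture` deterministically reproduces a published-style
count structure: 158 consequence-labeled events (52 NMD = 32.9%, 36
processed transcripts, 21 annotated-domain losses = 13.3%, 49 frameshifts)
and an 8,825-protein proteome in which the 52 NMD genes map to 44 measured
proteins (8 unmeasured) with 13 down (29.5%). The published-style analysis
reports only the bootstrap null *mean* of 9.3%; the fixture's background of
821 down proteins is therefore a **synthetic stand-in**, derived as
round(0.093 × 8825) so that random 44-protein sets average a 9.3%
down-fraction. The seed only shuffles row order; every count is fixed, and
the acceptance suite recomputes all of these numbers through the real
filter/mapping/bootstrap code paths rather than asserting literals against
literals.

## Synthetic data generator

Each gene occupies its own contig: 200-nt pads, a 60-nt 5'UTR, a CDS of
150–250 codons with the stop in the last exon (so every reference isoform
escapes NMD), a 150-nt 3'UTR, 4–8 exons (≥ 60 nt), introns of 300–900 nt.
Genes are assigned roles — target (bound + mis-spliced + PTC), bound-only,
spliced-only, or null — and built on the plus strand, then mirrored to the
minus strand for ~half the genes (coordinates reflected, sequence
reverse-complemented, dialect labels restored to genomic order; for MXE the
1st/2nd labels swap, so the recorded ΔPSI is negated to keep tracking the
poison exon).

Two constructions make the ground truth provable rather than probable:

- **A-free filler**: UTRs, intron interiors and planted alternative regions
  are drawn from {C, G, T} only. Without adenine, no ATG and no stop codon
  (TAA/TAG/TGA) can arise in any reading frame, so the only stops and starts
  are the ones placed deliberately.
- **Frame arithmetic**: if the coding offset at the insertion junction is
  `c`, the planted TAA goes at alternative-region offset `o + 3k` with
  `o = (−c) mod 3`, guaranteeing it is read in frame; region lengths are
  multiples of 3 (108-nt cassettes, 102-nt MXE exons) and the stop is placed
  ≥ 50 nt of downstream spliced sequence before the last junction. A
  self-consistency test asserts the consequence caller returns NMD for
  every `introduces_PTC` gene (recall 1.0 on generator output).

PSI values come from beta-binomial junction counts (coverage 100, modest
overdispersion) at control inclusion ~U(0.15, 0.45) shifted by +ΔPSI on
knockdown; null genes reuse an existing internal exon with zero shift.
Protein fold changes are one-sample t-tests over 4 simulated log2
replicates, with targets pulled to FC 0.7 with probability π_down. CLIP
counts are Poisson with the IP background-depletion model above; bound-only
genes get peaks without splicing shifts and spliced-only genes the reverse,
providing the confound controls.

With every fraction set to 0 the generator emits a pure-null dataset; a
20-seed test confirms no ground-truth flags, zero reproducible peaks, and a
significant-event rate at or below the nominal FDR. On a 200-gene dataset at
ΔPSI = 0.3, 8-fold CLIP and π_down = 0.9 the full pipeline recovers the
planted targets with precision and recall ≥ 0.9 (acceptance criterion).

### Known limitations

- One transcript per gene; no alternative TSS/polyA or multi-isoform hosts.
- Junction-count p-values use a pooled exact test, which is mildly
  anti-conservative under overdispersion; BH plus the |ΔPSI| gate keeps the
  realized false-positive rate below nominal in the regimes tested.
- Null events reuse frame-ambiguous host exons, so a chance-significant null
  event can legitimately classify as frameshift/NMD; planted-target
  *precision* is protected by the binding requirement (decoy windows cannot
  pass the peak filters).
- The proteome model is gaussian in log2 with a single effect size; no
  missing-not-at-random measurement model beyond the unmeasured-gene set.
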