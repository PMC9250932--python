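"""Deterministic fixture reproducing the printed count structure of the
published integrative analysis.

The fixture emits 158 consequence-labeled splicing events — 88 altering
coding potential (52 of them NMD-sensitive, 36 processed transcripts) and 70
altering the protein product (21 with complete/partial loss of an annotated
domain, 49 frameshifts without annotated-domain overlap) — together with a
proteome table of 8,825 proteins in which the 52 NMD genes map to 44 measured
proteins, 13 of which pass the down filter (mean FC < 0.9, FDR < 0.1).

The published analysis reports only the bootstrap null mean of 9.3% down
proteins, not the background down count; the fixture's background of 821
down-flagged proteins is a SYNTHETIC stand-in derived as round(0.093 x 8825)
so that random 44-protein sets average a 9.3% down-fraction.

The seed only shuffles row order; every count is fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_EVENTS = 158
N_NMD = 52
N_PROCESSED = 36
N_DOMAIN = 21
N_FRAMESHIFT = 49
N_PROTEOME = 8825
N_MEASURED = 44
N_MEASURED_DOWN = 13
N_BACKGROUND_DOWN = 821  # synthetic: round(0.093 * 8825)


def paper_marginals_fixture(seed: int = 0):
    """Return (event_table, proteome_table, mapping_table) DataFrames.

    event_table: event_id, gene_id, category
    proteome_table: gene_id, mean_fc, p, fdr
    mapping_table: event_id, gene_id, measured (bool)
    """
    rng = np.random.default_rng(seed)

    categories = (
        ["NMD"] * N_NMD
        + ["processed_transcript"] * N_PROCESSED
        + ["domain_loss_partial"] * N_DOMAIN
        + ["frameshift_no_domain"] * N_FRAMESHIFT
    )
    assert len(categories) == N_EVENTS
    genes = [f"FIXG{i:04d}" for i in range(N_EVENTS)]
    events = pd.DataFrame(
        {
            "event_id": [f"EV{i:04d}" for i in range(N_EVENTS)],
            "gene_id": genes,
            "category": categories,
        }
    )

    # NMD genes occupy indices 0..51; the first 44 are measured, 8 are not.
    nmd_genes = genes[:N_NMD]
    measured_nmd = nmd_genes[:N_MEASURED]
    unmeasured_nmd = nmd_genes[N_MEASURED:]

    background_genes = [f"BGP{i:05d}" for i in range(N_PROTEOME - N_MEASURED)]
    prot_genes = measured_nmd + background_genes
    down = np.zeros(N_PROTEOME, dtype=bool)
    down[:N_MEASURED_DOWN] = True  # 13 of the 44 measured NMD targets
    down[N_MEASURED : N_MEASURED + (N_BACKGROUND_DOWN - N_MEASURED_DOWN)] = True
    assert int(down.sum()) == N_BACKGROUND_DOWN

    proteome = pd.DataFrame(
        {
            "gene_id": prot_genes,
            "mean_fc": np.where(down, 0.8, 1.0),
            "p": np.where(down, 0.001, 0.5),
            "fdr": np.where(down, 0.01, 0.6),
        }
    )
    proteome = proteome.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    proteome = proteome.reset_index(drop=True)

    mapping = pd.DataFrame(
        {
            "event_id": events["event_id"][:N_NMD],
            "gene_id": nmd_genes,
            "measured": [g in set(measured_nmd) for g in nmd_genes],
        }
    )
    del unmeasured_nmd
    return events, proteome, mapping
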