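"""Proteome-change filtering and set-enrichment of NMD-predicted targets.

A protein is "down" when its knockdown/control mean fold change is < 0.9 with
FDR < 0.1 (both strict); "up" symmetrically at > 1.1.  The observed down-
fraction of a target set is compared against random same-size protein sets
drawn without replacement (the empirical bootstrap null) and against the
exact hypergeometric tail, its analytic twin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DOWN, UP, UNCHANGED = "down", "up", "unchanged"


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    mean_fc: float
    p: float
    fdr: float
    change_flag: str = UNCHANGED

    def __post_init__(self) -> None:
        if self.mean_fc <= 0:
            raise ValidationError(f"non-positive fold change for {self.gene_id}")


@dataclass(frozen=True)
class EnrichmentResult:
    n_target_measured: int
    k_target_down: int
    observed_fraction: float
    null_mean: float
    null_sd: float
    p_empirical: float
    p_hypergeom: float
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_target_measured": self.n_target_measured,
            "k_target_down": self.k_target_down,
            "observed_fraction": self.observed_fraction,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_empirical": self.p_empirical,
            "p_hypergeom": self.p_hypergeom,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------


def read_proteome_table(path) -> list[ProteinRecord]:
    """Proteome TSV columns: gene_id, mean_fc, p, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "mean_fc", "p", "fdr"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing proteome columns {sorted(missing)}")
    return [
        ProteinRecord(str(r.gene_id), float(r.mean_fc), float(r.p), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def filter_protein_changes(
    records: list[ProteinRecord],
    fdr_max: float = 0.1,
    fc_down: float = 0.9,
    fc_up: float = 1.1,
) -> list[ProteinRecord]:
    """Set each record's change flag; thresholds strict as printed."""
    out = []
    for r in records:
        if r.mean_fc < fc_down and r.fdr < fdr_max:
            flag = DOWN
        elif r.mean_fc > fc_up and r.fdr < fdr_max:
            flag = UP
        else:
            flag = UNCHANGED
        out.append(replace(r, change_flag=flag))
    return out


def map_and_count(
    nmd_genes, records: list[ProteinRecord]
) -> tuple[list[ProteinRecord], int, int, list[str]]:
    """Intersect a target gene list with measured proteins (case-insensitive
    exact match); duplicate protein rows keep the smallest FDR."""
    by_gene: dict[str, ProteinRecord] = {}
    for r in records:
        key = r.gene_id.lower()
        if key in by_gene and r.fdr >= by_gene[key].fdr:
            continue
        by_gene[key] = r
    measured, unmeasured = [], []
    seen = set()
    for g in nmd_genes:
        key = g.lower()
        if key in seen:
            continue
        seen.add(key)
        if key in by_gene:
            measured.append(by_gene[key])
        else:
            unmeasured.append(g)
    k_down = sum(1 for r in measured if r.change_flag == DOWN)
    return measured, len(measured), k_down, unmeasured


# ---------------------------------------------------------------------------
# enrichment statistics


def bootstrap_null(
    background_flags,
    n: int,
    observed_k: int,
    n_draws: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical null of the down-fraction over ``n_draws`` random ``n``-sized
    protein sets drawn without replacement from the background.

    Each draw's down-count follows the hypergeometric law of sampling ``n``
    distinct proteins from ``N`` with ``K`` flagged down, which is how the
    draws are generated.  ``p_empirical`` carries the +1 finite-sample
    correction and never returns 0.
    """
    flags = np.asarray(background_flags, dtype=bool)
    N = flags.size
    K = int(flags.sum())
    if n > N:
        raise ValidationError(f"subset size {n} exceeds background size {N}")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if not (0 <= observed_k <= n):
        raise ValidationError(f"observed k={observed_k} outside [0, {n}]")
    rng = np.random.default_rng(seed)
    ks = rng.hypergeometric(K, N - K, n, size=n_draws)
    fractions = ks / n if n else np.zeros(n_draws)
    observed_fraction = observed_k / n if n else 0.0
    p_emp = (1 + int(np.sum(fractions >= observed_fraction - 1e-12))) / (n_draws + 1)
    return EnrichmentResult(
        n_target_measured=n,
        k_target_down=observed_k,
        observed_fraction=observed_fraction,
        null_mean=float(fractions.mean()),
        null_sd=float(fractions.std(ddof=0)),
        p_empirical=float(p_emp),
        p_hypergeom=float(hypergeom_tail(observed_k, n, K, N)),
        n_draws=n_draws,
        seed=seed,
    )


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValidationError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))
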