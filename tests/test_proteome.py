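"""Protein-change filtering, target mapping and enrichment statistics."""

import math

import numpy as np
import pytest

from poisonscan.errors import ValidationError
from poisonscan.proteome import (
    DOWN,
    UNCHANGED,
    UP,
    ProteinRecord,
    bootstrap_null,
    filter_protein_changes,
    hypergeom_tail,
    map_and_count,
)


def _rec(gene, fc, fdr=0.01, p=0.001):
    return ProteinRecord(gene, fc, p, fdr)


class TestFilterProteinChanges:
    @pytest.mark.parametrize(
        "fc,fdr,flag",
        [
            (0.89, 0.09, DOWN),
            (0.90, 0.09, UNCHANGED),  # FC boundary is strict
            (0.89, 0.10, UNCHANGED),  # FDR boundary is strict
            (1.11, 0.05, UP),
            (1.10, 0.05, UNCHANGED),
            (1.00, 0.001, UNCHANGED),
        ],
    )
    def test_threshold_boundaries(self, fc, fdr, flag):
        [r] = filter_protein_changes([_rec("g", fc, fdr)])
        assert r.change_flag == flag

    def test_flags_partition_records(self):
        rng = np.random.default_rng(3)
        recs = [_rec(f"g{i}", float(fc), float(fdr))
                for i, (fc, fdr) in enumerate(zip(rng.uniform(0.5, 1.5, 200),
                                                  rng.uniform(0, 0.3, 200)))]
        flagged = filter_protein_changes(recs)
        counts = {f: sum(1 for r in flagged if r.change_flag == f)
                  for f in (DOWN, UP, UNCHANGED)}
        assert sum(counts.values()) == len(recs)

    def test_nonpositive_fc_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ProteinRecord("g", 0.0, 0.5, 0.5)


class TestMapAndCount:
    RECORDS = filter_protein_changes(
        [_rec("GeneA", 0.5), _rec("GeneB", 1.0), _rec("GeneC", 0.7)]
    )

    def test_case_insensitive_intersection(self):
        measured, n, k, unmeasured = map_and_count(["genea", "GENEB", "GeneZ"], self.RECORDS)
        assert n == 2
        assert k == 1  # only GeneA is down
        assert unmeasured == ["GeneZ"]

    def test_duplicate_protein_rows_keep_smallest_fdr(self):
        dups = filter_protein_changes(
            [_rec("G", 0.5, fdr=0.5), _rec("G", 0.5, fdr=0.01)]
        )
        measured, n, k, _ = map_and_count(["G"], dups)
        assert (n, k) == (1, 1)
        assert measured[0].fdr == 0.01

    def test_duplicate_targets_counted_once(self):
        _, n, _, unmeasured = map_and_count(["GeneA", "genea"], self.RECORDS)
        assert n == 1 and unmeasured == []


class TestHypergeomTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_tail(0, 5, 3, 20) == 1.0

    def test_all_background_down_forces_full_draws(self):
        assert hypergeom_tail(4, 4, 10, 10) == pytest.approx(1.0)

    def test_small_enumeration(self):
        # N=6 proteins, K=3 down, draw n=2: P(X >= 2) = C(3,2)/C(6,2) = 3/15
        assert hypergeom_tail(2, 2, 3, 6) == pytest.approx(3 / 15)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(3, 2, 1, 10)
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 5, 11, 10)


class TestBootstrapNull:
    def test_degenerate_all_down_background(self):
        res = bootstrap_null([True] * 8, n=3, observed_k=3, n_draws=500, seed=1)
        assert res.null_mean == pytest.approx(1.0)
        assert res.p_empirical == pytest.approx(1.0)
        assert res.p_hypergeom == pytest.approx(1.0)

    def test_null_distribution_matches_enumeration(self):
        # flags TTTFFF, n=2: P(k=2)=3/15, P(k=1)=9/15, P(k=0)=3/15
        flags = [True] * 3 + [False] * 3
        res = bootstrap_null(flags, n=2, observed_k=2, n_draws=60_000, seed=7)
        se = math.sqrt((3 / 15) * (12 / 15) / 60_000)
        assert res.p_empirical == pytest.approx(3 / 15, abs=4 * se + 1e-4)
        assert res.null_mean == pytest.approx(0.5, abs=4 * math.sqrt(0.5 * 0.5 / 60_000))
        assert res.p_hypergeom == pytest.approx(3 / 15)

    def test_null_mean_is_background_rate(self):
        rng = np.random.default_rng(5)
        flags = rng.random(400) < 0.1
        K, N = int(flags.sum()), flags.size
        res = bootstrap_null(flags, n=40, observed_k=10, n_draws=20_000, seed=2)
        mc_se = res.null_sd / math.sqrt(res.n_draws)
        assert res.null_mean == pytest.approx(K / N, abs=4 * mc_se)

    @pytest.mark.parametrize("N,K,n,k", [(30, 6, 10, 4), (50, 25, 8, 6), (40, 3, 12, 1)])
    def test_empirical_matches_hypergeometric(self, N, K, n, k):
        flags = [True] * K + [False] * (N - K)
        res = bootstrap_null(flags, n=n, observed_k=k, n_draws=40_000, seed=9)
        p = res.p_hypergeom
        se = math.sqrt(p * (1 - p) / res.n_draws)
        assert res.p_empirical == pytest.approx(p, abs=4 * se + 1e-4)

    def test_seed_reproducibility(self):
        flags = [True] * 10 + [False] * 90
        a = bootstrap_null(flags, n=20, observed_k=5, n_draws=2_000, seed=42)
        b = bootstrap_null(flags, n=20, observed_k=5, n_draws=2_000, seed=42)
        c = bootstrap_null(flags, n=20, observed_k=5, n_draws=2_000, seed=43)
        assert a == b
        assert a.p_empirical != c.p_empirical or a.null_mean != c.null_mean

    def test_subset_larger_than_background_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_null([True, False], n=3, observed_k=1)

    def test_empirical_p_never_zero(self):
        flags = [True] + [False] * 99
        res = bootstrap_null(flags, n=1, observed_k=1, n_draws=100, seed=0)
        assert res.p_empirical >= 1 / 101
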