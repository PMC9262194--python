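"""Feature-enrichment statistics against counting and hypergeometric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hicbg import (
    InteractionRecord,
    capture_permutation_enrichment,
    eqtl_pair_overlap,
    pair_enrichment,
    region_enrichment,
)
from hicbg.enrichment import fisher_pvalue


def _feature(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


GENOME = _feature([("chr1", 0, 10**9), ("chr2", 0, 10**9)])


def _rec(i, j, p=0.5):
    return InteractionRecord(i=i, j=j, d=10_000.0, x=1, mu=1.0, pvalue=p)


def hypergeom_two_sided(table) -> float:
    """Exact two-sided Fisher P by enumerating the hypergeometric pmf."""
    a, b, c, d = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-10)))


class TestRegionEnrichment:
    def test_genome_wide_feature_is_one(self, toy_bins):
        sig = [_rec(1, 3)]
        universe = sig + [_rec(1, 2), _rec(2, 3), _rec(1, 4)]
        res = region_enrichment(sig, universe, GENOME, toy_bins)
        assert res.enrichment == pytest.approx(1.0)

    def test_sig_equals_all_is_one(self, toy_bins):
        recs = [_rec(1, 3), _rec(1, 4)]
        feat = _feature([("chr1", 0, 10_000)])
        res = region_enrichment(recs, recs, feat, toy_bins)
        assert res.enrichment == pytest.approx(1.0)

    def test_counts_and_fisher_against_oracles(self, toy_bins):
        # 1/2 significant overlap vs 1/4 overall -> enrichment 2
        feat = _feature([("chr1", 25_000, 26_000)])  # hits only bin 3
        sig = [_rec(1, 3), _rec(1, 4)]
        universe = sig + [_rec(1, 2), _rec(2, 4)]
        res = region_enrichment(sig, universe, feat, toy_bins)
        assert res.table == (1, 1, 1, 3)
        assert res.enrichment == pytest.approx((1 / 2) / (1 / 4))
        assert res.pvalue == pytest.approx(hypergeom_two_sided(res.table), abs=1e-9)

    def test_undefined_when_reference_never_overlaps(self, toy_bins):
        feat = _feature([("chr2", 900_000, 901_000)])  # outside every bin
        sig = [_rec(1, 2)]
        res = region_enrichment(sig, sig, feat, toy_bins)
        assert np.isnan(res.enrichment)


class TestPairEnrichment:
    def test_genome_features_give_one(self, toy_bins):
        sig = [_rec(1, 3)]
        universe = sig + [_rec(2, 3)]
        res = pair_enrichment(sig, universe, GENOME, GENOME, toy_bins)
        assert res.enrichment == pytest.approx(1.0)

    def test_order_free_counting_oracle(self, toy_bins):
        # A hits bin 1 only, B hits bin 3 only; (1,3) matches in either
        # orientation, (1,2) and (2,3) do not
        feat_a = _feature([("chr1", 0, 10_000)])
        feat_b = _feature([("chr1", 20_000, 30_000)])
        sig = [_rec(1, 3)]
        universe = sig + [_rec(1, 2), _rec(2, 3), _rec(3, 4)]
        res = pair_enrichment(sig, universe, feat_a, feat_b, toy_bins)
        assert res.table == (1, 0, 1, 3)
        assert res.enrichment == pytest.approx(1.0 / (1 / 4))

    def test_empty_sig_is_undefined(self, toy_bins):
        universe = [_rec(1, 2)]
        res = pair_enrichment([], universe, GENOME, GENOME, toy_bins)
        assert np.isnan(res.enrichment)


class TestFisherOracle:
    def test_all_small_tables_match_hypergeometric_enumeration(self):
        # every 2x2 table with total <= 18 (the acceptance suite covers 50)
        total = 18
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    d = total - a - b - c
                    table = (a, b, c, d)
                    assert fisher_pvalue(table) == pytest.approx(
                        hypergeom_two_sided(table), abs=1e-9
                    ), table


class TestCapturePermutation:
    def test_feature_covering_everything(self, toy_bins):
        enr, p = capture_permutation_enrichment(
            np.array([0, 1]), np.array([2, 3, 4]), GENOME, toy_bins, n_perm=100, seed=1
        )
        assert enr == pytest.approx(1.0)
        assert p == pytest.approx(1.0, abs=0.02)

    def test_deterministic_under_seed(self, toy_bins):
        feat = _feature([("chr1", 0, 20_000)])
        args = (np.array([0, 1]), np.array([1, 2, 3, 4]), feat, toy_bins)
        a = capture_permutation_enrichment(*args, n_perm=200, seed=7)
        b = capture_permutation_enrichment(*args, n_perm=200, seed=7)
        assert a == b

    def test_pool_smaller_than_sample_fatal(self, toy_bins):
        with pytest.raises(ValueError):
            capture_permutation_enrichment(
                np.array([0, 1, 2]), np.array([3]), GENOME, toy_bins
            )

    def test_permutation_mean_matches_hypergeometric(self):
        from hicbg import BinTable

        n_pool = 100
        bins = BinTable(
            chrom=np.array(["chr1"] * n_pool, dtype=object),
            start=np.arange(n_pool) * 1000,
            end=(np.arange(n_pool) + 1) * 1000,
            bin_id=np.arange(1, n_pool + 1),
        )
        # feature covers bins 0..49 -> pool overlap fraction 0.5
        feat = _feature([("chr1", 0, 50_000)])
        sig = np.arange(10)
        pool = np.arange(n_pool)
        rng_mean = []
        enr, p = capture_permutation_enrichment(sig, pool, feat, bins, n_perm=1000, seed=3)
        # observed fraction 1.0 (bins 0..9 all covered); permutation mean ~ 0.5
        se = np.sqrt(0.5 * 0.5 / 10 / 1000) * 3  # 3 sigma of the mean of 1000 draws
        assert 1.0 / enr == pytest.approx(0.5, abs=3 * 0.05)
        assert p <= 0.01

    def test_null_pvalues_super_uniform(self):
        """With the feature independent of the calls, P(p <= 0.05) stays
        near or below nominal over repeated null replicates."""
        from hicbg import BinTable

        n_pool = 60
        bins = BinTable(
            chrom=np.array(["chr1"] * n_pool, dtype=object),
            start=np.arange(n_pool) * 1000,
            end=(np.arange(n_pool) + 1) * 1000,
            bin_id=np.arange(1, n_pool + 1),
        )
        feat = _feature([("chr1", 0, 30_000)])  # covers half the bins
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            chosen = rng.choice(n_pool, size=12, replace=False)
            sig, pool = chosen[:6], np.setdiff1d(np.arange(n_pool), chosen[:6])
            _, p = capture_permutation_enrichment(
                sig, pool, feat, bins, n_perm=199, seed=rep
            )
            hits += p <= 0.05
        assert hits / n_rep <= 0.08


class TestEqtlPairOverlap:
    def _eqtl(self, rows):
        return pd.DataFrame(rows, columns=["snp_chrom", "snp_pos", "tss_chrom", "tss_pos"])

    def test_three_record_toy(self, toy_bins):
        # SNP in bin 1, promoter around TSS in bin 3: only (1,3) bridges
        eqtl = self._eqtl([("chr1", 5_000, "chr1", 25_000)])
        recs = [_rec(1, 3), _rec(1, 2), _rec(2, 3)]
        frac, enr = eqtl_pair_overlap(recs[:1], recs, eqtl, toy_bins)
        assert frac == pytest.approx(1.0)
        # all-records fraction is 1/3 -> enrichment 3
        assert enr == pytest.approx(3.0)

    def test_same_end_snp_and_tss_not_counted(self, toy_bins):
        # SNP and TSS both inside bin 1; the other end never matches
        eqtl = self._eqtl([("chr1", 2_000, "chr1", 2_500)])
        recs = [_rec(1, 3)]
        frac, enr = eqtl_pair_overlap(recs, recs, eqtl, toy_bins, promoter_halfwidth=100)
        assert frac == 0.0

    def test_zero_halfwidth_requires_exact_tss_bin(self, toy_bins):
        eqtl = self._eqtl([("chr1", 5_000, "chr1", 20_000)])
        recs = [_rec(1, 3)]  # bin 3 is [20000, 30000): contains the TSS
        frac, _ = eqtl_pair_overlap(recs, recs, eqtl, toy_bins, promoter_halfwidth=0)
        assert frac == 1.0
        eqtl2 = self._eqtl([("chr1", 5_000, "chr1", 19_999)])  # TSS in bin 2
        frac2, _ = eqtl_pair_overlap(recs, recs, eqtl2, toy_bins, promoter_halfwidth=0)
        assert frac2 == 0.0
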