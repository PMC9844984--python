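"""Transmission-distortion statistics: scan, corrections, sharing, power."""

import numpy as np
import pytest
from scipy import stats

import meioscan as ms
from meioscan.matrix import NA
from meioscan.tdscan import _corr_from_genotypes


def imputed(genotypes, positions=None):
    geno = np.asarray(genotypes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, geno.shape[0] + 1)
    return ms.ImputedMatrix(
        positions=np.asarray(positions), gamete_ids=[f"g{j}" for j in range(geno.shape[1])],
        paths=np.zeros_like(geno), genotypes=geno,
        filled=np.zeros(geno.shape, dtype=bool), superimposed=True,
    )


class TestExactBinomialTest:
    @pytest.mark.parametrize("n", [1, 4, 10, 25, 61])
    def test_matches_the_reference_implementation(self, n):
        table = ms.exact_binom_two_sided(n)
        ref = [stats.binomtest(k, n, 0.5).pvalue for k in range(n + 1)]
        assert np.allclose(table, ref, rtol=1e-10)

    def test_balanced_count_has_p_one(self):
        assert ms.exact_binom_two_sided(100)[50] == pytest.approx(1.0)

    def test_extreme_count_tail_arithmetic(self):
        # 0 of 10: both extreme outcomes, p = 2 / 2^10
        assert ms.exact_binom_two_sided(10)[0] == pytest.approx(2 / 1024)

    def test_symmetry_of_the_two_tails(self):
        table = ms.exact_binom_two_sided(10)
        assert table[0] == pytest.approx(table[10])


class TestBinomialScan:
    def test_counts_fractions_and_pvalues(self):
        geno = [[1, 1, 1, 1], [0, 1, 0, 1], [0, 0, 0, NA]]
        scan = ms.binomial_scan(imputed(geno))
        assert scan.n1.tolist() == [4, 2, 0]
        assert scan.n0.tolist() == [0, 2, 3]
        assert scan.fraction.tolist() == [1.0, 0.5, 0.0]
        assert scan.pvalues[1] == pytest.approx(1.0)
        assert scan.pvalues[0] == pytest.approx(2 / 16)

    def test_zero_call_sites_are_skipped_with_warning(self, caplog):
        geno = [[1, 0, 1], [NA, NA, NA]]
        with caplog.at_level("WARNING"):
            scan = ms.binomial_scan(imputed(geno))
        assert len(scan.positions) == 1
        assert "zero genotype calls" in caplog.text

    def test_lead_site_is_the_minimum_p(self):
        geno = [[1, 1, 1, 1, 1, 1], [0, 1, 0, 1, 0, 1]]
        scan = ms.binomial_scan(imputed(geno, positions=[10, 20]))
        pos, p, frac = scan.lead()
        assert pos == 10 and frac == 1.0 and p == pytest.approx(2 / 64)


class TestEffectiveTests:
    def test_identical_snps_collapse_to_one_test(self):
        row = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.int8)
        geno = np.tile(row, (6, 1))
        assert ms.effective_tests(geno) == 1

    def test_orthogonal_snps_count_fully(self):
        # rows built from mutually orthogonal +-1 patterns (Hadamard-style)
        geno = np.array([
            [0, 0, 1, 1, 0, 0, 1, 1],
            [0, 1, 0, 1, 0, 1, 0, 1],
            [0, 1, 1, 0, 0, 1, 1, 0],
        ], dtype=np.int8)
        assert ms.effective_tests(geno) == 3

    def test_two_identical_plus_one_independent(self):
        geno = np.array([
            [0, 0, 1, 1, 0, 0, 1, 1],
            [0, 0, 1, 1, 0, 0, 1, 1],
            [0, 1, 0, 1, 0, 1, 0, 1],
        ], dtype=np.int8)
        # correlation eigenvalues {2, 1, 0}: two components carry >= 99.5%
        assert ms.effective_tests(geno) == 2

    def test_constant_rows_are_dropped(self, caplog):
        geno = np.array([[1, 1, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        with caplog.at_level("WARNING"):
            m = ms.effective_tests(geno)
        assert m == 1 and "constant" in caplog.text

    @pytest.mark.parametrize("block_size", [3, 7, 50])
    def test_blocked_estimate_matches_dense_oracle_on_block_multiples(self, block_size):
        # an independent dense eigendecomposition over each block is the
        # oracle; the implementation must agree for any block size
        rng = np.random.default_rng(8)
        geno = (rng.random((21, 60)) < 0.5).astype(np.int8)
        expected = 0
        rows = [r for r in range(21) if len(set(geno[r])) > 1]
        for start in range(0, len(rows), block_size):
            block = geno[rows[start:start + block_size]].astype(float)
            if block.shape[0] == 1:
                expected += 1
                continue
            eigs = np.sort(np.linalg.eigvalsh(np.corrcoef(block)))[::-1]
            cum = np.cumsum(np.clip(eigs, 0, None))
            expected += int(np.argmax(cum >= 0.995 * cum[-1]) + 1)
        assert ms.effective_tests(geno, block_size=block_size) == expected


class TestSignificanceThreshold:
    def test_published_scale_division(self):
        assert ms.significance_threshold(281_368) == pytest.approx(1.78e-7, rel=5e-3)

    def test_single_test_keeps_family_alpha(self):
        assert ms.significance_threshold(1) == 0.05

    def test_plain_arithmetic(self):
        assert ms.significance_threshold(2000) == pytest.approx(2.5e-5)

    def test_fractional_test_count_rejected(self):
        with pytest.raises(ValueError):
            ms.significance_threshold(0.5)


class TestAlleleSharing:
    def test_identical_gametes_share_everything(self):
        geno = np.array([[1, 1], [0, 0], [1, 1]], dtype=np.int8)
        assert ms.pairwise_allele_sharing(geno) == 1.0

    def test_complementary_gametes_share_nothing(self):
        geno = np.array([[1, 0], [0, 1], [1, 0]], dtype=np.int8)
        assert ms.pairwise_allele_sharing(geno) == 0.0

    def test_two_haplotype_groups_enumerate_to_one_third(self):
        h1 = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        geno = np.stack([h1, h1, 1 - h1, 1 - h1], axis=1)
        # 2 within-group pairs share 1.0; 4 cross pairs share 0.0
        assert ms.pairwise_allele_sharing(geno) == pytest.approx(1 / 3)

    def test_single_gamete_rejected(self):
        with pytest.raises(ValueError):
            ms.pairwise_allele_sharing(np.array([[1], [0]], dtype=np.int8))

    def test_vif_pruning_removes_duplicated_snps(self):
        rng = np.random.default_rng(5)
        indep = (rng.random((10, 80)) < 0.5).astype(np.int8)
        dup = np.repeat(indep[:3], 4, axis=0)  # 12 heavily correlated rows
        geno = np.vstack([dup, indep])
        kept = ms.prune_ld(geno, window=15, step=1, vif_threshold=2.0)
        # at most one copy of each duplicated pattern can survive
        patterns = {geno[i].tobytes() for i in kept}
        assert len(patterns) == len(kept)

    def test_null_simulations_centre_on_half(self):
        p, null_means = ms.allele_sharing_null(
            observed_mean=0.5, n_gametes=30, n_snps=60,
            crossover_counts=1.0, n_sims=100, seed=3)
        assert abs(null_means.mean() - 0.5) < 0.02

    def test_one_tailed_p_extremes(self):
        p_hi, _ = ms.allele_sharing_null(1.1, 20, 40, 1.0, n_sims=50, seed=4)
        p_lo, _ = ms.allele_sharing_null(-1.0, 20, 40, 1.0, n_sims=50, seed=4)
        assert p_hi == 0.0 and p_lo == 1.0


class TestPower:
    def test_null_transmission_is_calibrated(self):
        res = ms.power_binomial(1711, 0.5, alpha=1.78e-7, n_trials=1000, seed=0)
        assert res.power <= 0.002

    def test_power_monotone_in_sample_size_and_effect(self):
        grid_n = [ms.power_binomial(n, 0.58, 1.78e-7, n_trials=400, seed=1).power
                  for n in (500, 1500, 4000)]
        grid_k = [ms.power_binomial(1500, k, 1.78e-7, n_trials=400, seed=2).power
                  for k in (0.52, 0.57, 0.62)]
        assert grid_n == sorted(grid_n)
        assert grid_k == sorted(grid_k)

    def test_tdt_statistic_plug_in(self):
        assert ms.tdt_statistic(15, 5) == pytest.approx(5.0)

    def test_balanced_transmissions_never_reject(self):
        assert ms.tdt_statistic(7, 7) == 0.0
        res = ms.power_tdt(14, 0.5, alpha=1e-6, n_trials=200, seed=5)
        assert res.power <= 0.01

    def test_tdt_no_more_powerful_than_direct_binomial(self):
        for n, k in ((400, 0.6), (1000, 0.57)):
            pb = ms.power_binomial(n, k, alpha=1e-5, n_trials=600, seed=6).power
            pt = ms.power_tdt(n, k, alpha=1e-5, n_trials=600, seed=6).power
            assert pt <= pb + 0.05  # Monte-Carlo slack


class TestCorrelationHelper:
    def test_na_values_are_mean_filled(self):
        geno = np.array([[0, 1, NA, 1], [1, 0, 1, 0]], dtype=np.int8)
        corr = _corr_from_genotypes(geno)
        assert corr.shape == (2, 2)
        assert np.isfinite(corr).all()
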