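import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boronmap import (
    MISSING,
    SimulationConfig,
    centered_kinship,
    conditional_scan,
    effect_size_homozygous,
    filter_genotypes,
    filter_variants,
    genomic_control_lambda,
    group_difference_test,
    lmm_scan,
    significance_thresholds,
    simulate_island_population,
    simulate_trait,
    write_vcf,
)
from boronmap.assoc_core import expected_chi2_median

from conftest import make_genotype_matrix
from _oracles import gls_grid_oracle, ols_scan_pvalues


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


class TestGenotypeFiltering:
    def _write(self, tmp_path, body):
        path = tmp_path / "test.vcf"
        path.write_text(VCF_HEADER + body)
        return str(path)

    def test_dp_and_gq_are_strict_thresholds(self, tmp_path):
        body = ("chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t"
                "1/1:3:99\t1/1:4:21\t0/0:4:20\n")
        g = filter_genotypes(self._write(tmp_path, body))
        # DP=3 fails (needs >3), GQ=20 fails (needs >20), middle call passes
        assert list(g.calls[:, 0]) == [MISSING, 1, MISSING]

    def test_triallelic_record_dropped(self, tmp_path):
        body = ("chr1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT:DP:GQ\t"
                "1/1:30:99\t2/2:30:99\t0/0:30:99\n"
                "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT:DP:GQ\t"
                "1/1:30:99\t0/0:30:99\t0/0:30:99\n")
        g = filter_genotypes(self._write(tmp_path, body))
        assert g.n_variants == 1
        assert g.variants["pos"].iloc[0] == 200

    def test_good_calls_unchanged(self, tmp_path):
        body = ("chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t"
                "1/1:10:30\t0/0:10:30\t1/1:10:30\n")
        g = filter_genotypes(self._write(tmp_path, body))
        assert list(g.calls[:, 0]) == [1, 0, 1]

    @pytest.mark.parametrize("calls,maf_min,miss_max,kept", [
        # 3 alt of 100 -> MAF 0.03 < 0.05 dropped
        ([1] * 3 + [0] * 97, 0.05, 0.10, 0),
        # 15% missing -> dropped
        ([MISSING] * 15 + [1] * 40 + [0] * 45, 0.05, 0.10, 0),
        # monomorphic -> dropped
        ([0] * 100, 0.05, 0.10, 0),
        # common, complete -> kept
        ([1] * 40 + [0] * 60, 0.05, 0.10, 1),
    ])
    def test_variant_filters(self, calls, maf_min, miss_max, kept):
        g = make_genotype_matrix(np.array(calls).reshape(-1, 1))
        out = filter_variants(g, maf_min=maf_min, miss_max=miss_max)
        assert out.n_variants == kept


class TestKinship:
    def test_two_sample_hand_computation(self):
        g = make_genotype_matrix([[0], [1]])
        K = centered_kinship(g)
        assert np.allclose(K, [[0.25, -0.25], [-0.25, 0.25]])

    def test_duplicate_samples_have_identical_rows(self, tiny_genotypes):
        g = tiny_genotypes
        g.calls[1] = g.calls[0]
        K = centered_kinship(g)
        assert np.allclose(K[0], K[1])

    def test_centering_and_psd(self, tiny_genotypes):
        W = tiny_genotypes.dosage(impute=True)
        W = W - W.mean(axis=0)
        assert np.allclose(W.sum(axis=0), 0, atol=1e-10)
        K = centered_kinship(tiny_genotypes)
        assert np.all(np.linalg.eigvalsh(K) > -1e-10)


class TestLmmScan:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
        g = make_genotype_matrix(calls)
        y = rng.normal(size=30) + calls[:, 2] * 1.5
        res = lmm_scan(y, g, np.eye(30))
        ols_p = ols_scan_pvalues(y, calls.astype(float))
        assert np.allclose(res.table["p_wald"], ols_p, atol=1e-6)

    def test_exact_signal_recovered_without_noise(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, size=(20, 5)).astype(np.int8)
        g = make_genotype_matrix(calls)
        y = 2.0 + 3.7 * calls[:, 1]
        res = lmm_scan(y, g, centered_kinship(g))
        assert res.table["beta"].iloc[1] == pytest.approx(3.7, rel=1e-5)

    def test_matches_gls_grid_oracle_small_n(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            n = 8
            calls = rng.integers(0, 2, size=(n, 4)).astype(np.int8)
            calls[0], calls[1] = 0, 1
            g = make_genotype_matrix(calls)
            A = rng.normal(size=(n, n))
            K = A @ A.T / n
            y = rng.normal(size=n) + calls[:, 0]
            res = lmm_scan(y, g, K)
            X = g.dosage()
            for j in range(4):
                D = np.column_stack([np.ones(n), X[:, j]])
                b, se, p = gls_grid_oracle(y, D, K)
                assert res.table["beta"].iloc[j] == pytest.approx(b, rel=1e-4)
                assert res.table["se"].iloc[j] == pytest.approx(se, rel=1e-4)
                assert res.table["p_wald"].iloc[j] == pytest.approx(p, rel=1e-3)

    def test_collinear_marker_reported_missing(self):
        calls = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        g = make_genotype_matrix(calls)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = conditional_scan(y, g, np.eye(4), ["chr1:100"])
        # the remaining marker is identical to the conditioning covariate
        assert np.isnan(res.table["p_wald"].iloc[0])

    def test_phenotype_alignment_by_sample_id(self, tiny_genotypes):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=8),
                      index=tiny_genotypes.samples[::-1])
        res1 = lmm_scan(y, tiny_genotypes, np.eye(8))
        res2 = lmm_scan(y.reindex(tiny_genotypes.samples).to_numpy(),
                        tiny_genotypes, np.eye(8))
        assert np.allclose(res1.table["p_wald"], res2.table["p_wald"])

    def test_non_psd_kinship_rejected(self, tiny_genotypes):
        K = -np.eye(8)
        with pytest.raises(ValueError, match="semidefinite"):
            lmm_scan(np.zeros(8), tiny_genotypes, K)


class TestConditionalScan:
    def test_empty_condition_equals_plain_scan(self, tiny_genotypes):
        rng = np.random.default_rng(1)
        y = rng.normal(size=8)
        K = centered_kinship(tiny_genotypes)
        a = lmm_scan(y, tiny_genotypes, K)
        b = conditional_scan(y, tiny_genotypes, K, [])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_lead_marker_raises(self, tiny_genotypes):
        with pytest.raises(KeyError, match="chr9:1"):
            conditional_scan(np.zeros(8), tiny_genotypes, np.eye(8),
                             ["chr9:1"])

    def test_conditioning_on_causal_kills_regional_signal(self):
        """Conditioning on the causal variant leaves no significant
        neighbour, mirroring the single-haplotype logic of a conditional
        scan."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            cfg = SimulationConfig(n_samples=100, n_variants=60,
                                   causal_effect=10.0, true_h2=0.8,
                                   contamination_rate=0.0, missing_rate=0.0,
                                   maf_floor=0.05)
            g, truth = simulate_island_population(cfg, seed)
            pheno = simulate_trait(g, truth, cfg, seed + 1000)
            y = pheno.groupby("accession")["B"].mean().reindex(g.samples)
            K = centered_kinship(g)
            (vid, _), = truth.causal_snps.items()
            res = conditional_scan(y, g, K, [vid])
            if (res.table["p_wald"] < res.bonferroni_threshold).any():
                hits += 1
        assert hits <= 0.05 * n_runs + 2

    def test_uncorrelated_conditioning_leaves_top_hit(self):
        cfg = SimulationConfig(n_samples=150, n_variants=80,
                               causal_effect=5.0, true_h2=0.5, fst=0.1,
                               contamination_rate=0.0, missing_rate=0.0,
                               maf_floor=0.1)
        g, truth = simulate_island_population(cfg, 17)
        pheno = simulate_trait(g, truth, cfg, 18)
        y = pheno.groupby("accession")["B"].mean().reindex(g.samples)
        K = centered_kinship(g)
        base = lmm_scan(y, g, K)
        top = base.top_hit()
        # pick a conditioning marker nearly uncorrelated with the top hit
        X = g.dosage()
        j_top = list(g.variant_ids()).index(top["id"])
        r2 = np.array([np.corrcoef(X[:, j], X[:, j_top])[0, 1] ** 2
                       for j in range(g.n_variants)])
        j_far = int(np.argmin(r2))
        cond = conditional_scan(y, g, K, [g.variant_ids()[j_far]])
        p_before = -np.log10(top["p_wald"])
        p_after = -np.log10(
            cond.table.set_index("id")["p_wald"].loc[top["id"]])
        assert abs(p_after - p_before) / p_before < 0.10


class TestScanStatistics:
    def test_bonferroni_cut(self):
        bonf, _ = significance_thresholds([0.5] * 20, n_tests=20)
        assert bonf == pytest.approx(0.0025)

    def test_bh_step_up_enumeration(self):
        _, fdr = significance_thresholds([0.001, 0.02, 0.03, 0.5],
                                         fdr_q=0.10)
        assert fdr == pytest.approx(0.03)

    def test_bh_none_when_nothing_qualifies(self):
        _, fdr = significance_thresholds([1.0, 1.0, 1.0])
        assert fdr is None

    def test_empty_pvalues_rejected(self):
        with pytest.raises(ValueError):
            significance_thresholds([])

    def test_lambda_at_null_median(self):
        assert genomic_control_lambda([0.5] * 101) == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_lambda_uniform_null(self):
        rng = np.random.default_rng(0)
        lam = genomic_control_lambda(rng.uniform(size=100_000))
        assert 0.98 <= lam <= 1.02

    def test_lambda_doubled_statistics(self):
        rng = np.random.default_rng(1)
        chi = stats.chi2.rvs(1, size=100_001, random_state=2) * 2
        p = stats.chi2.sf(chi / 2, 1)  # null p of the undoubled stats
        doubled_p = stats.chi2.sf(chi, 1)
        lam_null = genomic_control_lambda(p)
        lam = genomic_control_lambda(doubled_p)
        assert lam == pytest.approx(2 * lam_null, rel=1e-9)

    def test_expected_median_constant(self):
        assert expected_chi2_median() == pytest.approx(0.454936, abs=1e-6)

    @pytest.mark.parametrize("beta,doubled", [(0.0, 0.0), (3.31, 6.62),
                                              (-1.5, -3.0)])
    def test_homozygous_effect_doubling(self, beta, doubled):
        assert effect_size_homozygous(beta) == pytest.approx(doubled)


class TestGroupDifference:
    def test_exact_small_sample(self):
        u, p = group_difference_test([1, 2, 3, 4, 5, 6],
                                     ["a", "a", "a", "b", "b", "b"])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        u, p = group_difference_test([1, 2, 3, 1, 2, 3],
                                     ["a"] * 3 + ["b"] * 3)
        assert p >= 0.99

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        z = rng.normal(2, 1, 100)
        _, p = group_difference_test(np.concatenate([x, z]),
                                     ["a"] * 100 + ["b"] * 100)
        assert p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([1, 2, 3], ["a", "a", "a"])


class TestPermutationNull:
    def test_permuted_phenotype_rarely_significant(self):
        cfg = SimulationConfig(n_samples=80, n_variants=60,
                               causal_effect=10.0, true_h2=0.8,
                               contamination_rate=0.0, missing_rate=0.0)
        g, truth = simulate_island_population(cfg, 30)
        pheno = simulate_trait(g, truth, cfg, 31)
        y = pheno.groupby("accession")["B"].mean().reindex(
            g.samples).to_numpy()
        K = centered_kinship(g)
        rng = np.random.default_rng(0)
        n_sig = 0
        n_perm = 40
        for _ in range(n_perm):
            yp = rng.permutation(y)
            res = lmm_scan(yp, g, K)
            if res.table["p_wald"].min() < res.bonferroni_threshold:
                n_sig += 1
        bound = 0.05 * n_perm + 3 * np.sqrt(n_perm * 0.05 * 0.95)
        assert n_sig <= bound
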