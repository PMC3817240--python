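import numpy as np
import pytest
from scipy import stats

from pathsel import SimulationSpec, simulate_phenotype
from pathsel.artp import (
    artp_gene_p,
    artp_layer,
    artp_pathway_p,
    default_truncation_grid,
    permutation_p_matrix,
    rtp_statistic,
)

from conftest import make_study, random_null_study
from helpers import artp_layer_bruteforce, score_test_p_single


class TestRTP:
    @pytest.mark.parametrize(
        "p,k,expected",
        [([0.01, 0.5], 1, 0.01), ([0.2, 0.1, 0.05], 2, 0.005), ([1.0, 1.0, 1.0], 3, 1.0)],
    )
    def test_known_products(self, p, k, expected):
        assert rtp_statistic(p, k) == pytest.approx(expected, rel=1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            rtp_statistic([0.1, 0.2], 3)

    def test_grid_capped_at_item_count(self):
        assert default_truncation_grid(3) == (1, 2, 3)
        assert max(default_truncation_grid(100)) == 20


class TestPermutationMatrix:
    def test_deterministic_under_seed(self):
        study = random_null_study(60, 4, seed=1)
        a = permutation_p_matrix(study, range(4), 5, seed=9)
        b = permutation_p_matrix(study, range(4), 5, seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (6, 4)

    def test_score_p_matches_independent_route(self):
        """Row-0 score p agrees with a statsmodels-based score test."""
        study = random_null_study(150, 3, seed=2)
        P = permutation_p_matrix(study, range(3), 1, seed=0)
        X = np.column_stack([np.ones(150), study.covariates["age"].to_numpy()])
        for j in range(3):
            ref = score_test_p_single(study.G[:, j], X, study.phenotype.astype(float))
            assert P[0, j] == pytest.approx(ref, rel=1e-6)

    def test_observed_rank_uniform_under_null(self):
        """Exchangeability: on null data the observed row's rank among
        replicates is uniform over 100 toys."""
        ranks = []
        for t in range(100):
            study = random_null_study(80, 1, seed=100 + t)
            P = permutation_p_matrix(study, [0], 19, seed=t)
            ranks.append(np.sum(P[1:, 0] <= P[0, 0]))
        # ranks should spread over 0..19; KS against discrete uniform
        ks = stats.kstest(np.array(ranks) / 20.0, "uniform").statistic
        assert ks < 0.15

    def test_single_class_phenotype_errors(self):
        study = random_null_study(50, 2, seed=3)
        study.phenotype = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            permutation_p_matrix(study, [0], 5)


class TestARTPGene:
    def test_single_snp_grid1_reduces_to_permutation_p(self):
        study = random_null_study(100, 1, seed=4)
        P = permutation_p_matrix(study, [0], 99, seed=5)
        gene_p, _ = artp_gene_p(P, truncation_grid=(1,))
        perm_p = (1 + np.sum(P[1:, 0] <= P[0, 0])) / 100
        assert gene_p == pytest.approx(perm_p)

    def test_matches_bruteforce_layer(self):
        rng = np.random.default_rng(6)
        P = rng.uniform(0.001, 1.0, size=(40, 7))
        grid = (1, 2, 5)
        p_fast, diag = artp_layer(P, grid)
        p_slow, minp_slow = artp_layer_bruteforce(P, grid)
        assert p_fast == pytest.approx(p_slow)
        np.testing.assert_allclose(diag["minp"], minp_slow)

    def test_exhaustive_toy_equals_enumeration(self):
        """n=8 with 4 cases: the ARTP gene p over the exhaustive 70-row
        ensemble equals the brute-force triple-loop enumeration."""
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(8, 3)).astype(float)
        study = make_study(G, y=[1, 1, 1, 1, 0, 0, 0, 0], seed=5)
        P = permutation_p_matrix(study, range(3), "exhaustive")
        assert P.shape == (70, 3)
        p_fast, _ = artp_gene_p(P)
        p_slow, _ = artp_layer_bruteforce(P, default_truncation_grid(3))
        assert p_fast == p_slow

    def test_invariant_to_snp_order(self):
        study = random_null_study(100, 6, seed=8)
        P = permutation_p_matrix(study, range(6), 50, seed=1)
        p1, _ = artp_gene_p(P)
        p2, _ = artp_gene_p(P[:, ::-1])
        assert p1 == p2

    def test_invariant_to_monotone_rescaling(self):
        """Gene p depends on per-SNP p only through ranks across the
        ensemble, so a monotone transform changes nothing."""
        rng = np.random.default_rng(9)
        P = rng.uniform(0.001, 1.0, size=(60, 4))
        p1, _ = artp_gene_p(P, (1, 2))
        p2, _ = artp_gene_p(np.sqrt(P), (1, 2))
        assert p1 == p2

    def test_permutation_floor_respected(self):
        rng = np.random.default_rng(10)
        P = rng.uniform(size=(30, 3))
        P[0] = 1e-12  # observed far stronger than every replicate
        p, _ = artp_gene_p(P)
        assert p == pytest.approx(1 / 30)

    def test_causal_gene_beats_null_gene(self):
        """A gene holding one OR-0.67 causal SNP (n=2000) gets a smaller
        ARTP p than a null gene in >=95% of 100 paired replicates."""
        wins = 0
        log_or = np.log(0.67)
        for rep in range(100):
            rng = np.random.default_rng(4000 + rep)
            G = rng.binomial(2, 0.3, size=(2000, 6)).astype(float)
            spec = SimulationSpec(n_snps=6, causal_snps=[(0, log_or)], rng_seed=rep)
            study = make_study(G)
            study.phenotype = None
            study = simulate_phenotype(study, spec, seed=rep)
            Pc = permutation_p_matrix(study, [0, 1, 2], 199, seed=rep)
            Pn = permutation_p_matrix(study, [3, 4, 5], 199, seed=rep)
            pc, _ = artp_gene_p(Pc)
            pn, _ = artp_gene_p(Pn)
            wins += pc < pn
        assert wins >= 95


class TestARTPPathway:
    def test_single_gene_pathway_equals_gene_p(self):
        study = random_null_study(100, 3, seed=12)
        P = permutation_p_matrix(study, range(3), 99, seed=2)
        gene_p, diag = artp_gene_p(P)
        path_p, _ = artp_pathway_p([diag["minp"]], gene_truncation_grid=(1,))
        assert path_p == pytest.approx(gene_p)

    def test_mismatched_permutation_counts_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            artp_pathway_p([np.ones(10), np.ones(12)])

    def test_null_pathway_p_uniform(self):
        """10 null genes, B=200: pathway p uniform over 100 replicates."""
        pvals = []
        for rep in range(100):
            rng = np.random.default_rng(6000 + rep)
            G = rng.binomial(2, 0.3, size=(300, 20)).astype(float)
            study = make_study(G, seed=rep)
            minps = []
            for g in range(10):
                P = permutation_p_matrix(study, range(2 * g, 2 * g + 2), 200,
                                         seed=rep * 10 + g)
                minps.append(artp_gene_p(P)[1]["minp"])
            pvals.append(artp_pathway_p(minps)[0])
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.15

    def test_pathway_with_causal_gene_is_stochastically_smaller(self):
        smaller = 0
        log_or = np.log(0.6)
        for rep in range(30):
            rng = np.random.default_rng(8000 + rep)
            G = rng.binomial(2, 0.3, size=(1000, 8)).astype(float)
            spec = SimulationSpec(n_snps=8, causal_snps=[(0, log_or)], rng_seed=rep)
            study = make_study(G)
            study.phenotype = None
            study = simulate_phenotype(study, spec, seed=rep)
            minps_with, minps_without = [], []
            for g in range(4):
                P = permutation_p_matrix(study, [2 * g, 2 * g + 1], 99, seed=rep * 7 + g)
                minp = artp_gene_p(P)[1]["minp"]
                minps_with.append(minp)
                if g > 0:
                    minps_without.append(minp)
            if artp_pathway_p(minps_with)[0] <= artp_pathway_p(minps_without)[0]:
                smaller += 1
        assert smaller >= 24
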