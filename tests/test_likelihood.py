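import math

import numpy as np
import pytest

from chronotree.errors import ConfigurationError, InputError
from chronotree.likelihood import (
    HKY,
    JC,
    Poisson,
    compress_patterns,
    log_likelihood,
    optimize_branch_lengths,
    pattern_log_likelihoods,
)
from chronotree.simulate import SimulationConfig, simulate_alignment
from chronotree.tree import read_newick
from conftest import simulated_phylogram


def uncompressed_loglik(tree, alignment, model):
    """Site-by-site oracle: likelihood of each column computed separately."""
    total = 0.0
    L = len(alignment[0][1])
    for j in range(L):
        col = [(name, seq[j]) for name, seq in alignment]
        pa = compress_patterns(col, model)
        total += log_likelihood(tree, pa, model)
    return total


def random_alignment(rng, n_taxa, n_sites, alphabet="ACGT-"):
    names = [f"t{i + 1}" for i in range(n_taxa)]
    return [
        (n, "".join(rng.choice(list(alphabet), size=n_sites))) for n in names
    ]


class TestCompression:
    def test_three_identical_sequences(self):
        pa = compress_patterns([("a", "AACG"), ("b", "AACG"), ("c", "AACG")])
        assert pa.L == 4 and pa.m == 3
        assert sorted(pa.weights.tolist()) == [1, 1, 2]

    def test_all_columns_identical(self):
        pa = compress_patterns([("a", "AAAA"), ("b", "CCCC")])
        assert pa.m == 1 and pa.weights.tolist() == [4]

    def test_all_columns_distinct(self):
        pa = compress_patterns([("a", "ACGT"), ("b", "AAAA")])
        assert pa.m == 4 and all(w == 1 for w in pa.weights)

    def test_weights_sum_to_L(self):
        rng = np.random.default_rng(0)
        aln = random_alignment(rng, 6, 80)
        pa = compress_patterns(aln, JC())
        assert pa.weights.sum() == pa.L == 80
        assert pa.m <= pa.L

    def test_gap_placement_distinguishes_patterns(self):
        pa = compress_patterns([("a", "A-"), ("b", "-A")], JC())
        assert pa.m == 2

    def test_ragged_rows_error(self):
        with pytest.raises(InputError, match="ragged"):
            compress_patterns([("a", "ACG"), ("b", "AC")])

    def test_unknown_character_error(self):
        with pytest.raises(InputError, match="column 2"):
            compress_patterns([("a", "A!G")], JC())


class TestTransitionMatrices:
    @pytest.mark.parametrize(
        "model",
        [JC(), HKY(kappa=4, freqs=[0.1, 0.2, 0.3, 0.4]), Poisson(),
         HKY(kappa=2, gamma_alpha=0.5)],
        ids=["jc", "hky", "poisson", "hky_gamma"],
    )
    @pytest.mark.parametrize("d", [0.0, 0.1, 1.0, 10.0])
    def test_rows_sum_to_one(self, model, d):
        P = model.transition_matrix(d)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        if d == 0.0:
            np.testing.assert_allclose(P, np.eye(model.n_states), atol=1e-12)

    def test_gamma_categories_mean_one(self):
        model = JC(gamma_alpha=0.7)
        rates = model.rate_categories
        assert len(rates) == 4
        assert sum(r * w for r, w in rates) == pytest.approx(1.0, abs=1e-9)


class TestLogLikelihood:
    def test_two_taxa_jc_closed_form(self):
        for d1, d2 in [(0.0, 0.0), (0.1, 0.2), (0.5, 0.25)]:
            tree = read_newick(f"(X:{d1},Y:{d2});")
            pa = compress_patterns([("X", "A"), ("Y", "A")], JC())
            d = d1 + d2
            expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3)))
            assert log_likelihood(tree, pa, JC()) == pytest.approx(expected, abs=1e-12)

    def test_saturation_approaches_stationarity(self):
        tree = read_newick("(X:40,Y:40);")
        for states in ("AA", "AG"):
            pa = compress_patterns([("X", states[0]), ("Y", states[1])], JC())
            assert log_likelihood(tree, pa, JC()) == pytest.approx(
                math.log(0.25 * 0.25), abs=1e-6
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_compressed_equals_uncompressed_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 13))
        n_sites = int(rng.integers(10, 201))
        model = JC() if seed % 2 else HKY(kappa=3, freqs=[0.3, 0.2, 0.2, 0.3])
        aln = random_alignment(rng, n_taxa, n_sites)
        _, phylo = simulated_phylogram(seed + 100, n_tips=n_taxa,
                                       rate_model="iid_lognormal")
        pa = compress_patterns(aln, model)
        assert log_likelihood(phylo, pa, model) == pytest.approx(
            uncompressed_loglik(phylo, aln, model), abs=1e-9
        )

    def test_site_order_invariance(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 5, 60)
        _, phylo = simulated_phylogram(12, n_tips=5)
        perm = rng.permutation(60)
        shuffled = [(n, "".join(s[j] for j in perm)) for n, s in aln]
        m = JC()
        assert log_likelihood(phylo, compress_patterns(aln, m), m) == pytest.approx(
            log_likelihood(phylo, compress_patterns(shuffled, m), m), abs=1e-9
        )

    def test_missing_tip_in_alignment_error(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        pa = compress_patterns([("A", "AC"), ("B", "AC")], JC())
        with pytest.raises(ConfigurationError, match="C"):
            log_likelihood(tree, pa, JC())

    def test_pattern_loglik_vector_length(self):
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, 4, 30)
        _, phylo = simulated_phylogram(9, n_tips=4)
        pa = compress_patterns(aln, JC())
        assert pattern_log_likelihoods(phylo, pa, JC()).shape == (pa.m,)


class TestBranchOptimization:
    def test_two_taxon_jc_distance(self):
        """Optimized branch total matches the closed-form JC distance."""
        L, k = 500, 60
        seq1 = "A" * L
        seq2 = "G" * k + "A" * (L - k)
        tree = read_newick("(X:0.05,Y:0.05);")
        pa = compress_patterns([("X", seq1), ("Y", seq2)], JC())
        opt = optimize_branch_lengths(tree, pa, JC())
        total = sum(nd.length for nd in opt.preorder() if not nd.is_root)
        expected = -0.75 * math.log(1 - 4 / 3 * (k / L))
        assert total == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_collapse(self):
        tree = read_newick("((A:0.2,B:0.2):0.1,C:0.3);")
        pa = compress_patterns([("A", "ACGT" * 20), ("B", "ACGT" * 20),
                                ("C", "ACGT" * 20)], JC())
        opt = optimize_branch_lengths(tree, pa, JC())
        for nd in opt.preorder():
            if not nd.is_root:
                assert nd.length <= 1e-5

    def test_parameter_recovery_within_three_se(self):
        """8-taxon simulated alignment: ML lengths near truth, SE from the
        observed curvature of the per-branch log-likelihood."""
        cfg = SimulationConfig(n_tips=8, seed=77, rate_model="strict",
                               mu=0.05, seq_length=5000)
        rng = cfg.rng()
        from chronotree.simulate import simulate_timetree, apply_rate_model

        timetree = simulate_timetree(cfg, rng)
        phylo = apply_rate_model(timetree, cfg, rng)
        aln = simulate_alignment(phylo, cfg, rng)
        pa = compress_patterns(aln, JC())
        opt = optimize_branch_lengths(phylo, pa, JC())
        for est, truth in zip(opt.preorder(), phylo.preorder()):
            if est.is_root:
                continue
            h = 1e-4
            base = est.length
            def ll(x):
                est.length = x
                return log_likelihood(opt, pa, JC())
            curv = (ll(base + h) - 2 * ll(base) + ll(max(base - h, 0.0))) / h**2
            est.length = base
            se = 1.0 / math.sqrt(max(-curv, 1e-12))
            assert abs(base - truth.length) <= 3 * se + 1e-4
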