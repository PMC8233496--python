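import itertools
import math

import numpy as np
import pytest

from chronotree.ep import ep_report, ep_scores
from chronotree.errors import ConfigurationError
from chronotree.likelihood import JC, Poisson
from chronotree.tree import read_newick


def brute_force_ep(tree, alignment, model):
    """Oracle: exhaustive summation over all internal-state assignments,
    focal tip free; O(k^internal) so only for tiny trees."""
    seqs = dict(alignment)
    focal = alignment[0][0]
    k = model.n_states
    lut = {c: i for i, c in enumerate(model.alphabet)}
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_tip]
    P = {n.id: model.transition_matrix(n.length) for n in nodes if not n.is_root}
    L = len(alignment[0][1])
    out = np.zeros((L, k))
    for site in range(L):
        for fx in range(k):
            total = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = {n.id: s for n, s in zip(internals, assign)}
                ok = True
                for tip in tree.tips():
                    if tip.name == focal:
                        amap[tip.id] = fx
                    else:
                        c = seqs[tip.name][site]
                        if c in lut:
                            amap[tip.id] = lut[c]
                        else:
                            amap[tip.id] = None  # missing: marginalized below
                p = model.freqs[amap[tree.root.id]]
                for n in nodes:
                    if n.is_root:
                        continue
                    s_parent = amap[n.parent.id]
                    s_child = amap[n.id]
                    if s_child is None:
                        p *= 1.0  # sum over child states of a row = 1
                    else:
                        p *= P[n.id][s_parent, s_child]
                total += p
            out[site, fx] = total
        out[site] /= out[site].sum()
    return out


UMT4 = "((F:0.1,X:0.1):0.05,(Y:0.05,Z:0.05):0.1);"


class TestClosedForms:
    @pytest.mark.parametrize("d", [0.1, 0.75, 2.0])
    def test_two_taxon_jc(self, d):
        tree = read_newick(f"(F:{d / 2},S:{d / 2});")
        res = ep_scores([("F", "A"), ("S", "A")], tree, JC(), rate=1.0)
        expected = 0.25 + 0.75 * math.exp(-4 * d / 3)
        assert res.ep[0, 0] == pytest.approx(expected, abs=1e-9)
        for j in range(1, 4):
            assert res.ep[0, j] == pytest.approx((1 - expected) / 3, abs=1e-9)

    def test_infinite_branches_give_stationary_frequencies(self):
        tree = read_newick("((F:50,X:50):50,(Y:50,Z:50):50);")
        res = ep_scores(
            [("F", "A"), ("X", "G"), ("Y", "C"), ("Z", "T")], tree, JC(), rate=1.0
        )
        np.testing.assert_allclose(res.ep[0], 0.25, atol=1e-6)

    def test_conserved_site_high_ep(self):
        """All non-focal taxa fixed for G on a very short tree: EP(G) ~ 1 and
        a deviant focal allele is flagged nonneutral."""
        tree = read_newick("((F:0.002,X:0.002):0.001,(Y:0.001,Z:0.001):0.002);")
        res = ep_scores(
            [("F", "A"), ("X", "G"), ("Y", "G"), ("Z", "G")], tree, JC(), rate=1.0
        )
        g = JC().alphabet.index("G")
        assert res.ep[0].argmax() == g
        assert res.ep[0, g] > 0.95
        assert bool(res.nonneutral[0])


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "aln",
        [
            [("F", "ACG"), ("X", "GCG"), ("Y", "GTG"), ("Z", "GAG")],
            [("F", "AC"), ("X", "G-"), ("Y", "-T"), ("Z", "GA")],
        ],
        ids=["plain", "with_gaps"],
    )
    def test_pruning_equals_exhaustive_sum(self, aln):
        tree = read_newick(UMT4)
        res = ep_scores(aln, tree, JC(), rate=1.0)
        oracle = brute_force_ep(tree, aln, JC())
        np.testing.assert_allclose(res.ep, oracle, atol=1e-9)

    def test_six_tip_tree(self):
        nwk = "(((F:0.05,A:0.05):0.05,(B:0.03,C:0.03):0.07):0.02,(D:0.04,E:0.04):0.08);"
        tree = read_newick(nwk)
        aln = [("F", "AG"), ("A", "AG"), ("B", "CG"), ("C", "AG"),
               ("D", "TG"), ("E", "AG")]
        res = ep_scores(aln, tree, JC(), rate=1.0)
        np.testing.assert_allclose(res.ep, brute_force_ep(tree, aln, JC()),
                                   atol=1e-9)


class TestInvariants:
    def test_rows_normalized(self):
        tree = read_newick(UMT4)
        aln = [("F", "ACGTAC"), ("X", "GCGTAC"), ("Y", "GTGAAC"), ("Z", "GAGTTC")]
        res = ep_scores(aln, tree, JC(), rate=1.0)
        np.testing.assert_allclose(res.ep.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_length_duplicate_taxon_is_neutral(self):
        base = read_newick(UMT4)
        dup = read_newick(
            "((F:0.1,X:0.1):0.05,((Y:0,Y2:0):0.05,Z:0.05):0.1);"
        )
        aln = [("F", "AC"), ("X", "GC"), ("Y", "GT"), ("Z", "GA")]
        aln_dup = aln + [("Y2", "GT")]
        a = ep_scores(aln, base, JC(), rate=1.0)
        b = ep_scores(aln_dup, dup, JC(), rate=1.0)
        np.testing.assert_allclose(a.ep, b.ep, atol=1e-9)

    def test_jc_label_symmetry(self):
        """Consistently permuting state labels permutes EP vectors."""
        tree = read_newick(UMT4)
        aln = [("F", "A"), ("X", "G"), ("Y", "C"), ("Z", "G")]
        perm = {"A": "C", "C": "G", "G": "T", "T": "A"}
        aln_p = [(n, "".join(perm[c] for c in s)) for n, s in aln]
        a = ep_scores(aln, tree, JC(), rate=1.0)
        b = ep_scores(aln_p, tree, JC(), rate=1.0)
        alpha = JC().alphabet
        for i, c in enumerate(alpha):
            assert b.ep[0, alpha.index(perm[c])] == pytest.approx(
                a.ep[0, i], abs=1e-12
            )

    def test_all_gap_site_returns_stationary_with_warning(self):
        tree = read_newick(UMT4)
        aln = [("F", "A"), ("X", "-"), ("Y", "-"), ("Z", "-")]
        res = ep_scores(aln, tree, JC(), rate=1.0)
        np.testing.assert_allclose(res.ep[0], 0.25, atol=1e-12)
        assert any("no observed states" in w for w in res.warnings)

    def test_phylogram_input_runs_reltime_internally(self):
        tree = read_newick("((F:0.2,X:0.1):0.05,(Y:0.15,Z:0.1):0.1);")
        aln = [("F", "ACGT"), ("X", "ACGA"), ("Y", "GCGT"), ("Z", "ACTT")]
        res = ep_scores(aln, tree, JC())  # auto rate fit
        assert res.rate > 0
        np.testing.assert_allclose(res.ep.sum(axis=1), 1.0, atol=1e-9)

    def test_amino_acid_alphabet(self):
        tree = read_newick(UMT4)
        aln = [("F", "MK"), ("X", "MK"), ("Y", "MR"), ("Z", "MK")]
        res = ep_scores(aln, tree, Poisson(), rate=1.0)
        assert res.ep.shape == (2, 20)
        np.testing.assert_allclose(res.ep.sum(axis=1), 1.0, atol=1e-9)


class TestErrorsAndReport:
    def test_focal_absent_from_tree(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ConfigurationError, match="focal"):
            ep_scores([("Q", "A"), ("A", "A"), ("B", "A"), ("C", "A")], tree, JC())

    def test_report_layout(self):
        tree = read_newick(UMT4)
        aln = [("F", "AG"), ("X", "GG"), ("Y", "GG"), ("Z", "GG")]
        res = ep_scores(aln, tree, JC(), rate=1.0)
        lines = ep_report(res).strip().split("\n")
        assert lines[0].split("\t") == [
            "site", "observed", "EP_A", "EP_C", "EP_G", "EP_T", "nonneutral"
        ]
        assert len(lines) == 3
        for row in lines[1:]:
            cells = row.split("\t")
            total = sum(float(x) for x in cells[2:6])
            assert total == pytest.approx(1.0, abs=1e-6)
            ep_obs = float(cells[2 + "ACGT".index(cells[1])])
            assert cells[6] == ("1" if ep_obs < 0.05 else "0")
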