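"""Likelihood engine, distances, NJ, bootstrap, collapsing, regrafting."""

import math

import numpy as np
import pytest

from olpiphy import synthdata as sd
from olpiphy import treekit as tk
from olpiphy.treekit import _topology_key


class TestMlDistance:
    def test_identical_sequences(self, jc):
        assert tk.ml_distance("ACGTACGT", "ACGTACGT", jc) == 0.0

    def test_closed_form_p03(self, jc):
        a = "A" * 70 + "C" * 30
        b = "A" * 70 + "G" * 30
        assert tk.ml_distance(a, b, jc) == pytest.approx(-0.75 * math.log(0.6))

    def test_saturation_ceiling_with_warning(self, jc):
        a = "A" * 100
        b = "C" * 80 + "G" * 20
        with pytest.warns(UserWarning, match="saturated"):
            d = tk.ml_distance(a, b, jc, ceiling=5.0)
        assert d == 5.0

    def test_gaps_excluded(self, jc):
        assert tk.ml_distance("AC-T", "ACGT", jc) == 0.0

    def test_no_comparable_sites(self, jc):
        with pytest.raises(ValueError):
            tk.ml_distance("--", "AA", jc)


def _ls_best_quartet(dm, taxa):
    """Least-squares oracle: best of the 3 unrooted quartet topologies."""
    best, best_err = None, np.inf
    idx = {t: i for i, t in enumerate(taxa)}
    for pair in [(0, 1), (0, 2), (0, 3)]:
        a, b = pair
        c, d = [x for x in range(4) if x not in pair]
        # additive fit: internal = (d_ac+d_bd+d_ad+d_bc)/4 - (d_ab+d_cd)/2
        internal = (
            dm[a, c] + dm[b, d] + dm[a, d] + dm[b, c]
        ) / 4 - (dm[a, b] + dm[c, d]) / 2
        err = -internal  # longer positive internal = better supported split
        if err < best_err:
            best_err, best = err, frozenset({taxa[a], taxa[b]})
    return best


class TestNeighborJoining:
    def test_additive_quartet(self):
        taxa = ["A", "B", "C", "D"]
        dm = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = tk.nj_tree(dm, taxa)
        # AB|CD split (stored as the side not containing the reference taxon A)
        assert frozenset({"C", "D"}) in _topology_key(tree)
        # internal branch length 1 under the four-point condition
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node is not None
            and not e.head_node.is_leaf()
            and e.head_node is not tree.seed_node
        ]
        assert internal and internal[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_least_squares_oracle(self, jc):
        rng = np.random.default_rng(0)
        taxa = ["A", "B", "C", "D"]
        for trial in range(5):
            tree = tk.read_tree(
                f"((A:{rng.uniform(.02,.2):.3f},B:{rng.uniform(.02,.2):.3f})"
                f":{rng.uniform(.05,.3):.3f},C:{rng.uniform(.02,.2):.3f},"
                f"D:{rng.uniform(.02,.2):.3f});"
            )
            aln = sd.simulate_alignment(tree, jc, 4000, seed=100 + trial)
            t2, dm = tk.distance_matrix(aln.rows, jc)
            nj = tk.nj_tree(dm, t2)
            oracle_side = _ls_best_quartet(dm, t2)
            labels = sorted(t2)
            if labels[0] in oracle_side:
                oracle_side = frozenset(labels) - oracle_side
            assert oracle_side in _topology_key(nj)

    def test_label_order_invariance(self):
        dm = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        taxa = ["A", "B", "C", "D"]
        t1 = tk.nj_tree(dm, taxa)
        perm = [2, 3, 0, 1]
        t2 = tk.nj_tree(dm[np.ix_(perm, perm)], [taxa[i] for i in perm])
        assert tk.robinson_foulds(t1, t2) == 0

    def test_asymmetric_rejected(self):
        dm = np.zeros((4, 4))
        dm[0, 1] = 1.0
        with pytest.raises(ValueError):
            tk.nj_tree(dm, list("ABCD"))


class TestPruningLikelihood:
    def test_two_taxon_zero_distance_total(self, jc):
        rows = {"A": "ACGT" * 25, "B": "ACGT" * 25}
        total, _ = tk.loglik(tk.read_tree("(A:0,B:0);"), rows, jc)
        assert total == pytest.approx(100 * math.log(0.25), abs=1e-10)

    def test_two_taxon_match_site_closed_form(self, jc):
        d = 0.1
        rows = {"A": "A", "B": "A"}
        _, per_site = tk.loglik(tk.read_tree(f"(A:{d},B:0);"), rows, jc)
        expected = math.log((1 / 16) * (1 + 3 * math.exp(-4 * d / 3)))
        assert per_site[0] == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_mismatch_site_closed_form(self, jc):
        d = 0.1
        rows = {"A": "A", "B": "C"}
        _, per_site = tk.loglik(tk.read_tree(f"(A:{d},B:0);"), rows, jc)
        expected = math.log((1 / 16) * (1 - math.exp(-4 * d / 3)))
        assert per_site[0] == pytest.approx(expected, abs=1e-10)

    def test_rerooting_invariance(self, jc, quartet_alignment):
        t1 = tk.read_tree("((A:0.1,B:0.1):0.5,C:0.1,D:0.1);")
        t2 = tk.read_tree("((C:0.1,D:0.1):0.5,A:0.1,B:0.1);")
        l1, _ = tk.loglik(t1, quartet_alignment, jc)
        l2, _ = tk.loglik(t2, quartet_alignment, jc)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_missing_leaf_row_rejected(self, jc):
        with pytest.raises(ValueError):
            tk.loglik(tk.read_tree("(A:0.1,B:0.1);"), {"A": "ACGT"}, jc)

    def test_gamma_categories_change_likelihood(self, quartet_alignment):
        t = tk.read_tree("((A:0.1,B:0.1):0.5,C:0.1,D:0.1);")
        hom, _ = tk.loglik(t, quartet_alignment, tk.SubstModel(n_states=4))
        het, _ = tk.loglik(
            t, quartet_alignment, tk.SubstModel(n_states=4, gamma_shape=0.5)
        )
        assert hom != het


class TestOptimizeBranchLengths:
    def test_recovers_generating_lengths(self, jc):
        true = tk.read_tree("((A:0.12,B:0.08):0.3,C:0.15,D:0.1);")
        aln = sd.simulate_alignment(true, jc, 10_000, seed=5)
        start = tk.read_tree("((A:0.3,B:0.3):0.3,C:0.3,D:0.3);")
        opt = tk.optimize_branch_lengths(start, aln.rows, jc, tol=1e-6)
        est = {
            frozenset(lf.taxon.label for lf in e.head_node.leaf_iter()): e.length
            for e in opt.preorder_edge_iter()
            if e.head_node is not opt.seed_node
        }
        truth = {
            frozenset({"A"}): 0.12,
            frozenset({"B"}): 0.08,
            frozenset({"A", "B"}): 0.3,
            frozenset({"C"}): 0.15,
            frozenset({"D"}): 0.1,
        }
        for key, val in truth.items():
            assert est[key] == pytest.approx(val, rel=0.10, abs=0.01)

    def test_zero_length_branch_estimated_near_zero(self, jc):
        true = tk.read_tree("((A:0.1,B:0.1):0.0,C:0.1,D:0.1);")
        aln = sd.simulate_alignment(true, jc, 10_000, seed=6)
        start = tk.read_tree("((A:0.1,B:0.1):0.05,C:0.1,D:0.1);")
        opt = tk.optimize_branch_lengths(start, aln.rows, jc, tol=1e-7)
        internal = [
            e.length
            for e in opt.preorder_edge_iter()
            if e.head_node is not opt.seed_node and not e.head_node.is_leaf()
        ]
        assert internal[0] <= 1e-3

    def test_idempotent(self, jc, quartet_alignment):
        start = tk.read_tree("((A:0.2,B:0.2):0.2,C:0.2,D:0.2);")
        once = tk.optimize_branch_lengths(start, quartet_alignment, jc)
        twice = tk.optimize_branch_lengths(once, quartet_alignment, jc)
        l1, _ = tk.loglik(once, quartet_alignment, jc)
        l2, _ = tk.loglik(twice, quartet_alignment, jc)
        assert l2 == pytest.approx(l1, abs=1e-4)


class TestBootstrap:
    def test_strong_quartet_support(self, jc, quartet_alignment):
        tree = tk.bootstrap_supports(
            quartet_alignment, jc, n_replicates=100, seed=1
        )
        assert tk.support_of_bipartition(tree, {"A", "B"}) >= 95

    def test_supports_in_range(self, jc, ten_taxon_tree):
        aln = sd.simulate_alignment(ten_taxon_tree, jc, 300, seed=2)
        tree = tk.bootstrap_supports(aln.rows, jc, n_replicates=50, seed=3)
        sups = [
            tk.get_support(nd)
            for nd in tree.postorder_internal_node_iter()
            if nd is not tree.seed_node and tk.get_support(nd) is not None
        ]
        assert sups and all(0.0 <= s <= 100.0 for s in sups)

    def test_replicate_count_reduces_support_variance(self, jc):
        # SE of the support estimate scales like 1/sqrt(n_replicates)
        tree = tk.read_tree("((A:0.1,B:0.1):0.02,(C:0.1,D:0.1):0.02,E:0.2);")
        aln = sd.simulate_alignment(tree, jc, 300, seed=4)
        small = [
            tk.bootstrap_bipartition_support(
                aln.rows, {"f": {"A", "B"}}, jc, n_replicates=20, seed=s
            )["f"]
            for s in range(8)
        ]
        large = [
            tk.bootstrap_bipartition_support(
                aln.rows, {"f": {"A", "B"}}, jc, n_replicates=180, seed=s
            )["f"]
            for s in range(8)
        ]
        assert np.std(large) < np.std(small)


class TestCollapse:
    def test_all_strong_is_identity(self):
        t = tk.read_tree("(((A:1,B:1)100:1,(C:1,D:1)100:1)100:1,E:1,F:1);")
        c = tk.collapse_nodes(t, 30)
        assert tk.robinson_foulds(t, c) == 0

    def test_boundary_support_retained(self):
        t = tk.read_tree("((A:1,B:1)30:1,(C:1,D:1)29:1,E:1);")
        c = tk.collapse_nodes(t, 30)
        key = _topology_key(c)
        labels = frozenset("ABCDE")
        side_ab = labels - {"A", "B"}  # sides are stored without taxon A
        side_cd = frozenset({"C", "D"})
        assert side_ab in key  # support exactly 30 kept (strict <)
        assert side_cd not in key  # support 29 collapsed

    def test_collapse_count(self):
        t = tk.read_tree("(((A:1,B:1)10:1,(C:1,D:1)90:1)10:1,E:1,F:1);")
        before = len(_topology_key(t))
        after = len(_topology_key(tk.collapse_nodes(t, 30)))
        assert before - after == 2

    def test_every_surviving_edge_meets_threshold(self):
        t = tk.read_tree(
            "(((A:1,B:1)45:1,(C:1,D:1)12:1)88:1,(E:1,F:1)29:1,G:1);"
        )
        c = tk.collapse_nodes(t, 30)
        for nd in c.postorder_internal_node_iter():
            if nd is c.seed_node:
                continue
            assert tk.get_support(nd) >= 30

    def test_missing_support_warns_and_collapses(self):
        t = tk.read_tree("((A:1,B:1):1,(C:1,D:1)80:1,E:1);")
        with pytest.warns(UserWarning):
            c = tk.collapse_nodes(t, 30)
        assert len(_topology_key(c)) == 1


class TestRegraft:
    def test_pruned_leaf_candidate_count(self):
        # backbone of n=4 leaves has 2n-3 = 5 branches
        t = tk.read_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert len(tk.regraft_candidates(t, "E")) == 5

    @pytest.mark.parametrize("n_leaves", [5, 6, 7])
    def test_count_scales_with_backbone(self, n_leaves):
        # pruning a leaf from an (n+1)-leaf caterpillar leaves an n-leaf
        # backbone with 2n-3 attachment branches
        labels = [chr(65 + i) for i in range(n_leaves)]
        sub = f"({labels[0]}:1,{labels[1]}:1)"
        for l in labels[2:-1]:
            sub = f"({sub}:1,{l}:1)"
        t = tk.read_tree(f"({sub}:1,{labels[-1]}:1,Z:1);")
        cands = tk.regraft_candidates(t, "Z")
        assert len(cands) == 2 * n_leaves - 3

    def test_contains_original_once(self):
        t = tk.read_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        keys = [_topology_key(c) for c in tk.regraft_candidates(t, "E")]
        assert keys.count(_topology_key(t)) == 1

    def test_leaf_sets_conserved(self):
        t = tk.read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,E:1,F:1);")
        for cand in tk.regraft_candidates(t, {"C", "D"}):
            assert {lf.taxon.label for lf in cand.leaf_node_iter()} == set(
                "ABCDEF"
            )

    def test_non_clade_rejected(self):
        t = tk.read_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        with pytest.raises(ValueError):
            tk.regraft_candidates(t, {"A", "C"})


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = tk.read_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert tk.robinson_foulds(t, t) == 0

    def test_distinct_quartets(self):
        t1 = tk.read_tree("((A,B),(C,D));")
        t2 = tk.read_tree("((A,C),(B,D));")
        assert tk.robinson_foulds(t1, t2) == 2

    def test_symmetric(self):
        t1 = tk.read_tree("(((A,B),(C,D)),E,F);")
        t2 = tk.read_tree("(((A,C),(B,D)),E,F);")
        assert tk.robinson_foulds(t1, t2) == tk.robinson_foulds(t2, t1)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tk.robinson_foulds(
                tk.read_tree("((A,B),(C,D));"), tk.read_tree("((A,B),(C,E));")
            )


class TestSubstModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        for m in (tk.SubstModel(4), tk.SubstModel(20)):
            assert np.allclose(m.rate_matrix().sum(axis=1), 0.0)

    def test_transition_matrix_rows_sum_to_one(self):
        m = tk.SubstModel(4, gamma_shape=0.5)
        p = m.transition_matrix(0.37)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_custom_exchange_matches_poisson_when_uniform(self):
        k = 20
        ex = np.ones((k, k)) - np.eye(k)
        custom = tk.SubstModel(n_states=20, exchange=ex)
        poisson = tk.SubstModel(n_states=20)
        assert np.allclose(
            custom.transition_matrix(0.3), poisson.transition_matrix(0.3),
            atol=1e-10,
        )

    def test_category_rates_mean_one(self):
        m = tk.SubstModel(4, gamma_shape=0.3, n_rate_categories=4)
        assert m.category_rates().mean() == pytest.approx(1.0)
        assert len(m.category_rates()) == 4
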