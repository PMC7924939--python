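import itertools
import math

import numpy as np
import pytest

from carrierphylo.io_formats import (AMINO_ACIDS, Alignment, PhyloTree,
                                     SeqRecord, TreeNode, parse_newick)
from carrierphylo.phylo import (DistanceMatrix, PhyloError,
                                bootstrap_support, brute_force_loglik,
                                empirical_frequencies, free_rate_init,
                                lg_model, nj_builder, nj_tree, nni_search,
                                optimize_numeric, poisson_distance,
                                poisson_model, tree_loglik)


def make_aln(rows):
    return Alignment([SeqRecord(k, v) for k, v in rows.items()])


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        dm = poisson_distance(make_aln({"a": "ACDEF", "b": "ACDEF"}))
        assert dm.pair("a", "b") == 0.0

    def test_half_different_closed_form(self):
        dm = poisson_distance(make_aln({"a": "AACC", "b": "AAGG"}))
        assert dm.pair("a", "b") == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_pairwise_deletion_hand_count(self):
        # usable sites {1, 2, 4}; p = 2/3
        dm = poisson_distance(make_aln({"a": "AC-D", "b": "AG-E"}))
        assert dm.pair("a", "b") == pytest.approx(-math.log(1 / 3), abs=1e-12)

    def test_x_treated_as_missing(self):
        dm = poisson_distance(make_aln({"a": "AXCD", "b": "AACD"}))
        assert dm.pair("a", "b") == 0.0
        assert dm.n_usable[0, 1] == 3

    def test_no_usable_sites_is_error(self):
        with pytest.raises(PhyloError, match="a.*b|b.*a"):
            poisson_distance(make_aln({"a": "A--", "b": "-CC"}))

    def test_saturation_capped_and_flagged(self):
        dm = poisson_distance(make_aln({"a": "ACDEFGHIKLMNPQRSTVWY",
                                        "b": "CDEFGHIKLMNPQRSTVWYA"}))
        assert dm.pair("a", "b") == pytest.approx(-math.log(0.05))
        assert ("a", "b") in dm.saturated

    def test_column_order_invariance(self, rng):
        rows = {"a": "ACDEFGHIKL", "b": "ACDWFGHIKL", "c": "ACDEFGVIKL"}
        perm = rng.permutation(10)
        shuffled = {k: "".join(v[i] for i in perm) for k, v in rows.items()}
        d1 = poisson_distance(make_aln(rows))
        d2 = poisson_distance(make_aln(shuffled))
        assert np.allclose(d1.d, d2.d)


def path_distances(tree: PhyloTree):
    """Leaf-to-leaf path-length matrix of a tree with branch lengths."""
    leaves = tree.leaf_names()
    idx = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def depth_map(node, acc, out):
        if node.is_leaf:
            out[node.name] = acc
        for c in node.children:
            depth_map(c, acc + (c.length or 0.0), out)

    for node in tree.postorder():
        if node.is_leaf:
            continue
        for c1, c2 in itertools.combinations(node.children, 2):
            m1, m2 = {}, {}
            depth_map(c1, c1.length or 0.0, m1)
            depth_map(c2, c2.length or 0.0, m2)
            for l1, x in m1.items():
                for l2, y in m2.items():
                    d[idx[l1], idx[l2]] = d[idx[l2], idx[l1]] = x + y
    return leaves, d


def random_unrooted_tree(n, rng):
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(3)]
    root = TreeNode()
    for nd in nodes:
        root.add(nd)
    for i in range(3, n):
        leaves_and_internals = [x for x in root.postorder()
                                if x.parent is not None]
        target = leaves_and_internals[rng.integers(len(leaves_and_internals))]
        parent = target.parent
        mid = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        half = (target.length or 0.0) / 2
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(target)
        mid.length, target.length = half, half
        mid.add(TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 1.0))))
    return PhyloTree(root)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(ids, d, np.full((3, 3), 10)))
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_identical_taxa_zero_cherry(self):
        ids = ["A", "B", "C", "D"]
        d = np.array([[0.0, 0.0, 0.5, 0.5],
                      [0.0, 0.0, 0.5, 0.5],
                      [0.5, 0.5, 0.0, 0.4],
                      [0.5, 0.5, 0.4, 0.0]])
        tree = nj_tree(DistanceMatrix(ids, d, np.full((4, 4), 10)))
        a = tree.find_leaf("A")
        b = tree.find_leaf("B")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_additive_matrices_recovered_exactly(self, rng):
        """NJ is exact on additive distances: topology and branch lengths."""
        for _ in range(200):
            n = int(rng.integers(4, 11))
            true = random_unrooted_tree(n, rng)
            leaves, d = path_distances(true)
            est = nj_tree(DistanceMatrix(leaves, d,
                                         np.full((n, n), 100)))
            assert est.bipartitions() == true.bipartitions()
            _, d_est = path_distances(est)
            order = [est.leaf_names().index(l) for l in leaves]
            assert np.allclose(d_est[np.ix_(order, order)], d, atol=1e-9)

    def test_topology_agrees_with_independent_nj(self, rng):
        """Cross-check against scikit-bio's neighbor joining on noisy
        (non-additive) matrices: same unrooted topology."""
        import skbio

        for _ in range(20):
            n = int(rng.integers(4, 9))
            true = random_unrooted_tree(n, rng)
            leaves, d = path_distances(true)
            d = d + rng.uniform(0, 0.02, size=d.shape)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = nj_tree(DistanceMatrix(leaves, d, np.full((n, n), 100)))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=leaves))
            ref_bips = set()
            all_names = frozenset(leaves)
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                other = all_names - side
                if side and other:
                    ref_bips.add(min(side, other,
                                     key=lambda s: (len(s), sorted(s))))
            assert mine.bipartitions() <= ref_bips | {frozenset()}

    def test_asymmetric_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 1.0
        with pytest.raises(PhyloError):
            DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3)))


def random_tree_and_alignment(n_leaves, n_sites, rng, with_gaps=False):
    tree = random_unrooted_tree(n_leaves, rng)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.05, 0.8))
    aa = AMINO_ACIDS + ("-X" if with_gaps else "")
    rows = {l: "".join(rng.choice(list(aa), n_sites))
            for l in tree.leaf_names()}
    return tree, make_aln(rows)


class TestLikelihood:
    def test_matches_bruteforce_small_trees(self, rng):
        """Pruning equals exhaustive ancestral-state summation."""
        models = [poisson_model(), lg_model(), poisson_model(2)]
        for n_leaves, n_sites in ((3, 6), (4, 4), (5, 2)):
            tree, aln = random_tree_and_alignment(n_leaves, n_sites, rng,
                                                  with_gaps=True)
            for model in models:
                ll = tree_loglik(aln, tree, model)
                bf = brute_force_loglik(aln, tree, model)
                assert ll == pytest.approx(bf, abs=1e-8)

    def test_star_tree_zero_lengths_closed_form(self):
        model = poisson_model()
        aln = make_aln({"a": "AC", "b": "AC", "c": "AC"})
        root = TreeNode()
        for name in "abc":
            root.add(TreeNode(name=name, length=0.0))
        ll = tree_loglik(aln, PhyloTree(root), model)
        assert ll == pytest.approx(2 * math.log(1 / 20), abs=1e-10)

    def test_rerooting_invariance(self, rng):
        """Pulley principle: likelihood identical under any rooting."""
        tree, aln = random_tree_and_alignment(5, 8, rng)
        model = lg_model()
        ll0 = tree_loglik(aln, tree, model)
        for leaf in tree.leaves()[:3]:
            rerooted = tree.rooted_at_edge(leaf)
            assert tree_loglik(aln, rerooted, model) == \
                   pytest.approx(ll0, abs=1e-8)

    def test_zero_weight_category_no_effect(self, rng):
        tree, aln = random_tree_and_alignment(4, 6, rng)
        base = poisson_model()
        padded = base.with_rates(np.array([1.0, 7.0]), np.array([1.0, 0.0]))
        assert tree_loglik(aln, tree, padded) == \
               pytest.approx(tree_loglik(aln, tree, base), abs=1e-12)

    def test_leaf_row_mismatch_rejected(self, rng):
        tree, aln = random_tree_and_alignment(4, 4, rng)
        bad = make_aln({"nope": "ACDE", **{l: "ACDE"
                        for l in tree.leaf_names()[:3]}})
        with pytest.raises(PhyloError):
            tree_loglik(bad, tree, poisson_model())


class TestFreeRate:
    def test_init_mean_rate_one(self):
        for k in (2, 3, 7):
            rates, weights = free_rate_init(k)
            assert rates @ weights == pytest.approx(1.0, abs=1e-12)
            assert weights.sum() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_empirical_frequencies_sum_to_one(self, sim_truth):
        f = empirical_frequencies(sim_truth.alignment)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert (f > 0).all()


class TestOptimize:
    def test_already_at_optimum_stops_immediately(self, rng):
        tree, aln = random_tree_and_alignment(4, 50, rng)
        model = poisson_model()
        t1, m1, ll1 = optimize_numeric(aln, tree, model, tol=1e-4)
        t2, m2, ll2 = optimize_numeric(aln, t1, m1, tol=1e-4)
        assert ll2 - ll1 < 1e-3

    def test_single_category_matches_homogeneous(self, rng):
        tree, aln = random_tree_and_alignment(4, 30, rng)
        k1 = poisson_model(1)
        assert tree_loglik(aln, tree, k1) == \
               pytest.approx(tree_loglik(aln, tree, poisson_model()),
                             abs=1e-12)

    def test_two_taxon_distance_recovery(self):
        """ML branch length close to the simulated Poisson distance."""
        rng = np.random.default_rng(3)
        model = poisson_model()
        n, true_d = 5000, 0.4
        root = rng.choice(20, size=n, p=model.frequencies)
        cum = np.cumsum(model.transition(true_d), axis=1)
        child = (rng.random(n)[:, None] > cum[root]).sum(1)
        aa = np.array(list(AMINO_ACIDS))
        aln = make_aln({"x": "".join(aa[root]), "y": "".join(aa[child])})
        tree = parse_newick("(x:0.1,y:0.1);")
        opt_tree, _, _ = optimize_numeric(aln, tree, model)
        total = sum(nd.length for nd in opt_tree.postorder()
                    if nd.parent is not None)
        assert total == pytest.approx(true_d, rel=0.15)


class TestNNI:
    @staticmethod
    def _sim_alignment(tree, n_sites, seed):
        rng = np.random.default_rng(seed)
        model = poisson_model()
        seqs = {}
        root_seq = rng.choice(20, size=n_sites, p=model.frequencies)
        state = {id(tree.root): root_seq}
        for node in tree.preorder():
            if node.parent is None:
                continue
            p = model.transition(node.length or 0.0)
            cum = np.cumsum(p, axis=1)
            parent = state[id(node.parent)]
            child = (rng.random(n_sites)[:, None] > cum[parent]).sum(1)
            state[id(node)] = child
            if node.is_leaf:
                seqs[node.name] = child
        aa = np.array(list(AMINO_ACIDS))
        return make_aln({k: "".join(aa[v]) for k, v in seqs.items()})

    def test_true_topology_is_local_optimum(self):
        true = parse_newick("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3,E:0.4);")
        aln = self._sim_alignment(true, 2000, seed=11)
        model = poisson_model()
        improved, ll = nni_search(aln, true, model)
        assert improved.bipartitions() == true.bipartitions()

    def test_perturbed_topology_restored(self):
        true = parse_newick("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3,E:0.4);")
        aln = self._sim_alignment(true, 2000, seed=11)
        # one NNI away: swap B and C
        wrong = parse_newick("((A:0.2,C:0.2):0.3,(B:0.2,D:0.2):0.3,E:0.4);")
        model = poisson_model()
        improved, ll = nni_search(aln, wrong, model)
        assert improved.bipartitions() == true.bipartitions()
        assert ll > tree_loglik(aln, wrong, model)


class TestBootstrap:
    def test_same_seed_identical_supports(self, sim_truth):
        rows = sorted(sim_truth.sequences)[:8]
        aln = sim_truth.alignment.subset(rows).drop_allgap_columns()
        t1 = bootstrap_support(aln, nj_builder, B=20, seed=4)
        t2 = bootstrap_support(aln, nj_builder, B=20, seed=4)
        s1 = {frozenset(n.leaf_names()): n.support for n in t1.postorder()
              if not n.is_leaf and n is not t1.root}
        s2 = {frozenset(n.leaf_names()): n.support for n in t2.postorder()
              if not n.is_leaf and n is not t2.root}
        assert s1 == s2

    def test_identical_sequences_complete_without_error(self):
        aln = make_aln({c: "ACDEFGHIKL" for c in "abcd"})
        tree = bootstrap_support(aln, nj_builder, B=5, seed=1)
        for n in tree.postorder():
            if not n.is_leaf and n is not tree.root:
                assert n.support is not None

    def test_zero_replicates_rejected(self):
        aln = make_aln({c: "ACDEFGHIKL" for c in "abc"})
        with pytest.raises(PhyloError):
            bootstrap_support(aln, nj_builder, B=0, seed=1)
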