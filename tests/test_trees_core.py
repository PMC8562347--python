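"""Species/gene tree structures, Newick I/O, MRCA, compatibility,
labeled-history counting."""

import itertools

import numpy as np
import pytest

from msctree.simulator import simulate_gene_tree
from msctree.trees_core import (GeneTree, TreeError,
                                count_labeled_histories, enumerate_topologies,
                                is_compatible, mrca, n_rooted_topologies,
                                parse_newick, random_topology_newick,
                                write_newick)


class TestNewick:
    def test_ages_from_branch_lengths(self):
        S = parse_newick("((A:1,B:1):1,C:2);")
        ab = mrca(S, 0, 1)
        assert S.tau[ab] == pytest.approx(1.0)
        assert S.tau[S.root] == pytest.approx(2.0)
        assert S.s == 3

    def test_non_binary_rejected(self):
        with pytest.raises(TreeError, match="non-binary"):
            parse_newick("(A:1,B:1,C:1);")

    def test_non_ultrametric_rejected_names_tips(self):
        with pytest.raises(TreeError, match="A.*C|C.*A"):
            parse_newick("((A:1,B:1):1,C:5);")

    def test_roundtrip_random_trees(self, rng):
        for _ in range(100):
            s = int(rng.integers(5, 9))
            labels = [f"T{i}" for i in range(s)]
            nwk = random_topology_newick(labels, rng)
            S = parse_newick(nwk, ages_from_branch_lengths=False)
            out = write_newick(S)
            assert parse_newick(out).topology_key() == S.topology_key()

    def test_canonical_form_invariant_to_child_order(self):
        a = parse_newick("((A:1,B:1):1,C:2);")
        b = parse_newick("(C:2,(B:1,A:1):1);")
        assert a.topology_key() == b.topology_key()

    def test_agrees_with_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        for seed in range(20):
            r = np.random.default_rng(seed)
            nwk = random_topology_newick(list("ABCDEF"), r)
            S = parse_newick(nwk, ages_from_branch_lengths=False)
            t = dendropy.Tree.get(data=nwk, schema="newick")
            # same set of clades (topology identity through a second parser)
            ours = {frozenset(S.labels[x] for x in S.clade_tips(v))
                    for v in range(S.s, S.n_nodes)}
            theirs = {frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
                      for nd in t.preorder_internal_node_iter()}
            assert ours == theirs


class TestMrca:
    def test_examples(self, tree3):
        a, b, c = 0, 1, 2
        assert mrca(tree3, a, b) != tree3.root
        assert mrca(tree3, a, c) == tree3.root

    def test_against_ancestor_set_intersection(self, rng):
        for _ in range(100):
            s = int(rng.integers(4, 9))
            S = parse_newick(
                random_topology_newick([f"T{i}" for i in range(s)], rng),
                ages_from_branch_lengths=False)
            u, v = rng.choice(S.n_nodes, size=2, replace=False)
            anc_u = set([int(u)] + S.ancestors(int(u)))
            anc_v = set([int(v)] + S.ancestors(int(v)))
            best = min(anc_u & anc_v, key=lambda x: S.tau[x])
            assert mrca(S, int(u), int(v)) == best


class TestCompatibility:
    def test_coalescence_before_divergence_is_incompatible(self, tree3):
        # a-b coalescing at 0.003 < tau_AB = 0.004 would split sequences
        # after the species split
        G = GeneTree(["a^A", "b^B"], np.array([0, 1]),
                     np.array([2, 2, -1]), np.array([[-1, -1], [-1, -1],
                                                     [0, 1]]),
                     np.array([0.0, 0.0, 0.003]))
        assert not is_compatible(G, tree3)
        G.age[2] = 0.005
        assert is_compatible(G, tree3)

    def test_simulated_gene_trees_always_compatible(self, tree5, rng):
        for _ in range(50):
            G = simulate_gene_tree(tree5, 2, rng)
            assert is_compatible(G, tree5)

    def test_invariant_under_child_swap(self, tree3, rng):
        G = simulate_gene_tree(tree3, 2, rng)
        v = int(rng.integers(G.n_tips, G.n_nodes))
        G.children[v] = G.children[v][::-1]
        assert is_compatible(G, tree3)


class TestLabeledHistories:
    def brute_force(self, S):
        internals = [v for v in range(S.s, S.n_nodes)]
        count = 0
        for perm in itertools.permutations(internals):
            rank = {v: i for i, v in enumerate(perm)}
            ok = all(rank[v] > rank[p] for v in internals
                     for p in [int(S.parent[v])] if p >= 0)
            count += ok
        return count

    @pytest.mark.parametrize("nwk,expected", [
        ("(((A,B),C),D);", 1),      # caterpillar
        ("((A,B),(C,D));", 2),      # balanced
    ])
    def test_four_taxon(self, nwk, expected):
        S = parse_newick(nwk, ages_from_branch_lengths=False)
        assert count_labeled_histories(S) == expected
        assert self.brute_force(S) == expected

    def test_caterpillar_always_one(self, rng):
        for s in (5, 8, 12):
            nwk = "A"
            for i in range(1, s):
                nwk = f"({nwk},T{i})"
            S = parse_newick(nwk + ";", ages_from_branch_lengths=False)
            assert count_labeled_histories(S) == 1

    def test_sum_over_all_five_taxon_topologies(self):
        keys = enumerate_topologies(list("ABCDE"))
        assert len(keys) == 105 == n_rooted_topologies(5)
        total = sum(count_labeled_histories(
            parse_newick(k, ages_from_branch_lengths=False)) for k in keys)
        assert total == 180   # prod_{k=2..5} C(k,2)

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(20):
            s = int(rng.integers(4, 7))
            S = parse_newick(
                random_topology_newick([f"T{i}" for i in range(s)], rng),
                ages_from_branch_lengths=False)
            assert count_labeled_histories(S) == self.brute_force(S)


class TestStructure:
    def test_internal_branch_count(self, rng):
        for s in (3, 5, 9):
            S = parse_newick(
                random_topology_newick([f"T{i}" for i in range(s)], rng),
                ages_from_branch_lengths=False)
            assert len(S.internal_branches()) == s - 2

    def test_random_topology_is_uniform(self, rng):
        from collections import Counter
        keys = enumerate_topologies(list("ABCD"))
        n = 6000
        cnt = Counter(
            parse_newick(random_topology_newick(list("ABCD"), rng),
                         ages_from_branch_lengths=False).topology_key()
            for _ in range(n))
        p = 1 / 15
        se = (p * (1 - p) / n) ** 0.5
        for k in keys:
            assert abs(cnt[k] / n - p) < 3.5 * se
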