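"""Distances, neighbor joining, bootstrap, Newick round-trip."""
import math

import numpy as np
import pytest

from cansynth import (
    SequenceRecord,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    write_newick,
)
from cansynth.phylo import DistanceError, DistanceMatrix, _bipartitions
from cansynth.simulate import _random_cds

from _oracles import random_additive_matrix, tree_path_distances


def _dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.full(d.shape, 100, dtype=int))


class TestDistances:
    def test_identical_sequences_have_zero_distance(self, rng):
        s = "".join(_random_cds(rng, 300))
        recs = [SequenceRecord(f"s{i}", s) for i in range(3)]
        for model in ("p-distance", "JC69", "TN93"):
            assert np.allclose(pairwise_distance(recs, model).d, 0.0)

    def test_p_distance_matches_counting(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = list(a)
        for i in range(0, 40):
            b[i * 10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i * 10]]
        recs = [SequenceRecord("a", a), SequenceRecord("b", "".join(b)),
                SequenceRecord("c", a)]
        dm = pairwise_distance(recs, "p-distance")
        assert abs(dm.d[0, 1] - 40 / 400) < 1e-12

    def test_tn93_reduces_to_jc69_in_the_symmetric_limit(self):
        # equal base frequencies, balanced substitution pattern: P1 = P2 = p/6
        base = ("A" * 75 + "C" * 75 + "G" * 75 + "T" * 75) * 2
        b = list(base)
        pools = {x: [i for i, c in enumerate(base) if c == x] for x in "ACGT"}
        swaps = [  # (from, to, how many): 4 of each transition, 2 of each transversion
            ("A", "G", 2), ("G", "A", 2), ("C", "T", 2), ("T", "C", 2),
            ("A", "C", 2), ("C", "A", 2), ("A", "T", 2), ("T", "A", 2),
            ("G", "C", 2), ("C", "G", 2), ("G", "T", 2), ("T", "G", 2),
        ]
        used = {x: 0 for x in "ACGT"}
        for src, dst, k in swaps:
            for _ in range(k):
                b[pools[src][used[src]]] = dst
                used[src] += 1
        recs = [SequenceRecord("x", base), SequenceRecord("y", "".join(b)),
                SequenceRecord("z", base)]
        tn = pairwise_distance(recs, "TN93").d[0, 1]
        jc = pairwise_distance(recs, "JC69").d[0, 1]
        assert abs(tn - jc) < 1e-9

    def test_pairwise_deletion_counts_retained_sites(self, rng):
        s = "".join(_random_cds(rng, 300))
        with_n = "N" * 10 + s[10:]
        recs = [SequenceRecord("a", s), SequenceRecord("b", with_n),
                SequenceRecord("c", s)]
        dm = pairwise_distance(recs, "p-distance")
        assert dm.sites_used[0, 1] == 290

    def test_saturation_raises_naming_the_pair(self):
        a = "A" * 90
        b = "C" * 90
        recs = [SequenceRecord("sat1", a), SequenceRecord("sat2", b),
                SequenceRecord("sat3", a)]
        with pytest.raises(DistanceError, match="sat"):
            pairwise_distance(recs, "JC69")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        tree = neighbor_joining(_dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]))
        lengths = {n.name: n.branch_length for n in tree.root.children}
        assert abs(lengths["A"] - 0.2) < 1e-12
        assert abs(lengths["B"] - 0.1) < 1e-12
        assert abs(lengths["C"] - 0.3) < 1e-12
        assert abs(tree.total_branch_length() - (0.3 + 0.5 + 0.4) / 2) < 1e-12

    def test_exact_on_random_additive_matrices(self):
        # 100 random 6-taxon additive matrices: path distances reproduced < 1e-9
        rng = np.random.default_rng(2024)
        max_err = 0.0
        for _ in range(100):
            D = random_additive_matrix(6, rng)
            ids = [f"T{i}" for i in range(6)]
            tree = neighbor_joining(_dm(ids, D))
            paths = tree_path_distances(tree)
            for i in range(6):
                for j in range(6):
                    max_err = max(max_err, abs(paths[(f"T{i}", f"T{j}")] - D[i, j]))
        assert max_err < 1e-9

    def test_matches_scikit_bio_on_an_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        D = random_additive_matrix(8, rng)
        ids = [f"T{i}" for i in range(8)]
        ours = neighbor_joining(_dm(ids, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        ours_paths = tree_path_distances(ours)
        for i in range(8):
            for j in range(8):
                theirs_d = theirs.find(f"T{i}").distance(theirs.find(f"T{j}"))
                assert abs(ours_paths[(f"T{i}", f"T{j}")] - theirs_d) < 1e-6

    def test_equal_distances_resolved_reproducibly(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        t1 = write_newick(neighbor_joining(_dm("ABCD", d)))
        t2 = write_newick(neighbor_joining(_dm("ABCD", d)))
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm("AB", [[0, 1], [1, 0]]))


class TestBootstrap:
    def _two_clades(self, rng):
        anc = _random_cds(rng, 300)

        def mutate(base, positions):
            s = list(base)
            for p in positions:
                s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
            return "".join(s)

        base = "".join(anc)
        clade_a = [SequenceRecord(f"a{i}", mutate(base, [10 + i])) for i in range(3)]
        other = mutate(base, list(range(30, 90)))
        clade_b = [SequenceRecord(f"b{i}", mutate(other, [120 + i])) for i in range(3)]
        return clade_a + clade_b

    def test_separating_edge_gets_high_support(self, rng):
        aln = self._two_clades(rng)
        tree = bootstrap_support(aln, n_reps=200, seed=11)
        bips = _bipartitions(tree, positive_only=False)
        split = frozenset(["a0", "a1", "a2"])
        target = bips.get(split) or bips.get(frozenset(["b0", "b1", "b2"]))
        assert target is not None and target.support >= 99.0

    def test_supports_bounded_and_deterministic(self, rng):
        aln = self._two_clades(rng)
        t1 = bootstrap_support(aln, n_reps=50, seed=3)
        t2 = bootstrap_support(aln, n_reps=50, seed=3)
        assert write_newick(t1) == write_newick(t2)

        def supports(node):
            out = [] if node.support is None else [node.support]
            for c in node.children:
                out += supports(c)
            return out

        assert all(0.0 <= s <= 100.0 for s in supports(t1.root))

    def test_collapse_is_monotone(self, rng):
        aln = self._two_clades(rng)

        def n_internal(tree):
            count = 0
            stack = list(tree.root.children)
            while stack:
                n = stack.pop()
                if not n.is_leaf:
                    count += 1
                stack.extend(n.children)
            return count

        loose = bootstrap_support(aln, n_reps=50, collapse_below=0.0, seed=9)
        strict = bootstrap_support(aln, n_reps=50, collapse_below=90.0, seed=9)
        assert n_internal(strict) <= n_internal(loose)

    def test_identical_sequences_collapse_to_star(self, rng):
        s = "".join(_random_cds(rng, 150))
        aln = [SequenceRecord(f"s{i}", s) for i in range(5)]
        tree = bootstrap_support(aln, n_reps=20, seed=2)
        assert len(tree.root.children) == 5
        assert all(c.is_leaf for c in tree.root.children)

    def test_zero_replicates_rejected(self, rng):
        aln = self._two_clades(rng)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0, seed=1)


class TestNewick:
    def test_roundtrip_topology_lengths_supports(self, rng):
        aln = TestBootstrap()._two_clades(rng)
        tree = bootstrap_support(aln, n_reps=20, seed=4)
        text = write_newick(tree)
        back = parse_newick(text)
        assert write_newick(back) == text
        assert sorted(back.leaf_names()) == sorted(tree.leaf_names())

    def test_polytomy_emitted_and_parsed(self, rng):
        s = "".join(_random_cds(rng, 90))
        aln = [SequenceRecord(f"s{i}", s) for i in range(4)]
        tree = bootstrap_support(aln, n_reps=5, seed=1)
        text = write_newick(tree)
        assert text.count(",") == 3  # 4-leaf star: one node, three commas
        assert len(parse_newick(text).root.children) == 4

    def test_dendropy_parses_our_output(self):
        dendropy = pytest.importorskip("dendropy")
        tree = neighbor_joining(
            _dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        )
        text = write_newick(tree)
        dtree = dendropy.Tree.get(data=text, schema="newick")
        assert {leaf.taxon.label for leaf in dtree.leaf_node_iter()} == {"A", "B", "C"}
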