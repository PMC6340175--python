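"""Dollo parsimony scoring and search, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from retrophylo import consistency_index, dollo_score, dollo_search
from retrophylo.dollo import (
    canonical,
    dollo_steps_per_character,
    from_dendropy,
    nni_neighbors,
    spr_neighbors,
    to_dendropy,
)
from retrophylo.matrix import PresenceAbsenceMatrix


# ---------------------------------------------------------------------------
# oracle: exhaustive minimisation over all Dollo-valid node labelings
# ---------------------------------------------------------------------------

def _edges_and_leaves(tree):
    """Flatten a tuple tree: list of (child, parent) index edges; leaf map."""
    edges, leaf_of = [], {}
    counter = itertools.count()

    def rec(node):
        idx = next(counter)
        if isinstance(node, (int, np.integer)):
            leaf_of[idx] = int(node)
        else:
            for c in node:
                cidx = rec(c)
                edges.append((cidx, idx))
        return idx

    root = rec(tree)
    n_nodes = next(counter)
    return edges, leaf_of, root, n_nodes


def oracle_dollo_steps(tree, column):
    """Minimum changes over all labelings with at most one 0->1 transition.

    The root hangs off a virtual all-absent ancestor, so a gain on the root
    edge is allowed.  Missing leaves are free.
    """
    edges, leaf_of, root, n_nodes = _edges_and_leaves(tree)
    free = [
        i for i in range(n_nodes)
        if i not in leaf_of or column[leaf_of[i]] == -1
    ]
    fixed = {i: int(column[leaf_of[i]]) for i in leaf_of if column[leaf_of[i]] != -1}
    best = None
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, bits))
        gains = int(state[root] == 1)  # virtual ancestor is 0
        changes = gains
        for c, p in edges:
            if state[c] != state[p]:
                changes += 1
                if state[c] == 1:
                    gains += 1
        if gains <= 1 and (best is None or changes < best):
            best = changes
    return best


def random_tree(rng, n_leaves):
    tree = (0, 1)
    for leaf in range(2, n_leaves):
        # insert at a random position: collect all insertion variants
        variants = _all_insertions(tree, leaf)
        tree = variants[rng.integers(len(variants))]
    return tree


def _all_insertions(tree, leaf):
    out = [(tree, leaf)]

    def rec(node):
        res = [(node, leaf)]
        if isinstance(node, tuple):
            for i, c in enumerate(node):
                for v in rec(c):
                    res.append(node[:i] + (v,) + node[i + 1:])
        return res

    if isinstance(tree, tuple):
        for i, c in enumerate(tree):
            for v in rec(c):
                out.append(tree[:i] + (v,) + tree[i + 1:])
    return out


def all_rooted_trees(n_leaves):
    trees = [(0, 1)]
    for leaf in range(2, n_leaves):
        trees = [t for base in trees for t in _all_insertions(base, leaf)]
    return trees


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestDolloScore:
    TREE = ((0, 1), (2, 3))  # ((A,B),(C,D))

    def score_one(self, column):
        states = np.array(column, dtype=np.int8).reshape(-1, 1)
        return int(dollo_steps_per_character(self.TREE, states)[0])

    def test_clade_character_is_single_gain(self):
        assert self.score_one([1, 1, 0, 0]) == 1

    def test_conflicting_character_needs_two_losses(self):
        # present in A and C: gain at the root, losses on B and D
        assert self.score_one([1, 0, 1, 0]) == 3

    def test_all_present_single_origin_on_root_edge(self):
        assert self.score_one([1, 1, 1, 1]) == 1

    def test_missing_states_are_free(self):
        assert self.score_one([1, -1, 0, 0]) == 1
        assert self.score_one([1, -1, 1, 0]) == 2  # C..A gain, D loss

    def test_taxon_not_in_tree_raises(self, quartet_matrix):
        with pytest.raises(ValueError, match="D"):
            dollo_score(((0, 1), 2), quartet_matrix)

    def test_score_invariant_under_child_rotation(self, quartet_matrix):
        a = dollo_score(((0, 1), (2, 3)), quartet_matrix).total_steps
        b = dollo_score(((3, 2), (1, 0)), quartet_matrix).total_steps
        assert a == b

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(4, 7))
            tree = random_tree(rng, n)
            states = rng.choice(
                [0, 1, -1], size=(n, 8), p=[0.45, 0.45, 0.1]
            ).astype(np.int8)
            got = dollo_steps_per_character(tree, states)
            want = [oracle_dollo_steps(tree, states[:, j]) for j in range(8)]
            assert got.tolist() == want


class TestConsistencyIndex:
    def test_hand_computed_quartet(self, quartet_matrix):
        # steps 1 + 1 + 3 = 5, minima 3 -> CI = 0.6
        assert consistency_index(((0, 1), (2, 3)), quartet_matrix) == pytest.approx(0.6)

    def test_ci_is_one_without_conflict(self, conflict_free_truth):
        m = conflict_free_truth.matrix.drop_absent_columns()
        tree, _ = dollo_search(m, n_addition_reps=3, seed=0)
        assert consistency_index(tree, m) == pytest.approx(1.0)

    def test_scale_free_under_character_duplication(self, quartet_matrix):
        m = quartet_matrix
        doubled = PresenceAbsenceMatrix(
            taxa=m.taxa,
            loci_ids=m.loci_ids + [l + "b" for l in m.loci_ids],
            states=np.hstack([m.states, m.states]),
        )
        t = ((0, 1), (2, 3))
        assert consistency_index(t, m) == pytest.approx(consistency_index(t, doubled))

    def test_no_variable_characters_raises(self):
        m = PresenceAbsenceMatrix(
            taxa=["a", "b"], loci_ids=[], states=np.empty((2, 0), dtype=np.int8)
        )
        with pytest.raises(ValueError):
            consistency_index((0, 1), m)


class TestDolloSearch:
    def make_five_taxon_matrix(self, seed):
        rng = np.random.default_rng(seed)
        return PresenceAbsenceMatrix(
            taxa=list("ABCDE"),
            loci_ids=[f"l{j}" for j in range(12)],
            states=rng.choice([0, 1], size=(5, 12)).astype(np.int8),
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_enumeration_on_five_taxa(self, seed):
        m = self.make_five_taxon_matrix(seed)
        best_exhaustive = min(
            int(dollo_steps_per_character(t, m.states).sum())
            for t in all_rooted_trees(5)
        )
        _, score = dollo_search(m, n_addition_reps=10, seed=0, swap="spr")
        assert score.total_steps == best_exhaustive

    def test_recovers_generating_topology(self, conflict_free_truth):
        from retrophylo.trees import unrooted_splits

        m = conflict_free_truth.matrix.drop_absent_columns()
        tree, score = dollo_search(m, n_addition_reps=5, seed=7)
        splits = unrooted_splits(tree, m.taxa)
        # generating topology as splits over the sampled individuals,
        # canonicalised to the side away from the reference taxon
        full = set(m.taxa)
        ref = m.taxa[0]
        expect = [
            {"blue_0", "sei_0"},
            {"fin_0", "humpback_0"},
            {"gray_0", "fin_0", "humpback_0"},
            {"blue_0", "sei_0", "gray_0", "fin_0", "humpback_0"},
            {"blue_0", "sei_0", "gray_0", "fin_0", "humpback_0", "minke_0"},
        ]
        for e in expect:
            side = frozenset(full - e if ref in e else e)
            assert side in splits
        # every character fits perfectly
        assert score.total_steps == score.min_steps

    def test_same_seed_same_result(self, quartet_matrix):
        m = self.make_five_taxon_matrix(9)
        t1, s1 = dollo_search(m, n_addition_reps=4, seed=5)
        t2, s2 = dollo_search(m, n_addition_reps=4, seed=5)
        assert s1.total_steps == s2.total_steps
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_outgroup_fixed_at_root(self):
        m = self.make_five_taxon_matrix(4)
        tree, _ = dollo_search(m, n_addition_reps=4, seed=1, outgroup="E")
        root_children = tree.seed_node.child_nodes()
        labels = [c.taxon.label if c.taxon else None for c in root_children]
        assert "E" in labels

    def test_too_few_taxa_raises(self, quartet_matrix):
        m = quartet_matrix.select_taxa(["A", "B", "C"])
        with pytest.raises(ValueError):
            dollo_search(m)


class TestNeighbourhoods:
    def test_nni_preserves_leaf_set(self):
        tree = ((0, (1, 2)), (3, 4))
        from retrophylo.dollo import tree_leaves

        for t in nni_neighbors(tree):
            assert sorted(tree_leaves(t)) == [0, 1, 2, 3, 4]

    def test_spr_contains_nni_topologies(self):
        tree = ((0, 1), (2, (3, 4)))
        nni = {canonical(t) for t in nni_neighbors(tree)}
        spr = {canonical(t) for t in spr_neighbors(tree)}
        assert nni <= spr

    def test_dendropy_roundtrip(self, quartet_matrix):
        tree = ((0, 1), (2, 3))
        d = to_dendropy(tree, quartet_matrix.taxa)
        assert canonical(from_dendropy(d, quartet_matrix.taxa)) == canonical(tree)
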