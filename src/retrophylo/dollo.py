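"""Dollo parsimony for insertion presence-absence characters.

Retroposon insertions are effectively homoplasy-free on the gain side: an
element integrates at a given genomic site once (0 -> 1), while precise
excision is essentially impossible; apparent absences inside a carrier clade
must be explained by losses (deletion of the locus, or lineage sorting when
viewed at the species level).  Dollo parsimony encodes exactly this: each
character is allowed a single gain and any number of losses.

For a rooted tree whose root is constrained to the all-absent ancestral
state, the minimal Dollo length of a character is

    steps = 1 (gain at the MRCA of the present leaves)
          + number of maximal all-absent subtrees inside that gain clade.

Missing states are free: they are resolved to whichever value minimises the
number of losses.  The implementation below computes this in vectorised form
across all characters at once, so trees with tens of leaves and tens of
thousands of characters score in milliseconds.

Trees are manipulated internally as nested tuples (leaf = taxon index,
internal node = tuple of children); conversion helpers to and from dendropy
trees live at the bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .matrix import PresenceAbsenceMatrix

TupleTree = int | tuple


@dataclass
class ParsimonyScore:
    """Dollo tree length and its per-character decomposition."""

    total_steps: int
    per_character_steps: np.ndarray
    min_steps: int

    def __post_init__(self) -> None:
        self.per_character_steps = np.asarray(self.per_character_steps, dtype=np.int64)
        if self.total_steps < self.min_steps:
            raise ValueError("total steps below the per-character minimum sum")


# ---------------------------------------------------------------------------
# tuple-tree plumbing
# ---------------------------------------------------------------------------

def _flatten(tree: TupleTree):
    """Postorder node list: (children_index_lists, leaf_taxon_or_-1, root_index)."""
    children: list[list[int]] = []
    leaf_taxon: list[int] = []

    def rec(node: TupleTree) -> int:
        if isinstance(node, (int, np.integer)):
            children.append([])
            leaf_taxon.append(int(node))
            return len(children) - 1
        idx = [rec(c) for c in node]
        children.append(idx)
        leaf_taxon.append(-1)
        return len(children) - 1

    root = rec(tree)
    return children, leaf_taxon, root


def tree_leaves(tree: TupleTree) -> list[int]:
    if isinstance(tree, (int, np.integer)):
        return [int(tree)]
    out: list[int] = []
    for c in tree:
        out.extend(tree_leaves(c))
    return out


def canonical(tree: TupleTree):
    """Order-independent canonical form of a rooted tuple tree."""
    if isinstance(tree, (int, np.integer)):
        return (int(tree),)
    return tuple(sorted((canonical(c) for c in tree), key=repr))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def dollo_steps_per_character(tree: TupleTree, states: np.ndarray) -> np.ndarray:
    """Vectorised Dollo steps for every character (column of *states*).

    *states* is the (taxa x loci) array with values {0, 1, -1}; leaf integers
    in *tree* index its rows.  Characters with no definite presence score 0.
    """
    children, leaf_taxon, root = _flatten(tree)
    n_nodes, n_loci = len(children), states.shape[1]
    has_p = np.zeros((n_nodes, n_loci), dtype=bool)
    has_a = np.zeros((n_nodes, n_loci), dtype=bool)
    n_pres_children = np.zeros((n_nodes, n_loci), dtype=np.int16)
    loss_children = np.zeros((n_nodes, n_loci), dtype=np.int16)

    for v in range(n_nodes):  # postorder by construction
        if not children[v]:
            has_p[v] = states[leaf_taxon[v]] == 1
            has_a[v] = states[leaf_taxon[v]] == 0
        else:
            for c in children[v]:
                has_p[v] |= has_p[c]
                has_a[v] |= has_a[c]
                n_pres_children[v] += has_p[c]
                loss_children[v] += ~has_p[c] & has_a[c]

    # losses counted at every presence-bearing node ...
    s_all = (has_p * loss_children).sum(axis=0)
    # ... minus those on the chain of strict ancestors of the gain MRCA
    anc = np.zeros((n_nodes, n_loci), dtype=bool)
    anc[root] = n_pres_children[root] == 1
    s_chain = (anc[root] * loss_children[root]).astype(np.int64)
    for v in range(n_nodes - 1, -1, -1):  # preorder = reversed postorder
        for c in children[v]:
            if children[c]:
                anc[c] = anc[v] & has_p[c] & (n_pres_children[c] == 1)
                s_chain += anc[c] * loss_children[c]
    return np.where(has_p[root], 1 + s_all.astype(np.int64) - s_chain, 0)


def dollo_score(tree, matrix: PresenceAbsenceMatrix) -> ParsimonyScore:
    """Score a rooted tree (dendropy or tuple form) under Dollo parsimony.

    The root is implicitly preceded by an all-absent ancestor, so a character
    present in every leaf still costs one gain (on the root edge).
    """
    ttree = tree if not isinstance(tree, dendropy.Tree) else from_dendropy(tree, matrix.taxa)
    leaves = tree_leaves(ttree)
    if sorted(leaves) != list(range(matrix.n_taxa)):
        missing = set(range(matrix.n_taxa)) - set(leaves)
        raise ValueError(
            "tree leaves do not cover the matrix taxa; missing: "
            + ", ".join(matrix.taxa[i] for i in sorted(missing))
        )
    steps = dollo_steps_per_character(ttree, matrix.states)
    min_steps = int((steps > 0).sum())  # one gain per observed character
    return ParsimonyScore(
        total_steps=int(steps.sum()), per_character_steps=steps, min_steps=min_steps
    )


def consistency_index(
    tree, matrix: PresenceAbsenceMatrix, include_all_present: bool = True
) -> float:
    """Consistency index CI = (sum of per-character minima) / tree length.

    CI is 1.0 when every character fits the tree with a single gain; conflict
    (characters needing losses) drives it below 1.  ``include_all_present``
    controls whether invariant all-present characters (which always score
    1/1) enter the ratio; excluding them lowers CI.
    """
    score = dollo_score(tree, matrix)
    steps = score.per_character_steps
    observed = steps > 0
    if not include_all_present:
        variable = observed & (matrix.states == 0).any(axis=0)
        steps = steps[variable]
        observed = observed[variable]
    total = int(steps.sum())
    if total == 0:
        raise ValueError("no variable characters: CI undefined")
    return float(observed.sum() / total)


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

def _insertions(tree: TupleTree, leaf: int) -> list[TupleTree]:
    """All trees obtained by attaching *leaf* on any edge of *tree* or above its root."""
    out: list[TupleTree] = [(tree, leaf)]

    def rec(node: TupleTree):
        if isinstance(node, (int, np.integer)):
            return [(int(node), leaf)]
        variants: list[TupleTree] = []
        for i, child in enumerate(node):
            for v in rec(child):
                variants.append(tuple(node[:i]) + (v,) + tuple(node[i + 1 :]))
        variants.append((node, leaf))
        return variants

    if not isinstance(tree, (int, np.integer)):
        for i, child in enumerate(tree):
            for v in rec(child):
                out.append(tuple(tree[:i]) + (v,) + tuple(tree[i + 1 :]))
    return out


def nni_neighbors(tree: TupleTree) -> list[TupleTree]:
    """Rooted NNI: for each internal edge, swap a grandchild with its uncle."""
    def neighbors(node: TupleTree) -> list[TupleTree]:
        if isinstance(node, (int, np.integer)):
            return []
        res: list[TupleTree] = []
        for i, child in enumerate(node):
            # recurse
            for v in neighbors(child):
                res.append(tuple(node[:i]) + (v,) + tuple(node[i + 1 :]))
            # NNI across the edge node-child
            if isinstance(child, tuple):
                other_idx = [j for j in range(len(node)) if j != i]
                for gi in range(len(child)):
                    for j in other_idx:
                        new_child = tuple(
                            node[j] if k == gi else child[k] for k in range(len(child))
                        )
                        pieces = []
                        for k in range(len(node)):
                            if k == i:
                                pieces.append(new_child)
                            elif k == j:
                                pieces.append(child[gi])
                            else:
                                pieces.append(node[k])
                        res.append(tuple(pieces))
        return res

    return neighbors(tree)


def _prune(tree: TupleTree, target) -> tuple | None:
    """Remove subtree equal to *target* (by identity of structure), suppress unary nodes."""
    if tree == target:
        return None
    if isinstance(tree, (int, np.integer)):
        return tree
    kept = []
    for child in tree:
        p = _prune(child, target)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def _subtrees(tree: TupleTree) -> list[TupleTree]:
    if isinstance(tree, (int, np.integer)):
        return [tree]
    out: list[TupleTree] = [tree]
    for c in tree:
        out.extend(_subtrees(c))
    return out


def _regraft_positions(tree: TupleTree, sub: TupleTree) -> list[TupleTree]:
    out: list[TupleTree] = [(tree, sub)]

    def rec(node: TupleTree) -> list[TupleTree]:
        variants: list[TupleTree] = [(node, sub)]
        if isinstance(node, tuple):
            base: list[TupleTree] = []
            for i, child in enumerate(node):
                for v in rec(child):
                    base.append(tuple(node[:i]) + (v,) + tuple(node[i + 1 :]))
            variants.extend(base)
        return variants

    if isinstance(tree, tuple):
        for i, child in enumerate(tree):
            for v in rec(child):
                out.append(tuple(tree[:i]) + (v,) + tuple(tree[i + 1 :]))
    return out


def spr_neighbors(tree: TupleTree) -> list[TupleTree]:
    """Rooted subtree-prune-regraft neighbourhood (excludes the trivial identity)."""
    out: list[TupleTree] = []
    for sub in _subtrees(tree):
        if sub == tree:
            continue
        pruned = _prune(tree, sub)
        if pruned is None:
            continue
        for t in _regraft_positions(pruned, sub):
            if canonical(t) != canonical(tree):
                out.append(t)
    return out


def dollo_search(
    matrix: PresenceAbsenceMatrix,
    n_addition_reps: int = 20,
    seed: int = 0,
    swap: str = "nni",
    outgroup: str | None = None,
):
    """Heuristic Dollo tree search: random stepwise addition + branch swapping.

    Each repetition builds a starting tree by adding taxa in random order at
    the best-scoring position, then hill-climbs through the NNI (optionally
    plus SPR) neighbourhood until no neighbour improves the score.  The best
    tree over all repetitions is returned as a rooted dendropy tree together
    with its :class:`ParsimonyScore`.  Deterministic given *seed*.

    With *outgroup* given, the outgroup is fixed as a child of the root
    (the search then effectively explores unrooted topologies of the full
    taxon set, directed by the outgroup); otherwise the root itself plays the
    role of the all-absent ancestor.
    """
    if swap not in ("nni", "spr"):
        raise ValueError("swap must be 'nni' or 'spr'")
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa for tree search")
    rng = np.random.default_rng(seed)
    states = matrix.states
    og_idx = matrix.taxon_index(outgroup) if outgroup is not None else None
    free = [i for i in range(matrix.n_taxa) if i != og_idx]

    cache: dict = {}

    def score_of(ingroup_tree: TupleTree) -> int:
        full = (og_idx, ingroup_tree) if og_idx is not None else ingroup_tree
        key = canonical(full)
        if key not in cache:
            cache[key] = int(dollo_steps_per_character(full, states).sum())
        return cache[key]

    best_tree: TupleTree | None = None
    best_score = np.inf
    for _ in range(max(1, n_addition_reps)):
        order = [int(x) for x in rng.permutation(free)]
        current: TupleTree = (order[0], order[1])
        for leaf in order[2:]:
            candidates = _insertions(current, int(leaf))
            scores = [score_of(t) for t in candidates]
            current = candidates[int(np.argmin(scores))]
        # hill climb
        cur_score = score_of(current)
        improved = True
        while improved:
            improved = False
            neigh = nni_neighbors(current)
            if swap == "spr":
                neigh = neigh + spr_neighbors(current)
            for t in neigh:
                s = score_of(t)
                if s < cur_score:
                    current, cur_score, improved = t, s, True
                    break
        if cur_score < best_score:
            best_tree, best_score = current, cur_score
    full = (og_idx, best_tree) if og_idx is not None else best_tree
    score = dollo_score(full, matrix)
    return to_dendropy(full, matrix.taxa), score


# ---------------------------------------------------------------------------
# dendropy conversions
# ---------------------------------------------------------------------------

def to_newick(tree: TupleTree, taxa: list[str]) -> str:
    def rec(node: TupleTree) -> str:
        if isinstance(node, (int, np.integer)):
            return taxa[int(node)].replace(" ", "_")
        return "(" + ",".join(rec(c) for c in node) + ")"

    return rec(tree) + ";"


def to_dendropy(tree: TupleTree, taxa: list[str]) -> dendropy.Tree:
    t = dendropy.Tree.get(data=to_newick(tree, taxa), schema="newick")
    t.is_rooted = True
    return t


def from_dendropy(tree: dendropy.Tree, taxa: list[str]) -> TupleTree:
    index = {name.replace(" ", "_"): i for i, name in enumerate(taxa)}

    def rec(node) -> TupleTree:
        if node.is_leaf():
            label = (node.taxon.label if node.taxon else node.label) or ""
            label = label.replace(" ", "_")
            if label not in index:
                raise ValueError(f"tree leaf {label!r} not among matrix taxa")
            return index[label]
        kids = node.child_nodes()
        if len(kids) == 1:
            return rec(kids[0])
        return tuple(rec(c) for c in kids)

    return rec(tree.seed_node)


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Return a copy of *tree* rerooted on the edge leading to *outgroup*."""
    t = tree.clone(depth=1)
    node = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon and leaf.taxon.label.replace(" ", "_") == outgroup.replace(" ", "_"):
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")
    t.reroot_at_edge(node.edge, update_bipartitions=False)
    t.is_rooted = True
    return t
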