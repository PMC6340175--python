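"""Distance trees and bootstrap support for presence-absence matrices.

Neighbor-Joining runs on the mean-character-difference distance (proportion
of characters differing among those non-missing in both taxa) via
scikit-bio's Saitou-Nei implementation; negative branch lengths are clamped
to zero.  Bootstrap support resamples characters with replacement and counts
how often each bipartition of the point-estimate tree recurs.
"""

from __future__ import annotations

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import dollo
from .matrix import MISSING, PresenceAbsenceMatrix


def mean_character_difference(matrix: PresenceAbsenceMatrix) -> np.ndarray:
    """Pairwise distance: fraction of shared non-missing characters that differ."""
    s = matrix.states
    n = matrix.n_taxa
    d = np.zeros((n, n))
    known = s != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = known[i] & known[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
                    "non-missing characters"
                )
            d[i, j] = d[j, i] = float((s[i, both] != s[j, both]).sum() / m)
    return d


def nj_tree(matrix: PresenceAbsenceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on the mean-character-difference matrix."""
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa for Neighbor-Joining")
    labels = [t.replace(" ", "_") for t in matrix.taxa]
    dm = DistanceMatrix(mean_character_difference(matrix), labels)
    sk = _skbio_nj(dm)
    tree = dendropy.Tree.get(data=str(sk), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions & bootstrap
# ---------------------------------------------------------------------------

def unrooted_splits(tree: dendropy.Tree, taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalised as the side NOT holding taxa[0]."""
    names = [t.replace(" ", "_") for t in taxa]
    ref = names[0]
    full = set(names)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {
            leaf.taxon.label.replace(" ", "_")
            for leaf in node.leaf_iter()
            if leaf.taxon
        }
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(names) - 2:
            splits.add(frozenset(side))
    return splits


def _estimate(matrix: PresenceAbsenceMatrix, method: str, seed: int, **kw) -> dendropy.Tree:
    if method == "nj":
        return nj_tree(matrix)
    if method == "dollo":
        tree, _ = dollo.dollo_search(matrix, seed=seed, **kw)
        return tree
    raise ValueError(f"unknown method {method!r}")


def bootstrap(
    matrix: PresenceAbsenceMatrix,
    n_reps: int,
    method: str = "nj",
    seed: int = 0,
    **search_kw,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Character bootstrap: support per bipartition of the point-estimate tree.

    Returns the point-estimate tree (internal node labels set to support
    values in [0, 1]) and the split -> support mapping.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = _estimate(matrix, method, seed=int(rng.integers(2**31 - 1)), **search_kw)
    ref_splits = unrooted_splits(point, matrix.taxa)
    hits = {s: 0 for s in ref_splits}
    for _ in range(n_reps):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        resampled = matrix.select_loci(idx)
        rep_tree = _estimate(
            resampled, method, seed=int(rng.integers(2**31 - 1)), **search_kw
        )
        rep_splits = unrooted_splits(rep_tree, matrix.taxa)
        for s in ref_splits & rep_splits:
            hits[s] += 1
    support = {s: hits[s] / n_reps for s in ref_splits}

    names = [t.replace(" ", "_") for t in matrix.taxa]
    ref, full = names[0], set(names)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {
            leaf.taxon.label.replace(" ", "_")
            for leaf in node.leaf_iter()
            if leaf.taxon
        }
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in support:
            node.label = f"{support[key]:.3f}"
    return point, support


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
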