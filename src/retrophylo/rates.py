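"""Per-branch insertion counts, heterozygosity, and per-generation rates.

Each insertion locus is placed on the branch of a dated species tree where
the insertion must have occurred: loci whose species presence set is a clade
go on that clade's stem branch; tree-incongruent loci (attributable to
incomplete lineage sorting) go on the stem of the MRCA of the carrier
species -- the most recent ancestral branch leading to all affected species.

The per-generation insertion rate on a branch is

    mu = n_insertions / (b / g)

with b the branch duration in years and g the generation time in years
(default 24.4, the mean for extant baleen whales).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix

DEFAULT_GENERATION_TIME = 24.4


@dataclass
class RateParams:
    """Rate-conversion parameters (generation time g, in years)."""

    generation_time_years: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be positive")


class DatedTree:
    """Rooted ultrametric species tree with branch lengths in years.

    Node ages (years before present) are derived from the branch lengths
    assuming extant leaves at age 0.  ``root_stem_years`` supplies a duration
    for the branch above the root, so loci shared by every species can still
    be assigned and dated.
    """

    def __init__(self, tree: dendropy.Tree, root_stem_years: float | None = None):
        self.tree = tree.clone(depth=1)
        self.tree.is_rooted = True
        self._age = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self._age[node] = 0.0
            else:
                kids = node.child_nodes()
                ages = [self._age[c] + (c.edge.length or 0.0) for c in kids]
                if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
                    raise ValueError(
                        "tree is not ultrametric: children of a node imply "
                        f"different ages {ages}"
                    )
                self._age[node] = float(np.mean(ages))
        root = self.tree.seed_node
        if root_stem_years is None:
            root_stem_years = root.edge.length if root.edge.length else None
        self.root_stem_years = root_stem_years
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                b = self._age[node.parent_node] - self._age[node]
                if b <= 0:
                    raise ValueError("parent age must exceed child age")

    @classmethod
    def from_newick(cls, path_or_string, root_stem_years: float | None = None):
        if isinstance(path_or_string, str) and "(" in path_or_string:
            t = dendropy.Tree.get(data=path_or_string, schema="newick")
        else:
            t = dendropy.Tree.get(path=str(path_or_string), schema="newick")
        return cls(t, root_stem_years=root_stem_years)

    # edge identifiers are the sorted tuple of leaf labels below the edge's child
    def edge_id(self, node) -> tuple[str, ...]:
        return tuple(
            sorted(
                leaf.taxon.label.replace(" ", "_")
                for leaf in node.leaf_iter()
                if leaf.taxon
            )
        )

    def node_age(self, node) -> float:
        return self._age[node]

    def branch_years(self, node) -> float:
        """Duration of the edge above *node* (the root uses root_stem_years)."""
        if node.parent_node is None:
            if self.root_stem_years is None:
                raise ValueError(
                    "root-edge duration unknown; pass root_stem_years to date "
                    "loci shared by all species"
                )
            return float(self.root_stem_years)
        return self._age[node.parent_node] - self._age[node]

    @property
    def leaf_labels(self) -> list[str]:
        return [
            leaf.taxon.label.replace(" ", "_")
            for leaf in self.tree.leaf_node_iter()
        ]

    def mrca(self, labels):
        labels = [l.replace(" ", "_") for l in labels]
        taxa = [
            t for t in self.tree.taxon_namespace
            if t.label.replace(" ", "_") in labels
        ]
        if len(taxa) != len(set(labels)):
            raise KeyError(f"labels {labels} not all present in tree")
        if len(taxa) == 1:
            for leaf in self.tree.leaf_node_iter():
                if leaf.taxon is taxa[0]:
                    return leaf
        return self.tree.mrca(taxa=taxa)


@dataclass
class BranchAssignment:
    """Locus -> edge mapping with per-locus congruence labels."""

    edge_of_locus: dict[str, tuple[str, ...]]
    congruent: dict[str, bool]
    n_congruent: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_congruent = sum(self.congruent.values())


def assign_branches(
    species_matrix: PresenceAbsenceMatrix, dated: DatedTree
) -> BranchAssignment:
    """Place every locus on a species-tree branch.

    Presence set equal to a clade -> that clade's stem edge (congruent);
    otherwise -> stem edge of the MRCA of the carriers (incongruent,
    attributed to lineage sorting).  Loci with missing species states or an
    empty presence set are not assignable and are omitted.
    """
    leaves = set(dated.leaf_labels)
    mat_taxa = {t.replace(" ", "_") for t in species_matrix.taxa}
    if mat_taxa != leaves:
        raise ValueError(
            f"matrix species {sorted(mat_taxa)} do not match tree leaves "
            f"{sorted(leaves)}"
        )
    edge_of: dict[str, tuple[str, ...]] = {}
    congruent: dict[str, bool] = {}
    # cache MRCA lookups by presence set
    cache: dict[frozenset, tuple] = {}
    taxa_clean = [t.replace(" ", "_") for t in species_matrix.taxa]
    for j, locus in enumerate(species_matrix.loci_ids):
        col = species_matrix.states[:, j]
        if (col == -1).any():
            continue
        present = frozenset(taxa_clean[i] for i in np.flatnonzero(col == 1))
        if not present:
            continue
        if present not in cache:
            node = dated.mrca(present)
            eid = dated.edge_id(node)
            cache[present] = (eid, frozenset(eid) == present)
        eid, is_clade = cache[present]
        edge_of[locus] = eid
        congruent[locus] = is_clade
    if not edge_of:
        raise ValueError("no assignable loci (all empty or missing)")
    return BranchAssignment(edge_of_locus=edge_of, congruent=congruent)


def branch_rates(
    assignment: BranchAssignment,
    dated: DatedTree,
    locus_any_het: dict[str, bool] | None = None,
    params: RateParams | None = None,
) -> pd.DataFrame:
    """Per-branch insertion counts, heterozygosity fractions, and rates.

    ``locus_any_het`` maps locus id -> True when the insertion is
    heterozygous in at least one carrier individual (the locus-level
    definition of unfixedness).  Returns a DataFrame with one row per edge
    that received at least one locus, plus zero rows for empty edges.
    """
    params = params or RateParams()
    g = params.generation_time_years
    per_edge: dict[tuple[str, ...], list[str]] = {}
    for locus, eid in assignment.edge_of_locus.items():
        per_edge.setdefault(eid, []).append(locus)
    rows = []
    for node in dated.tree.preorder_node_iter():
        eid = dated.edge_id(node)
        loci = per_edge.get(eid, [])
        if node.parent_node is None and dated.root_stem_years is None and not loci:
            continue
        b = dated.branch_years(node)
        if b <= 0:
            raise ValueError(f"non-positive branch duration for edge {eid}")
        n = len(loci)
        generations = b / g
        mu = n / generations
        if locus_any_het is not None and n > 0:
            het_frac = float(np.mean([bool(locus_any_het.get(l, False)) for l in loci]))
        else:
            het_frac = np.nan
        rows.append(
            {
                "edge": ",".join(eid),
                "n_insertions": n,
                "branch_years": b,
                "branch_generations": generations,
                "rate_per_generation": mu,
                "het_fraction": het_frac,
            }
        )
    return pd.DataFrame(rows)


def locus_het_from_matrix(matrix: PresenceAbsenceMatrix) -> dict[str, bool]:
    """Locus -> any-carrier-heterozygous flag, from an individual-level matrix."""
    any_het = matrix.het_flags.any(axis=0)
    return {l: bool(h) for l, h in zip(matrix.loci_ids, any_het)}
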