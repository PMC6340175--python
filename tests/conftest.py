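"""Shared fixtures: small hand-built matrices and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from retrophylo import SimConfig, SimSpeciesTree, simulate_insertion_matrix
from retrophylo.matrix import PresenceAbsenceMatrix

# 8-taxon whale-like species tree, branch lengths in generations.
# Topology: (((((blue,sei),(gray,(fin,humpback))),minke),right),bowhead)
WHALE_NEWICK = (
    "(((((blue:200000,sei:200000):100000,(gray:250000,"
    "(fin:200000,humpback:200000):50000):50000):50000,"
    "minke:350000):400000,right:750000):250000,bowhead:1000000);"
)

# same topology with the two internal branches around the gray-whale node
# shortened to 2,000 generations and ancestral sizes large enough that most
# informative loci sort incongruently
ILS_NEWICK = (
    "(((((blue:200000,sei:200000):2000,(gray:198000,"
    "(fin:148000,humpback:148000):50000):4000):100000,"
    "minke:302000):400000,right:702000):250000,bowhead:952000);"
)

WHALE_SPECIES = ["blue", "sei", "gray", "fin", "humpback", "minke", "right", "bowhead"]


@pytest.fixture(scope="session")
def conflict_free_truth():
    """2,500 loci on the whale-like tree with Ne so small that lineage
    sorting never contradicts the species tree."""
    sp = SimSpeciesTree(newick=WHALE_NEWICK, ne=50.0)
    cfg = SimConfig(n_loci=2500, genome_length=50_000_000, stem_generations=100_000)
    return simulate_insertion_matrix(sp, cfg, seed=11)


@pytest.fixture(scope="session")
def ils_truth():
    """12,000 loci with rampant incomplete lineage sorting around the
    gray/(fin,humpback)/(blue,sei) divergence (t/(2Ne) = 0.02-0.04)."""
    sp = SimSpeciesTree(newick=ILS_NEWICK, ne=50_000.0)
    cfg = SimConfig(n_loci=12_000, genome_length=50_000_000, stem_generations=100_000)
    return simulate_insertion_matrix(sp, cfg, seed=13)


@pytest.fixture
def quartet_matrix():
    """4 taxa, 3 characters: two supporting (A,B), one supporting (A,C)."""
    return PresenceAbsenceMatrix(
        taxa=["A", "B", "C", "D"],
        loci_ids=["l1", "l2", "l3"],
        states=np.array(
            [[1, 1, 1], [1, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8
        ),
    )


def species_map_of(truth):
    return {i: truth.species_of[i] for i in truth.individuals}
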