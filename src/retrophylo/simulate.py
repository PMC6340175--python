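"""Synthetic insertion data under the multispecies coalescent.

The generator reproduces the statistical structure that the downstream
analyses assume about real insertion call sets:

* each insertion locus has a single origin (a point event on a gene tree);
* gene trees are sampled under the standard multispecies coalescent over a
  dated species tree (msprime), so short internal branches and large
  ancestral population sizes produce tree-incongruent presence patterns by
  incomplete lineage sorting;
* individuals are diploid, so recent insertions segregate as heterozygotes;
* detection is imperfect: a coverage-dependent true-positive rate, genotype
  miscalls between het and hom, and missing genotypes.

The insertion is placed uniformly at random along the gene tree (branch
length-proportional), matching neutral clock-like retrotransposition; an
optional stem branch above the species root lets loci be shared by the whole
sampling (synapomorphies against the reference genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import msprime
import numpy as np

from .matrix import PresenceAbsenceMatrix
from .mei_io import GT_ABSENT, GT_HET, GT_HOM, GT_MISSING, MeiCallSet, MeiLocus


@dataclass
class SimSpeciesTree:
    """Dated species tree for simulation.

    Parameters
    ----------
    newick
        Rooted newick with branch lengths in generations; leaf labels are
        species names.  Internal node labels (if present) can be used to
        address ancestral populations in *ne*.
    ne
        Diploid effective population size: a single number for every branch,
        or a dict ``{population_name: Ne}`` with a required ``"default"``
        entry for unnamed populations.
    samples_per_species
        Diploid individuals sampled per extant species (default 1 each).
    """

    newick: str
    ne: float | dict = 10_000.0
    samples_per_species: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.tree = dendropy.Tree.get(data=self.newick, schema="newick")
        self.tree.is_rooted = True
        self.species = [l.taxon.label.replace(" ", "_") for l in self.tree.leaf_node_iter()]
        if self.samples_per_species is None:
            self.samples_per_species = {sp: 1 for sp in self.species}
        missing = set(self.samples_per_species) - set(self.species)
        if missing:
            raise ValueError(f"samples requested for unknown species {sorted(missing)}")
        for sp in self.species:
            self.samples_per_species.setdefault(sp, 0)
        if sum(self.samples_per_species.values()) == 0:
            raise ValueError("no samples requested")

    def _ne_of(self, name: str) -> float:
        if isinstance(self.ne, dict):
            ne = self.ne.get(name, self.ne.get("default"))
            if ne is None:
                raise ValueError(f"no Ne for population {name!r} and no default")
            return float(ne)
        return float(self.ne)

    def demography(self) -> tuple[msprime.Demography, float]:
        """Build the msprime demography; returns (demography, total_length_gens)."""
        dem = msprime.Demography()
        ages: dict = {}
        names: dict = {}
        counter = 0
        total_len = 0.0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                ages[node] = 0.0
                names[node] = node.taxon.label.replace(" ", "_")
            else:
                ages[node] = max(
                    ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                )
                label = (node.label or "").replace(" ", "_")
                names[node] = label if label else f"anc{counter}"
                counter += 1
            dem.add_population(name=names[node], initial_size=self._ne_of(names[node]))
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                total_len += ages[node.parent_node] - ages[node]
        # splits, oldest applied last; msprime requires sorted event times
        events = []
        for node in self.tree.postorder_node_iter():
            if not node.is_leaf():
                events.append(
                    (ages[node], [names[c] for c in node.child_nodes()], names[node])
                )
        for t, derived, anc in sorted(events, key=lambda e: e[0]):
            dem.add_population_split(time=t, derived=derived, ancestral=anc)
        dem.sort_events()
        return dem, total_len

    def clade_sets(self) -> set[frozenset]:
        """Species sets of all clades (for congruence labelling)."""
        out = set()
        for node in self.tree.preorder_node_iter():
            out.add(
                frozenset(
                    l.taxon.label.replace(" ", "_") for l in node.leaf_iter()
                )
            )
        return out


@dataclass
class SimConfig:
    """Simulation settings: locus count or rate, genome, and detection noise.

    Exactly one of ``n_loci`` / ``insertion_rate`` (per generation per
    lineage) drives the number of loci; in rate mode the expected locus count
    is rate x total species-tree length in generations (single-lineage
    approximation, accurate when lineage sorting is rare).

    The detection model emulates an MEI caller benchmarked on resequencing
    data: per-sample coverage maps to a logistic true-positive rate
    calibrated so TPR(5X) = 0.99; detected genotypes have their zygosity
    miscalled at the given rates (defaults reproduce a 92% homozygote call
    accuracy); genotypes additionally go missing at ``missing_rate``.
    """

    n_loci: int | None = 5_000
    insertion_rate: float | None = None
    genome_length: int = 100_000_000
    stem_generations: float = 0.0
    coverage: dict[str, float] | float = 20.0
    tpr_midpoint: float = 2.5
    tpr_slope: float = float(np.log(99.0) / 2.5)  # TPR(5X) = 0.99
    het_miscall_rate: float = 0.08
    hom_miscall_rate: float = 0.08
    missing_rate: float = 0.0
    undetected_missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if (self.n_loci is None) == (self.insertion_rate is None):
            raise ValueError("set exactly one of n_loci / insertion_rate")
        for p in (
            self.het_miscall_rate,
            self.hom_miscall_rate,
            self.missing_rate,
            self.undetected_missing_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must be in [0, 1]")

    def tpr(self, coverage) -> np.ndarray:
        """Logistic detection probability as a function of sequencing depth."""
        c = np.asarray(coverage, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.tpr_slope * (c - self.tpr_midpoint)))


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator."""

    species_tree: SimSpeciesTree
    individuals: list[str]
    species_of: dict[str, str]
    matrix: PresenceAbsenceMatrix            # individuals x loci
    genotypes: np.ndarray                    # loci x individuals codes
    positions: np.ndarray                    # 1-based, sorted
    origin_times: np.ndarray                 # generations before present
    congruent: np.ndarray                    # bool per locus (species-level)
    pair_tmrca: np.ndarray                   # loci x n_species x n_species

    def to_call_set(self, te_family: str = "SIM", chrom: str = "sim1") -> MeiCallSet:
        loci = [
            MeiLocus(chrom=chrom, pos=int(p), te_family=te_family)
            for p in self.positions
        ]
        return MeiCallSet(
            loci=loci, samples=list(self.individuals), genotypes=self.genotypes.copy()
        )


def simulate_insertion_matrix(
    species_tree: SimSpeciesTree, config: SimConfig, seed: int = 1
) -> SimTruth:
    """Simulate presence-absence data with coalescent lineage sorting.

    One gene tree per locus; one insertion per locus, placed uniformly along
    the gene tree (plus the optional stem above its root); presence is the
    set of descendant haplotypes; diploid genotypes follow from the two
    haplotypes of each individual.  Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    dem, total_len = species_tree.demography()
    if config.n_loci is not None:
        n_loci = int(config.n_loci)
    else:
        n_loci = int(
            rng.poisson(config.insertion_rate * (total_len + config.stem_generations))
        )
    if n_loci == 0:
        raise ValueError("simulation produced zero loci")
    sampled_species = [
        sp for sp in species_tree.species if species_tree.samples_per_species[sp] > 0
    ]
    sample_sets = [
        msprime.SampleSet(species_tree.samples_per_species[sp], population=sp)
        for sp in sampled_species
    ]
    individuals: list[str] = []
    species_of: dict[str, str] = {}
    for sp in sampled_species:
        for k in range(species_tree.samples_per_species[sp]):
            name = f"{sp}_{k}"
            individuals.append(name)
            species_of[name] = sp
    n_ind = len(individuals)
    n_sp = len(sampled_species)

    genotypes = np.zeros((n_loci, n_ind), dtype=np.int8)
    origin = np.zeros(n_loci)
    pair_tmrca = np.zeros((n_loci, n_sp, n_sp))
    congruent = np.zeros(n_loci, dtype=bool)
    clades = species_tree.clade_sets()

    msprime_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=msprime_seed,
    )
    for j, ts in enumerate(reps):
        tree = ts.first()
        if j == 0:
            # sample node -> individual index; first haplotype per species
            node_to_ind = np.full(ts.num_samples, -1, dtype=int)
            first_hap = np.zeros(n_sp, dtype=int)
            seen_sp: dict[str, int] = {}
            for ind in ts.individuals():
                pop = ts.node(ind.nodes[0]).population
                pop_name = ts.population(pop).metadata["name"]
                k = seen_sp.get(pop_name, 0)
                seen_sp[pop_name] = k + 1
                ind_idx = individuals.index(f"{pop_name}_{k}")
                for nd in ind.nodes:
                    node_to_ind[nd] = ind_idx
                if k == 0:
                    first_hap[sampled_species.index(pop_name)] = ind.nodes[0]
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        lens = np.array([tree.branch_length(u) for u in nodes])
        root = tree.root
        if config.stem_generations > 0:
            nodes.append(root)
            lens = np.append(lens, config.stem_generations)
        total = lens.sum()
        u = nodes[int(rng.choice(len(nodes), p=lens / total))]
        carriers = set(tree.samples(u))
        origin[j] = tree.time(u) + rng.uniform(0.0, tree.branch_length(u) or config.stem_generations)
        for s in carriers:
            genotypes[j, node_to_ind[s]] += 1
        for a in range(n_sp):
            for b in range(a + 1, n_sp):
                t = tree.tmrca(int(first_hap[a]), int(first_hap[b]))
                pair_tmrca[j, a, b] = pair_tmrca[j, b, a] = t
        present_species = frozenset(
            species_of[individuals[i]] for i in np.flatnonzero(genotypes[j] > 0)
        )
        congruent[j] = present_species in clades

    # map dosage 0/1/2 to genotype codes (same integers, named for clarity)
    genotypes = np.where(genotypes >= 2, GT_HOM, genotypes).astype(np.int8)

    positions = _unique_sorted_positions(rng, config.genome_length, n_loci)
    order = np.argsort(positions)
    positions = positions[order]
    genotypes = genotypes[order]
    origin = origin[order]
    pair_tmrca = pair_tmrca[order]
    congruent = congruent[order]

    states = (genotypes.T > 0).astype(np.int8)
    het = genotypes.T == GT_HET
    matrix = PresenceAbsenceMatrix(
        taxa=list(individuals),
        loci_ids=[f"sim1:{int(p)}" for p in positions],
        states=states,
        het_flags=het,
    )
    return SimTruth(
        species_tree=species_tree,
        individuals=individuals,
        species_of=species_of,
        matrix=matrix,
        genotypes=genotypes,
        positions=positions,
        origin_times=origin,
        congruent=congruent,
        pair_tmrca=pair_tmrca,
    )


def _unique_sorted_positions(rng, genome_length: int, n: int, min_spacing: int = 1):
    if n > genome_length // max(min_spacing, 1):
        raise ValueError("genome too short for the requested number of loci")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(1, genome_length + 1, size=n - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.array(sorted(chosen), dtype=np.int64)


def apply_detection_noise(
    truth: SimTruth, config: SimConfig, seed: int = 2, te_family: str = "SIM"
) -> MeiCallSet:
    """Corrupt true genotypes with the configured detection model.

    Present genotypes are detected with probability TPR(coverage of the
    sample); undetected genotypes become absent (or missing with
    ``undetected_missing_prob``); detected genotypes are zygosity-miscalled
    at the het/hom miscall rates; finally any genotype can drop out as
    missing at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    gt = truth.genotypes.copy()
    n_loci, n_ind = gt.shape
    if isinstance(config.coverage, dict):
        cov = np.array([config.coverage[i] for i in truth.individuals])
    else:
        cov = np.full(n_ind, float(config.coverage))
    tpr = config.tpr(cov)  # per individual
    u = rng.random(gt.shape)
    present = gt > 0
    undetected = present & (u >= tpr[None, :])
    miss_mask = undetected & (rng.random(gt.shape) < config.undetected_missing_prob)
    gt[undetected] = GT_ABSENT
    gt[miss_mask] = GT_MISSING

    detected = present & ~undetected
    flip = rng.random(gt.shape)
    het_to_hom = detected & (gt == GT_HET) & (flip < config.het_miscall_rate)
    hom_to_het = detected & (gt == GT_HOM) & (flip < config.hom_miscall_rate)
    gt[het_to_hom] = GT_HOM
    gt[hom_to_het] = GT_HET

    if config.missing_rate > 0:
        gt[rng.random(gt.shape) < config.missing_rate] = GT_MISSING

    loci = [
        MeiLocus(chrom="sim1", pos=int(p), te_family=te_family)
        for p in truth.positions
    ]
    return MeiCallSet(loci=loci, samples=list(truth.individuals), genotypes=gt)


def spike_reference(
    genome_length: int,
    n_insertions: int,
    element_length: int,
    seed: int = 0,
    min_spacing: int | None = None,
    sequence: str | None = None,
    element_sequence: str | None = None,
):
    """Randomly integrate elements into a reference sequence (truth spiking).

    Returns ``(positions, shift_map)`` where *positions* are sorted unique
    1-based insertion points on the original coordinate system with pairwise
    spacing >= *min_spacing* (default: the element length), and
    ``shift_map(x)`` converts an original coordinate to its coordinate in
    the modified sequence.  When *sequence* is given, the modified sequence
    (with *element_sequence* inserted after each position) is returned third.
    """
    if n_insertions < 0:
        raise ValueError("n_insertions must be >= 0")
    if min_spacing is None:
        min_spacing = element_length
    rng = np.random.default_rng(seed)
    if n_insertions == 0:
        positions = np.array([], dtype=np.int64)
    else:
        # draw sorted positions with a minimum gap by the shrunken-range trick
        usable = genome_length - (n_insertions - 1) * min_spacing
        if usable < n_insertions:
            raise ValueError("genome too short for n_insertions at this spacing")
        base = np.sort(rng.choice(usable, size=n_insertions, replace=False) + 1)
        positions = base + np.arange(n_insertions) * min_spacing

    def shift_map(x: int) -> int:
        return int(x + element_length * np.searchsorted(positions, x, side="right"))

    if sequence is None:
        return positions, shift_map
    if element_sequence is None:
        element_sequence = "".join(rng.choice(list("ACGT"), size=element_length))
    if len(sequence) < genome_length:
        raise ValueError("sequence shorter than genome_length")
    parts = []
    prev = 0
    for p in positions:
        parts.append(sequence[prev:p])
        parts.append(element_sequence)
        prev = p
    parts.append(sequence[prev:])
    return positions, shift_map, "".join(parts)
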