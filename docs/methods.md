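# Methods

This note documents the models and conventions behind `retrophylo`: what is
computed, which choices were open and how they were settled, and what the
synthetic data generator does and does not emulate.

## Presence/absence coding

A genotype with at least one alternate allele codes the insertion as present
(state 1); 0/0 codes absent; ./. and half-calls (./1) code missing (`?`).
Half-calls are mapped to missing deliberately: a half-call carries partial
evidence at best and MEI callers emit them in low-confidence regions. Phase
separators are ignored. Heterozygosity is carried in a parallel boolean
table (only valid where state = 1); since a binary NEXUS matrix cannot
express it, NEXUS export writes a TSV sidecar (locus, taxon, het).

Columns with no observed presence are dropped — relative to the reference
genome they carry no variation. All-present columns are **kept**: when calls
are made against an outgroup reference, an insertion carried by every sample
is a shared derived character of the whole ingroup and is the strongest
class of signal in the data.

## Dollo parsimony

Retroposon insertions fit Dollo's law: a character may be gained once
(0 → 1) and lost arbitrarily often. With the root constrained to the
all-absent ancestral state, the minimal length of a character is one gain at
the MRCA of its present leaves plus one loss per maximal all-absent subtree
inside that gain clade. Missing leaves resolve freely to whichever state
avoids a loss; an all-missing subtree inside the gain clade therefore costs
nothing, while a subtree containing a definite absence costs exactly one
loss at its stem. This is computed in vectorised form over all characters
simultaneously (boolean OR sweeps in post-order, a pre-order sweep to
subtract losses counted above the gain MRCA), and is verified in the test
suite against exhaustive enumeration of all valid labelings on trees with
≤ 6 leaves.

The heuristic search uses random stepwise addition (each taxon inserted at
its best-scoring position) followed by hill climbing through the rooted NNI
neighbourhood, optionally widened to SPR. TBR is not implemented: at the
8–12 taxa this package targets, random addition plus NNI/SPR reaches the
global optimum (checked against exhaustive enumeration of all 105 rooted
five-taxon topologies), and the search is deterministic given its seed. An
outgroup, when named, is pinned as a child of the root; otherwise the root
itself plays the role of the all-absent ancestor.

The consistency index is CI = Σ minima / Σ realised steps with a
per-character minimum of one. All-present characters (which always realise
1/1) are included by default; `include_all_present=False` restricts the
ratio to variable characters. Both conventions are exposed because
parsimony software differs silently on this point and published CI values
rarely say which was used.

## Neighbor-Joining and bootstrap

Distances are mean character differences — the proportion of differing
characters among those non-missing in both taxa (pairwise deletion); a taxon
pair sharing no scored character is an error, not a guess. The Saitou–Nei
algorithm itself is delegated to scikit-bio; negative branch lengths are
clamped to zero afterwards. Bootstrap support resamples characters with
replacement and reports, for every bipartition of the point-estimate tree,
the fraction of replicates containing it.

## Conflict counts and the polytomy test

After collapsing individuals to species (rule `all`: present only when every
genotyped individual carries the insertion — a segregating locus counts as
species-absent and is tallied in the diagnostics; rule `any` available),
each locus contributes one count to its exact presence set (exclusive,
UpSet-"distinct" semantics). Loci with a missing species state or an empty
collapsed presence set are skipped and reported, so the counts always form
an auditable partition.

Around a contested node, three mutually incompatible species subsets define
the conflict triple (n1 ≥ n2 ≥ n3). Two statistics are provided:

* **Default (binomial tail):** p = P(X ≥ n1) with X ~ Binomial(n, 1/3).
  This is the convention used with retroposon conflict counts in the
  literature this package follows, and on the whale counts 510:465:444 it
  gives p = 0.0204. Because n1 is *selected* as the maximum, this tail is
  anti-conservative as a frequentist test: its null rejection rate at level
  α approaches 3α (≈ 0.15 at α = 0.05 for n = 1419, measured by
  simulation). It is best read as a per-resolution tail probability.
* **Selection-adjusted:** `selection_adjusted=True` returns
  P(max(N1, N2, N3) ≥ n1) by inclusion–exclusion over the trinomial; this
  version is calibrated (type-I error ≤ α) and gives p ≈ 0.061 on the same
  counts. A Monte-Carlo trinomial mode cross-checks either tail.

The ILS-vs-introgression test is the two-sided exact binomial test of
n2 against n3 with success probability ½: under pure lineage sorting the two
tree-incongruent resolutions are exchangeable, so asymmetry indicates
directional gene flow. On 465 vs 444 it gives p ≈ 0.51.

## Branch assignment and insertion rates

Each locus is placed on the dated species tree: a presence set that is a
clade goes on that clade's stem branch; any other set is attributed to
incomplete lineage sorting and mapped to the stem of the MRCA of its
carriers — the most recent ancestral branch leading to all affected species.
Loci present in every species go on the root stem, whose duration must be
supplied (`root_stem_years`) since it is not part of an ultrametric tree.

The per-generation rate on a branch is μ = n / (b / g): n insertions over
b/g generations, with g the mean generation time in years (default 24.4,
appropriate for large baleen whales). μ is linear in g and inversely
proportional to b by construction. The heterozygosity fraction of a branch
is locus-level by default — the fraction of its loci heterozygous in at
least one carrier individual — because "unfixed in any sampled genome" is
the property relevant to dating fixation; a genotype-call-level alternative
can be derived from the same sidecar.

## PCA

Genotypes are coded as alternate-allele dosages 0/1/2; missing values are
mean-imputed per locus; loci are centred (variance scaling optional and off
by default — allele-frequency standardisation conventions differ between
tools and materially change the picture for small sample sizes); the
decomposition is an SVD. Signs are fixed by making the largest-magnitude
coordinate of each component positive.

## The synthetic-data generator

Each locus is an independent gene tree sampled under the standard
multispecies coalescent over the dated species tree (msprime; diploid time
scale, so two lineages in a population of size N_e coalesce at rate
1/(2N_e) per generation). One insertion is placed uniformly at random along
the gene tree — neutral, clock-like retrotransposition — and presence is
inherited by all descendant haplotypes; diploid genotypes follow from each
individual's two haplotypes, so recent insertions naturally segregate as
heterozygotes. An optional stem branch above the species root produces loci
shared by the entire sampling (the synapomorphy class seen against an
outgroup reference genome). In rate mode the expected locus count is the
insertion rate × total species-tree length in generations — a
single-lineage approximation that is accurate when within-species
coalescence is fast relative to branch lengths (the regime used for the
parameter-recovery checks; with one sampled individual and N_e ≪ branch
lengths the bias is well below sampling error).

The generator records, per locus, the origin time, the species-level
congruence label, and the gene-tree TMRCA for the first haplotype of every
species pair; the last makes coalescent theory directly testable — e.g. the
quartet check that the discordance fraction equals (2/3)·exp(−t/(2N_e)).

The detection model operates at the genotype level: each present genotype is
detected with probability TPR(coverage), a logistic in sequencing depth
calibrated so that TPR(5×) = 0.99; detected genotypes have their zygosity
miscalled at configurable rates (defaults 0.08 in both directions,
reproducing a 92% homozygote call accuracy); undetected genotypes become
absent or missing; an additional uniform missing rate is available. What
this deliberately does **not** emulate: read-level artefacts (mapping
ambiguity, low-complexity reference regions, breakpoint imprecision beyond
the matching window), caller-specific filter categories, and correlated
errors between samples. Tests that pass on these simulations therefore
demonstrate correctness of the downstream statistics under the stated
model, not robustness to every failure mode of a real caller; the spiking
utilities exist so real callers can be benchmarked externally through the
same evaluation module.

## Call benchmarking

Calls match truth positions one-to-one within a window (default 50 bp — MEI
breakpoint estimates are imprecise at the tens-of-bases scale). The matching
maximises the number of matched pairs and, among maximum matchings, the
total distance is minimal (optimal linear assignment). A greedy
nearest-first rule was considered and rejected: it can strand a matchable
pair (truth {0, 10}, calls {9, 20}, window 10), violating the equivalence
with optimal matching that the test suite enforces on small instances.

Metric naming follows the benchmarked-caller convention: DETR is sensitivity
over truth loci, TPR is the fraction of calls matching truth (a precision —
also exposed under that unambiguous name), FNR = 1 − DETR, FPR = 1 − TPR.
Genotype-level figures are reported separately: `genotype_sensitivity`
(truly present genotypes called present) and `genotype_concordance`
(correct zygosity among detected genotypes).

## Problem sizes and determinism

The test suite and the acceptance script run simulations of 1,200–12,000
loci on 3–8 species trees, with 100 Neighbor-Joining and 20 Dollo bootstrap
replicates and a 10⁶-draw Monte-Carlo oracle for the polytomy test — sizes
at which every stochastic check operates at ≥ 3 standard errors of
resolution while the whole battery completes in well under a minute. Every
stochastic component takes an explicit seed; a pipeline rerun with the same
configuration is byte-identical, and the manifest records seeds and file
hashes to prove it.

## Known limitations

* Dollo search is exact only in the small-taxon regime it targets; for
  hundreds of taxa a TBR-capable engine should be used on the exported
  NEXUS matrix.
* Bayesian tree inference and phylogenetic-network construction are out of
  scope; the NEXUS/Newick exports feed external tools.
* Branch-rate estimates inherit whatever error the supplied divergence
  times carry; the root-stem duration is a user input, not an estimate.
* The ILS mapping rule concentrates all incongruent loci on ancestral
  stems; under heavy introgression this overcounts those branches.
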