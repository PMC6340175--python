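"""Phylogenetic conflict from exclusive insertion synapomorphies.

Every insertion locus is a putative synapomorphy of exactly the species that
carry it.  Tallying loci by their exact species presence set (UpSet-style
"distinct" intersections) exposes how much of the data supports each
possible clade; around a contested node, the three mutually incompatible
resolutions yield three counts whose (a)symmetry is informative:

* a *hard polytomy* predicts all three resolutions equally often (each 1/3),
  tested by the exact binomial tail of the largest count;
* under pure incomplete lineage sorting the two minority counts are
  symmetric; an excess of one over the other suggests introgression, tested
  by a two-sided exact binomial test.

These are the count-based tests of the KKSC framework for retroposon
presence/absence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import MISSING, PresenceAbsenceMatrix


@dataclass
class CollapseDiagnostics:
    """Audit trail for individual -> species collapsing."""

    mixed_loci_per_species: dict[str, int] = field(default_factory=dict)
    n_loci_with_missing_species: int = 0


def collapse_to_species(
    matrix: PresenceAbsenceMatrix,
    species_map: dict[str, str],
    rule: str = "all",
) -> tuple[PresenceAbsenceMatrix, CollapseDiagnostics]:
    """Collapse individual samples to species rows.

    rule="all": a species is scored present only when every genotyped
    individual carries the insertion; a mixed (segregating) locus counts as
    species-absent, and the diagnostics record how often that happened per
    species.  rule="any": present when at least one individual carries it.
    Individuals with missing state are ignored for the unanimity check; a
    species with no genotyped individual at a locus is scored missing.

    Species-level het flag: set when the species is present and at least one
    individual is heterozygous there.
    """
    if rule not in ("all", "any"):
        raise ValueError("rule must be 'all' or 'any'")
    unmapped = [t for t in matrix.taxa if t not in species_map]
    if unmapped:
        raise ValueError(f"taxa not in species map: {unmapped}")
    species = list(dict.fromkeys(species_map[t] for t in matrix.taxa))
    diag = CollapseDiagnostics({sp: 0 for sp in species})
    n_loci = matrix.n_loci
    states = np.empty((len(species), n_loci), dtype=np.int8)
    het = np.zeros((len(species), n_loci), dtype=bool)
    for si, sp in enumerate(species):
        rows = [i for i, t in enumerate(matrix.taxa) if species_map[t] == sp]
        sub = matrix.states[rows, :]
        sub_het = matrix.het_flags[rows, :]
        known = sub != MISSING
        n_known = known.sum(axis=0)
        n_present = ((sub == 1) & known).sum(axis=0)
        all_present = (n_known > 0) & (n_present == n_known)
        any_present = n_present > 0
        mixed = any_present & ~all_present
        diag.mixed_loci_per_species[sp] = int(mixed.sum())
        if rule == "all":
            present = all_present
        else:
            present = any_present
        col = np.where(n_known == 0, MISSING, present.astype(np.int8)).astype(np.int8)
        states[si] = col
        het[si] = (col == 1) & sub_het.any(axis=0)
    diag.n_loci_with_missing_species = int((states == MISSING).any(axis=0).sum())
    return (
        PresenceAbsenceMatrix(
            taxa=species, loci_ids=list(matrix.loci_ids), states=states, het_flags=het
        ),
        diag,
    )


@dataclass
class IntersectionTable:
    """Exclusive (UpSet "distinct") counts: presence set -> number of loci."""

    entries: dict[tuple[str, ...], int]
    n_counted: int
    n_skipped_missing: int
    n_skipped_empty: int

    def count(self, subset) -> int:
        return self.entries.get(tuple(sorted(subset)), 0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("subset\tcount\n")
            for key in sorted(self.entries, key=lambda k: (-self.entries[k], k)):
                fh.write(",".join(key) + f"\t{self.entries[key]}\n")


def intersection_counts(species_matrix: PresenceAbsenceMatrix) -> IntersectionTable:
    """Tally loci by their exact species presence set.

    Loci with any missing species state are skipped (their presence set is
    not knowable) as are loci with an empty presence set (possible after
    rule="all" collapsing); both tallies are reported so the exclusive
    partition remains auditable: counts sum to n_counted.
    """
    entries: dict[tuple[str, ...], int] = {}
    n_missing = n_empty = n_counted = 0
    states = species_matrix.states
    taxa = species_matrix.taxa
    for j in range(species_matrix.n_loci):
        col = states[:, j]
        if (col == MISSING).any():
            n_missing += 1
            continue
        key = tuple(sorted(taxa[i] for i in np.flatnonzero(col == 1)))
        if not key:
            n_empty += 1
            continue
        entries[key] = entries.get(key, 0) + 1
        n_counted += 1
    return IntersectionTable(
        entries=entries,
        n_counted=n_counted,
        n_skipped_missing=n_missing,
        n_skipped_empty=n_empty,
    )


@dataclass
class ConflictTriple:
    """Counts for the three alternative resolutions around a focal node.

    Canonically sorted so n1 >= n2 >= n3; labels follow the same order.
    """

    n1: int
    n2: int
    n3: int
    labels: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2 + self.n3


def conflict_triple(table: IntersectionTable, hypothesis_sets) -> ConflictTriple:
    """Extract the counts for three mutually incompatible species subsets."""
    sets = [frozenset(s) for s in hypothesis_sets]
    if len(sets) != 3:
        raise ValueError("exactly three hypothesis subsets required")
    # alternative resolutions must be pairwise incompatible as clades:
    # neither identical, nested, nor disjoint
    for a in range(3):
        for b in range(a + 1, 3):
            if sets[a] == sets[b]:
                raise ValueError("hypothesis subsets must be distinct")
            if not (sets[a] & sets[b]) or sets[a] <= sets[b] or sets[b] <= sets[a]:
                raise ValueError(
                    "hypothesis subsets must be pairwise incompatible "
                    f"(got {sorted(sets[a])} vs {sorted(sets[b])})"
                )
    pairs = sorted(
        ((table.count(s), tuple(sorted(s))) for s in sets),
        key=lambda x: (-x[0], x[1]),
    )
    return ConflictTriple(
        n1=pairs[0][0],
        n2=pairs[1][0],
        n3=pairs[2][0],
        labels=(pairs[0][1], pairs[1][1], pairs[2][1]),
    )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_total: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def polytomy_test(
    triple: ConflictTriple,
    mc_reps: int | None = None,
    seed: int = 0,
    selection_adjusted: bool = False,
) -> TestResult:
    """Exact test of a hard polytomy against the largest resolution count.

    Under the null every locus supports each of the three resolutions with
    probability 1/3.  The default p-value is the one-sided binomial tail
    P(X >= n1), X ~ Binomial(n_total, 1/3), with n1 the largest count --
    the convention used with retroposon conflict counts in the literature
    this package follows.  Because n1 is selected as the maximum, this tail
    is anti-conservative as a frequentist test (its null rejection rate at
    level alpha approaches 3*alpha); ``selection_adjusted=True`` instead
    returns P(max(N1,N2,N3) >= n1) by inclusion-exclusion, which is
    calibrated.  With *mc_reps* set, a Monte Carlo trinomial estimate of the
    chosen tail is returned instead (agrees within sampling error).
    """
    n, n1 = triple.n_total, triple.n1
    if n < 1:
        raise ValueError("empty triple: no counted loci")
    if mc_reps is not None:
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, [1 / 3] * 3, size=int(mc_reps))
        stat = draws.max(axis=1) if selection_adjusted else draws[:, 0]
        p = float((stat >= n1).mean())
        return TestResult(statistic=float(n1), p_value=p,
                          method=f"monte-carlo-trinomial({mc_reps})", n_total=n)
    if not selection_adjusted:
        p = float(stats.binom.sf(n1 - 1, n, 1.0 / 3.0))
        return TestResult(statistic=float(n1), p_value=min(p, 1.0),
                          method="exact-binomial-max-tail", n_total=n)
    p = _max_count_tail(n, n1)
    return TestResult(statistic=float(n1), p_value=min(max(p, 0.0), 1.0),
                      method="exact-trinomial-max", n_total=n)


def _max_count_tail(n: int, x: int) -> float:
    """P(max of a trinomial(n; 1/3,1/3,1/3) >= x) by inclusion-exclusion."""
    single = float(stats.binom.sf(x - 1, n, 1.0 / 3.0))
    pair = 0.0
    if 2 * x <= n:
        i = np.arange(x, n - x + 1)
        pair = float(
            np.sum(
                stats.binom.pmf(i, n, 1.0 / 3.0)
                * stats.binom.sf(x - 1, n - i, 0.5)
            )
        )
    trip = 0.0
    if 3 * x <= n:
        for i in range(x, n - 2 * x + 1):
            j = np.arange(x, n - i - x + 1)
            trip += float(
                stats.binom.pmf(i, n, 1.0 / 3.0)
                * np.sum(stats.binom.pmf(j, n - i, 0.5) * ((n - i - j) >= x))
            )
    return 3.0 * single - 3.0 * pair + trip


def asymmetry_test(n2: int, n3: int) -> TestResult:
    """Two-sided exact binomial test of the two minority counts.

    Under pure lineage sorting the two species-tree-incongruent resolutions
    are equally probable; a significant asymmetry points to introgression.
    """
    n = n2 + n3
    if n < 1:
        raise ValueError("both minority counts are zero")
    p = float(stats.binomtest(n2, n, 0.5).pvalue)
    return TestResult(statistic=float(n2), p_value=min(p, 1.0),
                      method="exact-binomial-two-sided", n_total=n)


def write_upset_membership(table: IntersectionTable, path) -> None:
    """Binary membership matrix (one row per subset, one column per species)."""
    species = sorted({sp for key in table.entries for sp in key})
    with open(path, "w") as fh:
        fh.write("\t".join(species) + "\tcount\n")
        for key in sorted(table.entries, key=lambda k: (-table.entries[k], k)):
            row = "\t".join("1" if sp in key else "0" for sp in species)
            fh.write(row + f"\t{table.entries[key]}\n")
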