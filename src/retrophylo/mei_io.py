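"""Mobile-element insertion (MEI) call sets: VCF parsing, filtering, matrix building.

MEI callers such as MELT emit one VCF record per candidate insertion with a
per-sample genotype.  This module turns such call sets into the package's
presence-absence representation and computes the per-sample summary counts
(number of non-reference calls, number of heterozygous calls).

Genotype encoding used throughout:

* ``0``  homozygous reference (0/0) -- insertion absent
* ``1``  heterozygous (0/1) -- insertion present, unfixed
* ``2``  homozygous alternate (1/1) -- insertion present, fixed in the sample
* ``-1`` missing (./.) -- no call; half-calls like ``./1`` are treated as
  missing (conservative)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .matrix import PresenceAbsenceMatrix

GT_ABSENT, GT_HET, GT_HOM, GT_MISSING = 0, 1, 2, -1


@dataclass(frozen=True)
class MeiLocus:
    """A single insertion locus as called in a VCF record (1-based position)."""

    chrom: str
    pos: int
    te_family: str = "MEI"
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class MeiCallSet:
    """Loci x samples genotype table from an MEI VCF."""

    loci: list[MeiLocus]
    samples: list[str]
    genotypes: np.ndarray  # (n_loci, n_samples) int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8).reshape(
            len(self.loci), len(self.samples)
        )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample names must be unique")
        seen = set()
        for loc in self.loci:
            key = (loc.chrom, loc.pos)
            if key in seen:
                raise ValueError(f"duplicate locus {loc.locus_id}")
            seen.add(key)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _classify_gt(alleles: tuple) -> int:
    """Map a pysam GT allele tuple to the four-state genotype code."""
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return GT_MISSING
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return GT_ABSENT
    if n_alt == len(alleles):
        return GT_HOM
    return GT_HET


def read_mei_vcf(path, te_family: str = "MEI") -> MeiCallSet:
    """Parse an MEI VCF (plain or bgzipped) into a :class:`MeiCallSet`.

    Phase separators are ignored (``0|1`` equals ``0/1``); any non-zero
    allele index counts as insertion-present.  Raises ``ValueError`` when a
    record lacks a GT field.
    """
    loci: list[MeiLocus] = []
    rows: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            filt = ";".join(rec.filter.keys()) if len(rec.filter) else "PASS"
            loci.append(
                MeiLocus(chrom=rec.chrom, pos=rec.pos, te_family=te_family, filter=filt)
            )
            row = []
            for sample in samples:
                fmt = rec.samples[sample]
                if "GT" not in fmt:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks a GT field"
                    )
                row.append(_classify_gt(fmt["GT"]))
            rows.append(row)
    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return MeiCallSet(loci=loci, samples=samples, genotypes=genotypes)


def write_mei_vcf(calls: MeiCallSet, path) -> None:
    """Write a call set as a minimal VCF 4.2 file readable by :func:`read_mei_vcf`."""
    gt_str = {GT_ABSENT: "0/0", GT_HET: "0/1", GT_HOM: "1/1", GT_MISSING: "./."}
    chroms = list(dict.fromkeys(loc.chrom for loc in calls.loci))
    filters = sorted(
        {f for loc in calls.loci for f in loc.filter.split(";") if f != "PASS"}
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for f in filters:
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.samples)
            + "\n"
        )
        for i, loc in enumerate(calls.loci):
            gts = "\t".join(gt_str[int(g)] for g in calls.genotypes[i])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t.\tN\t<INS:ME:{loc.te_family}>\t.\t"
                f"{loc.filter}\tSVTYPE=INS\tGT\t{gts}\n"
            )


def filter_calls(calls: MeiCallSet, keep_filters: set[str] | None = None) -> MeiCallSet:
    """Retain loci whose FILTER value is in *keep_filters* (default {"PASS"})."""
    if keep_filters is None:
        keep_filters = {"PASS"}
    keep = [i for i, loc in enumerate(calls.loci) if loc.filter in keep_filters]
    return MeiCallSet(
        loci=[calls.loci[i] for i in keep],
        samples=list(calls.samples),
        genotypes=calls.genotypes[keep, :].copy()
        if keep
        else np.empty((0, calls.n_samples), dtype=np.int8),
    )


def build_matrix(calls: MeiCallSet) -> PresenceAbsenceMatrix:
    """Convert genotypes to a presence-absence matrix (samples x loci).

    State 1 wherever the genotype carries an alternate allele, 0 for 0/0,
    missing for ./.; columns with no presence anywhere are dropped (they carry
    no signal relative to the reference genome).  All-present columns are
    kept: they are shared derived insertions of the whole sampling versus the
    reference outgroup.
    """
    if calls.n_samples == 0:
        raise ValueError("call set has no samples")
    gt = calls.genotypes.T  # samples x loci
    states = np.where(gt == GT_MISSING, -1, (gt > 0).astype(np.int8)).astype(np.int8)
    het = gt == GT_HET
    matrix = PresenceAbsenceMatrix(
        taxa=list(calls.samples),
        loci_ids=[loc.locus_id for loc in calls.loci],
        states=states,
        het_flags=het,
    )
    return matrix.drop_absent_columns()


@dataclass(frozen=True)
class SampleCounts:
    """Per-sample tally of non-reference and heterozygous calls."""

    sample: str
    n_calls: int
    n_het: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_het <= self.n_calls:
            raise ValueError("0 <= n_het <= n_calls violated")


def per_sample_counts(calls: MeiCallSet, totals: bool = True) -> list[SampleCounts]:
    """Count non-reference and heterozygous loci per sample.

    With ``totals=True`` a final row named ``"Total"`` holds the column sums,
    mirroring the usual summary-table layout.
    """
    gt = calls.genotypes
    n_calls = (gt > 0).sum(axis=0)
    n_het = (gt == GT_HET).sum(axis=0)
    out = [
        SampleCounts(sample=s, n_calls=int(c), n_het=int(h))
        for s, c, h in zip(calls.samples, n_calls, n_het)
    ]
    if totals:
        out.append(
            SampleCounts(
                sample="Total", n_calls=int(n_calls.sum()), n_het=int(n_het.sum())
            )
        )
    return out


def read_species_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping sample name -> species name."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, species = line.split("\t")[:2]
            mapping[sample] = species
    return mapping
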