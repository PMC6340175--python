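"""Presence-absence matrix of mobile-element insertions.

The central object of the package: a taxa x loci table of binary
presence/absence states (with missing data) plus a parallel table of
heterozygosity flags.  States are stored as a small integer array:

* ``1``  -- insertion present (genotype carried at least one alternate allele)
* ``0``  -- insertion absent (homozygous reference)
* ``-1`` -- missing / unknown (``?`` in NEXUS)

A heterozygosity flag is only ever true where the state is 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_NEXUS_DATA_RE = re.compile(r"begin\s+data\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL)
_DIM_RE = re.compile(r"dimensions\s+([^;]*);", re.IGNORECASE)
_MATRIX_RE = re.compile(r"matrix\s(.*?);", re.IGNORECASE | re.DOTALL)


class NexusFormatError(ValueError):
    """Raised when a NEXUS file cannot be interpreted as a binary matrix."""


@dataclass
class PresenceAbsenceMatrix:
    """Binary (with missing) taxa x loci matrix plus heterozygosity flags.

    Parameters
    ----------
    taxa
        Ordered taxon (sample or species) names, unique.
    loci_ids
        Ordered locus identifiers, conventionally ``"chrom:pos"``.
    states
        ``(n_taxa, n_loci)`` int8 array with values in {0, 1, -1}.
    het_flags
        Boolean array of the same shape; True only where ``states == 1``.
    """

    taxa: list[str]
    loci_ids: list[str]
    states: np.ndarray
    het_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.loci_ids)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.loci_ids)} loci"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if not np.isin(self.states, (0, 1, MISSING)).all():
            raise ValueError("states must be in {0, 1, -1}")
        if self.het_flags is None:
            self.het_flags = np.zeros_like(self.states, dtype=bool)
        self.het_flags = np.asarray(self.het_flags, dtype=bool)
        if self.het_flags.shape != self.states.shape:
            raise ValueError("het_flags shape must match states")
        if (self.het_flags & (self.states != 1)).any():
            raise ValueError("het_flags may only be set where state == 1")

    # -- basic properties -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_loci(self) -> int:
        return len(self.loci_ids)

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"unknown taxon {name!r}") from None

    # -- transformations --------------------------------------------------
    def drop_absent_columns(self) -> "PresenceAbsenceMatrix":
        """Drop loci with no observed presence (monomorphic-absent columns)."""
        keep = (self.states == 1).any(axis=0)
        return self.select_loci(np.flatnonzero(keep))

    def select_loci(self, idx) -> "PresenceAbsenceMatrix":
        idx = np.asarray(idx, dtype=int)
        return PresenceAbsenceMatrix(
            taxa=list(self.taxa),
            loci_ids=[self.loci_ids[i] for i in idx],
            states=self.states[:, idx].copy(),
            het_flags=self.het_flags[:, idx].copy(),
        )

    def select_taxa(self, names: list[str]) -> "PresenceAbsenceMatrix":
        rows = [self.taxon_index(n) for n in names]
        return PresenceAbsenceMatrix(
            taxa=list(names),
            loci_ids=list(self.loci_ids),
            states=self.states[rows, :].copy(),
            het_flags=self.het_flags[rows, :].copy(),
        )

    def presence_sets(self):
        """Yield, per locus, the frozenset of taxa with state 1 (skips nothing)."""
        taxa = np.asarray(self.taxa, dtype=object)
        for j in range(self.n_loci):
            yield frozenset(taxa[self.states[:, j] == 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.loci_ids == other.loci_ids
            and np.array_equal(self.states, other.states)
        )


_STATE_TO_SYM = {0: "0", 1: "1", MISSING: "?"}
_SYM_TO_STATE = {"0": 0, "1": 1, "?": MISSING}


def write_nexus(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write a standard-datatype NEXUS DATA block (symbols "01", missing ?).

    Heterozygosity flags are not representable in a binary NEXUS matrix;
    use :func:`write_het_sidecar` alongside.
    """
    if matrix.n_taxa == 0 or matrix.n_loci == 0:
        raise ValueError("refusing to write an empty matrix")
    name_w = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_loci};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("    MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(_STATE_TO_SYM[int(s)] for s in matrix.states[i])
            fh.write(f"    {taxon.replace(' ', '_'):<{name_w}}{row}\n")
        fh.write("    ;\nEND;\n")
        # locus identifiers kept as a comment block so round trips preserve them
        fh.write("[LOCI " + " ".join(matrix.loci_ids) + "]\n")


def read_nexus(path) -> PresenceAbsenceMatrix:
    """Read a binary presence-absence matrix from a NEXUS DATA block."""
    with open(path) as fh:
        text = fh.read()
    m = _NEXUS_DATA_RE.search(text)
    if m is None:
        raise NexusFormatError(f"{path}: no DATA block found")
    block = m.group(1)
    dim = _DIM_RE.search(block)
    if dim is None:
        raise NexusFormatError(f"{path}: DATA block lacks DIMENSIONS")
    fields = dict(
        kv.split("=") for kv in dim.group(1).upper().split() if "=" in kv
    )
    try:
        ntax, nchar = int(fields["NTAX"]), int(fields["NCHAR"])
    except (KeyError, ValueError) as exc:
        raise NexusFormatError(f"{path}: bad DIMENSIONS: {dim.group(0)!r}") from exc
    mat = _MATRIX_RE.search(block)
    if mat is None:
        raise NexusFormatError(f"{path}: DATA block lacks MATRIX")
    taxa: list[str] = []
    rows: list[list[int]] = []
    for line in mat.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        name, seq = parts[0], "".join(parts[1:])
        try:
            rows.append([_SYM_TO_STATE[c] for c in seq])
        except KeyError as exc:
            raise NexusFormatError(
                f"{path}: unexpected symbol {exc.args[0]!r} in row {name!r}"
            ) from None
        taxa.append(name)
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise NexusFormatError(
            f"{path}: MATRIX block does not match NTAX={ntax} NCHAR={nchar}"
        )
    loci = re.search(r"\[LOCI ([^\]]*)\]", text)
    loci_ids = loci.group(1).split() if loci else [f"c{j}" for j in range(nchar)]
    if len(loci_ids) != nchar:
        loci_ids = [f"c{j}" for j in range(nchar)]
    return PresenceAbsenceMatrix(
        taxa=taxa, loci_ids=loci_ids, states=np.array(rows, dtype=np.int8)
    )


def write_het_sidecar(matrix: PresenceAbsenceMatrix, path) -> None:
    """TSV sidecar (locus, taxon, het) listing heterozygous presences."""
    with open(path, "w") as fh:
        fh.write("locus\ttaxon\thet\n")
        ti, lj = np.nonzero(matrix.het_flags)
        for i, j in zip(ti, lj):
            taxon = matrix.taxa[i].replace(" ", "_")
            fh.write(f"{matrix.loci_ids[j]}\t{taxon}\t1\n")


def read_het_sidecar(matrix: PresenceAbsenceMatrix, path) -> PresenceAbsenceMatrix:
    """Return a copy of *matrix* with het_flags loaded from a sidecar TSV."""
    het = np.zeros_like(matrix.states, dtype=bool)
    locus_idx = {l: j for j, l in enumerate(matrix.loci_ids)}
    taxon_idx = {t.replace(" ", "_"): i for i, t in enumerate(matrix.taxa)}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus"):
            raise ValueError(f"{path}: not a het sidecar (bad header)")
        for line in fh:
            locus, taxon, flag = line.rstrip("\n").split("\t")
            if flag == "1" and locus in locus_idx and taxon in taxon_idx:
                het[taxon_idx[taxon], locus_idx[locus]] = True
    return PresenceAbsenceMatrix(
        taxa=list(matrix.taxa),
        loci_ids=list(matrix.loci_ids),
        states=matrix.states.copy(),
        het_flags=het,
    )
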