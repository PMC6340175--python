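"""Principal component analysis of insertion genotypes.

Genotypes are coded as alternate-allele dosages (0/1/2); missing genotypes
are mean-imputed per locus; loci are centred (optionally variance scaled)
and the individuals x loci matrix is decomposed by SVD.  Sign convention:
within each component the largest-magnitude coordinate is made positive, so
results are reproducible across SVD implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mei_io import GT_MISSING, MeiCallSet
from .matrix import MISSING, PresenceAbsenceMatrix


@dataclass
class PcaResult:
    taxa: list[str]
    coordinates: np.ndarray  # taxa x components
    explained_fraction: np.ndarray

    def __post_init__(self) -> None:
        ef = np.asarray(self.explained_fraction, dtype=float)
        if np.any(np.diff(ef) > 1e-9):
            raise ValueError("explained fractions must be non-increasing")
        if ef.sum() > 1.0 + 1e-9:
            raise ValueError("explained fractions sum above 1")


def dosage_table(calls: MeiCallSet) -> tuple[list[str], np.ndarray]:
    """Samples x loci dosage matrix (0/1/2, NaN for missing)."""
    gt = calls.genotypes.T.astype(float)  # samples x loci; codes 0/1/2/-1
    gt[gt == GT_MISSING] = np.nan
    return list(calls.samples), gt


def dosage_from_matrix(matrix: PresenceAbsenceMatrix) -> tuple[list[str], np.ndarray]:
    """Binary fallback when only presence/absence (with het flags) is known."""
    d = matrix.states.astype(float)
    d[matrix.states == MISSING] = np.nan
    d = d * 2.0
    d[matrix.het_flags] = 1.0
    return list(matrix.taxa), d


def pca(
    table: MeiCallSet | PresenceAbsenceMatrix | tuple[list[str], np.ndarray],
    n_components: int = 10,
    scale: bool = False,
) -> PcaResult:
    """PCA of a dosage table; see module docstring for conventions."""
    if isinstance(table, MeiCallSet):
        taxa, d = dosage_table(table)
    elif isinstance(table, PresenceAbsenceMatrix):
        taxa, d = dosage_from_matrix(table)
    else:
        taxa, d = table
        d = np.asarray(d, dtype=float)
    n, m = d.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 taxa and 2 loci")
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d = d.copy()
    d[inds] = np.take(col_mean, inds[1])
    centred = d - d.mean(axis=0)
    if scale:
        sd = centred.std(axis=0, ddof=1)
        keep = sd > 0
        centred = centred[:, keep] / sd[keep]
    if not np.any(centred != 0):
        raise ValueError("constant matrix: PCA undefined")
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    # fix signs
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return PcaResult(
        taxa=taxa, coordinates=coords, explained_fraction=explained[:k]
    )
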