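"""Benchmarking insertion calls against a truth set.

Calls match truth positions one-to-one within a breakpoint window (default
50 bp -- MEI breakpoints are imprecise).  Matching maximises the number of
matched pairs and, among maximum matchings, minimises total distance
(optimal linear assignment), so results are order-independent.

Metric naming: DETR (detection rate, sensitivity over truth loci), FNR =
1 - DETR, TPR (fraction of calls matching truth -- a precision, following
the benchmarked caller's usage; exposed also as ``precision``), FPR =
1 - TPR.  Genotype-level figures: ``genotype_sensitivity`` (fraction of
truly present genotypes called present) and ``genotype_concordance``
(fraction of correctly zygosity-typed genotypes among detected ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .mei_io import GT_HET, GT_HOM, MeiCallSet

_BIG = 1e12


def match_calls(
    truth_positions, called_positions, window_bp: int = 50
) -> list[tuple[int, int]]:
    """One-to-one matching of call to truth positions within *window_bp*.

    Returns index pairs (truth_idx, call_idx).  The matching has maximum
    cardinality; ties are resolved toward smaller total distance, then by
    lower coordinates (inputs are processed in sorted order).
    """
    if window_bp < 0:
        raise ValueError("window must be non-negative")
    t = np.asarray(truth_positions, dtype=np.int64)
    c = np.asarray(called_positions, dtype=np.int64)
    t_order = np.argsort(t, kind="stable")
    c_order = np.argsort(c, kind="stable")
    if len(t) == 0 or len(c) == 0:
        return []
    dist = np.abs(t[t_order][:, None] - c[c_order][None, :]).astype(float)
    cost = np.where(dist <= window_bp, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    out = [
        (int(t_order[i]), int(c_order[j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= window_bp
    ]
    return sorted(out)


@dataclass
class EvalMetrics:
    detr: float
    tpr: float
    fpr: float
    fnr: float
    genotype_sensitivity: float
    genotype_concordance: float
    n_truth: int
    n_calls: int
    n_matched: int

    @property
    def sensitivity(self) -> float:
        return self.detr

    @property
    def precision(self) -> float:
        return self.tpr


def compute_metrics(
    matching: list[tuple[int, int]],
    truth_genotypes: np.ndarray | None = None,
    called_genotypes: np.ndarray | None = None,
    n_truth: int | None = None,
    n_calls: int | None = None,
) -> EvalMetrics:
    """Locus- and genotype-level accuracy from a matching.

    *truth_genotypes*/*called_genotypes* are (loci x samples) code arrays
    aligned to the original (unsorted) truth and call indices; either may be
    omitted, in which case the genotype metrics are NaN.
    """
    if truth_genotypes is not None and n_truth is None:
        n_truth = truth_genotypes.shape[0]
    if called_genotypes is not None and n_calls is None:
        n_calls = called_genotypes.shape[0]
    if n_truth is None or n_calls is None:
        raise ValueError("n_truth and n_calls required (directly or via genotypes)")
    if n_truth == 0:
        raise ValueError("empty truth set: detection rate undefined")
    n_matched = len(matching)
    detr = n_matched / n_truth
    tpr = n_matched / n_calls if n_calls else 0.0
    gsens = gconc = float("nan")
    if truth_genotypes is not None and called_genotypes is not None:
        ti = [m[0] for m in matching]
        ci = [m[1] for m in matching]
        tg = truth_genotypes[ti]
        cg = called_genotypes[ci]
        true_present = truth_genotypes > 0
        n_true_present = int(true_present.sum())
        # genotypes at unmatched truth loci count as undetected
        detected_present = (tg > 0) & (cg > 0)
        if n_true_present:
            gsens = float(detected_present.sum() / n_true_present)
        het_hom = detected_present & np.isin(tg, (GT_HET, GT_HOM))
        if het_hom.sum():
            gconc = float((tg[het_hom] == cg[het_hom]).sum() / het_hom.sum())
    return EvalMetrics(
        detr=detr,
        tpr=tpr,
        fpr=1.0 - tpr,
        fnr=1.0 - detr,
        genotype_sensitivity=gsens,
        genotype_concordance=gconc,
        n_truth=n_truth,
        n_calls=n_calls,
        n_matched=n_matched,
    )


def evaluate_call_set(
    truth: MeiCallSet, calls: MeiCallSet, window_bp: int = 50
) -> EvalMetrics:
    """Convenience wrapper: match by position and score genotypes."""
    matching = match_calls(
        [l.pos for l in truth.loci], [l.pos for l in calls.loci], window_bp
    )
    return compute_metrics(matching, truth.genotypes, calls.genotypes)


def evaluate_replicates(per_replicate: list[EvalMetrics]) -> pd.DataFrame:
    """One row per replicate plus a mean and an SD aggregate row."""
    cols = [
        "detr", "tpr", "fpr", "fnr",
        "genotype_sensitivity", "genotype_concordance",
        "n_truth", "n_calls", "n_matched",
    ]
    df = pd.DataFrame([{c: getattr(m, c) for c in cols} for m in per_replicate])
    df.insert(0, "replicate", range(1, len(per_replicate) + 1))
    agg = df[cols].agg(["mean", "std"])
    agg.insert(0, "replicate", ["mean", "sd"])
    return pd.concat([df, agg], ignore_index=True)


def read_bed_positions(path) -> np.ndarray:
    """1-based insertion points from a BED file (0-based half-open start)."""
    pos = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            pos.append(int(parts[1]) + 1)
    return np.array(pos, dtype=np.int64)


def write_bed_positions(positions, path, chrom: str = "sim1") -> None:
    """Write 1-based points as 0-based half-open single-base BED intervals."""
    with open(path, "w") as fh:
        for p in positions:
            fh.write(f"{chrom}\t{int(p) - 1}\t{int(p)}\n")
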