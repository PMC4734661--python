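"""Scoring of association scans against simulated truth: statistical power,
FDR and Type I error over threshold grids, and candidate-gene enrichment.

A QTN counts as identified when a positive marker lies within the matching
window of it on the same chromosome (inclusive boundary); positives near no
QTN are false positives; Type I error is computed on markers outside every
QTN window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "HitClassification",
    "EvaluationCurves",
    "classify_hits",
    "power_fdr_type1_curves",
    "power_at_type1",
    "enrichment_coefficient",
    "read_intervals_bed",
]

DEFAULT_WINDOW = 50_000


class HitClassification(NamedTuple):
    identified_qtns: np.ndarray    # positions into the truth's QTN list
    false_positives: np.ndarray    # marker indices
    positives: np.ndarray          # marker indices with P <= threshold


def _near_qtn_matrix(markers, truth, window: int) -> np.ndarray:
    """Boolean (m, k): marker within `window` bp of QTN on the same chrom."""
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy(np.int64)
    near = np.zeros((len(markers), truth.n_qtn), dtype=bool)
    for q, (qc, qp) in enumerate(zip(truth.qtn_chroms, truth.qtn_positions)):
        near[:, q] = (chrom == qc) & (np.abs(pos - qp) <= window)
    return near


def classify_hits(
    scan,
    truth,
    window: int = DEFAULT_WINDOW,
    threshold: float = 1e-5,
) -> HitClassification:
    """Split significant markers into QTN detections and false positives."""
    p = scan.p_value
    if np.isnan(p).any():
        raise ValueError("scan has sentinel P values; substitute first")
    positives = np.flatnonzero(p <= threshold)
    near = _near_qtn_matrix(scan.markers, truth, window)
    near_pos = near[positives]
    identified = np.flatnonzero(near_pos.any(axis=0))
    false_pos = positives[~near_pos.any(axis=1)]
    return HitClassification(identified, false_pos, positives)


@dataclass
class EvaluationCurves:
    thresholds: np.ndarray
    power: np.ndarray
    fdr: np.ndarray
    type1: np.ndarray
    window: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "power": self.power,
                "fdr": self.fdr,
                "type1": self.type1,
            }
        )


def power_fdr_type1_curves(
    scans: Sequence,
    truths: Sequence,
    window: int = DEFAULT_WINDOW,
    thresholds: Sequence[float] | None = None,
) -> EvaluationCurves:
    """Replicate-averaged power / FDR / Type I error per threshold.

    power = identified QTNs / total QTNs; FDR = false positives / positives
    (0 when there are no positives); Type I error = significant fraction of
    the markers outside every QTN window.
    """
    if len(scans) != len(truths) or not scans:
        raise ValueError("need equal, nonzero numbers of scans and truths")
    if thresholds is None:
        thresholds = np.logspace(-10, 0, 41)
    thresholds = np.asarray(thresholds, dtype=float)
    power = np.zeros(thresholds.size)
    fdr = np.zeros(thresholds.size)
    type1 = np.zeros(thresholds.size)
    for scan, truth in zip(scans, truths):
        p = scan.p_value
        if np.isnan(p).any():
            raise ValueError("scan has sentinel P values; substitute first")
        near = _near_qtn_matrix(scan.markers, truth, window)
        near_any = near.any(axis=1)
        null_p = p[~near_any]
        for i, thr in enumerate(thresholds):
            sig = p <= thr
            n_pos = int(sig.sum())
            power[i] += near[sig].any(axis=0).sum() / truth.n_qtn
            fdr[i] += (sig & ~near_any).sum() / n_pos if n_pos else 0.0
            type1[i] += (
                (null_p <= thr).mean() if null_p.size else 0.0
            )
    r = len(scans)
    return EvaluationCurves(thresholds, power / r, fdr / r, type1 / r, window)


def power_at_type1(
    scans: Sequence,
    truths: Sequence,
    type1_level: float,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Power at a matched Type I error level.

    The P-value threshold is calibrated as the ``type1_level`` quantile of
    the pooled non-QTN-area P values across replicates, then power is the
    replicate-averaged fraction of QTNs identified at that threshold.
    """
    null_pool = []
    per_rep = []
    for scan, truth in zip(scans, truths):
        near = _near_qtn_matrix(scan.markers, truth, window)
        null_pool.append(scan.p_value[~near.any(axis=1)])
        per_rep.append((scan.p_value, near))
    pooled = np.sort(np.concatenate(null_pool))
    k = int(np.floor(type1_level * pooled.size))
    if k == 0:
        thr = pooled[0] * 0.999999 if pooled.size else 0.0
    else:
        thr = pooled[k - 1]
    total = 0.0
    for p, near in per_rep:
        sig = p <= thr
        total += near[sig].any(axis=0).sum() / near.shape[1]
    return total / len(per_rep)


def _merge_intervals(intervals):
    """Union of 1-based inclusive (chrom, start, end) intervals."""
    by_chrom: dict[str, list[list[int]]] = {}
    for chrom, start, end in sorted(intervals):
        if end < start:
            raise ValueError(f"interval end before start: {(chrom, start, end)}")
        rows = by_chrom.setdefault(chrom, [])
        if rows and start <= rows[-1][1] + 1:
            rows[-1][1] = max(rows[-1][1], end)
        else:
            rows.append([start, end])
    return {
        c: [(s, e) for s, e in rows] for c, rows in by_chrom.items()
    }


def _total_length(merged) -> int:
    return sum(e - s + 1 for rows in merged.values() for s, e in rows)


def enrichment_coefficient(
    hit_positions,
    gene_intervals,
    genome_intervals,
    extension: int = 10_000,
) -> float:
    """Hit density in (extended) gene regions over density outside them.

    Intervals and hits are 1-based inclusive (chrom, start, end) /
    (chrom, pos).  Genes are widened by ``extension`` bp on either side and
    clipped to the genome.  Returns +inf when all hits fall inside genes,
    NaN when there are no hits at all.
    """
    genome = _merge_intervals(genome_intervals)
    bounds = {
        c: (min(s for s, _ in rows), max(e for _, e in rows))
        for c, rows in genome.items()
    }
    extended = []
    for chrom, start, end in gene_intervals:
        if chrom not in bounds:
            raise ValueError(f"gene interval on unknown chromosome {chrom!r}")
        lo, hi = bounds[chrom]
        extended.append(
            (chrom, max(start - extension, lo), min(end + extension, hi))
        )
    genes = _merge_intervals(extended)
    len_gene = _total_length(genes)
    len_genome = _total_length(genome)
    len_out = len_genome - len_gene
    if len_gene == 0 or len_out <= 0:
        raise ValueError("both gene and non-gene regions must have length > 0")

    n_in = 0
    n_total = 0
    for chrom, pos in hit_positions:
        n_total += 1
        for s, e in genes.get(chrom, ()):
            if s <= pos <= e:
                n_in += 1
                break
    if n_total == 0:
        return np.nan
    n_out = n_total - n_in
    if n_out == 0:
        return np.inf
    return (n_in / len_gene) / (n_out / len_out)


def read_intervals_bed(path):
    """BED records (0-based half-open) as 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out
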