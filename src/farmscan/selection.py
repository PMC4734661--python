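"""Pseudo-QTN selection: genomic binning, restricted-likelihood grid
optimization of (bin size, bin count), sample-size capping, and pruning of
correlated candidates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reml

log = logging.getLogger(__name__)

__all__ = [
    "PseudoQTNSet",
    "BinGrid",
    "assign_bins",
    "select_bin_representatives",
    "enforce_qtn_cap",
    "optimize_bin_grid",
    "prune_correlated",
    "qtn_cap",
]

DEFAULT_BIN_SIZES = (500_000, 5_000_000, 50_000_000)
DEFAULT_BIN_COUNTS = tuple(range(10, 101, 10))


@dataclass
class PseudoQTNSet:
    """Ordered pseudo-QTN marker indices, most significant first."""

    indices: np.ndarray
    p_values: np.ndarray
    iteration_added: int = 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.indices.shape != self.p_values.shape:
            raise ValueError("indices and p_values must align")
        if np.any(np.diff(self.p_values) < 0):
            order = np.argsort(self.p_values, kind="stable")
            self.indices = self.indices[order]
            self.p_values = self.p_values[order]

    @classmethod
    def empty(cls) -> "PseudoQTNSet":
        return cls(np.empty(0, int), np.empty(0))

    @property
    def size(self) -> int:
        return self.indices.size

    def marker_id_set(self, markers: pd.DataFrame) -> frozenset:
        return frozenset(markers["marker_id"].iloc[self.indices])


@dataclass
class BinGrid:
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS

    def __post_init__(self) -> None:
        self.bin_sizes = tuple(int(s) for s in self.bin_sizes)
        self.bin_counts = tuple(int(c) for c in self.bin_counts)
        if any(s <= 0 for s in self.bin_sizes):
            raise ValueError("bin sizes must be positive")
        if any(c <= 0 for c in self.bin_counts) or list(self.bin_counts) != sorted(
            set(self.bin_counts)
        ):
            raise ValueError("bin counts must be positive and strictly increasing")


def assign_bins(markers: pd.DataFrame, bin_size: int) -> np.ndarray:
    """Bin label per marker: (chromosome, floor((pos-1)/bin_size)).

    Bins restart at each chromosome boundary.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    chrom = markers["chrom"].to_numpy()
    bin_no = (markers["pos"].to_numpy(np.int64) - 1) // int(bin_size)
    return np.fromiter(
        (f"{c}:{b}" for c, b in zip(chrom, bin_no)), dtype=object, count=len(markers)
    )


def _candidate_frame(scan, bins: np.ndarray) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "index": np.arange(scan.n_markers),
            "p_value": scan.p_value,
            "pos": scan.markers["pos"].to_numpy(),
            "marker_id": scan.markers["marker_id"].to_numpy(),
            "bin": bins,
        }
    )
    if frame["p_value"].isna().any():
        raise ValueError("scan has sentinel P values; substitute before binning")
    return frame


def select_bin_representatives(scan, bins: np.ndarray) -> pd.DataFrame:
    """Most significant marker of each bin, sorted by P value ascending.

    Ties break toward the smaller position, then the lexicographically
    smaller marker id.
    """
    frame = _candidate_frame(scan, bins)
    frame = frame.sort_values(
        ["p_value", "pos", "marker_id"], kind="stable"
    ).drop_duplicates("bin", keep="first")
    return frame.reset_index(drop=True)


def qtn_cap(n_samples: int) -> int:
    """Pseudo-QTN budget floor(n / log10(n))."""
    if n_samples <= 1:
        raise ValueError("need more than one sample for the pseudo-QTN cap")
    return int(np.floor(n_samples / np.log10(n_samples)))


def enforce_qtn_cap(candidates: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    return candidates.head(qtn_cap(n_samples))


def prune_correlated(
    candidates, genotypes, threshold: float = 0.7, iteration: int = 0
) -> PseudoQTNSet:
    """Greedy sweep in significance order: keep a candidate only if its
    dosage column has |Pearson r| <= threshold with every kept one."""
    if isinstance(candidates, pd.DataFrame):
        indices = candidates["index"].to_numpy(int)
        pvals = candidates["p_value"].to_numpy(float)
    else:
        indices = np.asarray(candidates.indices, dtype=int)
        pvals = np.asarray(candidates.p_values, dtype=float)
    kept: list[int] = []
    kept_cols: list[np.ndarray] = []
    for k, idx in enumerate(indices):
        col = genotypes.dosages[:, idx].astype(float)
        sd = col.std()
        if sd == 0:
            continue  # constant marker carries no information
        colz = (col - col.mean()) / sd
        ok = True
        for other in kept_cols:
            r = float(colz @ other) / colz.size
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(k)
            kept_cols.append(colz)
    return PseudoQTNSet(indices[kept], pvals[kept], iteration_added=iteration)


def optimize_bin_grid(
    scan,
    genotypes,
    y,
    grid: BinGrid | None = None,
    candidate_threshold: float | None = None,
) -> tuple[PseudoQTNSet, dict]:
    """Pick the (bin size, bin count) pair whose top bin representatives
    maximize the restricted log-likelihood of the random-effect model.

    Counts are clamped to min(count, floor(n/log10 n), available bins).
    ``candidate_threshold``, if given, restricts candidacy to bin
    representatives with P at or below it before the grid search.
    Returns the winning candidate set plus a record of every grid
    evaluation.  Raises if every candidate set is degenerate.
    """
    grid = grid or BinGrid()
    n = genotypes.n_samples
    cap = qtn_cap(n)
    evaluations = []
    best = None
    for size in grid.bin_sizes:
        reps = select_bin_representatives(scan, assign_bins(scan.markers, size))
        if candidate_threshold is not None:
            reps = reps[reps["p_value"] <= candidate_threshold]
            if reps.empty:
                continue
        seen_counts = set()
        for count in grid.bin_counts:
            take = min(count, cap, len(reps))
            if take == 0 or take in seen_counts:
                continue
            seen_counts.add(take)
            subset = reps.head(take)
            try:
                factor = reml.build_kinship_factor(
                    genotypes, subset["index"].to_numpy(int)
                )
                vc = reml.estimate_variance_components(factor, y)
            except ValueError as exc:
                log.debug("grid (%d, %d) degenerate: %s", size, count, exc)
                continue
            evaluations.append(
                {
                    "bin_size": size,
                    "bin_count": count,
                    "n_pseudo": take,
                    "loglik": vc.loglik,
                    "delta": vc.delta,
                    "converged": vc.converged,
                }
            )
            if best is None or vc.loglik > best[0]:
                best = (vc.loglik, size, count, subset, vc)
    if best is None:
        raise ValueError("every candidate pseudo-QTN set was degenerate")
    loglik, size, count, subset, vc = best
    selected = PseudoQTNSet(
        subset["index"].to_numpy(int), subset["p_value"].to_numpy(float)
    )
    info = {
        "bin_size": size,
        "bin_count": count,
        "loglik": loglik,
        "variance_components": vc,
        "evaluations": evaluations,
    }
    return selected, info
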