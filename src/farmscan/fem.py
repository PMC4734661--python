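"""Fixed-effect single-marker scan with pseudo-QTN covariates.

Each marker is tested by least squares against a fixed design of intercept,
user covariates and the current pseudo-QTN dosage columns.  The design is
factorized once (QR); each marker test is then a rank-one update, so a whole
scan is linear in the number of markers.  Markers collinear with the design
— in particular the pseudo QTNs themselves — receive a not-estimable
sentinel that is later replaced by :func:`substitute_pvalues`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

log = logging.getLogger(__name__)

__all__ = [
    "DesignContext",
    "ScanResult",
    "MarkerTest",
    "build_design",
    "test_marker",
    "scan_genome",
    "substitute_pvalues",
]

#: relative residual-norm tolerance below which a column is collinear
COLLINEAR_TOL = 1e-8
#: smallest P value ever reported (perfect fits and underflow)
P_FLOOR = 1e-300
SUBSTITUTION_METHODS = ("min", "mean", "median", "max", "onsite")


@dataclass
class DesignContext:
    """QR-factorized fixed design [1 | covariates | pseudo-QTN dosages]."""

    design: np.ndarray          # n x p, full column rank
    q: np.ndarray               # n x p orthonormal
    r: np.ndarray               # p x p upper triangular
    r_inv: np.ndarray
    xtx_inv_diag: np.ndarray    # diag((X'X)^-1)
    pseudo_markers: np.ndarray  # marker indices of the retained pseudo cols
    pseudo_cols: np.ndarray     # their column positions in `design`
    dropped_covariates: list[str] = field(default_factory=list)
    dropped_pseudo: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_columns(self) -> int:
        return self.design.shape[1]

    @property
    def n_pseudo(self) -> int:
        return self.pseudo_cols.size


class MarkerTest(NamedTuple):
    effect: float
    se: float
    t_stat: float
    p_value: float
    estimable: bool
    perfect_fit: bool


NOT_ESTIMABLE = MarkerTest(np.nan, np.nan, np.nan, np.nan, False, False)


@dataclass
class ScanResult:
    """Per-marker test results; pseudo-QTN rows carry NaN until substitution."""

    markers: pd.DataFrame
    effect: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    is_pseudo_qtn: np.ndarray
    perfect_fit: np.ndarray
    pseudo_indices: np.ndarray
    pseudo_stats: dict[str, np.ndarray] = field(default_factory=dict)
    substituted_with: str | None = None

    @property
    def n_markers(self) -> int:
        return self.p_value.size

    def copy(self) -> "ScanResult":
        return ScanResult(
            markers=self.markers,
            effect=self.effect.copy(),
            se=self.se.copy(),
            t_stat=self.t_stat.copy(),
            p_value=self.p_value.copy(),
            is_pseudo_qtn=self.is_pseudo_qtn.copy(),
            perfect_fit=self.perfect_fit.copy(),
            pseudo_indices=self.pseudo_indices.copy(),
            pseudo_stats={k: v.copy() for k, v in self.pseudo_stats.items()},
            substituted_with=self.substituted_with,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.markers[["marker_id", "chrom", "pos"]].copy()
        frame["effect"] = self.effect
        frame["se"] = self.se
        frame["t_stat"] = self.t_stat
        frame["p_value"] = self.p_value
        frame["is_pseudo_qtn"] = self.is_pseudo_qtn
        return frame


def _orthonormal_sweep(columns: list[np.ndarray]) -> list[int]:
    """Indices of columns kept by a greedy Gram-Schmidt rank sweep."""
    kept: list[int] = []
    basis: list[np.ndarray] = []
    for i, col in enumerate(columns):
        resid = col.astype(float).copy()
        for q in basis:
            resid -= q @ col * q
        norm0 = np.linalg.norm(col)
        if np.linalg.norm(resid) <= COLLINEAR_TOL * max(norm0, 1.0):
            continue
        basis.append(resid / np.linalg.norm(resid))
        kept.append(i)
    return kept


def build_design(
    genotypes,
    pseudo_indices: Sequence[int] | np.ndarray = (),
    covariates=None,
) -> DesignContext:
    """Assemble and factorize [intercept | covariates | pseudo-QTN columns].

    Linearly dependent columns are dropped: covariates with a warning,
    pseudo QTNs (already significance-ordered, so later = less significant)
    with a log entry.
    """
    n = genotypes.n_samples
    pseudo_indices = np.asarray(pseudo_indices, dtype=int)
    cov_values = (
        covariates.values if covariates is not None else np.empty((n, 0))
    )
    cov_names = list(covariates.names) if covariates is not None else []
    cols = [np.ones(n)]
    labels: list[tuple[str, object]] = [("intercept", None)]
    for j, name in enumerate(cov_names):
        cols.append(cov_values[:, j])
        labels.append(("covariate", name))
    for idx in pseudo_indices:
        cols.append(genotypes.dosages[:, idx])
        labels.append(("pseudo", int(idx)))

    kept = _orthonormal_sweep(cols)
    dropped_cov = [
        labels[i][1] for i in range(len(cols))
        if i not in kept and labels[i][0] == "covariate"
    ]
    dropped_pseudo = [
        labels[i][1] for i in range(len(cols))
        if i not in kept and labels[i][0] == "pseudo"
    ]
    if dropped_cov:
        warnings.warn(f"dropping rank-deficient covariate columns: {dropped_cov}")
    if dropped_pseudo:
        log.info("dropping collinear pseudo QTNs: %s", dropped_pseudo)

    design = np.column_stack([cols[i] for i in kept])
    p = design.shape[1]
    if n <= p + 1:
        raise ValueError(
            f"n={n} samples leave no residual degrees of freedom for a "
            f"design with {p} columns plus one testing marker"
        )
    q, r = np.linalg.qr(design)
    r_inv = solve_triangular(r, np.eye(p))
    pseudo_cols = np.array(
        [k for k, i in enumerate(kept) if labels[i][0] == "pseudo"], dtype=int
    )
    pseudo_markers = np.array(
        [labels[i][1] for i in kept if labels[i][0] == "pseudo"], dtype=int
    )
    return DesignContext(
        design=design,
        q=q,
        r=r,
        r_inv=r_inv,
        xtx_inv_diag=(r_inv ** 2).sum(axis=1),
        pseudo_markers=pseudo_markers,
        pseudo_cols=pseudo_cols,
        dropped_covariates=[str(c) for c in dropped_cov],
        dropped_pseudo=[int(i) for i in dropped_pseudo],
    )


def _chunk_tests(context: DesignContext, y: np.ndarray, g: np.ndarray):
    """Vectorized marker tests for a block of dosage columns.

    Returns per-marker (effect, se, t, p, estimable, perfect) plus the
    pseudo-coefficient P-value matrix (t x block) with NaN in columns whose
    marker is not estimable.
    """
    n, p = context.design.shape
    df = n - p - 1
    qty = context.q.T @ y
    ypp = float(y @ y - qty @ qty)

    qtg = context.q.T @ g                      # p x b
    s = np.einsum("ij,ij->j", g, g) - np.einsum("ij,ij->j", qtg, qtg)
    gnorm2 = np.einsum("ij,ij->j", g, g)
    estimable = s > (COLLINEAR_TOL * np.maximum(np.sqrt(gnorm2), 1.0)) ** 2
    s_safe = np.where(estimable, s, 1.0)

    gy = g.T @ y - qtg.T @ qty
    beta = gy / s_safe
    rss = np.maximum(ypp - beta ** 2 * s_safe, 0.0)
    perfect = rss <= 1e-12 * max(ypp, 1e-12)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / s_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.maximum(pval, P_FLOOR)
    pval[perfect] = P_FLOOR

    bad = ~estimable
    for arr in (beta, se, t, pval):
        arr[bad] = np.nan
    perfect = perfect & estimable

    if context.n_pseudo:
        w = context.r_inv @ qtg                # p x b
        b0 = context.r_inv @ qty               # p
        rows = context.pseudo_cols
        b_ps = b0[rows, None] - w[rows] * beta[None, :]
        var_ps = sigma2[None, :] * (
            context.xtx_inv_diag[rows, None] + w[rows] ** 2 / s_safe[None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ps = b_ps / np.sqrt(var_ps)
        p_ps = 2.0 * stats.t.sf(np.abs(t_ps), df)
        p_ps = np.maximum(p_ps, P_FLOOR)
        p_ps[:, bad] = np.nan
    else:
        p_ps = np.empty((0, g.shape[1]))
    return beta, se, t, pval, estimable, perfect, p_ps


def test_marker(context: DesignContext, y, marker_dosages) -> MarkerTest:
    """Least-squares test of one marker against the fixed design."""
    y = np.asarray(getattr(y, "values", y), dtype=float)
    g = np.asarray(marker_dosages, dtype=float)
    if g.shape != (context.n_samples,):
        raise ValueError("marker dosage length does not match design")
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite marker dosages")
    beta, se, t, pval, estimable, perfect, _ = _chunk_tests(
        context, y, g[:, None]
    )
    if not estimable[0]:
        return NOT_ESTIMABLE
    return MarkerTest(
        float(beta[0]), float(se[0]), float(t[0]), float(pval[0]),
        True, bool(perfect[0]),
    )


def _onsite_pvalues(context: DesignContext, y: np.ndarray) -> np.ndarray:
    """Pseudo-QTN coefficient P values from the fit without a testing marker."""
    if not context.n_pseudo:
        return np.empty(0)
    n, p = context.design.shape
    qty = context.q.T @ y
    b0 = context.r_inv @ qty
    rss = max(float(y @ y - qty @ qty), 0.0)
    df = n - p
    sigma2 = rss / df
    rows = context.pseudo_cols
    var = sigma2 * context.xtx_inv_diag[rows]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, b0[rows] / np.sqrt(np.where(var > 0, var, 1.0)), np.inf)
    return np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)


def scan_genome(
    context: DesignContext,
    y,
    genotypes,
    chunk_size: int = 1024,
    collect: str = "summary",
) -> ScanResult:
    """Test every marker; pseudo-QTN markers receive the sentinel.

    ``collect`` controls how the pseudo-QTN P values observed across marker
    tests are retained for substitution: ``"summary"`` streams running
    min/max/mean (constant memory), ``"full"`` keeps the whole t x m matrix
    (needed only for median substitution).
    """
    if collect not in ("summary", "full"):
        raise ValueError(f"unknown collect mode {collect!r}")
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n, m = genotypes.dosages.shape
    t = context.n_pseudo
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    t_stat = np.full(m, np.nan)
    p_value = np.full(m, np.nan)
    perfect = np.zeros(m, dtype=bool)
    estimable = np.zeros(m, dtype=bool)

    run_min = np.full(t, np.inf)
    run_max = np.full(t, -np.inf)
    run_sum = np.zeros(t)
    run_count = np.zeros(t)
    full_rows: list[np.ndarray] = []

    for start in range(0, m, chunk_size):
        stop = min(start + chunk_size, m)
        block = genotypes.dosages[:, start:stop]
        if not np.all(np.isfinite(block)):
            raise ValueError("non-finite dosages in scan; impute first")
        b, s_, ts, pv, est, pf, p_ps = _chunk_tests(context, y, block)
        effect[start:stop] = b
        se[start:stop] = s_
        t_stat[start:stop] = ts
        p_value[start:stop] = pv
        estimable[start:stop] = est
        perfect[start:stop] = pf
        if t:
            valid = np.isfinite(p_ps)
            run_min = np.minimum(run_min, np.where(valid, p_ps, np.inf).min(axis=1))
            run_max = np.maximum(run_max, np.where(valid, p_ps, -np.inf).max(axis=1))
            run_sum += np.where(valid, p_ps, 0.0).sum(axis=1)
            run_count += valid.sum(axis=1)
            if collect == "full":
                full_rows.append(p_ps)

    is_pseudo = np.zeros(m, dtype=bool)
    is_pseudo[context.pseudo_markers] = True
    # pseudo markers are exactly collinear with the design; enforce sentinel
    for arr in (effect, se, t_stat, p_value):
        arr[is_pseudo] = np.nan
    perfect[is_pseudo] = False

    stats_map: dict[str, np.ndarray] = {}
    if t:
        with np.errstate(invalid="ignore"):
            stats_map["min"] = run_min
            stats_map["max"] = run_max
            stats_map["mean"] = run_sum / np.maximum(run_count, 1)
        stats_map["onsite"] = _onsite_pvalues(context, y)
        if collect == "full":
            matrix = np.concatenate(full_rows, axis=1)
            stats_map["median"] = np.nanmedian(matrix, axis=1)
    return ScanResult(
        markers=genotypes.markers,
        effect=effect,
        se=se,
        t_stat=t_stat,
        p_value=p_value,
        is_pseudo_qtn=is_pseudo,
        perfect_fit=perfect,
        pseudo_indices=context.pseudo_markers.copy(),
        pseudo_stats=stats_map,
    )


def substitute_pvalues(scan: ScanResult, pseudo, method: str = "min") -> ScanResult:
    """Replace each pseudo QTN's sentinel P value by a summary of the P
    values it attained across all marker tests (``min`` = most significant;
    ``onsite`` uses the fit without any testing marker)."""
    if method not in SUBSTITUTION_METHODS:
        raise ValueError(
            f"unknown substitution method {method!r}; "
            f"choose from {SUBSTITUTION_METHODS}"
        )
    indices = np.asarray(getattr(pseudo, "indices", pseudo), dtype=int)
    out = scan.copy()
    out.substituted_with = method
    if indices.size == 0:
        return out
    if not np.array_equal(np.sort(indices), np.sort(scan.pseudo_indices)):
        raise ValueError("pseudo set does not match the one used in the scan")
    if method not in scan.pseudo_stats:
        raise ValueError(
            f"scan did not collect statistics for method {method!r} "
            "(median substitution requires scan_genome(collect='full'))"
        )
    values = scan.pseudo_stats[method]
    for k, idx in enumerate(scan.pseudo_indices):
        out.p_value[idx] = values[k]
    return out
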