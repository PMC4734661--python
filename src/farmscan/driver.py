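"""Orchestration of the iterative fixed/random-model scan.

Each iteration: scan all markers with the current pseudo QTNs as covariates,
substitute the pseudo QTNs' sentinel P values, stop if nothing passes the
Bonferroni-corrected threshold, otherwise reselect pseudo QTNs by the
bin/likelihood grid, prune correlated ones, and repeat until no new pseudo
QTNs appear or the iteration budget is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fem, selection
from .fem import ScanResult
from .io import CovariateSet, GenotypeDataset, Phenotype
from .selection import BinGrid, PseudoQTNSet

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "IterationRecord",
    "RunTrace",
    "FarmCPUResult",
    "significance_gate",
    "converged",
    "run_farmcpu",
]


@dataclass
class RunConfig:
    threshold: float = 0.01              # significance level before Bonferroni
    max_iterations: int = 10
    substitution: str = "min"
    #: optional P-value pre-filter on pseudo-QTN candidates entering the
    #: bin/likelihood grid (None = candidacy is purely likelihood-driven)
    selection_threshold: float | None = None
    bin_grid: BinGrid = field(default_factory=BinGrid)
    prune_threshold: float = 0.7
    covariate_policy: str = "all_iterations"   # or "first_iteration_only"
    seed_qtn_ids: tuple[str, ...] = ()
    strict_convergence: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.covariate_policy not in ("all_iterations", "first_iteration_only"):
            raise ValueError(f"unknown covariate policy {self.covariate_policy!r}")
        if self.substitution not in fem.SUBSTITUTION_METHODS:
            raise ValueError(f"unknown substitution method {self.substitution!r}")


@dataclass
class IterationRecord:
    iteration: int
    pseudo_indices: np.ndarray
    gate_passed: bool
    n_significant: int
    bin_size: int | None = None
    bin_count: int | None = None
    loglik: float | None = None
    selected_indices: np.ndarray | None = None


RunTrace = list[IterationRecord]


@dataclass
class FarmCPUResult:
    scan: ScanResult
    pseudo: PseudoQTNSet
    trace: RunTrace
    status: str


def significance_gate(scan: ScanResult, threshold: float, m: int) -> bool:
    """True iff any marker passes the Bonferroni-corrected threshold."""
    p = scan.p_value[np.isfinite(scan.p_value)]
    return bool(p.size and p.min() <= threshold / m)


def converged(
    previous: PseudoQTNSet, current: PseudoQTNSet, strict: bool = False
) -> bool:
    """Default: stop when the new set adds no new marker (subset of the old);
    strict mode requires exact set equality."""
    prev = set(previous.indices.tolist())
    cur = set(current.indices.tolist())
    return cur == prev if strict else cur <= prev


def _seed_pseudo(genotypes: GenotypeDataset, ids: tuple[str, ...]) -> PseudoQTNSet:
    if not ids:
        return PseudoQTNSet.empty()
    lookup = {m: i for i, m in enumerate(genotypes.marker_ids)}
    missing = [m for m in ids if m not in lookup]
    if missing:
        raise ValueError(f"seed pseudo QTNs not in genotype data: {missing}")
    indices = np.array([lookup[m] for m in ids], dtype=int)
    return PseudoQTNSet(indices, np.zeros(indices.size))


def run_farmcpu(
    genotypes: GenotypeDataset,
    phenotype: Phenotype,
    covariates: CovariateSet | None = None,
    config: RunConfig | None = None,
) -> FarmCPUResult:
    """Run the full iterative procedure on aligned, imputed inputs."""
    config = config or RunConfig()
    if genotypes.has_missing():
        raise ValueError("impute missing genotypes before running")
    if list(phenotype.sample_ids) != list(genotypes.sample_ids):
        raise ValueError("phenotype is not aligned to genotype sample order")
    y = phenotype.values
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains missing values after alignment")
    m = genotypes.n_markers
    n = genotypes.n_samples
    cap = selection.qtn_cap(n)
    collect = "full" if config.substitution == "median" else "summary"

    pseudo = _seed_pseudo(genotypes, config.seed_qtn_ids)
    trace: RunTrace = []
    status = "max-iterations"
    scan: ScanResult | None = None

    for iteration in range(1, config.max_iterations + 1):
        cov = covariates
        if config.covariate_policy == "first_iteration_only" and iteration > 1:
            cov = None
        context = fem.build_design(genotypes, pseudo.indices, cov)
        scan = fem.scan_genome(context, y, genotypes, collect=collect)
        scan = fem.substitute_pvalues(
            scan, context.pseudo_markers, config.substitution
        )
        gate = significance_gate(scan, config.threshold, m)
        finite = scan.p_value[np.isfinite(scan.p_value)]
        record = IterationRecord(
            iteration=iteration,
            pseudo_indices=pseudo.indices.copy(),
            gate_passed=gate,
            n_significant=int((finite <= config.threshold / m).sum()),
        )
        trace.append(record)
        if not gate:
            status = "no-marker-significant"
            break
        if iteration == config.max_iterations:
            status = "max-iterations"
            break
        try:
            candidates, info = selection.optimize_bin_grid(
                scan, genotypes, y, config.bin_grid,
                candidate_threshold=config.selection_threshold,
            )
        except ValueError as exc:
            log.warning("pseudo-QTN selection degenerate: %s", exc)
            status = "no-signal"
            break
        if not any(e["converged"] for e in info["evaluations"]):
            log.warning("restricted likelihood flat on the whole grid")
            status = "no-signal"
            break
        new_pseudo = selection.prune_correlated(
            candidates, genotypes, config.prune_threshold, iteration=iteration
        )
        if new_pseudo.size > cap:  # cap is enforced pre-grid; re-assert
            new_pseudo = PseudoQTNSet(
                new_pseudo.indices[:cap], new_pseudo.p_values[:cap],
                iteration_added=iteration,
            )
        record.bin_size = info["bin_size"]
        record.bin_count = info["bin_count"]
        record.loglik = info["loglik"]
        record.selected_indices = new_pseudo.indices.copy()
        if converged(pseudo, new_pseudo, strict=config.strict_convergence):
            status = "converged"
            break
        pseudo = new_pseudo

    assert scan is not None
    return FarmCPUResult(scan=scan, pseudo=pseudo, trace=trace, status=status)
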