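"""Phenotype simulation with known QTNs, plus a synthetic-genotype fixture
generator with controllable LD blocks.

Phenotypes are additive: QTN effects follow either a geometric series
(effect of the i-th QTN is a**i, i starting at 1) or are all equal; the
residual variance is set from the realized additive variance so that the
realized heritability concentrates at the target:
``sigma_e2 = (1 - h2) * sigma_a2 / h2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset, Phenotype

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_fixture_genotypes",
    "qtn_effects",
    "simulate_phenotype",
    "exclude_qtn_markers",
    "add_group_shift",
    "permute_phenotype",
]


@dataclass
class SimulationConfig:
    n_qtn: int = 100
    heritability: float = 0.5
    effect_model: str = "geometric"      # or "equal"
    geometric_a: float = 0.9             # tested levels: 0.9, 0.95, 1
    qtn_chromosomes: tuple[str, ...] | None = None
    exclude_qtns: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        if not 0.0 < self.geometric_a <= 1.0:
            raise ValueError("geometric parameter must lie in (0, 1]")
        if self.effect_model not in ("geometric", "equal"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.n_qtn < 1:
            raise ValueError("need at least one QTN")


@dataclass
class SimulationTruth:
    qtn_indices: np.ndarray        # columns of the genotype matrix used
    qtn_marker_ids: np.ndarray
    qtn_chroms: np.ndarray
    qtn_positions: np.ndarray
    effects: np.ndarray
    additive: np.ndarray           # per-sample additive genetic value
    sigma_a2: float                # realized additive variance
    sigma_e2: float
    heritability: float            # target h2

    @property
    def n_qtn(self) -> int:
        return self.qtn_indices.size

    def realized_heritability(self, phenotype: Phenotype) -> float:
        total = float(np.var(phenotype.values))
        return float(np.var(self.additive)) / total if total > 0 else np.nan


def generate_fixture_genotypes(
    n: int,
    m: int,
    chromosomes: int = 5,
    chrom_length: int = 5_000_000,
    ld_block_length: int = 500_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_strength: float = 0.8,
    seed: int | None = None,
) -> GenotypeDataset:
    """Synthetic diploid dosages with block-wise LD.

    Two latent haplotypes per sample; within each LD block all markers load
    on a shared Gaussian block factor with weight ``ld_strength``, so
    within-block allele correlation exceeds the (zero) cross-block
    correlation.  Per-marker allele frequencies are uniform on
    ``maf_range``; positions are uniform within chromosomes.
    """
    if n < 2 or m < 2:
        raise ValueError("need at least 2 samples and 2 markers")
    if not 0.0 <= ld_strength < 1.0:
        raise ValueError("ld_strength must lie in [0, 1)")
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)

    per_chrom = np.full(chromosomes, m // chromosomes)
    per_chrom[: m % chromosomes] += 1
    dosage_parts = []
    records = []
    marker_no = 0
    for c in range(chromosomes):
        mc = int(per_chrom[c])
        if mc == 0:
            continue
        positions = np.sort(rng.choice(chrom_length, size=mc, replace=False)) + 1
        freqs = rng.uniform(lo, hi, size=mc)
        blocks = (positions - 1) // ld_block_length
        x = np.empty((2 * n, mc))
        for b in np.unique(blocks):
            cols = np.flatnonzero(blocks == b)
            factor = rng.standard_normal((2 * n, 1))
            noise = rng.standard_normal((2 * n, cols.size))
            x[:, cols] = (
                np.sqrt(ld_strength) * factor + np.sqrt(1 - ld_strength) * noise
            )
        alleles = (x < stats.norm.ppf(freqs)).astype(float)
        dosage_parts.append(alleles[:n] + alleles[n:])
        for pos in positions:
            records.append((f"snp{marker_no}", f"chr{c + 1}", int(pos)))
            marker_no += 1
    markers = pd.DataFrame(records, columns=["marker_id", "chrom", "pos"])
    return GenotypeDataset(
        np.concatenate(dosage_parts, axis=1),
        [f"s{i}" for i in range(n)],
        markers,
    )


def qtn_effects(config: SimulationConfig) -> np.ndarray:
    """Additive effect of the i-th QTN: a**i (geometric) or 1 (equal)."""
    if config.effect_model == "equal":
        return np.ones(config.n_qtn)
    i = np.arange(1, config.n_qtn + 1)
    return config.geometric_a ** i


def simulate_phenotype(
    genotypes: GenotypeDataset,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Phenotype, SimulationTruth]:
    """Sample QTNs, build additive values, add calibrated Gaussian residuals.

    QTNs with zero realized additive variance are resampled (up to 100
    attempts).  With ``exclude_qtns`` set, drop the QTN columns from the
    genotypes afterwards via :func:`exclude_qtn_markers`.
    """
    if config.n_qtn > genotypes.n_markers:
        raise ValueError("more QTNs requested than markers available")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.qtn_chromosomes is not None:
        eligible = np.flatnonzero(
            genotypes.markers["chrom"].isin(config.qtn_chromosomes).to_numpy()
        )
        if eligible.size < config.n_qtn:
            raise ValueError("not enough markers on the allowed chromosomes")
    else:
        eligible = np.arange(genotypes.n_markers)
    effects = qtn_effects(config)
    for _ in range(100):
        qtn = rng.choice(eligible, size=config.n_qtn, replace=False)
        additive = genotypes.dosages[:, qtn] @ effects
        sigma_a2 = float(np.var(additive))
        # relative guard: var of a constant vector is rounding noise, not 0
        if sigma_a2 > 1e-20 * max(float(np.mean(additive) ** 2), 1.0):
            break
    else:
        raise ValueError("could not sample QTNs with nonzero additive variance")

    h2 = config.heritability
    sigma_e2 = (1.0 - h2) * sigma_a2 / h2
    residual = (
        rng.normal(0.0, np.sqrt(sigma_e2), size=genotypes.n_samples)
        if sigma_e2 > 0
        else np.zeros(genotypes.n_samples)
    )
    phenotype = Phenotype(list(genotypes.sample_ids), additive + residual)
    truth = SimulationTruth(
        qtn_indices=qtn,
        qtn_marker_ids=genotypes.marker_ids[qtn],
        qtn_chroms=genotypes.markers["chrom"].to_numpy()[qtn],
        qtn_positions=genotypes.markers["pos"].to_numpy(np.int64)[qtn],
        effects=effects,
        additive=additive,
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        heritability=h2,
    )
    return phenotype, truth


def exclude_qtn_markers(
    genotypes: GenotypeDataset, truth: SimulationTruth
) -> GenotypeDataset:
    """Genotype view without the QTN columns (marker-density experiments)."""
    keep = np.setdiff1d(np.arange(genotypes.n_markers), truth.qtn_indices)
    return genotypes.take_markers(keep)


def add_group_shift(
    phenotype: Phenotype,
    groups,
    shift_fraction: float = 0.5,
    up_group=None,
    down_group=None,
) -> Phenotype:
    """Shift one group by +fraction*SD and another by -fraction*SD.

    Defaults to the first two distinct labels in order of appearance.
    """
    groups = np.asarray(groups)
    if groups.size != phenotype.n_samples:
        raise ValueError("one group label per sample required")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    up = labels[0] if up_group is None else up_group
    down = labels[1] if down_group is None else down_group
    for g in (up, down):
        if g not in labels:
            raise ValueError(f"unknown group label {g!r}")
    if shift_fraction == 0:
        return Phenotype(list(phenotype.sample_ids), phenotype.values.copy())
    sd = float(np.std(phenotype.values))
    values = phenotype.values.copy()
    values[groups == up] += shift_fraction * sd
    values[groups == down] -= shift_fraction * sd
    return Phenotype(list(phenotype.sample_ids), values)


def permute_phenotype(phenotype: Phenotype, seed: int | None = None) -> Phenotype:
    """Shuffle trait values uniformly at random, keeping sample ids fixed."""
    rng = np.random.default_rng(seed)
    return Phenotype(
        list(phenotype.sample_ids), rng.permutation(phenotype.values)
    )
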