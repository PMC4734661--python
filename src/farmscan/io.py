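"""Reading, writing and preparing genotype / phenotype / covariate tables.

File conventions
----------------
genotype  : delimited text, header row of marker ids, first column sample id,
            cells are allele dosages in [0, 2] or the missing code.  An
            optional transposed layout (markers as rows) is supported.
map       : delimited text with columns ``marker_id``, ``chrom``, ``pos``
            (1-based base pairs).
phenotype : two columns, sample id and trait value; non-numeric values are
            treated as missing.
covariates: delimited text, header row of covariate names, first column
            sample id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerRecord",
    "GenotypeDataset",
    "Phenotype",
    "CovariateSet",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "align_samples",
    "impute_missing",
    "filter_by_maf",
    "write_scan_result",
    "read_scan_result",
]

MAP_COLUMNS = ("marker_id", "chrom", "pos")
RESULT_COLUMNS = (
    "marker_id",
    "chrom",
    "pos",
    "effect",
    "se",
    "t_stat",
    "p_value",
    "is_pseudo_qtn",
)


class MarkerRecord(NamedTuple):
    marker_id: str
    chrom: str
    pos: int


@dataclass
class GenotypeDataset:
    """Samples x markers dosage matrix plus marker map.

    ``dosages`` is an ``(n, m)`` float array; missing entries are NaN until
    :func:`impute_missing` is applied.  ``markers`` is a DataFrame with
    columns ``marker_id``, ``chrom``, ``pos`` whose row order matches the
    dosage columns (sorted by position within chromosome).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x markers array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} map records for {m} markers")
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, mean(dosage)/2."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def take_markers(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            dosages=self.dosages[:, index],
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            dosages=self.dosages[index],
            sample_ids=[self.sample_ids[i] for i in index],
            markers=self.markers.copy(),
        )


@dataclass
class Phenotype:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.sample_ids) != self.values.size:
            raise ValueError("phenotype ids and values must align 1:1")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def dropna(self) -> "Phenotype":
        keep = np.isfinite(self.values)
        return Phenotype(
            [s for s, k in zip(self.sample_ids, keep) if k], self.values[keep]
        )


@dataclass
class CovariateSet:
    """An n x c matrix of user covariates (c may be 0)."""

    values: np.ndarray
    names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariates must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.names)):
            raise ValueError("covariate shape does not match ids/names")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, sample_ids: Sequence[str]) -> "CovariateSet":
        return cls(np.empty((len(sample_ids), 0)), [], list(sample_ids))


def _sort_map(markers: pd.DataFrame, dosages: np.ndarray):
    """Sort map records by (chrom, pos) keeping chromosome first-seen order."""
    chrom_order = {c: i for i, c in enumerate(markers["chrom"].unique())}
    order = np.lexsort(
        (
            markers["marker_id"].to_numpy(),
            markers["pos"].to_numpy(),
            markers["chrom"].map(chrom_order).to_numpy(),
        )
    )
    markers = markers.iloc[order].reset_index(drop=True)
    markers["source_index"] = order
    return markers, dosages[:, order]


def read_genotypes(
    genotype_path,
    map_path,
    missing_code: str = "NA",
    sep: str | None = None,
    transposed: bool = False,
) -> GenotypeDataset:
    """Read a dosage table and its marker map.

    The map is sorted by position within each chromosome; the original file
    column order is retained in a ``source_index`` map column.  Missing
    entries become NaN (flagged, not imputed).
    """
    sep = sep if sep is not None else r"\s+|,|\t"
    table = pd.read_csv(
        genotype_path, sep=sep, engine="python", index_col=0, dtype=str
    )
    if transposed:
        table = table.T
    if table.empty:
        raise ValueError(f"empty genotype table: {genotype_path}")
    dosages = (
        table.replace(missing_code, np.nan).apply(pd.to_numeric).to_numpy(float)
    )
    if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
        raise ValueError("dosages outside [0, 2]")

    markers = pd.read_csv(map_path, sep=sep, engine="python", dtype=str)
    markers.columns = [c.lower() for c in markers.columns]
    missing_cols = set(MAP_COLUMNS) - set(markers.columns)
    if missing_cols:
        raise ValueError(f"map file lacks columns {sorted(missing_cols)}")
    markers = markers[list(MAP_COLUMNS)].copy()
    markers["pos"] = markers["pos"].astype(np.int64)
    if (markers["pos"] < 1).any():
        raise ValueError("map positions must be >= 1")
    if len(markers) != table.shape[1]:
        raise ValueError(
            f"genotype table has {table.shape[1]} markers but map has "
            f"{len(markers)} records"
        )
    if not markers["marker_id"].equals(pd.Series(table.columns, name="marker_id")):
        # allow map in different order as long as the id sets agree
        if set(markers["marker_id"]) != set(table.columns):
            raise ValueError("marker ids in map and genotype table differ")
        markers = (
            markers.set_index("marker_id").loc[list(table.columns)].reset_index()
        )
    markers, dosages = _sort_map(markers, dosages)
    return GenotypeDataset(dosages, [str(s) for s in table.index], markers)


def write_genotypes(
    genotypes: GenotypeDataset, genotype_path, map_path, missing_code: str = "NA"
) -> None:
    frame = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample"),
        columns=genotypes.marker_ids,
    )
    frame.to_csv(genotype_path, sep="\t", na_rep=missing_code, float_format="%.17g")
    genotypes.markers[list(MAP_COLUMNS)].to_csv(map_path, sep="\t", index=False)


def read_phenotype(path) -> Phenotype:
    table = pd.read_csv(path, sep=r"\s+|,|\t", engine="python", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"phenotype file needs two columns: {path}")
    if table.empty:
        raise ValueError(f"empty phenotype file: {path}")
    def _parse(token) -> float:
        try:
            return float(token)  # Python strtod round-trips doubles exactly
        except (TypeError, ValueError):
            return np.nan

    values = np.array([_parse(v) for v in table.iloc[:, 1]], dtype=float)
    return Phenotype([str(s) for s in table.iloc[:, 0]], values)


def write_phenotype(phenotype: Phenotype, path) -> None:
    pd.DataFrame(
        {"sample": phenotype.sample_ids, "value": phenotype.values}
    ).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_covariates(path) -> CovariateSet:
    table = pd.read_csv(path, sep=r"\s+|,|\t", engine="python", index_col=0)
    return CovariateSet(
        table.to_numpy(float), [str(c) for c in table.columns],
        [str(s) for s in table.index],
    )


def align_samples(
    genotypes: GenotypeDataset,
    phenotype: Phenotype,
    covariates: CovariateSet | None = None,
):
    """Restrict all inputs to shared samples, in genotype order.

    Samples with missing phenotype are dropped.  Raises if fewer than two
    samples remain.
    """
    phenotype = phenotype.dropna()
    pheno_pos = {s: i for i, s in enumerate(phenotype.sample_ids)}
    cov_pos = (
        {s: i for i, s in enumerate(covariates.sample_ids)}
        if covariates is not None
        else None
    )
    keep = [
        i
        for i, s in enumerate(genotypes.sample_ids)
        if s in pheno_pos and (cov_pos is None or s in cov_pos)
    ]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} samples shared between inputs; need at least 2"
        )
    genotypes = genotypes.take_samples(np.asarray(keep))
    ids = genotypes.sample_ids
    phenotype = Phenotype(
        list(ids), phenotype.values[[pheno_pos[s] for s in ids]]
    )
    if covariates is None:
        covariates = CovariateSet.empty(ids)
    else:
        covariates = CovariateSet(
            covariates.values[[cov_pos[s] for s in ids]],
            list(covariates.names),
            list(ids),
        )
    return genotypes, phenotype, covariates


def impute_missing(
    genotypes: GenotypeDataset, strategy: str = "column_mean"
) -> GenotypeDataset:
    """Fill missing dosages per marker; drop all-missing markers."""
    if strategy not in ("column_mean", "major_allele"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    dosages = genotypes.dosages.copy()
    missing = np.isnan(dosages)
    if not missing.any():
        return genotypes
    all_missing = missing.all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} markers with no observed dosages"
        )
        genotypes = genotypes.take_markers(np.flatnonzero(~all_missing))
        dosages = genotypes.dosages.copy()
        missing = np.isnan(dosages)
    if strategy == "column_mean":
        fill = np.nanmean(dosages, axis=0)
    else:
        fill = np.empty(dosages.shape[1])
        for j in range(dosages.shape[1]):
            col = dosages[~missing[:, j], j]
            vals, counts = np.unique(col, return_counts=True)
            fill[j] = vals[np.argmax(counts)]
    dosages[missing] = np.broadcast_to(fill, dosages.shape)[missing]
    return replace(genotypes, dosages=dosages)


def filter_by_maf(genotypes: GenotypeDataset, threshold: float) -> GenotypeDataset:
    """Drop markers with minor allele frequency below ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    if genotypes.has_missing():
        raise ValueError("impute missing dosages before MAF filtering")
    keep = genotypes.minor_allele_frequencies() >= threshold
    if not keep.any():
        raise ValueError(f"no markers pass MAF >= {threshold}")
    if keep.all():
        return genotypes
    return genotypes.take_markers(np.flatnonzero(keep))


def write_scan_result(result, path) -> None:
    """Write a scan result as a TSV table (not-estimable entries as NA)."""
    result.to_frame().to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.12g"
    )


def read_scan_result(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"scan result file lacks columns {sorted(missing)}")
    return table
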