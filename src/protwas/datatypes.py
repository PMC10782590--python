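"""Core containers shared across the pipeline.

The pipeline is pandas/numpy-centric: per-SNP metadata lives in a
DataFrame indexed like the dosage columns, phenotypes and covariates are
DataFrames keyed by sample id. The thin dataclasses here exist where a
bare frame would lose an invariant (dosage/metadata alignment, weight
allele orientation, LD snp order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every SNP metadata frame carries
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]

#: QC statistics filled in by genotype_qc.compute_snp_stats
SNP_STAT_COLUMNS = ["maf", "info", "missing_rate", "hwe_p", "in_reference_panel"]

VALID_ALLELES = frozenset("ACGT")


class ProtwasError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(ProtwasError):
    """Invalid simulation or pipeline configuration."""


class DataError(ProtwasError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) plus per-SNP metadata.

    ``dosage`` holds values in [0, 2] with ``np.nan`` marking missing
    calls. ``snps`` is a DataFrame with at least :data:`SNP_META_COLUMNS`;
    QC statistics are added in place by ``genotype_qc.compute_snp_stats``.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be 2-dimensional (samples x snps)")
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise DataError(
                f"dosage has {n} rows but {len(self.samples)} sample ids"
            )
        if m != len(self.snps):
            raise DataError(
                f"dosage has {m} columns but {len(self.snps)} SNP records"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise DataError(f"SNP metadata missing columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def column(self, snp_id: str) -> np.ndarray:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(snp_id)
        return self.dosage[:, idx[0]]

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given SNP rows
        (boolean mask or positional index into ``snps``)."""
        sub = self.snps.loc[mask_or_index]
        cols = sub.index.to_numpy()
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=sub.reset_index(drop=True),
            dosage=self.dosage[:, cols],
        )


@dataclass
class WeightModel:
    """Per-SNP prediction weights for one aptamer.

    ``weights`` has columns snp_id, chrom, pos, a1, a2, weight (effect on
    the standardized phenotype per copy of a1). ``cv_r2`` is the internal
    cross-validation R^2 recorded before any retention gate.
    """

    aptamer_id: str
    method: str
    weights: pd.DataFrame
    cv_r2: float
    n_cis: int
    n_trans: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"top1", "lasso", "enet", "blup"}:
            raise DataError(f"unknown method {self.method!r}")
        if len(self.weights) == 0 or not (self.weights["weight"] != 0).any():
            raise DataError("a WeightModel needs at least one nonzero weight")

    @property
    def n_snps(self) -> int:
        return len(self.weights)


@dataclass
class LDMatrix:
    """SNP correlation matrix with an explicit SNP order."""

    snp_ids: list[str]
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = len(self.snp_ids)
        if self.sigma.shape != (k, k):
            raise DataError("LD matrix shape does not match SNP list")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-9):
            raise DataError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-9):
            raise DataError("LD matrix must have unit diagonal")
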