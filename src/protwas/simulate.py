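"""Synthetic cohorts with known truth.

Generates LD-structured genotypes, covariates, protein abundances with
planted cis/trans heritability, and GWAS summary-statistic z-vectors —
everything the pipeline consumes, at desk scale, with bit-reproducible
seeding. A violation-planting helper produces QC fixtures whose
per-criterion exclusion counts are known by construction.

Genotype model: within each LD block, haplotype alleles are indicator
thresholds of a latent AR(1) Gaussian. The latent autocorrelation is
calibrated by root-finding on the bivariate normal orthant probability so
the *dosage* correlation of adjacent SNPs equals the configured ``ld_rho``
(thresholding attenuates correlation, so the latent value is larger).
All SNPs in a block share an allele frequency; blocks are independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    ConfigurationError,
    DataError,
    GenotypeMatrix,
    LDMatrix,
)

logger = logging.getLogger(__name__)

# non-ambiguous allele pairs to draw (a1, a2) from
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_WITHIN_BLOCK_SPACING = 5_000  # bp between adjacent SNPs in a block
_BLOCK_GAP = 3_000_000  # bp between blocks on the same chromosome
_N_CHROMS = 22


@dataclass(frozen=True)
class SimConfig:
    """Dimensions and LD structure of the synthetic study."""

    n_train: int = 2481
    n_valid: int = 820
    n_ref: int = 500
    n_snps: int = 20  # SNPs per LD block
    n_blocks: int = 5
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.4)
    missing_rate: float = 0.0
    info_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_valid", "n_ref", "n_snps", "n_blocks"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be a subset of (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Generative truth for one aptamer, used only by tests/recovery."""

    aptamer_id: str
    gene: str
    gene_chrom: str
    tss: int
    causal_cis_snps: list[tuple[str, float]] = field(default_factory=list)
    causal_trans_snps: list[tuple[str, float]] = field(default_factory=list)
    h2_cis: float = 0.0
    h2_trans: float = 0.0
    gamma: float = 0.0
    gwas_n: int = 100_000

    def __post_init__(self) -> None:
        if self.h2_cis < 0 or self.h2_trans < 0:
            raise ConfigurationError("heritability shares must be non-negative")
        if self.h2_cis + self.h2_trans >= 1:
            raise ConfigurationError("h2_cis + h2_trans must be < 1")
        if self.h2_cis > 0 and not self.causal_cis_snps:
            raise ConfigurationError("h2_cis > 0 requires causal cis SNPs")
        if self.h2_trans > 0 and not self.causal_trans_snps:
            raise ConfigurationError("h2_trans > 0 requires causal trans SNPs")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _binary_corr(t: float, latent_rho: float, p: float) -> float:
    """Pearson correlation of two threshold indicators with latent corr rho."""
    if latent_rho == 0:
        return 0.0
    cov = np.array([[1.0, latent_rho], [latent_rho, 1.0]])
    # P(X > t, Y > t) = P(X <= -t, Y <= -t) by symmetry
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-t, -t])
    return float((p11 - p * p) / (p * (1 - p)))


def _calibrate_latent_rho(target: float, p: float) -> float:
    """Latent Gaussian correlation giving dosage correlation ``target``."""
    if target == 0:
        return 0.0
    t = stats.norm.isf(p)  # allele-1 indicator threshold

    def f(r: float) -> float:
        return _binary_corr(t, r, p) - target

    hi = 0.999999
    if f(hi) < 0:  # target unreachable (should not happen for equal p)
        return hi
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


def simulate_genotypes(
    config: SimConfig, n: int | None = None, seed: int | None = None
) -> GenotypeMatrix:
    """Draw a cohort of dosages with blockwise LD.

    ``n`` defaults to ``config.n_train``; ``seed`` defaults to
    ``config.seed``. Pass distinct seeds to draw independent cohorts from
    the same generative law.
    """
    n = config.n_train if n is None else int(n)
    if n < 1:
        raise ConfigurationError("sample count must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    m = config.n_snps * config.n_blocks
    dosage = np.empty((n, m), dtype=float)
    meta_rows = []

    # SNP identity (layout, alleles, frequencies, info) depends only on the
    # config, so cohorts drawn with different seeds describe the same panel
    meta_rng = np.random.default_rng(config.seed)
    block_mafs = meta_rng.uniform(*config.maf_range, size=config.n_blocks)
    allele_idx = meta_rng.integers(0, len(_ALLELE_PAIRS), size=m)
    infos = meta_rng.uniform(*config.info_range, size=m)

    chrom_cursor: dict[str, int] = {}
    col = 0
    for b in range(config.n_blocks):
        p = block_mafs[b]
        k = config.n_snps
        latent_rho = _calibrate_latent_rho(config.ld_rho, p) if k > 1 else 0.0

        # two haplotypes per sample, latent AR(1) along the block
        z = np.empty((2 * n, k))
        z[:, 0] = rng.standard_normal(2 * n)
        if k > 1:
            eps = rng.standard_normal((2 * n, k - 1))
            c = np.sqrt(1.0 - latent_rho**2)
            for j in range(1, k):
                z[:, j] = latent_rho * z[:, j - 1] + c * eps[:, j - 1]
        t = stats.norm.isf(p)
        alleles = (z > t).astype(float)
        dosage[:, col : col + k] = alleles[:n] + alleles[n:]

        chrom = str(b % _N_CHROMS + 1)
        start = chrom_cursor.get(chrom, 1_000_000) + (
            _BLOCK_GAP if chrom in chrom_cursor else 0
        )
        for j in range(k):
            a1, a2 = _ALLELE_PAIRS[allele_idx[col + j]]
            meta_rows.append(
                {
                    "snp_id": f"rs{col + j + 1}",
                    "chrom": chrom,
                    "pos": start + j * _WITHIN_BLOCK_SPACING,
                    "a1": a1,
                    "a2": a2,
                    "info": infos[col + j],
                    "in_reference_panel": True,
                    "block": b,
                }
            )
        chrom_cursor[chrom] = start + (k - 1) * _WITHIN_BLOCK_SPACING
        col += k

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=pd.DataFrame(meta_rows), dosage=dosage)


@dataclass(frozen=True)
class ViolationSpec:
    """How many SNPs to corrupt per QC criterion (classes disjoint)."""

    low_maf: int = 0
    low_info: int = 0
    high_missing: int = 0
    hwe: int = 0
    ambiguous: int = 0
    not_in_panel: int = 0

    def total(self) -> int:
        return (
            self.low_maf + self.low_info + self.high_missing
            + self.hwe + self.ambiguous + self.not_in_panel
        )


def plant_qc_violations(
    G: GenotypeMatrix, spec: ViolationSpec, seed: int = 0
) -> GenotypeMatrix:
    """Return a copy of ``G`` with exactly the requested QC violations.

    Each corrupted SNP violates a single criterion; assignments are
    disjoint by construction, and ``planted_<class>`` metadata columns
    record the truth.
    """
    if spec.total() > G.n_snps:
        raise ConfigurationError(
            f"requested {spec.total()} violations but only {G.n_snps} SNPs"
        )
    rng = np.random.default_rng(seed)
    n = G.n_samples
    dosage = G.dosage.copy()
    snps = G.snps.copy()

    order = rng.permutation(G.n_snps)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor : cursor + k]
        cursor += k
        return idx

    classes = ["low_maf", "low_info", "high_missing", "hwe", "ambiguous", "not_in_panel"]
    for cls in classes:
        snps[f"planted_{cls}"] = False

    for j in take(spec.low_maf):
        p = rng.uniform(0.005, 0.03)
        dosage[:, j] = rng.binomial(2, p, size=n).astype(float)
        snps.loc[j, "planted_low_maf"] = True

    for j in take(spec.low_info):
        snps.loc[j, "info"] = rng.uniform(0.2, 0.65)
        snps.loc[j, "planted_low_info"] = True

    for j in take(spec.high_missing):
        mask = rng.random(n) < 0.10
        # guarantee the 5% threshold is crossed even at small n
        need = int(np.ceil(0.07 * n)) - int(mask.sum())
        if need > 0:
            extra = rng.choice(np.flatnonzero(~mask), size=need, replace=False)
            mask[extra] = True
        dosage[mask, j] = np.nan
        snps.loc[j, "planted_high_missing"] = True

    for j in take(spec.hwe):
        # inbreeding-style excess homozygosity: with prob F the genotype is
        # homozygous-by-descent, else Hardy-Weinberg
        p = rng.uniform(0.2, 0.4)
        f_inb = 0.5
        ibd = rng.random(n) < f_inb
        g = np.where(ibd, 2 * rng.binomial(1, p, size=n), rng.binomial(2, p, size=n))
        dosage[:, j] = g.astype(float)
        snps.loc[j, "planted_hwe"] = True

    for j in take(spec.ambiguous):
        a1, a2 = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        snps.loc[j, ["a1", "a2"]] = [a1, a2]
        snps.loc[j, "planted_ambiguous"] = True

    for j in take(spec.not_in_panel):
        snps.loc[j, "in_reference_panel"] = False
        snps.loc[j, "planted_not_in_panel"] = True

    return GenotypeMatrix(samples=list(G.samples), snps=snps, dosage=dosage)


def simulate_covariates(samples: list[str], seed: int = 0) -> pd.DataFrame:
    """Age, sex, processing duration and three ancestry PCs."""
    rng = np.random.default_rng(seed)
    n = len(samples)
    return pd.DataFrame(
        {
            "age": rng.normal(55.0, 8.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "duration": np.clip(rng.normal(24.0, 6.0, size=n), 0.5, None),
            "pc1": rng.normal(0.0, 1.0, size=n),
            "pc2": rng.normal(0.0, 1.0, size=n),
            "pc3": rng.normal(0.0, 1.0, size=n),
        },
        index=samples,
    )


DEFAULT_COV_LOADINGS = {
    "age": 0.01,
    "sex": 0.15,
    "duration": 0.01,
    "pc1": 0.05,
    "pc2": 0.05,
    "pc3": 0.05,
}


def _standardize_imputed(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries, then standardize columns."""
    X = np.array(dosage, dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def _genetic_component(
    G: GenotypeMatrix, causal: list[tuple[str, float]], h2: float
) -> np.ndarray:
    """Linear combination of standardized dosages rescaled to variance h2.

    The empirical rescaling makes the planted variance share exact on the
    generated cohort, which is what recovery tests assert against.
    """
    if h2 == 0 or not causal:
        return np.zeros(G.n_samples)
    ids = [s for s, _ in causal]
    lookup = {s: i for i, s in enumerate(G.snps["snp_id"])}
    missing = [s for s in ids if s not in lookup]
    if missing:
        raise ConfigurationError(f"causal SNPs absent from genotypes: {missing}")
    X = _standardize_imputed(G.dosage[:, [lookup[s] for s in ids]])
    g = X @ np.array([e for _, e in causal])
    sd = g.std()
    if sd == 0:
        raise ConfigurationError("causal component has zero variance")
    return g / sd * np.sqrt(h2)


def simulate_proteome(
    G: GenotypeMatrix,
    covariates: pd.DataFrame,
    truth: list[TruthRecord],
    seed: int = 0,
    cov_loadings: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw (exponentiated) protein abundances plus aptamer metadata.

    The latent value is cis + trans + covariate loadings + Gaussian noise
    with variance shares h2_cis / h2_trans / (1 - h2_cis - h2_trans) on
    the genetic+noise part; the emitted raw abundance is exp(latent).
    Returns ``(raw_table, aptamer_meta)`` where the metadata carries the
    encoding gene, its chromosome, and the TSS.
    """
    loadings = DEFAULT_COV_LOADINGS if cov_loadings is None else cov_loadings
    rng = np.random.default_rng(seed)
    covariates = covariates.loc[G.samples]
    cov_part = np.zeros(G.n_samples)
    for name, coef in loadings.items():
        x = covariates[name].to_numpy(dtype=float)
        sd = x.std()
        cov_part = cov_part + coef * ((x - x.mean()) / sd if sd > 0 else 0.0)

    raw = {}
    meta_rows = []
    for rec in truth:
        g_cis = _genetic_component(G, rec.causal_cis_snps, rec.h2_cis)
        g_trans = _genetic_component(G, rec.causal_trans_snps, rec.h2_trans)
        noise_var = 1.0 - rec.h2_cis - rec.h2_trans
        noise = rng.standard_normal(G.n_samples) * np.sqrt(noise_var)
        latent = g_cis + g_trans + cov_part + noise
        raw[rec.aptamer_id] = np.exp(latent)
        meta_rows.append(
            {
                "aptamer_id": rec.aptamer_id,
                "gene": rec.gene,
                "chrom": rec.gene_chrom,
                "tss": rec.tss,
            }
        )
    table = pd.DataFrame(raw, index=G.samples)
    return table, pd.DataFrame(meta_rows)


def scale_weights_unit_variance(w: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Rescale w so the predicted protein has unit variance under sigma."""
    w = np.asarray(w, dtype=float)
    v = float(w @ sigma @ w)
    if v <= 0:
        raise DataError("w' sigma w must be positive to normalize weights")
    return w / np.sqrt(v)


def draw_z(
    sigma: np.ndarray,
    mu: np.ndarray | float = 0.0,
    seed: int = 0,
    size: int = 1,
) -> np.ndarray:
    """Draw ``size`` z-vectors from MVN(mu, sigma); shape (size, k)."""
    sigma = np.asarray(sigma, dtype=float)
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < -1e-8:
        raise DataError(f"LD matrix not PSD (min eigenvalue {vals.min():.3g})")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((size, sigma.shape[0])) @ root.T
    return z + np.asarray(mu, dtype=float)


def simulate_gwas_sumstats(
    ld: LDMatrix,
    snps: pd.DataFrame,
    w_true: np.ndarray,
    gamma: float,
    N: int,
    seed: int = 0,
    null: bool = False,
) -> pd.DataFrame:
    """One GWAS z-vector as a 4-column sumstats frame (SNP A1 A2 Z).

    Under the null the mean is zero; under a protein->disease effect the
    mean is gamma * sqrt(N) * sigma @ w_true, with w_true scaled to unit
    predicted-protein variance.
    """
    sigma = ld.sigma
    if null:
        mu = np.zeros(len(ld.snp_ids))
    else:
        w = scale_weights_unit_variance(np.asarray(w_true, dtype=float), sigma)
        mu = gamma * np.sqrt(N) * sigma @ w
    z = draw_z(sigma, mu, seed=seed, size=1)[0]
    lookup = snps.set_index("snp_id")
    return pd.DataFrame(
        {
            "SNP": ld.snp_ids,
            "A1": lookup.loc[ld.snp_ids, "a1"].to_numpy(),
            "A2": lookup.loc[ld.snp_ids, "a2"].to_numpy(),
            "Z": z,
        }
    )


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truth], fh, indent=1)
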