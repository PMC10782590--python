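"""Variant-level quality control.

Filters applied to the genotype panel before model training: imputation
info >= 0.7, MAF >= 0.05, Hardy-Weinberg exact p >= 5e-6, per-SNP missing
rate < 5%, and membership in the LD reference panel. Strand-ambiguous
(A/T, C/G) variants are flagged here but excluded later, at predictor
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeMatrix, VALID_ALLELES


@dataclass(frozen=True)
class QCThresholds:
    min_info: float = 0.7
    min_maf: float = 0.05
    min_hwe_p: float = 5e-6
    max_missing: float = 0.05  # exclusive: kept iff missing_rate < max_missing
    require_panel: bool = True


#: criterion labels in reporting order
QC_CRITERIA = ["low_info", "low_maf", "hwe", "high_missing", "not_in_panel"]


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over every heterozygote count compatible with the observed
    allele counts, the conditional probability of configurations no more
    probable than the observed one (Wigginton/Cutler/Abecasis). Returns a
    value in (0, 1].
    """
    for name, v in (("n_hom1", n_hom1), ("n_het", n_het), ("n_hom2", n_hom2)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise DataError("HWE test undefined: no genotypes observed")

    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)  # rare allele count
    obs_het = n_het

    # probabilities of each possible het count, built by the standard
    # two-sided recurrence from the mode, then normalized
    probs = {}
    # start at the mode of the distribution
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2) inverse
    common = 2 * n - rare  # common allele count
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[obs_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hard_calls(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest genotype in {0, 1, 2}; NaN preserved."""
    calls = np.rint(dosage)
    return np.clip(calls, 0, 2, out=calls)


def compute_snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Populate maf / missing_rate / hwe_p on ``G.snps`` (in place).

    MAF is computed on non-missing dosages and folded to <= 0.5; the HWE
    p-value uses hard-call genotype counts. A SNP with every entry
    missing gets ``all_missing=True`` and NaN stats — flagged, never
    silently dropped.
    """
    n, m = G.dosage.shape
    miss = np.isnan(G.dosage)
    n_obs = n - miss.sum(axis=0)
    missing_rate = miss.sum(axis=0) / float(n)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_dos = np.nanmean(np.where(miss, np.nan, G.dosage), axis=0)
    freq = mean_dos / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    calls = hard_calls(G.dosage)
    hwe_p = np.full(m, np.nan)
    for j in range(m):
        if n_obs[j] == 0:
            continue
        col = calls[:, j]
        col = col[~np.isnan(col)]
        n_hom1 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 2).sum())
        hwe_p[j] = hwe_exact_test(n_hom1, n_het, n_hom2)

    G.snps["maf"] = maf
    G.snps["missing_rate"] = missing_rate
    G.snps["hwe_p"] = hwe_p
    G.snps["all_missing"] = n_obs == 0
    if "info" not in G.snps.columns:
        G.snps["info"] = 1.0
    if "in_reference_panel" not in G.snps.columns:
        G.snps["in_reference_panel"] = True
    return G.snps


def is_ambiguous(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    for a in (a1, a2):
        if a not in VALID_ALLELES:
            raise ValueError(f"unsupported allele {a!r}; expected one of A,C,G,T")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def filter_snps(
    records: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[set[str], dict[str, int]]:
    """Apply the variant filters; return (kept snp_ids, exclusion counts).

    A SNP is kept iff info >= min_info AND maf >= min_maf AND
    hwe_p >= min_hwe_p AND missing_rate < max_missing AND (when required)
    it is present in the reference panel. A dropped SNP is attributed to
    *every* criterion it fails.
    """
    needed = ["maf", "info", "missing_rate", "hwe_p"]
    for col in needed:
        if col not in records.columns:
            raise DataError(f"SNP stats not populated: missing column {col!r}")
        bad = records.loc[records[col].isna() & ~records.get("all_missing", False)]
        if len(bad):
            raise DataError(
                f"SNP {bad.iloc[0]['snp_id']!r} has undefined {col}; "
                "run compute_snp_stats first"
            )

    fail = pd.DataFrame(index=records.index)
    fail["low_info"] = records["info"] < thresholds.min_info
    fail["low_maf"] = ~(records["maf"] >= thresholds.min_maf)  # NaN maf fails
    fail["hwe"] = ~(records["hwe_p"] >= thresholds.min_hwe_p)
    fail["high_missing"] = ~(records["missing_rate"] < thresholds.max_missing)
    if thresholds.require_panel and "in_reference_panel" in records.columns:
        fail["not_in_panel"] = ~records["in_reference_panel"].astype(bool)
    else:
        fail["not_in_panel"] = False

    dropped = fail.any(axis=1)
    kept = set(records.loc[~dropped, "snp_id"])
    counts = {c: int(fail.loc[dropped, c].sum()) for c in QC_CRITERIA}
    return kept, counts


def qc_report(records: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Per-SNP QC table: stats plus pass/fail flags and overall verdict."""
    kept, _ = filter_snps(records, thresholds)
    rep = records.copy()
    rep["fail_low_info"] = rep["info"] < thresholds.min_info
    rep["fail_low_maf"] = ~(rep["maf"] >= thresholds.min_maf)
    rep["fail_hwe"] = ~(rep["hwe_p"] >= thresholds.min_hwe_p)
    rep["fail_high_missing"] = ~(rep["missing_rate"] < thresholds.max_missing)
    if thresholds.require_panel and "in_reference_panel" in rep.columns:
        rep["fail_not_in_panel"] = ~rep["in_reference_panel"].astype(bool)
    else:
        rep["fail_not_in_panel"] = False
    rep["kept"] = rep["snp_id"].isin(kept)
    return rep
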