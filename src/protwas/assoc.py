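"""Summary-statistic association of predicted protein levels with the
outcome: Z = w'z / sqrt(w' Sigma w) over allele-harmonized model SNPs,
with Sigma estimated from an LD reference panel.

The statistic uses weights on the standardized-dosage scale (per-allele
weights are multiplied by the reference-panel dosage SD) so that it is the
summary-statistic analogue of regressing the outcome on the model
prediction. Models with more than half of their SNPs unusable are skipped;
significance is Bonferroni over the models actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError, GenotypeMatrix, LDMatrix, WeightModel
from .qc import is_ambiguous
from .simulate import _standardize_imputed

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
EIG_FLOOR = 1e-8
MAX_MISSING_FRAC = 0.5  # strictly-greater-than skip rule


@dataclass
class Harmonized:
    """Alignment of one model against the sumstats (and panel)."""

    snp_ids: list[str]
    z: np.ndarray  # sumstats z oriented to the model a1
    w: np.ndarray  # per-allele model weights for the kept SNPs
    missing_frac: float
    dispositions: dict[str, str]  # snp_id -> kept/absent/mismatch/ambiguous


def harmonize(
    model: WeightModel,
    ss: pd.DataFrame,
    panel_snps: set[str] | None = None,
) -> Harmonized:
    """Align model SNPs with sumstats alleles.

    Exact (A1, A2) matches keep z as is; swapped alleles negate z;
    ambiguous, allele-mismatched, or absent SNPs (including SNPs missing
    from the LD panel, when given) are dropped. ``missing_frac`` is
    dropped / total model SNPs.
    """
    if len(model.weights) == 0:
        raise DataError("cannot harmonize an empty model")
    ss_idx = ss.set_index("SNP")
    kept_ids, zs, ws = [], [], []
    dispositions: dict[str, str] = {}
    for _, row in model.weights.iterrows():
        sid = row["snp_id"]
        if sid not in ss_idx.index:
            dispositions[sid] = "absent"
            continue
        if panel_snps is not None and sid not in panel_snps:
            dispositions[sid] = "absent_from_panel"
            continue
        rec = ss_idx.loc[sid]
        a1, a2 = str(rec["A1"]), str(rec["A2"])
        try:
            ambiguous = is_ambiguous(a1, a2) or is_ambiguous(row["a1"], row["a2"])
        except ValueError:
            dispositions[sid] = "mismatch"
            continue
        if ambiguous:
            dispositions[sid] = "ambiguous"
            continue
        if (row["a1"], row["a2"]) == (a1, a2):
            z = float(rec["Z"])
        elif (row["a1"], row["a2"]) == (a2, a1):
            z = -float(rec["Z"])
        else:
            dispositions[sid] = "mismatch"
            continue
        dispositions[sid] = "kept"
        kept_ids.append(sid)
        zs.append(z)
        ws.append(float(row["weight"]))
    missing_frac = 1.0 - len(kept_ids) / len(model.weights)
    return Harmonized(
        snp_ids=kept_ids,
        z=np.asarray(zs, dtype=float),
        w=np.asarray(ws, dtype=float),
        missing_frac=missing_frac,
        dispositions=dispositions,
    )


def _psd_repair(sigma: np.ndarray) -> np.ndarray:
    """Floor eigenvalues at EIG_FLOOR, re-symmetrize, restore unit diagonal."""
    sigma = (sigma + sigma.T) / 2.0
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() >= EIG_FLOOR:
        return sigma
    vals = np.maximum(vals, EIG_FLOOR)
    rep = (vecs * vals) @ vecs.T
    rep = (rep + rep.T) / 2.0
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return rep


def ld_from_panel(
    G_ref: GenotypeMatrix,
    snp_ids: list[str],
    orient_a1: list[str] | None = None,
) -> LDMatrix:
    """Pearson correlation of mean-imputed standardized panel dosages.

    ``orient_a1`` (one allele per SNP) flips any panel column stored with
    the opposite counted allele so the correlations are signed
    consistently with the harmonized weights/z. SNPs absent from the
    panel are dropped with a log entry (they count as missing upstream).
    """
    lookup = {s: i for i, s in enumerate(G_ref.snps["snp_id"])}
    cols, kept = [], []
    for i, sid in enumerate(snp_ids):
        j = lookup.get(sid)
        if j is None:
            logger.warning("SNP %s absent from LD panel; dropped", sid)
            continue
        d = G_ref.dosage[:, j].copy()
        if orient_a1 is not None:
            pa1 = str(G_ref.snps.loc[j, "a1"])
            pa2 = str(G_ref.snps.loc[j, "a2"])
            if orient_a1[i] == pa2:
                d = 2.0 - d
            elif orient_a1[i] != pa1:
                logger.warning("SNP %s alleles mismatch panel; dropped", sid)
                continue
        cols.append(d)
        kept.append(sid)
    if not cols:
        raise DataError("no model SNP present in the LD panel")
    X = _standardize_imputed(np.column_stack(cols))
    sigma = X.T @ X / X.shape[0]
    sigma = _psd_repair(sigma)
    np.fill_diagonal(sigma, 1.0)
    return LDMatrix(snp_ids=kept, sigma=sigma)


def pwas_z(w: np.ndarray, z: np.ndarray, sigma: np.ndarray) -> float:
    """The association statistic w'z / sqrt(w' sigma w)."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if w.shape != z.shape or sigma.shape != (w.size, w.size):
        raise DataError("dimension mismatch between w, z and sigma")
    denom = float(w @ sigma @ w)
    if denom <= 1e-12:
        raise DataError("degenerate variance: w' sigma w <= 1e-12")
    return float(w @ z / np.sqrt(denom))


def pvalue(z: float) -> float:
    """Two-sided normal p, floored at 1e-300."""
    if not np.isfinite(z):
        raise DataError("p-value undefined for non-finite z")
    return max(float(2.0 * stats.norm.sf(abs(z))), P_FLOOR)


def panel_dosage_sd(G_ref: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(G_ref.snps["snp_id"])}
    sds = []
    for sid in snp_ids:
        d = G_ref.dosage[:, lookup[sid]]
        sds.append(float(np.nanstd(d)))
    return np.asarray(sds)


def run_pwas(
    models: list[WeightModel],
    ss: pd.DataFrame,
    panel: GenotypeMatrix,
    alpha: float = 0.05,
    abs_threshold: float | None = None,
    extra_meta: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Batch association. Per model: harmonize -> skip if more than half
    the SNPs are unusable -> LD over used SNPs -> z -> p. The Bonferroni
    denominator is the number of models actually tested; pass
    ``abs_threshold`` to additionally flag at a fixed p cutoff.
    """
    if not models:
        raise DataError("no retained models to test")
    panel_ids = set(panel.snps["snp_id"])
    rows = []
    for model in models:
        meta = (extra_meta or {}).get(model.aptamer_id, {})
        base = {
            "aptamer_id": model.aptamer_id,
            "method": model.method,
            "cv_r2": model.cv_r2,
            "n_model_snps": model.n_snps,
            **meta,
        }
        try:
            h = harmonize(model, ss, panel_snps=panel_ids)
            if h.missing_frac > MAX_MISSING_FRAC:
                rows.append(
                    {**base, "n_used": len(h.snp_ids),
                     "missing_frac": h.missing_frac, "z": np.nan, "p": np.nan,
                     "skip_reason": "missing_frac>0.5"}
                )
                continue
            orient = (
                model.weights.set_index("snp_id").loc[h.snp_ids, "a1"]
                .astype(str).tolist()
            )
            ld = ld_from_panel(panel, h.snp_ids, orient_a1=orient)
            if ld.snp_ids != h.snp_ids:  # panel drops count as missing
                keep = [i for i, s in enumerate(h.snp_ids) if s in set(ld.snp_ids)]
                frac = 1.0 - len(keep) / model.n_snps
                if frac > MAX_MISSING_FRAC:
                    rows.append(
                        {**base, "n_used": len(keep), "missing_frac": frac,
                         "z": np.nan, "p": np.nan,
                         "skip_reason": "missing_frac>0.5"}
                    )
                    continue
                h.z, h.w = h.z[keep], h.w[keep]
                h.snp_ids = [h.snp_ids[i] for i in keep]
                h.missing_frac = frac
            sd = panel_dosage_sd(panel, h.snp_ids)
            w_std = h.w * sd  # per-allele -> standardized-dosage scale
            z = pwas_z(w_std, h.z, ld.sigma)
            rows.append(
                {**base, "n_used": len(h.snp_ids), "missing_frac": h.missing_frac,
                 "z": z, "p": pvalue(z), "skip_reason": ""}
            )
        except DataError as exc:
            logger.warning("association skipped for %s: %s", model.aptamer_id, exc)
            rows.append(
                {**base, "n_used": 0, "missing_frac": np.nan, "z": np.nan,
                 "p": np.nan, "skip_reason": str(exc)}
            )
    out = pd.DataFrame(rows)
    tested = out["skip_reason"] == ""
    m = int(tested.sum())
    out["n_tested"] = m
    out["significant"] = False
    if m > 0:
        out.loc[tested, "significant"] = out.loc[tested, "p"] < alpha / m
    if abs_threshold is not None:
        out["significant_abs"] = False
        out.loc[tested, "significant_abs"] = out.loc[tested, "p"] < abs_threshold
    return out
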