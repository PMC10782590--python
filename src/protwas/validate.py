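"""External validation: apply trained weights to an independent cohort and
gate on predicted-vs-measured Pearson correlation (signed, r >= 0.1)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeMatrix, WeightModel
from .qc import is_ambiguous

logger = logging.getLogger(__name__)

R_MIN = 0.1


def predict(G2: GenotypeMatrix, model: WeightModel) -> np.ndarray:
    """Predicted protein level: sum of weight * dosage-of-a1 per model SNP.

    Allele handling: exact (a1, a2) matches use the dosage as stored;
    swapped storage contributes flipped dosage (2 - d); ambiguous or
    allele-mismatched or absent SNPs are dropped. Missing dosage entries
    are mean-imputed per SNP.
    """
    lookup = {
        s: i for i, s in enumerate(G2.snps["snp_id"])
    }
    pred = np.zeros(G2.n_samples)
    used = 0
    for _, row in model.weights.iterrows():
        j = lookup.get(row["snp_id"])
        if j is None:
            continue
        ga1, ga2 = G2.snps.loc[j, "a1"], G2.snps.loc[j, "a2"]
        try:
            if is_ambiguous(ga1, ga2):
                continue
        except ValueError:
            continue
        if (row["a1"], row["a2"]) == (ga1, ga2):
            d = G2.dosage[:, j]
        elif (row["a1"], row["a2"]) == (ga2, ga1):
            d = 2.0 - G2.dosage[:, j]
        else:
            continue
        if np.isnan(d).any():
            mu = np.nanmean(d)
            d = np.where(np.isnan(d), mu, d)
        pred = pred + row["weight"] * d
        used += 1
    if used == 0:
        raise DataError(
            f"no usable SNP from model {model.aptamer_id!r} in validation genotypes"
        )
    return pred


@dataclass
class ValidationResult:
    aptamer_id: str
    r: float
    r2: float
    n_used: int
    passed: bool
    reason: str = ""


def validate(
    pred: np.ndarray,
    y2: np.ndarray,
    aptamer_id: str = "",
    r_min: float = R_MIN,
) -> ValidationResult:
    """Signed Pearson correlation of prediction vs measured phenotype."""
    pred = np.asarray(pred, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    paired = np.isfinite(pred) & np.isfinite(y2)
    n = int(paired.sum())
    if n < 10:
        raise DataError(f"need >= 10 paired samples, got {n}")
    p, y = pred[paired], y2[paired]
    if np.std(p) == 0:
        return ValidationResult(aptamer_id, np.nan, np.nan, n, False,
                                reason="zero-variance prediction")
    r = float(np.corrcoef(p, y)[0, 1])
    return ValidationResult(aptamer_id, r, r * r, n, r >= r_min)


def validate_models(
    G2: GenotypeMatrix,
    pheno2: pd.DataFrame,
    models: list[WeightModel],
    r_min: float = R_MIN,
) -> pd.DataFrame:
    """Validation report over a batch of models; failures never abort."""
    rows = []
    for model in models:
        try:
            pred = predict(G2, model)
            res = validate(
                pred, pheno2[model.aptamer_id].to_numpy(), model.aptamer_id, r_min
            )
        except (DataError, KeyError) as exc:
            logger.warning("validation skipped for %s: %s", model.aptamer_id, exc)
            res = ValidationResult(model.aptamer_id, np.nan, np.nan, 0, False,
                                   reason=str(exc))
        rows.append(
            {
                "aptamer_id": res.aptamer_id,
                "r": res.r,
                "r2": res.r2,
                "n_used": res.n_used,
                "pass": res.passed,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)
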