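"""Protein preprocessing: log transform, covariate adjustment, rank-based
inverse normal transform.

Raw relative abundances are log-transformed and regressed on intercept +
age + sex + blood-draw-to-processing duration + three ancestry PCs; the
OLS residuals are then mapped through the normal quantile function at
Blom plotting positions (offset c = 3/8, average ranks for ties).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["age", "sex", "duration", "pc1", "pc2", "pc3"]


def _design_matrix(covs: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(covs))] + [covs[c].to_numpy(dtype=float) for c in columns]
    )
    return X


def adjust_covariates(
    raw: pd.Series | np.ndarray,
    covs: pd.DataFrame,
    columns: list[str] | None = None,
) -> np.ndarray:
    """OLS residuals of log(raw) on intercept + covariates.

    ``raw`` must be strictly positive. ``covs`` rows are aligned
    positionally with ``raw``.
    """
    columns = COVARIATE_COLUMNS if columns is None else columns
    y = np.asarray(raw, dtype=float)
    if len(y) != len(covs):
        raise DataError("abundance vector and covariate table differ in length")
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        sample = covs.index[bad[0]] if covs.index.size else bad[0]
        raise DataError(
            f"non-positive abundance at sample {sample!r}: cannot log-transform"
        )
    logy = np.log(y)
    X = _design_matrix(covs, columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cond = np.linalg.cond(X)
        raise np.linalg.LinAlgError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}, "
            f"condition number {cond:.3g})"
        )
    beta, *_ = np.linalg.lstsq(X, logy, rcond=None)
    return logy - X @ beta


def rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    value_i = Phi^-1((rank_i - c) / (n - 2c + 1)) with average ranks for
    ties; output order matches input order.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DataError(f"rank-inverse normal transform needs n >= 3, got {n}")
    if np.nanmax(x) == np.nanmin(x):
        raise DataError("degenerate input: all values identical")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def prepare_phenotypes(
    proteins: pd.DataFrame,
    covs: pd.DataFrame,
    columns: list[str] | None = None,
    c: float = 3.0 / 8.0,
) -> pd.DataFrame:
    """Adjust and INT-transform every aptamer column.

    ``proteins``: raw abundances, one row per sample (index = sample id),
    one column per aptamer. Samples with any missing covariate are
    dropped listwise (count logged). Returns the adjusted phenotype frame
    on the retained samples.
    """
    columns = COVARIATE_COLUMNS if columns is None else columns
    covs = covs.loc[proteins.index]
    complete = covs[columns].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d samples with missing covariates", n_drop)
    proteins = proteins.loc[complete]
    covs = covs.loc[complete]

    out = {}
    for apt in proteins.columns:
        resid = adjust_covariates(proteins[apt], covs, columns)
        out[apt] = rank_inverse_normal(resid, c=c)
    return pd.DataFrame(out, index=proteins.index)
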