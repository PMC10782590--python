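"""Per-protein predictor selection and weight training.

Seeds are SNPs marginally associated with the adjusted phenotype — cis
(within 1 Mb of the encoding gene's TSS) at Benjamini-Hochberg FDR < 0.05
computed over that protein's cis SNPs, trans elsewhere at p <= 5e-8. All
QC-passing, non-ambiguous SNPs within 100 kb of a seed become candidate
predictors, re-addressed on a single pseudo chromosome. Four learners are
fitted (top1, LASSO, elastic net with mixing 0.5, BLUP-as-ridge); the
method with the best 5-fold out-of-fold R^2 is retained when that R^2 is
at least 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .datatypes import DataError, GenotypeMatrix, WeightModel
from .qc import is_ambiguous
from .simulate import _standardize_imputed

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
CIS_WINDOW = 1_000_000
SEED_WINDOW = 100_000
PSEUDO_SPACER = 1_000_000
METHOD_ORDER = ["top1", "lasso", "enet", "blup"]  # tie-break: sparser first


def _chrom_sort_key(chrom: str):
    c = str(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


def marginal_scan(G: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """Simple linear regression of y on each mean-imputed standardized SNP.

    Returns a frame aligned with ``G.snps`` carrying beta (effect per SD
    of dosage), se, z and the two-sided normal p. Monomorphic SNPs get
    NaN statistics and are skipped downstream.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_samples:
        raise DataError("phenotype length does not match genotype samples")
    n = len(y)
    X = np.array(G.dosage, dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    mono = sd == 0
    sd_safe = np.where(mono, 1.0, sd)
    X /= sd_safe

    yc = y - y.mean()
    beta = X.T @ yc / n  # slope of y on standardized x (var(x)=1)
    resid_var = (yc @ yc) / n - beta**2
    se = np.sqrt(np.maximum(resid_var, 0.0) / (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)

    out = pd.DataFrame(
        {
            "snp_id": G.snps["snp_id"].to_numpy(),
            "chrom": G.snps["chrom"].to_numpy(),
            "pos": G.snps["pos"].to_numpy(),
            "beta": np.where(mono, np.nan, beta),
            "se": np.where(mono, np.nan, se),
            "z": np.where(mono, np.nan, z),
            "p": np.where(mono, np.nan, p),
        }
    )
    n_mono = int(mono.sum())
    if n_mono:
        logger.info("skipped %d monomorphic SNPs in marginal scan", n_mono)
    return out


def bh_reject(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    rejected, *_ = multipletests(p, alpha=q, method="fdr_bh")[:1]
    return rejected


def select_seed_snps(
    scan: pd.DataFrame,
    gene_chrom: str,
    tss: int,
    cis_fdr: float = 0.05,
    trans_p: float = 5e-8,
) -> pd.DataFrame:
    """Seed SNPs: cis by per-protein BH FDR, trans by fixed p threshold.

    cis = within 1 Mb of the TSS on the gene's chromosome; trans is
    everything else (including the rest of the gene's own chromosome).
    Returns the seed rows of ``scan`` with a ``region`` column; empty
    frame when nothing passes (the protein is then unmodellable).
    """
    if tss is None or (isinstance(tss, float) and np.isnan(tss)):
        raise DataError("unknown TSS: protein skipped")
    valid = scan["p"].notna()
    cis_mask = (
        valid
        & (scan["chrom"].astype(str) == str(gene_chrom))
        & ((scan["pos"] - tss).abs() <= CIS_WINDOW)
    )
    trans_mask = valid & ~cis_mask

    keep = np.zeros(len(scan), dtype=bool)
    cis_idx = np.flatnonzero(cis_mask.to_numpy())
    if cis_idx.size:
        keep[cis_idx] = bh_reject(scan.loc[cis_mask, "p"].to_numpy(), q=cis_fdr)
    trans_idx = np.flatnonzero(
        (trans_mask & (scan["p"] <= trans_p)).to_numpy()
    )
    keep[trans_idx] = True

    seeds = scan.loc[keep].copy()
    seeds["region"] = np.where(cis_mask.loc[keep], "cis", "trans")
    return seeds


@dataclass
class SelectionWindows:
    """Merged +/-100 kb windows around seeds with a pseudo-coordinate map.

    ``windows``: list of (chrom, start, end), half-open [start, end),
    sorted by (chrom, start) with overlapping/adjacent intervals merged.
    Each window block occupies a contiguous pseudo range; blocks are
    separated by a 1 Mb spacer, so within-window order and pairwise
    distances are preserved.
    """

    windows: list[tuple[str, int, int]]
    offsets: list[int] = field(default_factory=list)  # pseudo start per window

    def __post_init__(self) -> None:
        if not self.offsets:
            cursor = 1
            for _, start, end in self.windows:
                self.offsets.append(cursor)
                cursor += (end - start) + PSEUDO_SPACER

    def contains(self, chrom: str, pos: int) -> bool:
        return self._find(chrom, pos) is not None

    def _find(self, chrom: str, pos: int) -> int | None:
        for i, (c, s, e) in enumerate(self.windows):
            if str(c) == str(chrom) and s <= pos < e:
                return i
        return None

    def to_pseudo(self, chrom: str, pos: int) -> int:
        i = self._find(chrom, pos)
        if i is None:
            raise KeyError(f"position {chrom}:{pos} not covered by any window")
        _, start, _ = self.windows[i]
        return self.offsets[i] + (pos - start)

    def from_pseudo(self, pseudo: int) -> tuple[str, int]:
        for i, (c, s, e) in enumerate(self.windows):
            off = self.offsets[i]
            if off <= pseudo < off + (e - s):
                return c, s + (pseudo - off)
        raise KeyError(f"pseudo position {pseudo} outside every window block")


def build_windows(seeds: pd.DataFrame, width: int = SEED_WINDOW) -> SelectionWindows:
    """Merge +/-width intervals around seed SNPs into SelectionWindows."""
    if len(seeds) == 0:
        raise DataError("seed set is empty")
    intervals: dict[str, list[tuple[int, int]]] = {}
    for _, row in seeds.iterrows():
        chrom = str(row["chrom"])
        start = max(1, int(row["pos"]) - width)
        end = int(row["pos"]) + width
        intervals.setdefault(chrom, []).append((start, end))

    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(intervals, key=_chrom_sort_key):
        ivs = sorted(intervals[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlapping or adjacent
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return SelectionWindows(windows=merged)


def extract_predictors(
    G: GenotypeMatrix,
    windows: SelectionWindows,
    kept_snps: set[str] | None = None,
) -> pd.DataFrame:
    """QC-passing, non-ambiguous SNPs inside any window, with pseudo positions.

    Returns the metadata rows (original index preserved as ``col`` for
    dosage lookup) plus a ``pseudo_pos`` column.
    """
    rows = []
    for col, row in G.snps.iterrows():
        if kept_snps is not None and row["snp_id"] not in kept_snps:
            continue
        if is_ambiguous(row["a1"], row["a2"]):
            continue
        if not windows.contains(row["chrom"], int(row["pos"])):
            continue
        r = row.to_dict()
        r["col"] = col
        r["pseudo_pos"] = windows.to_pseudo(row["chrom"], int(row["pos"]))
        rows.append(r)
    if not rows:
        logger.info("no predictors in windows: protein skipped")
        return pd.DataFrame(columns=list(G.snps.columns) + ["col", "pseudo_pos"])
    return pd.DataFrame(rows).sort_values("pseudo_pos").reset_index(drop=True)


# ---------------------------------------------------------------------------
# learners


def _top1_weights(X: np.ndarray, y: np.ndarray, snp_ids: list[str]) -> np.ndarray:
    """Single best marginal predictor; weight = its marginal beta."""
    n = len(y)
    yc = y - y.mean()
    beta = X.T @ yc / n
    resid_var = np.maximum((yc @ yc) / n - beta**2, 0.0)
    se = np.sqrt(resid_var / (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta / se)
    p = 2.0 * stats.norm.sf(z)
    # tie-break: smallest p, then largest |z|, then lexicographic snp_id
    order = sorted(
        range(len(snp_ids)), key=lambda j: (p[j], -z[j], str(snp_ids[j]))
    )
    best = order[0]
    w = np.zeros(X.shape[1])
    w[best] = beta[best]
    return w


def _estimate_h2_ml(X: np.ndarray, y: np.ndarray, grid=None) -> float:
    """Single-component maximum-likelihood h^2 of y = g + e, g = Xu.

    Works in the m x m eigenbasis of X'X/m (m = predictors), profiling the
    total variance. Returns the grid argmax; callers treat a boundary hit
    as an estimation failure.
    """
    n, m = X.shape
    grid = np.linspace(0.01, 0.99, 99) if grid is None else grid
    K_small = X.T @ X / m  # m x m; nonzero eigvals shared with XX'/m
    vals, vecs = np.linalg.eigh(K_small)
    vals = np.clip(vals, 0.0, None)
    yc = y - y.mean()
    yty = yc @ yc
    # unit eigenvectors of XX'/m: u = X v / sqrt(m * lambda)
    proj = (X @ vecs) / np.sqrt(np.maximum(m * vals, 1e-300))  # n x m
    u2 = (proj.T @ yc) ** 2
    u2 = np.where(vals > 1e-12, u2, 0.0)
    rest = yty - u2.sum()  # mass in the null space of XX'

    best_h2, best_ll = grid[0], -np.inf
    n_rest = n - int((vals > 1e-12).sum())
    for h2 in grid:
        d = h2 * vals + (1 - h2)  # eigenvalues of h2*K + (1-h2)I
        quad = (u2 / d).sum() + rest / (1 - h2)
        logdet = np.log(d[vals > 1e-12]).sum() + n_rest * np.log(1 - h2)
        s2 = quad / n  # profiled total variance
        ll = -0.5 * (n * np.log(s2) + logdet)
        if ll > best_ll:
            best_ll, best_h2 = ll, h2
    return float(best_h2)


def _blup_weights(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """BLUP as ridge on standardized genotypes, lambda = m (1-h2)/h2.

    Falls back to a CV-chosen ridge penalty when the h^2 grid estimate
    hits its boundary.
    """
    n, m = X.shape
    h2 = _estimate_h2_ml(X, y)
    if h2 <= 0.011 or h2 >= 0.989:
        lambdas = np.geomspace(1e-3, 1e4, 20)
        kf = KFold(n_splits=3, shuffle=True, random_state=seed)
        scores = np.zeros(len(lambdas))
        for tr, te in kf.split(X):
            for i, lam in enumerate(lambdas):
                r = Ridge(alpha=lam).fit(X[tr], y[tr])
                pred = r.predict(X[te])
                scores[i] += -((y[te] - pred) ** 2).sum()
        lam = float(lambdas[int(np.argmax(scores))])
    else:
        lam = m * (1 - h2) / h2
    model = Ridge(alpha=lam).fit(X, y)
    return model.coef_


def _lasso_weights(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    cv = LassoCV(alphas=30, cv=3, random_state=seed, max_iter=5000).fit(X, y)
    return cv.coef_


def _enet_weights(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    cv = ElasticNetCV(
        l1_ratio=0.5, alphas=30, cv=3, random_state=seed, max_iter=5000
    ).fit(X, y)
    return cv.coef_


_FITTERS = {
    "top1": lambda X, y, ids, seed: _top1_weights(X, y, ids),
    "lasso": lambda X, y, ids, seed: _lasso_weights(X, y, seed),
    "enet": lambda X, y, ids, seed: _enet_weights(X, y, seed),
    "blup": lambda X, y, ids, seed: _blup_weights(X, y, seed),
}


@dataclass
class MethodFit:
    method: str
    weights_std: np.ndarray  # per-SD-of-dosage scale
    cv_r2: float


def _fold_assignment(samples: list[str], folds: int, seed: int) -> np.ndarray:
    """Deterministic outer folds from the seed and *sorted* sample ids.

    Sorting first makes the assignment — and hence cv_r2 — invariant to
    the order samples arrive in.
    """
    order = np.argsort(np.asarray(samples, dtype=object))
    rng = np.random.default_rng(seed)
    labels_sorted = rng.permutation(np.arange(len(samples)) % folds)
    labels = np.empty(len(samples), dtype=int)
    labels[order] = labels_sorted
    return labels


def fit_models(
    X_raw: np.ndarray,
    y: np.ndarray,
    samples: list[str],
    snp_ids: list[str],
    folds: int = 5,
    seed: int = 0,
    methods: list[str] | None = None,
) -> dict[str, MethodFit]:
    """Fit the four learners; cv_r2 is out-of-fold squared correlation.

    ``X_raw`` is the raw dosage submatrix (missing allowed); columns are
    standardized after mean imputation. Weights are returned on the
    standardized-dosage scale.
    """
    methods = METHOD_ORDER if methods is None else methods
    y = np.asarray(y, dtype=float)
    n, m = X_raw.shape
    if n <= folds:
        raise DataError(f"need more samples ({n}) than folds ({folds})")
    if m < 1:
        raise DataError("need at least one predictor")
    # canonical sample order: makes the fold assignment *and* the inner CV
    # splits invariant to the order samples arrive in
    order = np.argsort(np.asarray(samples, dtype=object))
    X_raw = np.asarray(X_raw, dtype=float)[order]
    y = y[order]
    samples = [samples[i] for i in order]
    X = _standardize_imputed(X_raw)
    fold_of = _fold_assignment(samples, folds, seed)

    fits: dict[str, MethodFit] = {}
    for method in methods:
        fitter = _FITTERS[method]
        try:
            oof = np.empty(n)
            for k in range(folds):
                te = fold_of == k
                tr = ~te
                w_k = fitter(X[tr], y[tr], snp_ids, seed)
                oof[te] = X[te] @ w_k
            if np.std(oof) == 0:
                cv_r2 = 0.0
            else:
                cv_r2 = float(np.corrcoef(oof, y)[0, 1] ** 2)
            w_full = fitter(X, y, snp_ids, seed)
            if not np.any(w_full != 0):
                logger.info("method %s produced an all-zero model", method)
                continue
            fits[method] = MethodFit(method=method, weights_std=w_full, cv_r2=cv_r2)
        except Exception as exc:  # per-method failure never kills the protein
            logger.warning("method %s failed: %s", method, exc)
    if not fits:
        raise DataError("every method failed or produced an empty model")
    return fits


@dataclass
class Rejection:
    aptamer_id: str
    reason: str
    best_cv_r2: float | None = None


def choose_best(
    fits: dict[str, MethodFit],
    aptamer_id: str,
    predictors: pd.DataFrame,
    cis_flags: np.ndarray,
    r2_min: float = 0.01,
) -> WeightModel | Rejection:
    """Retain the method with maximal cv_r2 (ties: top1<lasso<enet<blup)."""
    if not fits:
        return Rejection(aptamer_id, "no method fitted")
    best = max(
        fits.values(),
        key=lambda f: (f.cv_r2, -METHOD_ORDER.index(f.method)),
    )
    if best.cv_r2 < r2_min:
        return Rejection(aptamer_id, f"cv_r2 {best.cv_r2:.4f} < {r2_min}", best.cv_r2)

    sd = np.asarray(predictors["dosage_sd"], dtype=float)
    # convert SD-scale weights to per-allele-copy of a1
    with np.errstate(divide="ignore"):
        per_allele = np.where(sd > 0, best.weights_std / sd, 0.0)
    nz = best.weights_std != 0
    weights = pd.DataFrame(
        {
            "snp_id": predictors["snp_id"].to_numpy()[nz],
            "chrom": predictors["chrom"].to_numpy()[nz],
            "pos": predictors["pos"].to_numpy()[nz],
            "a1": predictors["a1"].to_numpy()[nz],
            "a2": predictors["a2"].to_numpy()[nz],
            "weight": per_allele[nz],
            "weight_std": best.weights_std[nz],
        }
    )
    return WeightModel(
        aptamer_id=aptamer_id,
        method=best.method,
        weights=weights,
        cv_r2=best.cv_r2,
        n_cis=int(cis_flags[nz].sum()),
        n_trans=int((~cis_flags[nz]).sum()),
    )


def train_protein(
    G: GenotypeMatrix,
    y: np.ndarray,
    aptamer_id: str,
    gene_chrom: str,
    tss: int,
    kept_snps: set[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    cis_fdr: float = 0.05,
    trans_p: float = 5e-8,
    r2_min: float = 0.01,
) -> WeightModel | Rejection:
    """Full per-protein pipeline: scan, seed, window, fit, gate."""
    scan = marginal_scan(G, y)
    seeds = select_seed_snps(scan, gene_chrom, tss, cis_fdr=cis_fdr, trans_p=trans_p)
    if len(seeds) == 0:
        return Rejection(aptamer_id, "no seed SNP passed cis FDR or trans threshold")
    windows = build_windows(seeds)
    predictors = extract_predictors(G, windows, kept_snps=kept_snps)
    if len(predictors) == 0:
        return Rejection(aptamer_id, "no usable predictor SNP in windows")

    cols = predictors["col"].to_numpy()
    X_raw = G.dosage[:, cols]
    sd = np.nanstd(X_raw, axis=0)
    predictors = predictors.assign(dosage_sd=sd)
    cis_flags = (
        (predictors["chrom"].astype(str) == str(gene_chrom))
        & ((predictors["pos"] - tss).abs() <= CIS_WINDOW)
    ).to_numpy()

    fits = fit_models(
        X_raw, y, G.samples, predictors["snp_id"].tolist(), folds=folds, seed=seed
    )
    return choose_best(fits, aptamer_id, predictors, cis_flags, r2_min=r2_min)
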