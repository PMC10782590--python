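"""Association summaries, risk-SNP distance annotation, and consistency
checks against the packaged 69-row association fixture."""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError

FIXTURE_COLUMNS = [
    "protein", "full_name", "somamer_id", "gene", "method", "n_snps",
    "n_cis", "n_trans", "cv_r2", "external_r2", "z", "p", "distance_kb",
]


def load_table1() -> pd.DataFrame:
    """The packaged 69-row association fixture.

    ``p`` stays a string because two rows carry an upper bound
    ("<1.09e-298") rather than a value; ``p_value``/``p_is_bound`` hold
    the parsed form. ``distance_kb`` is NaN where no risk SNP shares the
    gene's chromosome.
    """
    with resources.files("protwas.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"p": str, "z": str})
    missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"fixture missing columns: {missing}")
    df["z_str"] = df["z"]  # printed form, keeps the decimal count
    df["z"] = df["z"].astype(float)
    df["p_is_bound"] = df["p"].str.startswith("<")
    df["p_value"] = df["p"].str.lstrip("<").astype(float)
    df["distance_kb"] = pd.to_numeric(df["distance_kb"], errors="coerce")
    return df


@dataclass
class AssociationSummary:
    n_tested: int
    n_skipped: int
    n_significant: int
    n_positive: int
    n_negative: int


def summarize(results: pd.DataFrame, z_col: str = "z",
              significant_col: str = "significant") -> AssociationSummary:
    """Counts and direction split over an association table."""
    if len(results) == 0:
        raise DataError("cannot summarize an empty result table")
    if "skip_reason" in results.columns:
        skipped = results["skip_reason"].fillna("") != ""
    else:
        skipped = results[z_col].isna()
    sig = results.get(significant_col, pd.Series(True, index=results.index))
    sig = sig.fillna(False).astype(bool) & ~skipped
    z = results.loc[sig, z_col]
    return AssociationSummary(
        n_tested=int((~skipped).sum()),
        n_skipped=int(skipped.sum()),
        n_significant=int(sig.sum()),
        n_positive=int((z > 0).sum()),
        n_negative=int((z < 0).sum()),
    )


def annotate_distance(gene_chrom: str, tss: int, risk: pd.DataFrame) -> float:
    """Distance in kb from the TSS to the nearest risk SNP on the same
    chromosome, to 2 decimals; NaN when the chromosome has no risk SNP."""
    same = risk.loc[risk["chrom"].astype(str) == str(gene_chrom)]
    if len(same) == 0:
        return float("nan")
    return round(float((same["pos"] - tss).abs().min()) / 1000.0, 2)


_Z_DECIMALS = re.compile(r"\.(\d+)\s*$")


def _printed_decimals(z_str: str) -> int:
    """Effective printed precision of a z score.

    Trailing zeros are not significant in the fixture's source table
    (rows like 19.80 or 11.10 back-compute to z rounded at 1 decimal),
    so they do not count toward the precision.
    """
    m = _Z_DECIMALS.search(str(z_str))
    return len(m.group(1).rstrip("0")) if m else 0


def _p_range_from_printed_z(z_printed: float, decimals: int) -> tuple[float, float]:
    """Two-sided p interval implied by a z printed to ``decimals`` places."""
    half_ulp = 0.5 * 10.0 ** (-decimals)
    az = abs(z_printed)
    lo = 2.0 * stats.norm.sf(az + half_ulp)
    hi = 2.0 * stats.norm.sf(max(az - half_ulp, 0.0))
    return float(lo), float(hi)


def check_table1(fixture: pd.DataFrame | None = None, rel_tol: float = 0.05) -> dict:
    """Consistency report for the packaged fixture.

    Per row: the printed p must equal 2(1-Phi(|z|)) within ``rel_tol``
    after accounting for the z's printed precision (bound rows "<X" only
    require the recomputed p to fall at or below X). Also checks the
    45/24 direction split and that every row clears the printed
    Bonferroni threshold.
    """
    df = load_table1() if fixture is None else fixture
    missing = [c for c in ("z", "p_value", "p_is_bound") if c not in df.columns]
    if missing:
        raise DataError(f"fixture missing columns: {missing}")

    rows = []
    for _, row in df.iterrows():
        z = float(row["z"])
        decimals = _printed_decimals(row.get("z_str", row["z"]))
        if row["p_is_bound"]:
            p_exact = 2.0 * stats.norm.sf(abs(z))
            ok = p_exact <= row["p_value"]
        else:
            lo, hi = _p_range_from_printed_z(z, decimals)
            ok = (row["p_value"] >= lo * (1 - rel_tol)) and (
                row["p_value"] <= hi * (1 + rel_tol)
            )
        rows.append(ok)
    pz_ok = np.asarray(rows, dtype=bool)

    n_pos = int((df["z"] > 0).sum())
    n_neg = int((df["z"] < 0).sum())
    # bound rows ("<X") are below the threshold by construction; the last
    # row prints exactly at the threshold, so the comparison is inclusive
    below = (df["p_value"] <= 3.01e-5 * (1 + 1e-9)) | df["p_is_bound"]

    return {
        "n_rows": int(len(df)),
        "pz_consistent": bool(pz_ok.all()),
        "pz_failures": df.loc[~pz_ok, "somamer_id"].tolist() if not pz_ok.all() else [],
        "n_positive": n_pos,
        "n_negative": n_neg,
        "direction_split_ok": (n_pos, n_neg) == (45, 24),
        "all_below_bonferroni": bool(below.all()),
    }
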