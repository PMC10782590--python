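"""Plain-text readers and writers.

Genotypes use a two-file TSV dialect: ``<prefix>.dosage.tsv`` (sample_id
column + one column per SNP id, empty cells = missing) and
``<prefix>.snps.tsv`` (snp_id, chrom, pos, a1, a2, info, ...). Summary
statistics are the 4-column "SNP A1 A2 Z" layout; weight models are one
TSV per aptamer plus a JSON sidecar and an index TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeMatrix, WeightModel


def write_genotypes(G: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dos = pd.DataFrame(G.dosage, columns=G.snp_ids)
    dos.insert(0, "sample_id", G.samples)
    dos.to_csv(f"{prefix}.dosage.tsv", sep="\t", index=False, na_rep="")
    G.snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    dos = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t")
    snps = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
    samples = dos["sample_id"].astype(str).tolist()
    matrix = dos.drop(columns=["sample_id"])
    if list(matrix.columns) != snps["snp_id"].tolist():
        raise DataError("dosage columns and SNP metadata rows disagree")
    return GenotypeMatrix(
        samples=samples, snps=snps, dosage=matrix.to_numpy(dtype=float)
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, index_label="sample_id" if index else None)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t")
    needed = {"SNP", "A1", "A2", "Z"}
    if not needed.issubset(ss.columns):
        raise DataError(f"sumstats must have columns {sorted(needed)}")
    if ss["SNP"].duplicated().any():
        raise DataError("duplicate SNP ids in sumstats")
    if not np.isfinite(ss["Z"].to_numpy(dtype=float)).all():
        raise DataError("non-finite Z in sumstats")
    return ss


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ss[["SNP", "A1", "A2", "Z"]].to_csv(path, sep="\t", index=False)


def write_model(model: WeightModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model.weights.to_csv(outdir / f"{model.aptamer_id}.weights.tsv",
                         sep="\t", index=False)
    sidecar = {
        "aptamer_id": model.aptamer_id,
        "method": model.method,
        "cv_r2": model.cv_r2,
        "n_cis": model.n_cis,
        "n_trans": model.n_trans,
        **model.extra,
    }
    with open(outdir / f"{model.aptamer_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_model(outdir: str | Path, aptamer_id: str) -> WeightModel:
    outdir = Path(outdir)
    weights = pd.read_csv(
        outdir / f"{aptamer_id}.weights.tsv", sep="\t", dtype={"chrom": str}
    )
    with open(outdir / f"{aptamer_id}.json") as fh:
        sidecar = json.load(fh)
    extra = {
        k: v
        for k, v in sidecar.items()
        if k not in {"aptamer_id", "method", "cv_r2", "n_cis", "n_trans"}
    }
    return WeightModel(
        aptamer_id=sidecar["aptamer_id"],
        method=sidecar["method"],
        weights=weights,
        cv_r2=sidecar["cv_r2"],
        n_cis=sidecar["n_cis"],
        n_trans=sidecar["n_trans"],
        extra=extra,
    )


def write_model_index(models: list[WeightModel], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = pd.DataFrame(
        [
            {
                "aptamer_id": m.aptamer_id,
                "method": m.method,
                "n_snps": m.n_snps,
                "n_cis": m.n_cis,
                "n_trans": m.n_trans,
                "cv_r2": m.cv_r2,
            }
            for m in models
        ]
    )
    idx.to_csv(outdir / "models.index.tsv", sep="\t", index=False)


def read_model_index(outdir: str | Path) -> list[WeightModel]:
    outdir = Path(outdir)
    idx = pd.read_csv(outdir / "models.index.tsv", sep="\t")
    return [read_model(outdir, a) for a in idx["aptamer_id"]]
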