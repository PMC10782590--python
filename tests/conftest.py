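import numpy as np
import pytest

from protwas.qc import compute_snp_stats, filter_snps
from protwas.simulate import (
    SimConfig,
    TruthRecord,
    simulate_covariates,
    simulate_genotypes,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(
        n_train=600, n_valid=300, n_ref=400, n_snps=15, n_blocks=3,
        ld_rho=0.5, maf_range=(0.1, 0.4), seed=11,
    )


@pytest.fixture(scope="session")
def genotypes(sim_config):
    G = simulate_genotypes(sim_config)
    compute_snp_stats(G)
    return G


@pytest.fixture(scope="session")
def genotypes_valid(sim_config):
    G = simulate_genotypes(sim_config, n=sim_config.n_valid, seed=12)
    compute_snp_stats(G)
    return G


@pytest.fixture(scope="session")
def genotypes_ref(sim_config):
    G = simulate_genotypes(sim_config, n=sim_config.n_ref, seed=13)
    compute_snp_stats(G)
    return G


@pytest.fixture(scope="session")
def kept_snps(genotypes):
    kept, _ = filter_snps(genotypes.snps)
    return kept


@pytest.fixture(scope="session")
def truth_record(genotypes):
    chrom = genotypes.snps.loc[0, "chrom"]
    tss = int(genotypes.snps.loc[7, "pos"])
    return TruthRecord(
        aptamer_id="APT1",
        gene="GENE1",
        gene_chrom=chrom,
        tss=tss,
        causal_cis_snps=[("rs3", 0.8), ("rs9", 0.4)],
        causal_trans_snps=[("rs35", 1.0)],
        h2_cis=0.25,
        h2_trans=0.05,
        gamma=0.05,
        gwas_n=100_000,
    )


@pytest.fixture(scope="session")
def study(genotypes, genotypes_valid, truth_record):
    """Raw proteins + covariates for both cohorts under one truth record."""
    covs1 = simulate_covariates(genotypes.samples, seed=21)
    covs2 = simulate_covariates(genotypes_valid.samples, seed=22)
    raw1, meta = simulate_proteome(genotypes, covs1, [truth_record], seed=23)
    raw2, _ = simulate_proteome(genotypes_valid, covs2, [truth_record], seed=24)
    return {
        "covs1": covs1, "covs2": covs2, "raw1": raw1, "raw2": raw2, "meta": meta,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
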