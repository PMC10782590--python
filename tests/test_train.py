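"""Predictor selection (BH seeds, windows, pseudo chromosome) and the four
learners with out-of-fold R^2."""

import numpy as np
import pandas as pd
import pytest

from protwas.datatypes import DataError
from protwas.prep import prepare_phenotypes
from protwas.simulate import (
    SimConfig,
    TruthRecord,
    simulate_covariates,
    simulate_genotypes,
    simulate_proteome,
)
from protwas.train import (
    Rejection,
    SelectionWindows,
    bh_reject,
    build_windows,
    choose_best,
    extract_predictors,
    fit_models,
    marginal_scan,
    select_seed_snps,
    train_protein,
)


def bh_stepup_oracle(pvals, q):
    """Brute-force step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestMarginalScan:
    def test_noiseless_single_snp(self, genotypes):
        y = 2.0 * np.nan_to_num(genotypes.dosage[:, 0])
        scan = marginal_scan(genotypes, y)
        assert scan.loc[0, "p"] <= 1e-30
        # slope on the standardized dosage equals 2 * sd(dosage)
        sd = genotypes.dosage[:, 0].std()
        assert scan.loc[0, "beta"] == pytest.approx(2.0 * sd, rel=1e-6)

    def test_null_uniformity(self):
        cfg = SimConfig(n_train=500, n_snps=50, n_blocks=4, ld_rho=0.0, seed=31)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(32)
        y = rng.standard_normal(G.n_samples)
        scan = marginal_scan(G, y)
        frac = (scan["p"] < 0.05).mean()
        # binomial 99.9% band around 0.05 with m=200
        assert abs(frac - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 200)

    def test_planted_effect_noncentrality(self):
        # median z over replicates ~ sqrt(n h2/(1-h2)) = 16.6 at n=2481
        n, h2 = 2481, 0.1
        rng = np.random.default_rng(33)
        zs = []
        for s in range(12):
            cfg = SimConfig(n_train=n, n_snps=1, n_blocks=1, seed=40 + s)
            G = simulate_genotypes(cfg)
            x = (G.dosage[:, 0] - G.dosage[:, 0].mean()) / G.dosage[:, 0].std()
            y = np.sqrt(h2) * x + np.sqrt(1 - h2) * rng.standard_normal(n)
            zs.append(abs(marginal_scan(G, y).loc[0, "z"]))
        expected = np.sqrt(n * h2 / (1 - h2))
        assert np.median(zs) == pytest.approx(expected, rel=0.15)

    def test_monomorphic_snp_skipped(self, genotypes):
        G2 = genotypes.subset_snps(genotypes.snps.index[:2])
        G2.dosage = G2.dosage.copy()
        G2.dosage[:, 1] = 1.0
        rng = np.random.default_rng(34)
        scan = marginal_scan(G2, rng.standard_normal(G2.n_samples))
        assert np.isnan(scan.loc[1, "z"]) and not np.isnan(scan.loc[0, "z"])


class TestBhAndSeeds:
    def test_bh_hand_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.8])
        rej = bh_reject(p, q=0.05)
        # step-up: p_(4)=0.04 <= 4/5*0.05 -> first four rejected
        assert rej.tolist() == [True, True, True, True, False]

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(35)
        for _ in range(200):
            m = rng.integers(1, 11)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(
                bh_reject(p, q), bh_stepup_oracle(p, q)
            )

    def _scan_frame(self, chrom="1", tss=5_000_000):
        pos = np.array([tss - 500, tss + 10_000, tss + 900_000,
                        tss + 2_000_000, tss + 3_000_000])
        return pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(5)],
                "chrom": [chrom] * 5,
                "pos": pos,
                "p": [0.001, 0.01, 0.8, 4e-8, 5e-8],
                "z": [3.3, 2.6, 0.2, 5.5, 5.45],
                "beta": 0.1, "se": 0.03,
            }
        )

    def test_cis_trans_partition_and_thresholds(self):
        scan = self._scan_frame()
        seeds = select_seed_snps(scan, "1", 5_000_000)
        by_id = seeds.set_index("snp_id")
        # cis: s0,s1 pass BH over the 3 cis p-values (0.001, 0.01, 0.8)
        assert by_id.loc["s0", "region"] == "cis"
        assert by_id.loc["s1", "region"] == "cis"
        assert "s2" not in by_id.index
        # trans: boundary p = 5e-8 is inclusive
        assert by_id.loc["s3", "region"] == "trans"
        assert by_id.loc["s4", "region"] == "trans"

    def test_same_chromosome_beyond_1mb_is_trans(self):
        scan = self._scan_frame()
        seeds = select_seed_snps(scan, "1", 5_000_000)
        assert (seeds.set_index("snp_id").loc[["s3", "s4"], "region"]
                == "trans").all()

    def test_empty_seed_set(self):
        scan = self._scan_frame()
        scan["p"] = [0.5, 0.6, 0.8, 1e-6, 1e-5]  # nothing passes
        seeds = select_seed_snps(scan, "1", 5_000_000)
        assert len(seeds) == 0

    def test_unknown_tss_raises(self):
        with pytest.raises(DataError):
            select_seed_snps(self._scan_frame(), "1", float("nan"))


class TestWindows:
    def _seeds(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])

    def test_overlap_merge(self):
        seeds = self._seeds([("a", "1", 1_000_000), ("b", "1", 1_150_000)])
        w = build_windows(seeds)
        assert w.windows == [("1", 900_000, 1_250_000)]

    def test_left_clip(self):
        w = build_windows(self._seeds([("a", "1", 50_000)]))
        assert w.windows == [("1", 1, 150_000)]

    def test_cross_chromosome_spacer(self):
        seeds = self._seeds([("a", "2", 500_000), ("b", "7", 500_000)])
        w = build_windows(seeds)
        assert len(w.windows) == 2
        end_block1 = w.offsets[0] + (w.windows[0][2] - w.windows[0][1])
        assert w.offsets[1] >= end_block1 + 1_000_000

    def test_pseudo_map_round_trip_and_order(self):
        seeds = self._seeds(
            [("a", "2", 500_000), ("b", "2", 900_000), ("c", "7", 3_000_000)]
        )
        w = build_windows(seeds)
        pts = [("2", 450_000), ("2", 520_000), ("2", 899_000), ("7", 2_950_000)]
        pseudo = [w.to_pseudo(c, p) for c, p in pts]
        assert pseudo == sorted(pseudo)
        for (c, p), q in zip(pts, pseudo):
            assert w.from_pseudo(q) == (c, p)
        # within-window distances preserved
        assert pseudo[1] - pseudo[0] == 70_000

    def test_empty_seeds_rejected(self):
        with pytest.raises(DataError):
            build_windows(pd.DataFrame(columns=["snp_id", "chrom", "pos"]))


class TestExtractPredictors:
    def test_ambiguous_excluded_and_halfopen_end(self, genotypes):
        snps = genotypes.snps
        chrom = snps.loc[0, "chrom"]
        # window covering the first two SNPs, ending exactly at the third
        w = SelectionWindows(
            windows=[(chrom, int(snps.loc[0, "pos"]), int(snps.loc[2, "pos"]))]
        )
        G = genotypes.subset_snps(snps.index[:4])
        G.snps.loc[1, ["a1", "a2"]] = ["A", "T"]  # make one ambiguous
        pred = extract_predictors(G, w)
        assert pred["snp_id"].tolist() == [snps.loc[0, "snp_id"]]

    def test_additive_over_disjoint_windows(self, genotypes):
        snps = genotypes.snps
        chroms = snps["chrom"].unique()
        w1 = SelectionWindows(windows=[(chroms[0], 1, 10**9)])
        w2 = SelectionWindows(windows=[(chroms[1], 1, 10**9)])
        w12 = SelectionWindows(
            windows=[(chroms[0], 1, 10**9), (chroms[1], 1, 10**9)]
        )
        n1 = len(extract_predictors(genotypes, w1))
        n2 = len(extract_predictors(genotypes, w2))
        n12 = len(extract_predictors(genotypes, w12))
        assert n1 > 0 and n2 > 0 and n12 == n1 + n2

    def test_kept_snps_filter_applied(self, genotypes):
        chrom = genotypes.snps.loc[0, "chrom"]
        w = SelectionWindows(windows=[(chrom, 1, 10**9)])
        allpred = extract_predictors(genotypes, w)
        some = set(allpred["snp_id"][: len(allpred) // 2])
        pred = extract_predictors(genotypes, w, kept_snps=some)
        assert set(pred["snp_id"]) == some


class TestFitAndChoose:
    def test_single_noiseless_causal_snp(self, genotypes):
        x = genotypes.dosage[:, 3]
        y = 1.7 * (x - x.mean()) / x.std()
        X = genotypes.dosage[:, [3]]
        fits = fit_models(X, y, genotypes.samples, ["rs4"], seed=0)
        for f in fits.values():
            assert f.cv_r2 == pytest.approx(1.0, abs=0.02)
        assert fits["top1"].weights_std[0] == pytest.approx(1.7, rel=1e-6)

    def test_null_cv_r2_is_small(self):
        # pure-noise phenotype: out-of-fold squared correlation hovers near
        # 1/n; selection noise (top1 especially) fattens the tail, so the
        # assertion is on the mean and on a majority of replicates being
        # rejected by the 0.01 gate rather than on every replicate
        cfg = SimConfig(n_train=500, n_snps=50, n_blocks=1, ld_rho=0.2, seed=51)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(52)
        reps, maxima = 12, []
        for _ in range(reps):
            y = rng.standard_normal(G.n_samples)
            fits = fit_models(G.dosage, y, G.samples, G.snp_ids, seed=1)
            maxima.append(max(f.cv_r2 for f in fits.values()))
        maxima = np.asarray(maxima)
        assert maxima.mean() < 0.02
        assert (maxima < 0.01).sum() >= reps // 2

    def test_sample_and_snp_permutation_invariance(self, genotypes):
        rng = np.random.default_rng(53)
        X = genotypes.dosage[:, :10]
        y = X[:, 2] * 0.4 + rng.standard_normal(genotypes.n_samples)
        base = fit_models(X, y, genotypes.samples, [f"s{j}" for j in range(10)],
                          seed=7)
        perm = rng.permutation(genotypes.n_samples)
        shuffled = fit_models(
            X[perm], y[perm], [genotypes.samples[i] for i in perm],
            [f"s{j}" for j in range(10)], seed=7,
        )
        for m in base:
            assert shuffled[m].cv_r2 == pytest.approx(base[m].cv_r2, rel=1e-9)
        cols = rng.permutation(10)
        colperm = fit_models(X[:, cols], y, genotypes.samples,
                             [f"s{j}" for j in cols], seed=7)
        for m in ("top1", "lasso", "enet", "blup"):
            # coordinate descent visits columns in order, so permuted
            # columns agree only to solver tolerance
            assert colperm[m].cv_r2 == pytest.approx(base[m].cv_r2, rel=1e-4)

    def _fits(self, scores):
        from protwas.train import MethodFit

        return {
            m: MethodFit(m, np.array([0.1]), r2) for m, r2 in scores.items()
        }

    def _predictors(self):
        return pd.DataFrame(
            {"snp_id": ["s0"], "chrom": ["1"], "pos": [100], "a1": ["A"],
             "a2": ["G"], "dosage_sd": [0.7]}
        )

    def test_argmax_choice(self):
        fits = self._fits({"top1": 0.02, "lasso": 0.05, "enet": 0.049,
                           "blup": 0.03})
        model = choose_best(fits, "apt", self._predictors(),
                            np.array([True]))
        assert model.method == "lasso"

    def test_gate_rejects_below_threshold(self):
        fits = self._fits({"top1": 0.005, "blup": 0.009})
        res = choose_best(fits, "apt", self._predictors(), np.array([True]))
        assert isinstance(res, Rejection)
        assert res.best_cv_r2 == pytest.approx(0.009)

    def test_tie_prefers_sparser_method(self):
        fits = self._fits({"lasso": 0.05, "enet": 0.05})
        model = choose_best(fits, "apt", self._predictors(), np.array([True]))
        assert model.method == "lasso"

    def test_per_allele_weight_conversion(self):
        fits = self._fits({"top1": 0.2})
        model = choose_best(fits, "apt", self._predictors(), np.array([True]))
        assert model.weights["weight"].iloc[0] == pytest.approx(0.1 / 0.7)


class TestTrainProtein:
    def test_recovers_planted_architecture(self, genotypes, kept_snps,
                                           truth_record, study):
        pheno = prepare_phenotypes(study["raw1"], study["covs1"])
        res = train_protein(
            genotypes, pheno["APT1"].to_numpy(), "APT1",
            truth_record.gene_chrom, truth_record.tss,
            kept_snps=kept_snps, seed=2,
        )
        assert not isinstance(res, Rejection)
        assert res.cv_r2 > 0.1
        assert res.n_cis >= 1

    def test_pure_noise_protein_rejected(self, genotypes, kept_snps):
        rng = np.random.default_rng(54)
        y = rng.standard_normal(genotypes.n_samples)
        res = train_protein(
            genotypes, y, "NULLAPT", genotypes.snps.loc[0, "chrom"],
            int(genotypes.snps.loc[5, "pos"]), kept_snps=kept_snps, seed=3,
        )
        assert isinstance(res, Rejection)
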