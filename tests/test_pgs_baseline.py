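import inspect

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pgsnn import (
    CovariateTable,
    LdBlockSpec,
    distance_filter,
    fit_covariate_baseline,
    fit_pgs_weights,
    ld_clump,
    pairwise_r2,
    parse_scoring_file,
    run_gwas,
    score_pgs,
    simulate_genotypes,
    split_samples,
    write_scoring_file,
)
from pgsnn.pgs_baseline import PgsWeightSet

from conftest import brute_force_clump, brute_force_distance_filter


class TestRunGwas:
    def test_exact_linear_recovery(self, ld_free_panel):
        y = 2.0 * ld_free_panel.column(ld_free_panel.snp_ids[3]).astype(float)
        gwas = run_gwas(ld_free_panel, y)
        row = gwas.table.set_index("snp_id").loc[ld_free_panel.snp_ids[3]]
        assert row["beta"] == pytest.approx(2.0, abs=1e-10)
        assert row["p_value"] < 1e-300

    def test_matches_statsmodels_ols(self, small_panel):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(small_panel.n_samples)
        gwas = run_gwas(small_panel, y)
        for sid in small_panel.snp_ids[:5]:
            x = small_panel.column(sid).astype(float)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            row = gwas.table.set_index("snp_id").loc[sid]
            assert row["beta"] == pytest.approx(ref.params[1], abs=1e-10)
            assert row["se"] == pytest.approx(ref.bse[1], abs=1e-10)
            assert row["p_value"] == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_permutation_null_calibration(self, small_panel):
        """Under permuted phenotypes ~5% of SNP tests reach p < 0.05."""
        rng = np.random.default_rng(2)
        y = rng.standard_normal(small_panel.n_samples)
        hits, total = 0, 0
        for _ in range(20):
            perm = rng.permutation(small_panel.n_samples)
            gwas = run_gwas(small_panel, y[perm])
            p = gwas.valid["p_value"].to_numpy()
            hits += int((p < 0.05).sum())
            total += len(p)
        assert hits / total == pytest.approx(0.05, abs=0.025)

    def test_monomorphic_snp_flagged(self, small_panel):
        clone = small_panel.subset_samples(small_panel.sample_ids)
        clone.dosages = clone.dosages.copy()
        clone.dosages[:, 0] = 1
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="monomorphic"):
            gwas = run_gwas(clone, rng.standard_normal(clone.n_samples))
        assert np.isnan(gwas.table["beta"].iloc[0])
        assert gwas.valid.shape[0] == small_panel.n_snps - 1

    def test_subset_restricts_samples(self, small_panel):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(small_panel.n_samples)
        gwas = run_gwas(small_panel, y, subset=small_panel.sample_ids[:200])
        assert (gwas.table["n_used"] == 200).all()


def _six_sample_oracle():
    """Closed-form simple regression on a printed 6-sample fixture."""
    x = np.array([0.0, 1, 2, 0, 1, 2])
    y = np.array([0.3, 1.4, 2.2, -0.1, 1.0, 2.5])
    n = 6
    sxx = ((x - x.mean()) ** 2).sum()
    beta = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    rss = ((y - y.mean()) ** 2).sum() - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    return x, y, beta, se


def test_gwas_six_sample_closed_form():
    from test_genotype_sim import panel_from_matrix

    x, y, beta, se = _six_sample_oracle()
    panel = panel_from_matrix(np.column_stack([x, [0, 1, 1, 2, 0, 1]]))
    gwas = run_gwas(panel, y)
    row = gwas.table.set_index("snp_id").loc["s0"]
    assert row["beta"] == pytest.approx(beta, abs=1e-10)
    assert row["se"] == pytest.approx(se, abs=1e-10)


def _random_instance(rng, n_snps, n_samples=120):
    """Random panel + GWAS summary for clump/distance fuzzing."""
    spec = LdBlockSpec(
        n_snps=n_snps,
        block_size=int(rng.integers(1, 5)),
        within_block_rho=float(rng.uniform(0, 0.95)),
        maf_range=(0.2, 0.5),
        bp_spacing=int(rng.integers(50_000, 400_000)),
        blocks_per_chrom=int(rng.integers(2, 6)),
    )
    panel = simulate_genotypes(n_samples, spec, seed=int(rng.integers(2**31)))
    p_values = 10.0 ** rng.uniform(-9, 0, n_snps)
    gwas_table = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "effect_allele": "A",
            "beta": rng.standard_normal(n_snps),
            "se": 1.0,
            "p_value": p_values,
            "n_used": n_samples,
        }
    )
    from pgsnn.pgs_baseline import GwasSummary

    return panel, GwasSummary(gwas_table)


def _oracle_inputs(panel, gwas):
    meta = panel.snps.set_index("snp_id")
    records = [
        (r.snp_id, str(meta.at[r.snp_id, "chrom"]), int(meta.at[r.snp_id, "pos"]), r.p_value)
        for r in gwas.table.itertuples()
    ]
    r2_table = {
        (a, b): pairwise_r2(panel, a, b)
        for a in panel.snp_ids
        for b in panel.snp_ids
        if a != b
    }
    return records, r2_table


class TestLdClump:
    def test_single_snp_kept(self):
        from test_genotype_sim import panel_from_matrix

        panel = panel_from_matrix(np.array([[0], [1], [2], [1]]))
        from pgsnn.pgs_baseline import GwasSummary

        gwas = GwasSummary(
            pd.DataFrame(
                {
                    "snp_id": ["s0"],
                    "effect_allele": "A",
                    "beta": [0.5],
                    "se": [0.1],
                    "p_value": [0.01],
                    "n_used": 4,
                }
            )
        )
        assert ld_clump(gwas, panel) == ["s0"]

    def test_defaults_match_protocol(self):
        sig = inspect.signature(ld_clump)
        assert sig.parameters["r2_threshold"].default == 0.5
        assert sig.parameters["window_kb"].default == 500

    def test_index_absorbs_tagged_neighbour_only(self):
        """Three-SNP configuration: strong tag absorbed, weak tag kept."""
        rng = np.random.default_rng(5)
        n = 4000
        a = rng.integers(0, 3, n)
        flip = rng.random(n) < 0.15
        b = np.where(flip, rng.integers(0, 3, n), a)  # strongly correlated with a
        c = rng.integers(0, 3, n)  # ~independent
        from test_genotype_sim import panel_from_matrix

        panel = panel_from_matrix(np.column_stack([a, b, c]), bp_spacing=100_000)
        assert pairwise_r2(panel, "s0", "s1") > 0.5
        assert pairwise_r2(panel, "s0", "s2") < 0.1
        from pgsnn.pgs_baseline import GwasSummary

        gwas = GwasSummary(
            pd.DataFrame(
                {
                    "snp_id": ["s0", "s1", "s2"],
                    "effect_allele": "A",
                    "beta": 0.1,
                    "se": 0.1,
                    "p_value": [1e-8, 1e-5, 1e-4],
                    "n_used": n,
                }
            )
        )
        assert ld_clump(gwas, panel, r2_threshold=0.5, window_kb=500) == ["s0", "s2"]

    def test_fuzz_matches_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            panel, gwas = _random_instance(rng, int(rng.integers(2, 25)))
            r2_thr = float(rng.uniform(0.05, 0.9))
            window_kb = int(rng.integers(100, 1500))
            records, r2_table = _oracle_inputs(panel, gwas)
            expected = brute_force_clump(records, r2_table, r2_thr, window_kb * 1000)
            assert ld_clump(gwas, panel, r2_thr, window_kb) == expected

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        panel, gwas = _random_instance(rng, 15)
        from pgsnn.pgs_baseline import GwasSummary

        shuffled = GwasSummary(gwas.table.sample(frac=1, random_state=1).reset_index(drop=True))
        assert ld_clump(gwas, panel) == ld_clump(shuffled, panel)


class TestDistanceFilter:
    def test_different_chromosomes_all_kept(self):
        snps = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chrom": ["1", "2", "3"],
                "pos": [100, 120, 90],
                "p_value": [0.1, 0.001, 0.01],
            }
        )
        assert sorted(distance_filter(snps, min_kb=500)) == ["a", "b", "c"]

    def test_chain_keeps_flanks(self):
        """0 / 300kb / 600kb with p 1e-9, 1e-4, 1e-6: middle SNP yields."""
        snps = pd.DataFrame(
            {
                "snp_id": ["x", "y", "z"],
                "chrom": "1",
                "pos": [1, 300_001, 600_001],
                "p_value": [1e-9, 1e-4, 1e-6],
            }
        )
        assert sorted(distance_filter(snps, min_kb=500)) == ["x", "z"]

    def test_default_min_kb(self):
        assert inspect.signature(distance_filter).parameters["min_kb"].default == 500

    def test_fuzz_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            k = int(rng.integers(1, 40))
            snps = pd.DataFrame(
                {
                    "snp_id": [f"v{j}" for j in range(k)],
                    "chrom": rng.choice(["1", "2"], k),
                    "pos": rng.integers(1, 3_000_000, k),
                    "p_value": 10.0 ** rng.uniform(-9, 0, k),
                }
            )
            min_kb = int(rng.integers(10, 1000))
            records = [
                (r.snp_id, r.chrom, int(r.pos), r.p_value) for r in snps.itertuples()
            ]
            expected = brute_force_distance_filter(records, min_kb * 1000)
            assert distance_filter(snps, min_kb) == expected


class TestFitPgsWeights:
    def test_ld_free_small_lambda_recovers_marginal_betas(self, ld_free_panel):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(ld_free_panel.n_samples)
        gwas = run_gwas(ld_free_panel, y)
        # windows of one SNP each make R exactly the identity
        weights = fit_pgs_weights(
            gwas, ld_free_panel, hyper={"lambda_grid": (1e-10,), "window_kb": 1}
        )
        assert np.allclose(
            weights.table["weight"].to_numpy(), gwas.valid["beta"].to_numpy(), atol=1e-8
        )

    def test_two_snp_block_matches_direct_solve(self, small_panel):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(small_panel.n_samples)
        sub = small_panel.drop_snps(small_panel.snp_ids[2:])
        gwas = run_gwas(sub, y)
        lam = 0.5
        weights = fit_pgs_weights(gwas, sub, hyper={"lambda_grid": (lam,), "window_kb": 10_000})
        X = sub.dosages.astype(float)
        sd = X.std(axis=0)
        Z = (X - X.mean(0)) / sd
        R = Z.T @ Z / len(y)
        r = gwas.valid["beta"].to_numpy() * sd
        expected = np.linalg.solve(R + lam * np.eye(2), r) / sd
        assert np.allclose(weights.table["weight"].to_numpy(), expected, atol=1e-10)

    def test_shrinkage_beats_marginal_on_reduced_panel(self):
        """On joint-tagging reduced panels the LD-aware weights score better
        than raw marginal betas (validation r^2, averaged over seeds)."""
        from pgsnn import (
            draw_architecture,
            reduce_panel_joint_tagging,
            simulate_phenotype,
        )
        from pgsnn.eval_stats import r_squared

        gains = []
        for seed in range(5):
            spec = LdBlockSpec(n_snps=60, block_size=4, within_block_rho=0.9,
                               maf_range=(0.2, 0.5), blocks_per_chrom=5)
            panel = simulate_genotypes(3_000, spec, seed=100 + seed)
            arch = draw_architecture(panel, "additive", 20, 0.5, seed=seed)
            pheno = simulate_phenotype(panel, arch)
            observed, _ = reduce_panel_joint_tagging(panel, arch.causal_ids, seed=seed)
            splits = split_samples(panel.sample_ids, (6, 2, 2), seed=seed)
            pos = {s: i for i, s in enumerate(panel.sample_ids)}
            val = [pos[s] for s in splits["validation"]]
            gwas = run_gwas(observed, pheno.y, subset=splits["train"])
            ridge = fit_pgs_weights(
                gwas, observed,
                hyper={"train_ids": splits["train"]},
                validation=(splits["validation"], pheno.y[val]),
            )
            r2_ridge = r_squared(pheno.y[val], score_pgs(observed, ridge)[val])
            marginal = PgsWeightSet(ridge.table.assign(weight=gwas.valid["beta"].to_numpy()))
            r2_marg = r_squared(pheno.y[val], score_pgs(observed, marginal)[val])
            gains.append(r2_ridge - r2_marg)
        assert np.mean(gains) > 0

    def test_clump_threshold_zeroes_non_index_snps(self, small_panel):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(small_panel.n_samples)
        gwas = run_gwas(small_panel, y)
        weights = fit_pgs_weights(gwas, small_panel, method="clump_threshold")
        kept = set(weights.table["snp_id"])
        assert kept == set(ld_clump(gwas, small_panel))
        betas = gwas.valid.set_index("snp_id")["beta"]
        for rec in weights.table.itertuples():
            assert rec.weight == betas[rec.snp_id]


class TestScorePgs:
    def _weights(self, panel, values):
        t = panel.snps[["snp_id", "effect_allele", "other_allele"]].copy()
        t["weight"] = values
        return PgsWeightSet(t)

    def test_zero_weights_zero_scores(self, small_panel):
        w = self._weights(small_panel, np.zeros(small_panel.n_snps))
        assert np.all(score_pgs(small_panel, w) == 0)

    def test_forced_dot_product(self):
        from test_genotype_sim import panel_from_matrix

        panel = panel_from_matrix(np.array([[0, 1, 2]]))
        t = panel.snps[["snp_id", "effect_allele", "other_allele"]].copy()
        t["weight"] = [0.5, -1.0, 0.25]
        assert score_pgs(panel, PgsWeightSet(t))[0] == pytest.approx(-0.5)

    def test_allele_flip_identity(self, small_panel):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal(small_panel.n_snps)
        w = self._weights(small_panel, vals)
        base = score_pgs(small_panel, w)
        flipped_table = w.table.copy()
        flipped_table.loc[0, ["effect_allele", "other_allele"]] = (
            w.table.loc[0, "other_allele"],
            w.table.loc[0, "effect_allele"],
        )
        flipped = score_pgs(small_panel, PgsWeightSet(flipped_table))
        d = small_panel.dosages[:, 0].astype(float)
        expected = base - vals[0] * d + vals[0] * (2 - d)
        assert np.allclose(flipped, expected, atol=1e-12)

    def test_linearity_in_weights(self, small_panel):
        rng = np.random.default_rng(12)
        w1 = self._weights(small_panel, rng.standard_normal(small_panel.n_snps))
        w2 = self._weights(small_panel, rng.standard_normal(small_panel.n_snps))
        wsum = self._weights(
            small_panel, w1.table["weight"].to_numpy() + w2.table["weight"].to_numpy()
        )
        assert np.allclose(
            score_pgs(small_panel, wsum),
            score_pgs(small_panel, w1) + score_pgs(small_panel, w2),
            atol=1e-10,
        )

    def test_partial_match_warns_and_no_match_errors(self, small_panel):
        t = small_panel.snps[["snp_id", "effect_allele", "other_allele"]].head(3).copy()
        t.loc[len(t)] = ["rs_missing", "A", "G", ]
        t["weight"] = 1.0
        with pytest.warns(UserWarning, match="unmatched"):
            score_pgs(small_panel, PgsWeightSet(t))
        alien = PgsWeightSet(
            pd.DataFrame(
                {
                    "snp_id": ["rs0"],
                    "effect_allele": ["A"],
                    "other_allele": ["G"],
                    "weight": [1.0],
                }
            )
        )
        with pytest.raises(ValueError, match="no scoring-file SNP"):
            score_pgs(small_panel, alien)


class TestScoringFileIO:
    def test_minimal_file(self):
        text = "rsID\teffect_allele\teffect_weight\nrs1\tA\t0.123\n"
        ws = parse_scoring_file(text)
        assert len(ws.table) == 1
        assert ws.table["weight"].iloc[0] == 0.123

    def test_comment_preamble_ignored(self):
        text = (
            "# PGS metadata\n# trait = example\n"
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t1000\tA\tG\t-0.5\n"
        )
        ws = parse_scoring_file(text)
        assert list(ws.table["snp_id"]) == ["rs1"]
        assert ws.table["weight"].iloc[0] == -0.5

    def test_round_trip_thousand_snps(self, tmp_path):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            {
                "snp_id": [f"rs{j}" for j in range(1_000)],
                "effect_allele": rng.choice(list("ACGT"), 1_000),
                "other_allele": "N",
                "weight": rng.standard_normal(1_000),
                "chrom": rng.choice(["1", "2", "X"], 1_000),
                "pos": rng.integers(1, 10**8, 1_000),
            }
        )
        ws = PgsWeightSet(table, provenance="roundtrip test")
        path = tmp_path / "weights.txt"
        write_scoring_file(ws, str(path))
        back = parse_scoring_file(str(path))
        assert list(back.table["snp_id"]) == list(table["snp_id"])
        assert np.array_equal(back.table["weight"].to_numpy(), table["weight"].to_numpy())
        assert list(back.table["effect_allele"]) == list(table["effect_allele"])

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="effect_weight"):
            parse_scoring_file("rsID\teffect_allele\nrs1\tA\n")

    def test_non_numeric_weight_reports_line(self):
        text = "rsID\teffect_allele\teffect_weight\nrs1\tA\tok?\n"
        with pytest.raises(ValueError, match="line"):
            parse_scoring_file(text)


class TestCovariateBaseline:
    def _table(self, data):
        types = {c: "numeric" for c in data.columns}
        return CovariateTable(data, types)

    def test_noise_covariates_screened_out(self):
        rng = np.random.default_rng(14)
        n, k = 5_000, 40
        pgs = rng.standard_normal(n)
        y = pgs + rng.standard_normal(n)
        cov = pd.DataFrame(
            rng.standard_normal((n, k)),
            columns=[f"c{j}" for j in range(k)],
            index=[f"i{i}" for i in range(n)],
        )
        model = fit_covariate_baseline(
            pgs, self._table(cov), y, list(cov.index), family="linear"
        )
        # expected retention is the type-I rate (~5%)
        assert len(model.retained_covariates) <= 6
        assert model.pgs_coefficient == pytest.approx(1.0, abs=0.1)

    def test_perfect_covariate_retained(self):
        rng = np.random.default_rng(15)
        n = 2_000
        pgs = rng.standard_normal(n)
        env = rng.standard_normal(n)
        y = 0.5 * pgs + env
        cov = pd.DataFrame({"env": env}, index=[f"i{i}" for i in range(n)])
        model = fit_covariate_baseline(pgs, self._table(cov), y, list(cov.index))
        assert model.retained_covariates == ["env"]
        assert model.covariate_coefficients["env"] == pytest.approx(1.0, abs=0.05)

    def test_alpha_default(self):
        sig = inspect.signature(fit_covariate_baseline)
        assert sig.parameters["alpha"].default == 0.05

    def test_logistic_family(self):
        rng = np.random.default_rng(16)
        n = 2_000
        pgs = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-pgs))
        y = rng.binomial(1, p)
        model = fit_covariate_baseline(pgs, None, y, [f"i{i}" for i in range(n)], family="logistic")
        assert model.family == "logistic"
        assert model.pgs_coefficient == pytest.approx(1.0, abs=0.25)
        assert model.model_p_value < 1e-10
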