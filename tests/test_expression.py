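"""Expression models: design-factor OLS, vehicle deltas, exposure PK/PD."""

import numpy as np
import pandas as pd
import pytest

from levnet import synthetic as syn
from levnet.expression import (ExpressionTable, GeneExposureModel,
                               de_linear_model, delta_from_vehicle,
                               module_signature_correlation,
                               network_metric_exposure_model)


def make_metadata(n=80, treatments=("vehicle", "low", "medium", "high"),
                  genotypes=("WT", "5XFAD"), seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"a{i}" for i in range(n)]
    return pd.DataFrame({
        "sex": np.where(np.arange(n) % 2 == 0, "male", "female"),
        "genotype": rng.choice(genotypes, n),
        "treatment": rng.choice(treatments, n),
        "auc": rng.uniform(0, 900, n),
    }, index=idx)


def make_table(meta, genes=("g1", "g2"), beta_auc=0.0, beta_sex=0.0,
               noise_sd=0.1, seed=1):
    spec = syn.ExpressionSimSpec(genes=tuple(genes), beta_auc=beta_auc,
                                 beta_sex=beta_sex, noise_sd=noise_sd,
                                 seed=seed)
    vals = syn.generate_expression(spec, meta["auc"].to_numpy(),
                                   meta["sex"].tolist(),
                                   animal_ids=list(meta.index))
    return ExpressionTable(vals, meta)


class TestDeLinearModel:
    def test_pure_sex_effect_noiseless(self):
        meta = make_metadata(n=77)
        table = make_table(meta, beta_sex=0.5, noise_sd=0.0)
        out = de_linear_model(table)
        assert (out["p_sex"] < 1e-12).all()
        assert (out["p_genotype"] > 0.05).all()
        assert (out["p_treatment"] > 0.05).all()
        assert out["significant"].all()

    def test_coefficients_match_normal_equations(self):
        meta = make_metadata(n=60, seed=3)
        table = make_table(meta, beta_auc=0.0005, beta_sex=-0.1, seed=4)
        out = de_linear_model(table)
        # independent normal-equations solve on an equivalent design
        sex = (meta["sex"] == sorted(meta["sex"].unique())[1]).astype(float)
        geno = (meta["genotype"] == sorted(meta["genotype"].unique())[1]
                ).astype(float)
        trt_levels = sorted(meta["treatment"].unique())[1:]
        X = np.column_stack(
            [np.ones(len(meta)), geno, sex]
            + [(meta["treatment"] == t).astype(float) for t in trt_levels])
        for gene in table.genes:
            y = table.values.loc[gene].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            got = out.loc[gene, [c for c in out.columns
                                 if c.startswith("beta_")]].to_numpy(float)
            np.testing.assert_allclose(np.sort(got), np.sort(beta),
                                       atol=1e-10)

    def test_null_gene_flag_rate_matches_familywise_level(self):
        # 500 independent null genes; per-factor rejection ~5%
        meta = make_metadata(n=77, seed=5)
        genes = tuple(f"g{i}" for i in range(500))
        table = make_table(meta, genes=genes, noise_sd=0.1, seed=6)
        out = de_linear_model(table)
        for factor in ("genotype", "sex", "treatment"):
            rate = (out[f"p_{factor}"] < 0.05).mean()
            # binomial 99.9% CI around 0.05 with n=500
            assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / 500) < rate \
                < 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / 500)

    def test_single_level_factor_rejected(self):
        meta = make_metadata(n=20, genotypes=("WT",))
        table = make_table(meta)
        with pytest.raises(ValueError, match="levels"):
            de_linear_model(table)


class TestDeltaFromVehicle:
    def test_vehicle_against_itself_is_zero(self):
        meta = make_metadata(n=40, seed=7)
        table = make_table(meta, seed=8)
        deltas = delta_from_vehicle(table)
        for sex in ("male", "female"):
            np.testing.assert_allclose(deltas[(sex, "vehicle")], 0.0,
                                       atol=1e-14)

    def test_translation_equivariance(self):
        meta = make_metadata(n=40, seed=9)
        table = make_table(meta, seed=10)
        shifted_vals = table.values.copy()
        grp = meta.index[(meta["sex"] == "male")
                         & (meta["treatment"] == "high")]
        shifted_vals[grp] = shifted_vals[grp] + 0.7
        d0 = delta_from_vehicle(table)
        d1 = delta_from_vehicle(ExpressionTable(shifted_vals, meta))
        np.testing.assert_allclose(d1[("male", "high")],
                                   d0[("male", "high")] + 0.7, atol=1e-12)
        np.testing.assert_allclose(d1[("female", "high")],
                                   d0[("female", "high")], atol=1e-12)

    def test_matches_groupby_mean_oracle(self):
        meta = make_metadata(n=50, seed=11)
        table = make_table(meta, seed=12)
        deltas = delta_from_vehicle(table)
        for (sex, trt) in deltas.columns:
            grp = meta.index[(meta["sex"] == sex) & (meta["treatment"] == trt)]
            veh = meta.index[(meta["sex"] == sex)
                             & (meta["treatment"] == "vehicle")]
            oracle = (table.values[grp].mean(axis=1)
                      - table.values[veh].mean(axis=1))
            np.testing.assert_allclose(deltas[(sex, trt)], oracle, atol=1e-13)

    def test_missing_vehicle_cell_reported_as_nan(self):
        meta = make_metadata(n=30, treatments=("low", "high"), seed=13)
        table = make_table(meta, seed=14)
        deltas = delta_from_vehicle(table)
        assert deltas.isna().all().all()


class TestGeneExposureModel:
    def test_effect_sizes_on_reported_scale_recovered_exactly(self):
        # noiseless fit at the published effect-size scale
        meta = make_metadata(n=77, seed=15)
        table = make_table(meta, beta_auc=0.00075, beta_sex=-0.069,
                           noise_sd=0.0)
        fit = GeneExposureModel(table).fit()
        np.testing.assert_allclose(fit.table["beta_auc"], 0.00075, rtol=1e-10)
        np.testing.assert_allclose(fit.table["beta_sex"], -0.069, rtol=1e-10)
        np.testing.assert_allclose(fit.table["r_squared"], 1.0, atol=1e-10)

    def test_r_squared_matches_decomposition_oracle(self):
        meta = make_metadata(n=60, seed=16)
        table = make_table(meta, beta_auc=0.0006, beta_sex=-0.05, seed=17)
        fit = GeneExposureModel(table).fit()
        sex = (meta["sex"] == "female").astype(float).to_numpy()
        X = np.column_stack([np.ones(len(meta)), meta["auc"].to_numpy(), sex])
        for gene in table.genes:
            y = table.values.loc[gene].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss = ((y - X @ beta) ** 2).sum()
            tss = ((y - y.mean()) ** 2).sum()
            assert fit.table.loc[gene, "r_squared"] == pytest.approx(
                1 - rss / tss, abs=1e-12)
            assert fit.table.loc[gene, "beta_auc"] == pytest.approx(
                beta[1], abs=1e-12)

    def test_bias_small_at_study_size(self):
        # many genes as replicates: mean estimate within 5% of truth
        meta = make_metadata(n=77, seed=18)
        genes = tuple(f"g{i}" for i in range(300))
        table = make_table(meta, genes=genes, beta_auc=0.00075,
                           beta_sex=-0.069, noise_sd=0.12, seed=19)
        fit = GeneExposureModel(table).fit()
        assert abs(fit.table["beta_auc"].mean() - 0.00075) < 0.05 * 0.00075
        assert abs(fit.table["beta_sex"].mean() + 0.069) < 0.05 * 0.069

    def test_constant_auc_rejected(self):
        meta = make_metadata(n=20, seed=20)
        meta["auc"] = 5.0
        table = make_table(meta, seed=21)
        with pytest.raises(ValueError, match="constant"):
            GeneExposureModel(table).fit()

    def test_fit_invariant_to_animal_and_gene_order(self):
        meta = make_metadata(n=40, seed=22)
        table = make_table(meta, genes=("g1", "g2", "g3"), beta_auc=0.0005,
                           seed=23)
        fit = GeneExposureModel(table).fit()
        perm = np.random.default_rng(0).permutation(len(meta))
        meta_p = meta.iloc[perm]
        vals_p = table.values[meta_p.index].loc[["g3", "g1", "g2"]]
        fit_p = GeneExposureModel(ExpressionTable(vals_p, meta_p)).fit()
        for gene in ("g1", "g2", "g3"):
            np.testing.assert_allclose(
                fit.table.loc[gene].to_numpy(),
                fit_p.table.loc[gene].to_numpy(), atol=1e-12)

    def test_summary_prints_table_schema(self):
        meta = make_metadata(n=30, seed=24)
        table = make_table(meta, seed=25)
        text = GeneExposureModel(table).fit().summary()
        assert "beta_auc" in text and "r_squared" in text


class TestNetworkMetricExposure:
    def test_exact_linear_metric_gives_r2_one(self):
        df = pd.DataFrame({
            "auc": [100, 300, 500, 700, 200, 400],
            "sex": ["male"] * 3 + ["female"] * 3,
        })
        df["mean_degree"] = 2.0 + 0.01 * df["auc"] - 0.5 * (df["sex"] == "female")
        out = network_metric_exposure_model(df)
        assert out.loc["mean_degree", "r_squared"] == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert out.loc["mean_degree", "beta_auc"] == pytest.approx(0.01,
                                                                   rel=1e-10)

    def test_null_metric_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(26)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            df = pd.DataFrame({
                "auc": rng.uniform(0, 900, 12),
                "sex": ["male", "female"] * 6,
                "density": rng.normal(0.3, 0.05, 12),
            })
            out = network_metric_exposure_model(df)
            rejections += out.loc["density", "p_auc"] < 0.05
        rate = rejections / n_rep
        assert 0.01 < rate < 0.10

    def test_coefficients_match_generic_ols_oracle(self):
        rng = np.random.default_rng(27)
        df = pd.DataFrame({
            "auc": rng.uniform(0, 900, 10),
            "sex": ["male", "female"] * 5,
            "mean_s_pos": rng.normal(5, 1, 10),
        })
        out = network_metric_exposure_model(df)
        X = np.column_stack([np.ones(10), df["auc"],
                             (df["sex"] == "female").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ df["mean_s_pos"].to_numpy())
        assert out.loc["mean_s_pos", "beta_auc"] == pytest.approx(beta[1],
                                                                  abs=1e-10)


class TestModuleSignature:
    def test_correlation_against_signature_vector(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sig = pd.Series(rng.normal(size=30), index=genes)
        deltas = pd.DataFrame({"grp1": 2.0 * sig + rng.normal(0, 0.01, 30),
                               "grp2": rng.normal(size=30)}, index=genes)
        out = module_signature_correlation(deltas, sig)
        assert out.loc["grp1", "r"] > 0.99
        assert abs(out.loc["grp2", "r"]) < 0.6
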