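"""Statistical structure of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ttwas.synthetic_cohort import (
    SimulationConfig,
    TruthRecord,
    compute_gwas_summary,
    make_variant_layout,
    rescale_to_heritability,
    simulate_annotations,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotype,
)


class TestGenotypes:
    def test_maf_recovered_without_ld(self):
        layout = make_variant_layout(
            [("chr1", 1_000_000, 20)], maf_sampler=lambda r, k: np.full(k, 0.3), seed=1
        )
        gm = simulate_genotypes(10_000, layout, ld_rho=0.0, seed=2)
        se = np.sqrt(0.3 * 0.7 / (2 * 10_000))
        assert np.all(np.abs(gm.empirical_maf() - 0.3) < 3 * se + 1e-9)

    def test_ld_monotone_in_rho(self):
        layout = make_variant_layout([("chr1", 1_000_000, 30)], seed=3)

        def mean_adj_corr(rho, seed):
            gm = simulate_genotypes(3_000, layout, ld_rho=rho, seed=seed)
            c = np.corrcoef(gm.dosages, rowvar=False)
            return np.mean([c[i, i + 1] for i in range(29)])

        assert mean_adj_corr(0.9, 4) > mean_adj_corr(0.0, 4) + 0.2

    def test_same_seed_identical(self):
        layout = make_variant_layout([("chr1", 1, 10)], seed=5)
        a = simulate_genotypes(50, layout, ld_rho=0.5, seed=6)
        b = simulate_genotypes(50, layout, ld_rho=0.5, seed=6)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_too_few_samples(self):
        layout = make_variant_layout([("chr1", 1, 2)], seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(1, layout)


class TestHeritabilityRescaling:
    @pytest.mark.parametrize(
        "sigma_g2,h2,expected_sigma_e2", [(1.0, 0.5, 1.0), (2.0, 0.2, 8.0), (1.0, 1.0, 0.0)]
    )
    def test_algebra(self, rng, sigma_g2, h2, expected_sigma_e2):
        g = rng.normal(0, np.sqrt(sigma_g2), 200_000)
        sigma_e = rescale_to_heritability(g, h2)
        assert sigma_e**2 == pytest.approx(expected_sigma_e2, rel=0.02, abs=1e-6)

    def test_h2_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            rescale_to_heritability(rng.normal(size=100), 0.0)

    def test_constant_component_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_heritability(np.ones(100), 0.5)


class TestExpression:
    def test_variance_decomposition_recovered(self, small_cohort):
        layout, _ = small_cohort
        gm = simulate_genotypes(5_000, layout, ld_rho=0.2, seed=21)
        ids = layout["variant_id"].tolist()
        truth = TruthRecord("g", cis_variants=ids[:5],
                            trans_groups={"TF0": ids[50:60], "TF1": ids[70:80]})
        expr, truth = simulate_expression(gm, truth, 0.3, 0.3, seed=22)
        # independent oracle: regression of expression on the true causal dosages
        Xc = gm.columns(truth.cis_variants)
        Xt = gm.columns(truth.causal_trans_variants)
        for X, target in ((Xc, 0.3), (Xt, 0.3)):
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(expr)), X]), expr, rcond=None
            )
            comp = X @ beta[1:]
            frac = np.var(comp) / np.var(expr)
            assert frac == pytest.approx(target, abs=0.03)
        assert truth.realized_h2_cis + truth.realized_h2_trans == pytest.approx(0.6, abs=0.05)

    def test_zero_effects_pure_noise(self, small_cohort, caplog):
        import logging

        layout, gm = small_cohort
        truth = TruthRecord("g")
        with caplog.at_level(logging.WARNING):
            expr, _ = simulate_expression(gm, truth, 0.0, 0.0, seed=1)
        assert "pure noise" in caplog.text
        assert np.std(expr) == pytest.approx(1.0, abs=0.1)

    def test_deterministic(self, small_cohort):
        layout, gm = small_cohort
        ids = layout["variant_id"].tolist()
        t = TruthRecord("g", cis_variants=ids[:3])
        a, _ = simulate_expression(gm, t, 0.4, 0.0, seed=9)
        b, _ = simulate_expression(gm, TruthRecord("g", cis_variants=ids[:3]), 0.4, 0.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestPhenotype:
    def test_causality_heritability(self, small_cohort):
        layout, _ = small_cohort
        gm = simulate_genotypes(20_000, layout, ld_rho=0.2, seed=31)
        ids = layout["variant_id"].tolist()
        expr, truth = simulate_expression(
            gm, TruthRecord("g", cis_variants=ids[:5]), 0.4, 0.0, seed=32
        )
        y = simulate_phenotype(gm, expr, "causality", 0.5, seed=33)
        assert np.corrcoef(y, expr)[0, 1] ** 2 == pytest.approx(0.5, abs=0.02)

    def test_null_trait_independent_of_genotype(self, small_cohort):
        layout, gm = small_cohort
        expr, _ = simulate_expression(
            gm, TruthRecord("g", cis_variants=layout["variant_id"].tolist()[:5]),
            0.4, 0.0, seed=41,
        )
        y = simulate_phenotype(gm, expr, "causality", 0.0, seed=42)
        ss = compute_gwas_summary(gm, y, "linear")
        ks = stats.kstest(ss.table["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_scenarios_share_marginal_variance(self, small_cohort):
        layout, _ = small_cohort
        gm = simulate_genotypes(8_000, layout, ld_rho=0.2, seed=51)
        ids = layout["variant_id"].tolist()
        expr, truth = simulate_expression(
            gm, TruthRecord("g", cis_variants=ids[:5], trans_groups={"TF0": ids[50:55]}),
            0.2, 0.2, seed=52,
        )
        yc = simulate_phenotype(gm, expr, "causality", 0.4, seed=53, truth=truth)
        yp = simulate_phenotype(gm, expr, "pleiotropy", 0.4, seed=54, truth=truth)
        assert np.var(yc) == pytest.approx(np.var(yp), rel=0.05)

    def test_binary_trait_balanced_and_deterministic(self, small_cohort):
        layout, gm = small_cohort
        expr, _ = simulate_expression(
            gm, TruthRecord("g", cis_variants=layout["variant_id"].tolist()[:5]),
            0.4, 0.0, seed=61,
        )
        a = simulate_phenotype(gm, expr, "causality", 0.3, "binary", seed=62)
        b = simulate_phenotype(gm, expr, "causality", 0.3, "binary", seed=62)
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) == {0.0, 1.0}
        assert abs(a.mean() - 0.5) < 0.01

    def test_unknown_scenario(self, small_cohort):
        _, gm = small_cohort
        with pytest.raises(ValueError, match="scenario"):
            simulate_phenotype(gm, np.zeros(gm.n_samples), "mediation", 0.3)


class TestGwasSummary:
    def test_null_mean_chi2_near_one(self, small_cohort):
        layout, gm = small_cohort
        y = np.random.default_rng(71).binomial(1, 0.5, gm.n_samples).astype(float)
        for model in ("linear", "logistic"):
            ss = compute_gwas_summary(gm, y, model)
            m = len(ss)
            assert ss.chi2().mean() == pytest.approx(1.0, abs=3 * np.sqrt(2 / m))

    def test_causal_variant_has_smallest_p(self, small_cohort):
        layout, gm = small_cohort
        vid = layout["variant_id"].iloc[0]
        rng = np.random.default_rng(72)
        y = 2.0 * gm.column(vid) + rng.standard_normal(gm.n_samples)
        ss = compute_gwas_summary(gm, y, "linear")
        # the top association is the causal variant or an LD neighbour
        assert ss.table["pvalue"].idxmin() in layout["variant_id"].iloc[:3].tolist()
        assert ss.table["pvalue"].idxmin() == vid

    def test_constant_phenotype_rejected(self, small_cohort):
        _, gm = small_cohort
        with pytest.raises(ValueError, match="constant"):
            compute_gwas_summary(gm, np.ones(gm.n_samples), "linear")

    def test_monomorphic_variant_excluded(self):
        layout = make_variant_layout([("chr1", 1, 3)], seed=0)
        gm = simulate_genotypes(100, layout, seed=1)
        gm.dosages[:, 1] = 0.0
        y = np.random.default_rng(2).standard_normal(100)
        ss = compute_gwas_summary(gm, y, "linear")
        assert layout["variant_id"].iloc[1] not in ss
        assert ss.n_excluded_monomorphic == 1

    def test_logistic_matches_statsmodels_single_variant(self, small_cohort):
        import statsmodels.api as sm

        layout, gm = small_cohort
        rng = np.random.default_rng(73)
        x = gm.dosages[:, 0]
        eta = -0.2 + 0.5 * x
        y = (rng.random(gm.n_samples) < 1 / (1 + np.exp(-eta))).astype(float)
        ss = compute_gwas_summary(gm, y, "logistic")
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        vid = layout["variant_id"].iloc[0]
        assert ss.table.loc[vid, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
        assert ss.table.loc[vid, "se"] == pytest.approx(fit.bse[1], abs=1e-6)


class TestAnnotations:
    def test_eqtl_table_size(self):
        cfg = SimulationConfig(n_genes=2, n_trans_regions=10, variants_per_region=50)
        ann = simulate_annotations(cfg, seed=1)
        assert len(ann.eqtl) == 10 * 50

    def test_planted_peaks_within_tss_flank(self):
        cfg = SimulationConfig(n_genes=3, n_trans_regions=4, variants_per_region=10)
        ann = simulate_annotations(cfg, seed=2)
        tss = {r.gene_id: r.start for r in ann.gene_table.itertuples()}
        for tf, gid in ann.planted_tf_genes:
            chrom = ann.gene_table.set_index("gene_id").loc[gid, "chrom"]
            hits = ann.tf_peaks[tf].overlapping(chrom, tss[gid] - 20_000, tss[gid] + 20_000)
            assert hits, f"no {tf} peak near {gid}"

    def test_deterministic(self):
        cfg = SimulationConfig(n_genes=2, n_trans_regions=3, variants_per_region=5)
        a = simulate_annotations(cfg, seed=3)
        b = simulate_annotations(cfg, seed=3)
        pd.testing.assert_frame_equal(a.eqtl, b.eqtl)
        pd.testing.assert_frame_equal(a.tf_cis_layout, b.tf_cis_layout)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(h2_expr_cis=0.7, h2_expr_trans=0.5),
            dict(n_causal_cis=300),
            dict(n_causal_trans_regions=11),
            dict(scenario="other"),
            dict(trait_type="count"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
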