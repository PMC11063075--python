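"""Generator contracts: determinism, planted structure, null uniformity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import exertrait
from exertrait.config import ConfigError, H2Law, PlantedEffects, SimConfig
from exertrait.simulate import (
    generate_de_study,
    generate_evidence,
    generate_gsnp,
    generate_human_cohort,
    generate_twas,
    write_study,
)


def _cfg(**kw):
    base = dict(
        n_tissues=2, n_traits=3, n_categories=2, n_genes=200,
        n_samples_human=50, n_snps=80, seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(de_fraction=1.5)
        with pytest.raises(ConfigError):
            _cfg(theta_true=-0.1)

    def test_too_few_samples_for_residualization(self):
        with pytest.raises(ConfigError):
            _cfg(n_samples_human=5, n_covariates=5)

    def test_planted_effect_shape_validation(self):
        cfg = _cfg(planted_effects=PlantedEffects(alpha=1.0, beta=np.zeros(7)))
        with pytest.raises(ConfigError):
            cfg.planted_effects.resolve(cfg.n_tissues, cfg.n_traits)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = _cfg(gsnp_block_r=0.8)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back.to_dict() == cfg.to_dict()


class TestDEStudy:
    def test_no_planting_gives_all_null_states(self):
        de = generate_de_study(_cfg(de_fraction=0.0))
        assert (de.states[["state_F", "state_M"]] == 0).all().all()

    def test_full_up_planting_gives_up_up_states_at_8w(self):
        de = generate_de_study(
            _cfg(de_fraction=1.0, de_up_fraction=1.0, expressed_fraction=1.0)
        )
        last = de.states[de.states["timepoint"] == "8w"]
        assert (last["state_F"] == 1).all() and (last["state_M"] == 1).all()

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(
            n_tissues=2, n_traits=3, n_categories=2, n_genes=2000,
            n_samples_human=50, n_snps=80, de_fraction=0.1, seed=7,
        )
        de = generate_de_study(cfg)
        null = de.truth[~de.truth["de_true"]][["gene", "tissue"]]
        merged = de.results.merge(null, on=["gene", "tissue"])
        stat = kstest(merged["p_value"], "uniform")
        assert stat.pvalue > 0.01

    def test_null_uniformity_across_replicates(self):
        # p-values of unplanted genes pass the KS test in >= 95% of seeds
        passes = 0
        for seed in range(100):
            cfg = _cfg(n_genes=300, seed=seed)
            de = generate_de_study(cfg)
            null = de.truth[~de.truth["de_true"]][["gene", "tissue"]]
            p = de.results.merge(null, on=["gene", "tissue"])["p_value"]
            passes += kstest(p, "uniform").pvalue > 0.01
        assert passes >= 95

    def test_de_states_match_log2fc_sign_at_8w(self):
        de = generate_de_study(_cfg(de_fraction=0.3))
        st8 = de.states[de.states["timepoint"] == "8w"].set_index(["gene", "tissue"])
        res8 = de.results[de.results["timepoint"] == "8w"]
        for _, row in res8.iterrows():
            s = st8.loc[(row["gene"], row["tissue"]), "state_F"]
            if s != 0:
                assert np.sign(row["log2fc"]) == s

    def test_determinism_byte_identical(self, tmp_path):
        cfg = _cfg()
        for d in ("a", "b"):
            de = generate_de_study(cfg)
            twas = generate_twas(cfg, de)
            ev = generate_evidence(cfg)
            gsnp = generate_gsnp(cfg)
            write_study(tmp_path / d, cfg, de, twas, ev, gsnp)
        for name in ("de_results.tsv", "de_states.tsv", "twas.tsv",
                     "evidence.tsv", "gsnp.tsv", "de_truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestHumanCohort:
    def test_zero_heritability_means_zero_genetic_component(self):
        cfg = _cfg(h2_distribution=H2Law(kind="point", value=0.0))
        cohort = generate_human_cohort(cfg)
        for tc in cohort.per_tissue.values():
            assert np.allclose(tc.genetic_component, 0.0)

    def test_variance_decomposition_recovers_planted_h2(self):
        cfg = SimConfig(
            n_tissues=1, n_traits=2, n_categories=2, n_genes=300,
            n_samples_human=300, n_snps=150, seed=1,
            h2_distribution=H2Law(kind="point", value=0.5),
        )
        tc = generate_human_cohort(cfg).per_tissue["BLOOD"]
        var_g = tc.genetic_component.var(axis=0)
        var_e = tc.residual_component.var(axis=0)
        ratio = np.mean(var_g / (var_g + var_e))
        assert abs(ratio - 0.5) < 0.1

    def test_counts_mapping_nonnegative_and_invertible(self):
        cohort = generate_human_cohort(_cfg())
        for tc in cohort.per_tissue.values():
            assert (tc.expression >= 0).all()

    def test_grm_psd_with_unit_like_diagonal(self):
        cohort = generate_human_cohort(_cfg())
        for tc in cohort.per_tissue.values():
            vals = np.linalg.eigvalsh(tc.grm)
            assert vals.min() > -1e-8
            assert abs(np.mean(np.diag(tc.grm)) - 1.0) < 0.2

    def test_snp_mode_matches_planted_variance(self):
        cfg = _cfg(grm_mode="snp", h2_distribution=H2Law(kind="point", value=0.4),
                   n_samples_human=200, n_genes=200)
        tc = generate_human_cohort(cfg).per_tissue["BLOOD"]
        var_g = tc.genetic_component.var(axis=0)
        var_e = tc.residual_component.var(axis=0)
        assert abs(np.mean(var_g / (var_g + var_e)) - 0.4) < 0.1


class TestTwas:
    def test_pvalue_consistent_with_zscore(self, small_twas):
        from scipy.stats import norm

        p_expect = 2 * norm.sf(np.abs(small_twas.table["zscore"]))
        assert np.allclose(small_twas.table["p_value"], p_expect, atol=1e-8)

    def test_no_planting_equalizes_hit_rates(self):
        cfg = _cfg(
            n_genes=3000, de_fraction=0.3,
            planted_effects=PlantedEffects(alpha=0.0),
        )
        de = generate_de_study(cfg)
        twas = generate_twas(cfg, de)
        degs = exertrait.deg_sets(de)
        t = twas.truth.copy()
        t["deg"] = [
            g in degs.sets[ti] for g, ti in zip(t["gene"], t["tissue"])
        ]
        rate_in = t.loc[t["deg"], "hit_true"].mean()
        rate_out = t.loc[~t["deg"], "hit_true"].mean()
        assert abs(rate_in - rate_out) < 0.02

    def test_planted_alpha_sets_log_odds_difference(self):
        cfg = SimConfig(
            n_tissues=3, n_traits=4, n_categories=2, n_genes=4000,
            n_samples_human=50, n_snps=80, de_fraction=0.3, seed=2,
            planted_effects=PlantedEffects(alpha=1.0),
        )
        de = generate_de_study(cfg)
        twas = generate_twas(cfg, de)
        degs = exertrait.deg_sets(de)
        t = twas.truth.copy()
        t["deg"] = [
            g in degs.sets[ti] for g, ti in zip(t["gene"], t["tissue"])
        ]
        p_in = t.loc[t["deg"], "hit_true"].mean()
        p_out = t.loc[~t["deg"], "hit_true"].mean()
        logodds = np.log(p_in / (1 - p_in)) - np.log(p_out / (1 - p_out))
        assert abs(logodds - 1.0) < 0.2

    def test_extreme_direction_mean_forces_positive_products(self):
        cfg = _cfg(
            n_genes=2000, de_fraction=0.4,
            planted_direction_means=np.full(3, 10.0),
        )
        de = generate_de_study(cfg)
        twas = generate_twas(cfg, de)
        degs = exertrait.deg_sets(de)
        truth = twas.truth[twas.truth["hit_true"]]
        products = []
        for _, row in truth.iterrows():
            d = degs.direction.get((row["tissue"], row["gene"]))
            if d:
                products.append(d * row["sign_true"])
        assert len(products) > 30
        assert np.mean(np.array(products) > 0) >= 0.99

    def test_wrong_gene_universe_rejected(self, small_twas):
        cfg = _cfg(n_genes=123)
        with pytest.raises(ConfigError):
            generate_twas(cfg, _StubDE())


class _StubDE:
    genes = ["x1", "x2"]


class TestEvidenceAndGsnp:
    def test_point_mass_scores_exceed_any_threshold(self):
        from exertrait.config import EvidenceLaw

        cfg = _cfg(evidence_score_law=EvidenceLaw(kind="point", value=1.0))
        ev = generate_evidence(cfg)
        assert (ev.table["score"] > 0.999).all()

    def test_single_trait_gsnp_is_unit(self):
        cfg = SimConfig(
            n_tissues=2, n_traits=1, n_categories=1, n_genes=50,
            n_samples_human=50, n_snps=80, seed=0,
        )
        assert generate_gsnp(cfg).matrix.tolist() == [[1.0]]

    def test_gsnp_is_valid_correlation(self):
        g = generate_gsnp(_cfg(n_traits=10)).matrix
        assert np.allclose(g, g.T)
        assert np.allclose(np.diag(g), 1.0)
        assert np.linalg.eigvalsh(g).min() > -1e-8
        assert np.abs(g).max() <= 1.0 + 1e-12

    def test_blocked_gsnp_structure(self):
        cfg = _cfg(n_traits=6, n_categories=2, gsnp_block_r=0.9)
        g = generate_gsnp(cfg).matrix
        cat = cfg.trait_category_index()
        same = cat[:, None] == cat[None, :]
        off = ~np.eye(6, dtype=bool)
        assert np.all(g[same & off] == 0.9)
        assert np.all(g[~same] == 0.0)

    def test_evidence_scores_unique_per_pair(self):
        ev = generate_evidence(_cfg())
        assert not ev.table.duplicated(["gene", "trait"]).any()
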