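"""Trio simulator: HWE founders, copula assortment, Mendelian transmission,
phenotype injection, and seeded reproducibility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadsim import (
    SimulationConfig,
    assert_mendel_consistent,
    cohort_similarity,
    draw_panel,
    simulate_parents,
    simulate_phenotypes,
    simulate_trios,
    standardize_similarity,
    transmit,
)
from dyadsim.panel_io import MISSING
from dyadsim.pgs import compute_pgs, standardize
from dyadsim.synthetic_data import simulate_control_genotypes
from tests.conftest import make_panel


class TestDrawPanel:
    def test_seeded_determinism_and_size(self):
        cfg = SimulationConfig(n_snps=109, seed=5)
        p1 = draw_panel(cfg, cfg.rng())
        p2 = draw_panel(cfg, cfg.rng())
        assert len(p1) == 109
        np.testing.assert_array_equal(p1.weights, p2.weights)
        np.testing.assert_array_equal(p1.freqs, p2.freqs)

    def test_frequency_bounds(self):
        cfg = SimulationConfig(n_snps=200, freq_low=0.1, freq_high=0.9, seed=1)
        p = draw_panel(cfg, cfg.rng())
        assert ((p.freqs > 0.1) & (p.freqs < 0.9)).all()
        assert not p.is_ambiguous().any()

    def test_different_seeds_differ(self):
        c1, c2 = SimulationConfig(seed=1), SimulationConfig(seed=2)
        assert not np.array_equal(draw_panel(c1, c1.rng()).weights,
                                  draw_panel(c2, c2.rng()).weights)


class TestTransmit:
    def test_homozygote_parents_are_deterministic(self, rng):
        assert transmit(2, 2, rng) == 2
        assert transmit(0, 0, rng) == 0
        np.testing.assert_array_equal(
            transmit(np.full(100, 2), np.full(100, 0), rng), np.ones(100))

    def test_double_het_distribution(self, rng):
        """Enumerating the four equiprobable transmissions from 1x1 parents
        gives child dosage probabilities {0: 1/4, 1: 1/2, 2: 1/4}."""
        n = 40_000
        child = transmit(np.ones(n, dtype=int), np.ones(n, dtype=int), rng)
        freqs = np.bincount(child, minlength=3) / n
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_missing_parent_gives_missing_child(self, rng):
        assert transmit(MISSING, 1, rng) == MISSING
        assert transmit(1, MISSING, rng) == MISSING


class TestSimulateParents:
    def test_dosage_mean_matches_hwe(self, rng):
        panel = make_panel([0.3] * 5)
        mothers, _ = simulate_parents(panel, 5000, 0.0, rng)
        assert mothers.dosage.mean(axis=0) == pytest.approx([0.6] * 5, abs=0.02)

    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_couple_pgs_correlation_hits_target(self, rho):
        """Gaussian-copula rank pairing realizes the requested spousal PGS
        correlation (Monte-Carlo check at n = 5,000)."""
        cfg = SimulationConfig(n_snps=109, seed=42)
        rng = cfg.rng()
        panel = draw_panel(cfg, rng)
        mothers, fathers = simulate_parents(panel, 5000, rho, rng)
        w = panel.weights
        r = np.corrcoef(mothers.dosage @ w, fathers.dosage @ w)[0, 1]
        assert r == pytest.approx(rho, abs=0.05)

    def test_extreme_rho_with_ties_still_pairs(self):
        # a monomorphic-ish panel gives many tied PGS values
        panel = make_panel([0.5], weights=[0.0])
        rng = np.random.default_rng(0)
        mothers, fathers = simulate_parents(panel, 50, 1.0, rng)
        assert mothers.n_individuals == fathers.n_individuals == 50


class TestTrios:
    @given(st.integers(min_value=2, max_value=40), st.integers(0, 2**20))
    def test_mendel_consistency_everywhere(self, n_trios, seed):
        cfg = SimulationConfig(n_trios=n_trios, n_snps=12, seed=seed)
        _, cohort = simulate_trios(cfg, cfg.rng())
        assert_mendel_consistent(cohort)

    def test_mendel_consistency_with_missingness(self):
        cfg = SimulationConfig(n_trios=50, n_snps=20, missing_rate=0.1, seed=9)
        _, cohort = simulate_trios(cfg, cfg.rng())
        assert_mendel_consistent(cohort)
        assert (cohort.mothers.dosage == MISSING).any()

    def test_parent_child_pgs_correlation_near_half(self):
        """Under random mating Cov(parent, child) = p(1-p) per SNP against a
        variance of 2p(1-p), so the standardized-PGS correlation tends to 0.5."""
        cfg = SimulationConfig(n_trios=4000, n_snps=109, spousal_rho=0.0, seed=21)
        panel, cohort = simulate_trios(cfg, cfg.rng())
        zm = standardize(compute_pgs(cohort.mothers, panel)).z
        zf = standardize(compute_pgs(cohort.fathers, panel)).z
        zc = standardize(compute_pgs(cohort.children, panel)).z
        assert np.corrcoef(zm, zc)[0, 1] == pytest.approx(0.5, abs=0.05)
        assert np.corrcoef(zf, zc)[0, 1] == pytest.approx(0.5, abs=0.05)
        assert np.corrcoef(zm, zf)[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_mother_child_more_similar_than_couples(self):
        cfg = SimulationConfig(n_trios=800, n_snps=109, spousal_rho=0.0, seed=13)
        panel, cohort = simulate_trios(cfg, cfg.rng())
        mc = (cohort.mothers.dosage == cohort.children.dosage).mean()
        mp = (cohort.mothers.dosage == cohort.fathers.dosage).mean()
        assert mc > mp

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimulationConfig(n_trios=80, n_snps=30, seed=7)
        panel1, c1 = simulate_trios(cfg, cfg.rng())
        panel2, c2 = simulate_trios(cfg, cfg.rng())
        np.testing.assert_array_equal(c1.children.dosage, c2.children.dosage)
        np.testing.assert_array_equal(c1.child_sex, c2.child_sex)
        np.testing.assert_array_equal(panel1.weights, panel2.weights)

    def test_control_genotypes_share_ids_and_are_mendelian(self, tiny_cohort):
        cfg, _, cohort = tiny_cohort
        from dyadsim.synthetic_data import TrioCohort
        rng = np.random.default_rng(3)
        panel, m, f, c = simulate_control_genotypes(cohort, cfg, rng, n_snps=40)
        assert len(panel) == 40
        assert m.individual_ids == cohort.mothers.individual_ids
        assert_mendel_consistent(TrioCohort(m, f, c, cohort.dyads, cohort.child_sex))


def _mc_similarity_z(cohort):
    mc = cohort.dyads.loc[cohort.dyads["dyad_type"] == "mother_child"]
    sim = cohort_similarity(cohort.mothers, cohort.children, mc)
    return standardize_similarity(sim)["z"].to_numpy()


class TestPhenotypes:
    def test_null_effect_leaves_similarity_uncorrelated(self):
        cfg = SimulationConfig(n_trios=4704, n_snps=109, beta_similarity=0.0,
                               beta_conflict=0.0, seed=2)
        _, cohort = simulate_trios(cfg, cfg.rng())
        z = _mc_similarity_z(cohort)
        pheno = simulate_phenotypes(cohort, z, cfg, np.random.default_rng(5))
        assert np.corrcoef(z, pheno["enjoyment"])[0, 1] == pytest.approx(0.0, abs=0.05)
        assert np.corrcoef(z, pheno["conflict"])[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_noise_free_limit_recovers_similarity(self):
        cfg = SimulationConfig(n_trios=300, n_snps=60, beta_similarity=1.0,
                               noise_sd=1e-12, seed=3)
        _, cohort = simulate_trios(cfg, cfg.rng())
        z = _mc_similarity_z(cohort)
        pheno = simulate_phenotypes(cohort, z, cfg, np.random.default_rng(5))
        np.testing.assert_allclose(pheno["enjoyment"], z, atol=1e-9)

    def test_son_specific_effect_is_added(self):
        cfg = SimulationConfig(n_trios=500, n_snps=40, beta_similarity=0.2,
                               beta_similarity_male=0.5, noise_sd=1e-12, seed=4)
        _, cohort = simulate_trios(cfg, cfg.rng())
        z = _mc_similarity_z(cohort)
        pheno = simulate_phenotypes(cohort, z, cfg, np.random.default_rng(5))
        son = cohort.child_sex == "male"
        np.testing.assert_allclose(pheno.loc[son, "enjoyment"], 0.7 * z[son], atol=1e-9)
        np.testing.assert_allclose(pheno.loc[~son, "enjoyment"], 0.2 * z[~son], atol=1e-9)

    def test_cts2_scale_bounds_and_descriptives(self):
        cfg = SimulationConfig(n_trios=4704, seed=6)
        _, cohort = simulate_trios(cfg, cfg.rng())
        z = _mc_similarity_z(cohort)
        pheno = simulate_phenotypes(cohort, z, cfg, np.random.default_rng(5))
        mc = pheno["marital_conflict"]
        assert mc.between(10, 49).all()
        assert mc.mean() == pytest.approx(21.61, abs=0.5)
        assert (mc == np.round(mc)).all()
        # depression subgroup rate ~ 98/4704
        assert pheno["depression_flag"].mean() == pytest.approx(98 / 4704, abs=0.01)

    def test_zero_variance_similarity_rejected(self, tiny_cohort):
        cfg, _, cohort = tiny_cohort
        with pytest.raises(ValueError, match="zero-variance"):
            simulate_phenotypes(cohort, np.zeros(cfg.n_trios), cfg,
                                np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"freq_low": 0.9, "freq_high": 0.1},
        {"noise_sd": 0.0},
        {"spousal_rho": 1.5},
        {"depression_rate": 0.0},
        {"cts2_min": 50, "cts2_max": 10},
        {"n_trios": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
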