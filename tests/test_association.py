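"""OLS association battery: standardized betas, strata, covariates, controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadsim import (
    BatteryInputs,
    BatteryOptions,
    SimulationConfig,
    StratumSpec,
    cohort_similarity,
    fit_linear,
    quantile_strata,
    results_to_frame,
    run_analysis_battery,
    simulate_phenotypes,
    simulate_trios,
    standardize_similarity,
)
from dyadsim.pgs import compute_pgs, standardize
from dyadsim.synthetic_data import simulate_control_genotypes


def zscore(x):
    return (x - x.mean()) / x.std(ddof=1)


def normal_equations_oracle(x, y, cov=None):
    """Explicit matrix-algebra OLS on z-scored data with classical SEs."""
    x, y = zscore(np.asarray(x, float)), zscore(np.asarray(y, float))
    cols = [np.ones_like(x), x]
    if cov is not None:
        cols += [zscore(c) for c in np.atleast_2d(cov.T)]
    X = np.column_stack(cols)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    return beta[1], np.sqrt(cov_beta[1, 1]), dof


class TestFitLinear:
    def test_identity_fit(self, rng):
        x = rng.normal(size=50)
        res = fit_linear(x, x.copy())
        assert res.beta_std == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-10
        assert res.n == 50

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        res = fit_linear(x, y)
        beta, se, dof = normal_equations_oracle(x, y)
        assert res.beta_std == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        expected_p = 2 * stats.t.sf(abs(beta / se), dof)
        assert res.p == pytest.approx(expected_p, rel=1e-10)
        assert (res.ci_low, res.ci_high) == pytest.approx(
            (beta - 1.96 * se, beta + 1.96 * se), abs=1e-10)

    def test_covariate_fit_matches_oracle(self, rng):
        x = rng.normal(size=40)
        c = rng.normal(size=40)
        y = 0.3 * x + 0.5 * c + rng.normal(size=40)
        res = fit_linear(x, y, covariates=c)
        beta, se, _ = normal_equations_oracle(x, y, cov=c[:, None].T.T)
        assert res.beta_std == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_bivariate_beta_equals_pearson(self, rng):
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        res = fit_linear(x, y)
        assert res.beta_std == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_constant_exposure_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_linear(np.ones(20), np.random.default_rng(0).normal(size=20))

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError, match="too few"):
            fit_linear(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.5]))

    def test_incomplete_rows_dropped_and_counted(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        x[[3, 5]] = np.nan
        res = fit_linear(x, y)
        assert res.n == 28

    def test_independent_covariate_barely_moves_beta(self, rng):
        n = 2000
        x = rng.normal(size=n)
        c = rng.normal(size=n)  # independent of x and of y|x
        y = 0.3 * x + rng.normal(size=n)
        plain = fit_linear(x, y)
        adj = fit_linear(x, y, covariates=c)
        assert adj.beta_std == pytest.approx(plain.beta_std, abs=0.02)

    def test_mediator_covariate_attenuates_beta(self, rng):
        # x -> m -> y: adjusting for the mediator removes most of the effect
        n = 2000
        x = rng.normal(size=n)
        m = 0.8 * x + 0.3 * rng.normal(size=n)
        y = 0.8 * m + 0.3 * rng.normal(size=n)
        plain = fit_linear(x, y)
        adj = fit_linear(x, y, covariates=m)
        assert abs(adj.beta_std) < 0.5 * abs(plain.beta_std)


class TestQuantileStrata:
    def test_rank_construction(self):
        a = np.array([10.0, 1.0, 10.0, 5.0])
        b = np.array([9.0, 1.0, 1.0, 5.0])
        labels = quantile_strata(a, b, q=0.25)
        assert labels[0] == "both_high"
        assert labels[1] == "both_low"
        assert labels[2] == "other"
        assert labels[3] == "other"

    def test_partition(self, rng):
        a, b = rng.normal(size=4704), rng.normal(size=4704)
        labels = quantile_strata(a, b, q=0.5)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 4704

    def test_orthant_mass_matches_bivariate_normal(self, rng):
        """Fraction of dyads with both members above the within-role 75th
        percentile matches the closed-form bivariate-normal orthant mass."""
        n = 200_000
        rho = 0.5
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        labels = quantile_strata(xy[:, 0], xy[:, 1], q=0.25)
        frac_high = np.mean(labels == "both_high")
        a = stats.norm.ppf(0.75)
        expected = stats.multivariate_normal(mean=[0, 0], cov=cov).cdf([-a, -a])
        assert frac_high == pytest.approx(expected, abs=0.01)

    def test_q_domain(self):
        with pytest.raises(ValueError):
            quantile_strata(np.zeros(4), np.zeros(4), q=0.7)


class TestStratumSpec:
    def test_quantile_kinds_require_q(self):
        with pytest.raises(ValueError, match="require"):
            StratumSpec(kind="both_high_quantile")
        StratumSpec(kind="both_high_quantile", q=0.25)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            StratumSpec(kind="by_zodiac")


def build_battery_inputs(cfg, pheno_seed=77):
    panel, cohort = simulate_trios(cfg, cfg.rng())
    mc = cohort.dyads.loc[cohort.dyads["dyad_type"] == "mother_child"]
    mp = cohort.dyads.loc[cohort.dyads["dyad_type"] == "mother_partner"]
    sim_mc = standardize_similarity(cohort_similarity(cohort.mothers, cohort.children, mc))
    sim_mp = standardize_similarity(cohort_similarity(cohort.mothers, cohort.fathers, mp))
    rng2 = np.random.default_rng(pheno_seed)
    pheno = simulate_phenotypes(cohort, sim_mc["z"].to_numpy(), cfg, rng2,
                                similarity_mp_z=sim_mp["z"].to_numpy())
    _, cm, _, cc = simulate_control_genotypes(cohort, cfg, rng2, n_snps=87)
    sim_neg = standardize_similarity(cohort_similarity(cm, cc, mc))
    return BatteryInputs(
        mother_scores=standardize(compute_pgs(cohort.mothers, panel)),
        child_scores=standardize(compute_pgs(cohort.children, panel)),
        partner_scores=standardize(compute_pgs(cohort.fathers, panel)),
        similarity_mc=sim_mc, similarity_mp=sim_mp, similarity_negative=sim_neg,
        phenotypes=pheno, dyads=cohort.dyads,
    )


class TestBattery:
    def test_ordered_analysis_set_and_flags(self):
        cfg = SimulationConfig(n_trios=300, n_snps=60, seed=8)
        res = run_analysis_battery(build_battery_inputs(cfg),
                                   BatteryOptions(q=0.25, min_n=30))
        df = results_to_frame(res)
        # ordered sections: PGS mains, mc similarity, mp similarity, controls
        assert df.loc[0, "exposure"] == "mother_pgs"
        mc_rows = df[df["exposure"] == "similarity_mc"]
        assert list(mc_rows["stratum"])[:2] == ["overall", "overall"]
        assert {"child_sex=male", "child_sex=female",
                "both_high_q=0.25", "both_low_q=0.25",
                "depression_subgroup"} <= set(mc_rows["stratum"])
        assert (df["exposure"] == "similarity_control_panel").sum() == 2
        # depression subgroup is tiny at n=300 and must be flagged, not fitted
        dep = df[df["stratum"] == "depression_subgroup"].iloc[0]
        assert dep["note"] == "insufficient_n"
        assert np.isnan(dep["beta_std"])
        # informational BH column exists and is monotone-safe
        fitted = df["p"].notna()
        assert (df.loc[fitted, "p_bh"] >= df.loc[fitted, "p"] - 1e-12).all()

    def test_null_cohort_recovers_null(self):
        cfg = SimulationConfig(n_trios=4704, n_snps=109, beta_similarity=0.0,
                               beta_conflict=0.0, seed=10)
        df = results_to_frame(run_analysis_battery(build_battery_inputs(cfg)))
        overall = df[(df["exposure"] == "similarity_mc") & (df["stratum"] == "overall")]
        assert overall["beta_std"].abs().max() < 0.05

    def test_injected_effect_shows_up_overall(self):
        cfg = SimulationConfig(n_trios=4704, n_snps=109, beta_similarity=0.15, seed=10)
        df = results_to_frame(run_analysis_battery(build_battery_inputs(cfg)))
        row = df[(df["exposure"] == "similarity_mc")
                 & (df["outcome"] == "enjoyment")
                 & (df["stratum"] == "overall")].iloc[0]
        assert row["beta_std"] == pytest.approx(0.15, abs=0.05)
        assert row["n"] == 4704

    def test_marital_confounder_attenuates_partner_effect(self):
        """When the marital outcome drives both the phenotype link and the
        covariate, adjustment attenuates the mother-partner similarity beta."""
        cfg = SimulationConfig(n_trios=4704, n_snps=109, beta_similarity=0.0,
                               beta_similarity_marital=-0.5, seed=12)
        inputs = build_battery_inputs(cfg)
        # make enjoyment a function of (low) marital conflict: mediator-like
        pheno = inputs.phenotypes.copy()
        mcz = (pheno["marital_conflict"] - pheno["marital_conflict"].mean()) \
            / pheno["marital_conflict"].std(ddof=1)
        rng = np.random.default_rng(13)
        pheno["enjoyment"] = -0.6 * mcz + 0.8 * rng.normal(size=len(pheno))
        inputs.phenotypes = pheno
        df = results_to_frame(run_analysis_battery(inputs))
        mp = df[(df["exposure"] == "similarity_mp") & (df["outcome"] == "enjoyment")]
        plain = mp[mp["stratum"] == "overall"].iloc[0]["beta_std"]
        adj = mp[mp["stratum"] == "adjusted_marital_conflict"].iloc[0]["beta_std"]
        assert plain > 0.05  # the unadjusted association is visible
        assert abs(adj) < 0.5 * abs(plain)

    def test_positive_control_direction(self):
        cfg = SimulationConfig(n_trios=4704, n_snps=109, beta_similarity=0.0,
                               beta_similarity_marital=-0.3, seed=14)
        df = results_to_frame(run_analysis_battery(build_battery_inputs(cfg)))
        row = df[(df["outcome"] == "marital_quality") & (df["stratum"] == "overall")].iloc[0]
        # similarity lowers conflict -> raises the flipped quality outcome
        assert row["beta_std"] > 0.1
        assert row["p"] < 0.001
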