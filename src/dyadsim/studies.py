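"""Replicated simulation studies: the package's headline numerical checks.

Each function here runs one self-contained study on the synthetic trio
generator — the worked-example similarity score, the Mendelian parent-child
PGS correlation, the match-frequency agreement with the HWE closed forms,
parameter recovery and CI coverage for an injected similarity effect, the
negative-control type-I error, and the relatedness ordering of similarity
distributions. The acceptance script and the analysis scripts are thin
wrappers over these.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import panel_io
from .data import table1_paths
from .pgs import compute_pgs, standardize
from .similarity import aligned_similarity, cohort_similarity, expected_match_probability
from .association import fit_linear
from .synthetic_data import (
    SimulationConfig,
    draw_panel,
    simulate_parents,
    simulate_phenotypes,
    simulate_trios,
    transmit,
)


def worked_example_similarity() -> dict:
    """Score the packaged 8-SNP parent/child worked example via the file path."""
    paths = table1_paths()
    panel = panel_io.read_weights(paths["panel"])
    gm = panel_io.read_genotypes(paths["genotypes"], panel, format="tsv")
    dyads = panel_io.read_dyads(paths["dyads"])
    row = cohort_similarity(gm, gm, dyads).iloc[0]
    return {"proportion": float(row["proportion"]),
            "n_matched": int(row["n_matched"]),
            "n_compared": int(row["n_compared"])}


def mother_child_pgs_correlation(
    n_trios: int = 5000, n_snps: int = 109, seed: int = 0,
) -> dict:
    """Pearson r between mother and child standardized PGS under random mating.

    HWE founders, Mendelian transmission, U(0.1, 0.9) frequencies, N(0, 1)
    weights; theory gives 0.5 (per-SNP Cov(parent, child) = p(1-p) against a
    variance of 2p(1-p)).
    """
    cfg = SimulationConfig(n_trios=n_trios, n_snps=n_snps, spousal_rho=0.0, seed=seed)
    panel, cohort = simulate_trios(cfg, cfg.rng())
    zm = standardize(compute_pgs(cohort.mothers, panel)).z
    zc = standardize(compute_pgs(cohort.children, panel)).z
    return {"r": float(np.corrcoef(zm, zc)[0, 1]), "n": n_trios}


def match_frequency_study(
    p_grid=tuple(np.round(np.arange(0.1, 0.91, 0.1), 2)),
    n_dyads: int = 50_000,
    n_snps: int = 8,
    seed: int = 0,
) -> list[dict]:
    """Empirical per-SNP genotype-match frequencies versus the HWE closed forms.

    At each allele frequency, ``n_dyads`` pairs are simulated on a small panel
    of independent SNPs all at that frequency (averaging over the panel tightens
    the Monte-Carlo error without changing the estimand, by linearity), for
    both unrelated pairs and parent-offspring pairs.
    """
    rng = np.random.default_rng(seed)
    out = []
    for p in p_grid:
        a = rng.binomial(2, p, size=(n_dyads, n_snps)).astype(np.int16)
        b = rng.binomial(2, p, size=(n_dyads, n_snps)).astype(np.int16)
        mate = rng.binomial(2, p, size=(n_dyads, n_snps)).astype(np.int16)
        child = transmit(a, mate, rng)
        for rel, other in (("unrelated", b), ("parent_offspring", child)):
            emp = float((a == other).mean())
            out.append({"p": float(p), "relationship": rel,
                        "empirical": emp,
                        "expected": expected_match_probability(float(p), rel),
                        "n_dyads": n_dyads})
    return out


def _one_cohort_estimate(cfg: SimulationConfig, seed: int) -> tuple[float, float, float]:
    """Simulate one cohort, inject the phenotype effect, fit the primary model.

    Returns (beta_std, ci_low, ci_high) for enjoyment on mother-child
    similarity.
    """
    cfg = dataclasses.replace(cfg, seed=seed)
    rng = cfg.rng()
    panel, cohort = simulate_trios(cfg, rng)
    sim = aligned_similarity(cohort.mothers.dosage, cohort.children.dosage)
    prop = sim["proportion"].to_numpy()
    z = (prop - prop.mean()) / prop.std(ddof=1)
    pheno = simulate_phenotypes(cohort, z, cfg, rng)
    res = fit_linear(prop, pheno["enjoyment"].to_numpy(),
                     exposure_name="similarity_mc", outcome_name="enjoyment")
    return res.beta_std, res.ci_low, res.ci_high


def effect_recovery_study(
    beta: float = 0.15,
    n_reps: int = 600,
    n_trios: int = 4704,
    n_snps: int = 109,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Parameter recovery for an injected similarity effect on enjoyment.

    Each replicate redraws the full cohort (panel fixed conditions, fresh
    genotypes and noise). The estimand on the standardized scale is
    beta / sqrt(beta^2 + noise_sd^2); coverage counts 95% CIs bracketing it.
    """
    cfg = SimulationConfig(n_trios=n_trios, n_snps=n_snps,
                           beta_similarity=beta, beta_similarity_male=0.0,
                           noise_sd=noise_sd, seed=seed)
    truth = beta / np.hypot(beta, noise_sd)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    betas = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(rep_seeds):
        b, lo, hi = _one_cohort_estimate(cfg, int(s))
        betas[i] = b
        covered[i] = lo <= truth <= hi
    return {"mean_beta": float(betas.mean()),
            "sd_beta": float(betas.std(ddof=1)),
            "coverage": float(covered.mean()),
            "truth_std": float(truth),
            "injected_beta": beta,
            "n_reps": n_reps, "n_trios": n_trios}


def negative_control_study(
    n_reps: int = 800,
    n_trios: int = 4704,
    n_snps: int = 109,
    n_snps_control: int = 87,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the control-panel similarity test.

    Each replicate simulates the study cohort with the usual injected effect of
    the trait-panel similarity on enjoyment, then tests enjoyment against
    similarity on an independent second panel that has no phenotype link; the
    rejection rate at ``alpha`` estimates the type-I error.
    """
    base = SimulationConfig(n_trios=n_trios, n_snps=n_snps, seed=seed)
    ss = np.random.SeedSequence(seed + 1)
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    pvals = np.empty(n_reps)
    for i, s in enumerate(rep_seeds):
        cfg = dataclasses.replace(base, seed=int(s))
        rng = cfg.rng()
        panel, cohort = simulate_trios(cfg, rng)
        sim = aligned_similarity(cohort.mothers.dosage, cohort.children.dosage)
        prop = sim["proportion"].to_numpy()
        z = (prop - prop.mean()) / prop.std(ddof=1)
        pheno = simulate_phenotypes(cohort, z, cfg, rng)
        # independent control panel: same individuals, no phenotype link
        ctrl_cfg = dataclasses.replace(cfg, n_snps=n_snps_control)
        ctrl_panel = draw_panel(ctrl_cfg, rng)
        m = rng.binomial(2, ctrl_panel.freqs, size=(n_trios, n_snps_control)).astype(np.int16)
        f = rng.binomial(2, ctrl_panel.freqs, size=(n_trios, n_snps_control)).astype(np.int16)
        c = transmit(m, f, rng)
        ctrl_prop = aligned_similarity(m, c)["proportion"].to_numpy()
        res = fit_linear(ctrl_prop, pheno["enjoyment"].to_numpy())
        pvals[i] = res.p
    return {"type1_error": float((pvals < alpha).mean()),
            "alpha": alpha, "n_reps": n_reps, "pvals": pvals}


def relatedness_ordering_study(
    n_reps: int = 50,
    n_trios: int = 300,
    n_snps: int = 109,
    seed: int = 0,
) -> dict:
    """Mean mother-child similarity minus mean couple similarity, per replicate.

    Parent-offspring pairs share one transmitted allele per SNP, so their IBS
    proportion stochastically dominates that of unrelated couples; the study
    records the mean difference in every replicate.
    """
    ss = np.random.SeedSequence(seed + 2)
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    diffs = np.empty(n_reps)
    for i, s in enumerate(rep_seeds):
        cfg = SimulationConfig(n_trios=n_trios, n_snps=n_snps,
                               spousal_rho=0.0, seed=int(s))
        _, cohort = simulate_trios(cfg, cfg.rng())
        mc = aligned_similarity(cohort.mothers.dosage, cohort.children.dosage)
        mp = aligned_similarity(cohort.mothers.dosage, cohort.fathers.dosage)
        diffs[i] = mc["proportion"].mean() - mp["proportion"].mean()
    return {"mean_diffs": diffs, "all_positive": bool((diffs > 0).all()),
            "n_reps": n_reps, "n_trios": n_trios}


def spousal_assortment_check(
    rho: float = 0.05, n_trios: int = 5000, n_snps: int = 109, seed: int = 0,
) -> dict:
    """Realized couple PGS correlation under copula-paired assortment."""
    cfg = SimulationConfig(n_trios=n_trios, n_snps=n_snps, spousal_rho=rho, seed=seed)
    rng = cfg.rng()
    panel = draw_panel(cfg, rng)
    mothers, fathers = simulate_parents(panel, n_trios, rho, rng)
    w = panel.weights
    r = float(np.corrcoef(mothers.dosage @ w, fathers.dosage @ w)[0, 1])
    return {"target_rho": rho, "realized_r": r, "n": n_trios}
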