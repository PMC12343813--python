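"""Standardized linear-model association battery with stratified and control runs.

Every association is an OLS fit of a z-scored outcome on a z-scored exposure
(plus optional covariates), reporting the standardized beta with classical
standard errors, a 95% CI of beta +/- 1.96*se, and a two-sided t-test p-value.
The battery mirrors a dyadic gene-environment analysis: PGS main effects,
mother-child similarity overall and stratified (child sex, joint PGS
quantiles, depression subgroup), mother-partner similarity with and without a
marital-conflict covariate, a positive control on the marital outcome, and a
negative control using a second, mechanistically unrelated panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pgs import ScoreVector

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "stratum", "beta_std", "se",
    "ci_low", "ci_high", "p", "n", "note",
]


@dataclass
class AssociationResult:
    """One exposure-outcome-stratum cell: standardized beta, 95% CI, p, n."""

    exposure: str
    outcome: str
    stratum: str
    beta_std: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.beta_std) and not (
            self.ci_low <= self.beta_std <= self.ci_high
        ):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class StratumSpec:
    """Which stratification to apply; q is the quantile for high/low splits."""

    kind: str = "none"  # none | child_sex | both_high_quantile | both_low_quantile | depression_subgroup
    q: float | None = None

    def __post_init__(self) -> None:
        quantile_kinds = {"both_high_quantile", "both_low_quantile"}
        if self.kind in quantile_kinds:
            if self.q is None or not 0.0 < self.q <= 0.5:
                raise ValueError("quantile strata require 0 < q <= 0.5")
        valid = {"none", "child_sex", "depression_subgroup"} | quantile_kinds
        if self.kind not in valid:
            raise ValueError(f"unknown stratum kind {self.kind!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - np.mean(x)) / sd


def fit_linear(
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    stratum: str = "overall",
) -> AssociationResult:
    """OLS of z(outcome) on z(exposure) [+ covariates], complete cases only.

    Classical (non-robust) SEs; 95% CI = beta +/- 1.96*se; two-sided p from
    the t distribution with residual degrees of freedom.
    """
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ok = np.isfinite(exposure) & np.isfinite(outcome) & np.isfinite(covariates).all(axis=1)
    else:
        ok = np.isfinite(exposure) & np.isfinite(outcome)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("fit %s ~ %s [%s]: dropped %d incomplete rows",
                    outcome_name, exposure_name, stratum, n_dropped)
    x = exposure[ok]
    y = outcome[ok]
    k_params = 2 + (0 if covariates is None else covariates.shape[1])
    if len(x) < k_params + 2:
        raise ValueError(f"too few complete cases (n={len(x)}) for {k_params}-parameter model")
    x = _zscore(x)
    y = _zscore(y)
    design = [np.ones_like(x), x]
    if covariates is not None:
        cov = covariates[ok]
        design.extend(_zscore(cov[:, j]) for j in range(cov.shape[1]))
    X = np.column_stack(design)
    model = sm.OLS(y, X).fit()
    beta = float(model.params[1])
    se = float(model.bse[1])
    dof = int(model.df_resid)
    if se == 0.0:
        p = 0.0 if beta != 0.0 else 1.0
    else:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return AssociationResult(
        exposure=exposure_name,
        outcome=outcome_name,
        stratum=stratum,
        beta_std=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=max(p, np.finfo(float).tiny),
        n=int(len(x)),
    )


def quantile_strata(score_a: np.ndarray, score_b: np.ndarray, q: float) -> np.ndarray:
    """Label each dyad both_high / both_low / other by within-role quantiles.

    both_high: both members at or above their role's (1-q) quantile;
    both_low: both at or below the q quantile.
    """
    if not 0.0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    hi_a, hi_b = np.nanquantile(a, 1.0 - q), np.nanquantile(b, 1.0 - q)
    lo_a, lo_b = np.nanquantile(a, q), np.nanquantile(b, q)
    out = np.full(a.shape, "other", dtype=object)
    out[(a >= hi_a) & (b >= hi_b)] = "both_high"
    out[(a <= lo_a) & (b <= lo_b)] = "both_low"
    return out


@dataclass
class BatteryInputs:
    """Everything the analysis battery consumes, keyed consistently.

    Similarity tables carry a z column (standardized within dyad_type);
    phenotypes are keyed by mother individual_id. ``similarity_negative`` is
    the second-panel (control) mother-child similarity.
    """

    mother_scores: ScoreVector
    child_scores: ScoreVector
    partner_scores: ScoreVector
    similarity_mc: pd.DataFrame
    similarity_mp: pd.DataFrame
    similarity_negative: pd.DataFrame
    phenotypes: pd.DataFrame
    dyads: pd.DataFrame


@dataclass
class BatteryOptions:
    q: float = 0.25
    min_n: int = 30
    # positive-control outcome: marital quality = sign-flipped standardized
    # conflict by default (higher = better relationship)
    flip_marital_outcome: bool = True
    negative_label: str = "similarity_control_panel"


def _score_map(sv: ScoreVector) -> dict[str, float]:
    return dict(zip(sv.individual_ids, sv.z))


def _assemble_mc(inp: BatteryInputs, sim: pd.DataFrame) -> pd.DataFrame:
    """One row per mother-child dyad: similarity z, outcomes, sex, member z-scores."""
    d = inp.dyads.loc[inp.dyads["dyad_type"] == "mother_child",
                      ["dyad_id", "person_a_id", "person_b_id", "child_sex"]]
    df = d.merge(sim[["dyad_id", "z"]], on="dyad_id", how="left")
    df = df.rename(columns={"z": "similarity_z"})
    pheno = inp.phenotypes.set_index("individual_id")
    df = df.join(pheno[["enjoyment", "conflict", "marital_conflict", "depression_flag"]],
                 on="person_a_id")
    mz = _score_map(inp.mother_scores)
    cz = _score_map(inp.child_scores)
    df["mother_z"] = df["person_a_id"].map(mz)
    df["child_z"] = df["person_b_id"].map(cz)
    return df


def _assemble_mp(inp: BatteryInputs) -> pd.DataFrame:
    d = inp.dyads.loc[inp.dyads["dyad_type"] == "mother_partner",
                      ["dyad_id", "person_a_id", "person_b_id"]]
    df = d.merge(inp.similarity_mp[["dyad_id", "z"]], on="dyad_id", how="left")
    df = df.rename(columns={"z": "similarity_z"})
    pheno = inp.phenotypes.set_index("individual_id")
    df = df.join(pheno[["enjoyment", "conflict", "marital_conflict"]], on="person_a_id")
    mz = _score_map(inp.mother_scores)
    pz = _score_map(inp.partner_scores)
    df["mother_z"] = df["person_a_id"].map(mz)
    df["partner_z"] = df["person_b_id"].map(pz)
    return df


def _fit_or_flag(df: pd.DataFrame, exposure: str, outcome: str, stratum: str,
                 min_n: int, exposure_name: str, outcome_name: str,
                 covariates: list[str] | None = None) -> AssociationResult:
    cols = [exposure, outcome] + (covariates or [])
    sub = df.dropna(subset=cols)
    if len(sub) < min_n:
        return AssociationResult(
            exposure=exposure_name, outcome=outcome_name, stratum=stratum,
            beta_std=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
            p=np.nan, n=int(len(sub)), note="insufficient_n",
        )
    cov = sub[covariates].to_numpy() if covariates else None
    return fit_linear(
        sub[exposure].to_numpy(), sub[outcome].to_numpy(), covariates=cov,
        exposure_name=exposure_name, outcome_name=outcome_name, stratum=stratum,
    )


def run_analysis_battery(
    inputs: BatteryInputs,
    options: BatteryOptions | None = None,
) -> list[AssociationResult]:
    """The full ordered analysis set.

    1. mother / child / partner PGS main effects on enjoyment and conflict;
    2. mother-child similarity on enjoyment and conflict: overall, by child
       sex, by both-high / both-low joint PGS quantile strata, and within the
       depression subgroup (enjoyment);
    3. mother-partner similarity on enjoyment and conflict, without and with
       the marital-conflict covariate;
    4. positive control: mother-partner similarity on the marital outcome,
       overall and by joint quantile strata;
    5. negative control: second-panel mother-child similarity on enjoyment
       and conflict.

    Strata below ``min_n`` complete cases are flagged, not fitted.
    """
    opt = options or BatteryOptions()
    results: list[AssociationResult] = []
    mc = _assemble_mc(inputs, inputs.similarity_mc)
    mp = _assemble_mp(inputs)

    # (1) PGS main effects
    for role, col, frame in (("mother_pgs", "mother_z", mc),
                             ("child_pgs", "child_z", mc),
                             ("partner_pgs", "partner_z", mp)):
        for out in ("enjoyment", "conflict"):
            results.append(_fit_or_flag(frame, col, out, "overall",
                                        opt.min_n, role, out))

    # (2) mother-child similarity
    for out in ("enjoyment", "conflict"):
        results.append(_fit_or_flag(mc, "similarity_z", out, "overall",
                                    opt.min_n, "similarity_mc", out))
    for sex in ("male", "female"):
        sub = mc.loc[mc["child_sex"] == sex]
        results.append(_fit_or_flag(sub, "similarity_z", "enjoyment",
                                    f"child_sex={sex}", opt.min_n,
                                    "similarity_mc", "enjoyment"))
    labels = quantile_strata(mc["mother_z"].to_numpy(),
                             mc["child_z"].to_numpy(), opt.q)
    for lab in ("both_high", "both_low"):
        sub = mc.loc[labels == lab]
        results.append(_fit_or_flag(sub, "similarity_z", "enjoyment",
                                    f"{lab}_q={opt.q:g}", opt.min_n,
                                    "similarity_mc", "enjoyment"))
    dep = mc.loc[mc["depression_flag"].astype(bool)]
    results.append(_fit_or_flag(dep, "similarity_z", "enjoyment",
                                "depression_subgroup", opt.min_n,
                                "similarity_mc", "enjoyment"))

    # (3) mother-partner similarity on mother-child outcomes
    for out in ("enjoyment", "conflict"):
        results.append(_fit_or_flag(mp, "similarity_z", out, "overall",
                                    opt.min_n, "similarity_mp", out))
        results.append(_fit_or_flag(mp, "similarity_z", out,
                                    "adjusted_marital_conflict", opt.min_n,
                                    "similarity_mp", out,
                                    covariates=["marital_conflict"]))

    # (4) positive control: marital outcome
    mp = mp.copy()
    sign = -1.0 if opt.flip_marital_outcome else 1.0
    mp["marital_outcome"] = sign * mp["marital_conflict"]
    results.append(_fit_or_flag(mp, "similarity_z", "marital_outcome", "overall",
                                opt.min_n, "similarity_mp", "marital_quality"))
    mp_labels = quantile_strata(mp["mother_z"].to_numpy(),
                                mp["partner_z"].to_numpy(), opt.q)
    for lab in ("both_high", "both_low"):
        sub = mp.loc[mp_labels == lab]
        results.append(_fit_or_flag(sub, "similarity_z", "marital_outcome",
                                    f"{lab}_q={opt.q:g}", opt.min_n,
                                    "similarity_mp", "marital_quality"))

    # (5) negative control
    neg = _assemble_mc(inputs, inputs.similarity_negative)
    for out in ("enjoyment", "conflict"):
        results.append(_fit_or_flag(neg, "similarity_z", out, "overall",
                                    opt.min_n, opt.negative_label, out))
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy results table with an informational Benjamini-Hochberg column."""
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame([vars(r) for r in results], columns=RESULT_COLUMNS)
    ok = df["p"].notna()
    df["p_bh"] = np.nan
    if ok.sum():
        df.loc[ok, "p_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df
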