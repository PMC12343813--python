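"""Synthetic trio cohorts: HWE founders, optional spousal assortment, Mendelian
transmission, and phenotypes with configurable injected similarity effects.

The generator emulates a mother/partner/child cohort scored on an independent
SNP panel: parental genotypes are Binomial(2, p_j) per SNP (Hardy-Weinberg),
couples can be rank-coupled on their raw polygenic score through a Gaussian
copula to hit a target spousal PGS correlation, and children receive one
allele from each parent with probability dosage/2. Maternal-report outcomes
(parenting enjoyment, conflict, CTS2-like marital conflict, a depression flag)
are linear-Gaussian functions of standardized dyadic similarity, so known
effect sizes can be injected and recovered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import (
    MISSING,
    GenotypeMatrix,
    SNPPanel,
    write_dyads,
    write_genotypes,
    write_phenotypes,
    write_weights,
)

# unambiguous allele pairs only, so file round trips never drop panel SNPs
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated cohort: 4,704 complete-data trios scored on a
    109-variant panel, a spousal PGS correlation of 0.05, an injected overall
    similarity effect of 0.15 outcome-SD per similarity-SD on enjoyment and
    -0.09 on conflict, CTS2 marital-conflict scores with mean 21.61 and SD 7.25
    clipped to the 10-49 scale range, and a 2.08% severe-depression rate.
    """

    n_trios: int = 4704
    n_snps: int = 109
    freq_low: float = 0.1
    freq_high: float = 0.9
    weight_sd: float = 1.0
    spousal_rho: float = 0.05
    beta_similarity: float = 0.15
    beta_similarity_male: float = 0.0
    beta_conflict: float = -0.09
    beta_similarity_marital: float = 0.0
    noise_sd: float = 1.0
    cts2_mean: float = 21.61
    cts2_sd: float = 7.25
    cts2_min: float = 10.0
    cts2_max: float = 49.0
    depression_rate: float = 98 / 4704
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1 or self.n_snps < 1:
            raise ValueError("n_trios and n_snps must be positive")
        if not (0.0 < self.freq_low < self.freq_high < 1.0):
            raise ValueError("need 0 < freq_low < freq_high < 1")
        if not self.cts2_min < self.cts2_max:
            raise ValueError("need cts2_min < cts2_max")
        for name in ("weight_sd", "noise_sd", "cts2_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.spousal_rho <= 1.0:
            raise ValueError("spousal_rho must lie in [-1, 1]")
        if not 0.0 < self.depression_rate < 1.0:
            raise ValueError("depression_rate must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrioCohort:
    """Aligned mother/father/child genotype matrices plus the dyad table.

    Row i of each matrix is trio i; every child dosage is Mendel-consistent
    with its parents at every non-missing SNP.
    """

    mothers: GenotypeMatrix
    fathers: GenotypeMatrix
    children: GenotypeMatrix
    dyads: pd.DataFrame
    child_sex: np.ndarray = field(repr=False)  # "male"/"female" per trio


def draw_panel(config: SimulationConfig, rng: np.random.Generator) -> SNPPanel:
    """Draw an independent-variant weights panel: freq ~ U(freq_low, freq_high),
    weight ~ N(0, weight_sd), unambiguous allele pairs."""
    m = config.n_snps
    freqs = rng.uniform(config.freq_low, config.freq_high, size=m)
    weights = rng.normal(0.0, config.weight_sd, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    entries = pd.DataFrame({
        "snp_id": [f"snp_{j + 1:04d}" for j in range(m)],
        "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "weight": weights,
        "freq": freqs,
    })
    return SNPPanel(entries)


def _raw_pgs(dosage: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return dosage @ weights


def simulate_parents(
    panel: SNPPanel,
    n: int,
    spousal_rho: float,
    rng: np.random.Generator,
    id_prefixes: tuple[str, str] = ("M", "P"),
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two HWE founder pools paired into couples, optionally assorted on PGS.

    Each dosage is Binomial(2, freq_j) independently. With nonzero
    ``spousal_rho`` the two pools are rank-coupled on raw PGS through a
    Gaussian copula: couple i takes the mother whose PGS rank equals the rank
    of U_i and the father whose rank equals the rank of V_i, with (U, V)
    bivariate normal at correlation ``spousal_rho``. Genotypes are untouched;
    only the pairing changes. Ties break by stable sort order.
    """
    if n < 2:
        raise ValueError("need at least 2 couples")
    freqs = panel.freqs
    dos_m = rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int16)
    dos_f = rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int16)
    if spousal_rho != 0.0:
        w = panel.weights
        cov = [[1.0, spousal_rho], [spousal_rho, 1.0]]
        uv = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        order_m = np.argsort(_raw_pgs(dos_m, w), kind="stable")
        order_f = np.argsort(_raw_pgs(dos_f, w), kind="stable")
        rank_u = np.argsort(np.argsort(uv[:, 0], kind="stable"), kind="stable")
        rank_v = np.argsort(np.argsort(uv[:, 1], kind="stable"), kind="stable")
        dos_m = dos_m[order_m[rank_u]]
        dos_f = dos_f[order_f[rank_v]]
    ids_m = [f"{id_prefixes[0]}{i + 1:05d}" for i in range(n)]
    ids_f = [f"{id_prefixes[1]}{i + 1:05d}" for i in range(n)]
    mothers = GenotypeMatrix(ids_m, panel.snp_ids, dos_m)
    fathers = GenotypeMatrix(ids_f, panel.snp_ids, dos_f)
    return mothers, fathers


def transmit(
    mother_dosage: np.ndarray | int,
    father_dosage: np.ndarray | int,
    rng: np.random.Generator,
) -> np.ndarray | int:
    """Mendelian transmission: child = m_allele + f_allele, where each parent
    passes the effect allele with probability dosage/2, independently.
    Missing parental dosage yields a missing child dosage."""
    m = np.asarray(mother_dosage)
    f = np.asarray(father_dosage)
    scalar = m.ndim == 0
    m, f = np.atleast_1d(m), np.atleast_1d(f)
    miss = (m == MISSING) | (f == MISSING)
    pm = np.where(miss, 0, m) / 2.0
    pf = np.where(miss, 0, f) / 2.0
    child = rng.binomial(1, pm) + rng.binomial(1, pf)
    child = np.where(miss, MISSING, child).astype(np.int16)
    return child[0] if scalar else child


def simulate_trios(config: SimulationConfig, rng: np.random.Generator | None = None,
                   panel: SNPPanel | None = None) -> tuple[SNPPanel, TrioCohort]:
    """End-to-end cohort draw: panel, assorted parents, Mendelian children,
    Bernoulli(0.5) child sex, and the mother-child / mother-partner dyad table."""
    if rng is None:
        rng = config.rng()
    if panel is None:
        panel = draw_panel(config, rng)
    mothers, fathers = simulate_parents(panel, config.n_trios, config.spousal_rho, rng)
    child_dos = transmit(mothers.dosage, fathers.dosage, rng)
    ids_c = [f"C{i + 1:05d}" for i in range(config.n_trios)]
    children = GenotypeMatrix(ids_c, panel.snp_ids, child_dos)
    child_sex = np.where(rng.random(config.n_trios) < 0.5, "male", "female")

    if config.missing_rate > 0.0:
        for gm in (mothers, fathers, children):
            mask = rng.random(gm.dosage.shape) < config.missing_rate
            gm.dosage[mask] = MISSING

    dyads = pd.DataFrame({
        "dyad_id": [f"mc_{i + 1:05d}" for i in range(config.n_trios)]
                   + [f"mp_{i + 1:05d}" for i in range(config.n_trios)],
        "person_a_id": mothers.individual_ids * 2,
        "person_b_id": children.individual_ids + fathers.individual_ids,
        "dyad_type": ["mother_child"] * config.n_trios
                     + ["mother_partner"] * config.n_trios,
        "child_sex": list(child_sex) + ["not_applicable"] * config.n_trios,
    })
    cohort = TrioCohort(mothers, fathers, children, dyads, child_sex)
    return panel, cohort


def simulate_phenotypes(
    cohort: TrioCohort,
    similarity_mc_z: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    similarity_mp_z: np.ndarray | None = None,
) -> pd.DataFrame:
    """Maternal-report phenotypes keyed by mother id.

    enjoyment = beta_similarity * z(sim_mc) + beta_similarity_male * z * 1[son]
    + N(0, noise_sd); conflict analogous with beta_conflict. Marital conflict
    is a rounded-clipped Normal on the CTS2 scale, optionally shifted by
    beta_similarity_marital * z(sim_mp) in scale-SD units. The similarity
    inputs must already be standardized (zero-variance similarity cannot be).
    """
    z = np.asarray(similarity_mc_z, dtype=float)
    n = len(z)
    if n != cohort.mothers.n_individuals:
        raise ValueError("similarity vector does not match cohort size")
    sd = np.nanstd(z)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance similarity cannot be standardized")
    son = (cohort.child_sex == "male").astype(float)
    enjoyment = (
        config.beta_similarity * z
        + config.beta_similarity_male * z * son
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    conflict = config.beta_conflict * z + rng.normal(0.0, config.noise_sd, size=n)

    marital = rng.normal(config.cts2_mean, config.cts2_sd, size=n)
    if similarity_mp_z is not None and config.beta_similarity_marital != 0.0:
        marital = marital + config.beta_similarity_marital * config.cts2_sd * np.asarray(
            similarity_mp_z, dtype=float
        )
    marital = np.clip(np.round(marital), config.cts2_min, config.cts2_max)
    depression = rng.random(n) < config.depression_rate

    return pd.DataFrame({
        "individual_id": cohort.mothers.individual_ids,
        "enjoyment": enjoyment,
        "conflict": conflict,
        "marital_conflict": marital,
        "depression_flag": depression,
    })


def simulate_control_genotypes(
    cohort: TrioCohort,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_snps: int = 87,
    snp_prefix: str = "ctrl",
) -> tuple[SNPPanel, GenotypeMatrix, GenotypeMatrix, GenotypeMatrix]:
    """Second-panel genotypes for the same individuals (negative control).

    Parents are fresh HWE draws on an independent panel (no assortment, no
    phenotype link); children remain Mendelian within each trio. Individual
    ids are copied from the cohort so dyad lookups work unchanged.
    """
    import dataclasses

    cfg = dataclasses.replace(config, n_snps=n_snps)
    panel = draw_panel(cfg, rng)
    entries = panel.entries.copy()
    entries["snp_id"] = [f"{snp_prefix}_{j + 1:04d}" for j in range(n_snps)]
    panel = SNPPanel(entries)
    n = cohort.mothers.n_individuals
    dos_m = rng.binomial(2, panel.freqs, size=(n, n_snps)).astype(np.int16)
    dos_f = rng.binomial(2, panel.freqs, size=(n, n_snps)).astype(np.int16)
    dos_c = transmit(dos_m, dos_f, rng)
    mothers = GenotypeMatrix(list(cohort.mothers.individual_ids), panel.snp_ids, dos_m)
    fathers = GenotypeMatrix(list(cohort.fathers.individual_ids), panel.snp_ids, dos_f)
    children = GenotypeMatrix(list(cohort.children.individual_ids), panel.snp_ids, dos_c)
    return panel, mothers, fathers, children


def assert_mendel_consistent(cohort: TrioCohort) -> None:
    """Raise if any child dosage is impossible given its parents' dosages."""
    m, f, c = cohort.mothers.dosage, cohort.fathers.dosage, cohort.children.dosage
    ok = (m != MISSING) & (f != MISSING) & (c != MISSING)
    # transmissible effect-allele count from a parent: floor(d/2)..ceil(d/2)
    lo = (m > 1).astype(np.int16) + (f > 1).astype(np.int16)
    hi = (m > 0).astype(np.int16) + (f > 0).astype(np.int16)
    bad = ok & ((c < lo) | (c > hi))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AssertionError(
            f"Mendel violation at trio {i}, SNP {j}: parents "
            f"({m[i, j]}, {f[i, j]}) child {c[i, j]}"
        )


def write_cohort(
    panel: SNPPanel,
    cohort: TrioCohort,
    phenotypes: pd.DataFrame,
    outdir: str | Path,
    genotype_format: str = "tsv",
) -> dict[str, Path]:
    """Emit the cohort in the formats panel_io reads; returns the file map."""
    from .panel_io import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"panel": outdir / "panel.tsv",
             "dyads": outdir / "dyads.csv",
             "phenotypes": outdir / "phenotypes.csv"}
    write_weights(panel, paths["panel"])
    write_dyads(cohort.dyads, paths["dyads"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    ext = "vcf" if genotype_format == "vcf" else "tsv"
    for role, gm in (("mothers", cohort.mothers), ("fathers", cohort.fathers),
                     ("children", cohort.children)):
        p = outdir / f"genotypes_{role}.{ext}"
        if genotype_format == "vcf":
            write_vcf(gm, panel, p)
        else:
            write_genotypes(gm, p)
        paths[role] = p
    return paths
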