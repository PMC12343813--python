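"""Proportion-of-similarity statistic for dyads, with HWE closed-form expectations.

The statistic is a panel-restricted identity-by-state proportion: the fraction
of panel SNPs at which the two members of a dyad carry the identical unphased
effect-allele dosage (0=0, 1=1, 2=2). The closed forms below give its per-SNP
expectation under Hardy-Weinberg equilibrium for unrelated pairs and for
parent-offspring pairs, and serve as the independent oracle for the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

SIMILARITY_COLUMNS = ["dyad_id", "dyad_type", "n_compared", "n_matched", "proportion"]


@dataclass(frozen=True)
class SimilarityScore:
    """Per-dyad IBS proportion with its numerator and denominator.

    ``proportion`` is NaN when fewer than ``min_callrate`` of the panel could be
    compared (either side missing removes a SNP from both numerator and
    denominator under the pairwise-complete rule).
    """

    dyad_id: str
    n_compared: int
    n_matched: int
    proportion: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= self.n_compared:
            raise ValueError(
                f"invalid counts: {self.n_matched} matched of {self.n_compared} compared"
            )


def proportion_similarity(
    g_a: np.ndarray,
    g_b: np.ndarray,
    min_callrate: float = 0.8,
    dyad_id: str = "dyad",
    fixed_denominator: bool = False,
) -> SimilarityScore:
    """IBS proportion between two aligned dosage vectors.

    A SNP matches iff both dosages are non-missing and equal. With
    ``fixed_denominator`` the denominator is the full panel length regardless of
    missingness (the alternative reading of the statistic); the two coincide on
    complete data.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    if g_a.shape != g_b.shape or g_a.ndim != 1:
        raise ValueError(f"vector length mismatch: {g_a.shape} vs {g_b.shape}")
    both = (g_a != MISSING) & (g_b != MISSING)
    n_compared = int(both.sum())
    n_matched = int(((g_a == g_b) & both).sum())
    panel_size = g_a.size
    denom = panel_size if fixed_denominator else n_compared
    if panel_size == 0 or n_compared / panel_size < min_callrate or denom == 0:
        prop = float("nan")
    else:
        prop = n_matched / denom
    return SimilarityScore(dyad_id, n_compared, n_matched, prop)


def cohort_similarity(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    dyads: pd.DataFrame,
    min_callrate: float = 0.8,
    fixed_denominator: bool = False,
) -> pd.DataFrame:
    """Score every dyad, looking ``person_a_id`` up in ``matrix_a`` and
    ``person_b_id`` in ``matrix_b`` (falling back to the other matrix).

    Returns a tidy frame (dyad_id, dyad_type, n_compared, n_matched,
    proportion); dyads with an absent member are scored NaN with a warning.
    """
    if matrix_a.snp_ids != matrix_b.snp_ids:
        raise ValueError("matrices must share the same SNP ordering")
    idx_a = matrix_a.row_index()
    idx_b = matrix_b.row_index()
    rows = []
    n_absent = 0
    for rec in dyads.itertuples(index=False):
        da, db = None, None
        if rec.person_a_id in idx_a:
            da = matrix_a.dosage[idx_a[rec.person_a_id]]
        elif rec.person_a_id in idx_b:
            da = matrix_b.dosage[idx_b[rec.person_a_id]]
        if rec.person_b_id in idx_b:
            db = matrix_b.dosage[idx_b[rec.person_b_id]]
        elif rec.person_b_id in idx_a:
            db = matrix_a.dosage[idx_a[rec.person_b_id]]
        if da is None or db is None:
            n_absent += 1
            rows.append((rec.dyad_id, rec.dyad_type, 0, 0, float("nan")))
            continue
        s = proportion_similarity(
            da, db, min_callrate=min_callrate, dyad_id=rec.dyad_id,
            fixed_denominator=fixed_denominator,
        )
        rows.append((s.dyad_id, rec.dyad_type, s.n_compared, s.n_matched, s.proportion))
    if n_absent:
        logger.warning("%d dyads had an absent member and were scored missing", n_absent)
    out = pd.DataFrame(rows, columns=SIMILARITY_COLUMNS)
    for dtype, grp in out.groupby("dyad_type"):
        p = grp["proportion"].dropna()
        if len(p):
            logger.info(
                "%s: n=%d mean=%.4f min=%.4f max=%.4f",
                dtype, len(p), p.mean(), p.min(), p.max(),
            )
    return out


def aligned_similarity(
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    min_callrate: float = 0.8,
    fixed_denominator: bool = False,
) -> pd.DataFrame:
    """Vectorized IBS proportions for row-aligned dosage matrices.

    Row i of ``dos_a`` is paired with row i of ``dos_b``; equivalent to calling
    :func:`proportion_similarity` per row, but in one array pass (the per-dyad
    route is the oracle in tests). Returns n_compared / n_matched / proportion
    per pair.
    """
    dos_a = np.asarray(dos_a)
    dos_b = np.asarray(dos_b)
    if dos_a.shape != dos_b.shape:
        raise ValueError(f"shape mismatch: {dos_a.shape} vs {dos_b.shape}")
    both = (dos_a != MISSING) & (dos_b != MISSING)
    n_compared = both.sum(axis=1)
    n_matched = ((dos_a == dos_b) & both).sum(axis=1)
    panel_size = dos_a.shape[1]
    denom = np.full_like(n_compared, panel_size) if fixed_denominator else n_compared
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(denom > 0, n_matched / np.maximum(denom, 1), np.nan)
    prop = np.where(n_compared / panel_size < min_callrate, np.nan, prop)
    return pd.DataFrame({
        "n_compared": n_compared, "n_matched": n_matched, "proportion": prop,
    })


def standardize_similarity(scores: pd.DataFrame) -> pd.DataFrame:
    """Add a z column standardizing ``proportion`` within each dyad_type."""
    out = scores.copy()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero-variance similarity cannot be standardized")
        return (x - x.mean()) / sd

    out["z"] = out.groupby("dyad_type")["proportion"].transform(_z)
    return out


# ---------------------------------------------------------------------------
# closed-form expectations under HWE


def _hwe_probs(p: float) -> np.ndarray:
    """P(dosage = 0, 1, 2) for effect-allele frequency p under HWE."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def expected_match_probability(p: float, relationship: str) -> float:
    """Per-SNP probability that two individuals share a genotype under HWE.

    ``unrelated``: both genotypes drawn independently from HWE, so the match
    probability is the sum of squared genotype probabilities. ``parent_offspring``:
    the child receives one allele transmitted by the parent (probability
    dosage/2 of the effect allele) and one from a random mate (frequency p);
    the sum runs over parent genotype x transmitted allele x mate allele.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must lie in (0, 1), got {p}")
    probs = _hwe_probs(p)
    if relationship == "unrelated":
        return float(np.sum(probs**2))
    if relationship == "parent_offspring":
        total = 0.0
        for g, pg in enumerate(probs):
            # transmitted effect-allele indicator: Bernoulli(g / 2)
            for t, pt in ((0, 1.0 - g / 2.0), (1, g / 2.0)):
                if pt == 0.0:
                    continue
                for m, pm in ((0, 1.0 - p), (1, p)):
                    if t + m == g:
                        total += pg * pt * pm
        return float(total)
    raise ValueError(f"unknown relationship {relationship!r}")


def expected_panel_similarity(freqs: Iterable[float], relationship: str) -> float:
    """Expected IBS proportion over a panel: mean of per-SNP match probabilities
    (by linearity of expectation; SNPs are independent)."""
    vals = [expected_match_probability(p, relationship) for p in freqs]
    return float(np.mean(vals))
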