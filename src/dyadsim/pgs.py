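"""Weighted polygenic scores: effect-allele dosage times GWAS weight, summed.

raw_i = sum_j dosage_ij * weight_j over the SNPs passing the missing-data
policy; scores are then z-standardized over the scored sample before use in
any association model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypeMatrix, SNPPanel

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-individual polygenic scores.

    ``raw`` is the weighted dosage sum (NaN where unscoreable), ``z`` the
    standardized score (NaN until :func:`standardize` fills it) and
    ``n_snps_used`` the number of SNPs entering each individual's sum.
    """

    scores: pd.DataFrame  # columns: individual_id, raw, z, n_snps_used

    @property
    def individual_ids(self) -> list[str]:
        return self.scores["individual_id"].tolist()

    @property
    def raw(self) -> np.ndarray:
        return self.scores["raw"].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        return self.scores["z"].to_numpy(dtype=float)

    @property
    def n_snps_used(self) -> np.ndarray:
        return self.scores["n_snps_used"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.scores)


def compute_pgs(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    missing_policy: str = "skip",
) -> ScoreVector:
    """Raw weighted sum scores on the panel's effect-allele dosages.

    ``skip`` omits missing SNPs from an individual's sum (n_snps_used records
    how many contributed); ``mean_impute`` replaces a missing dosage with its
    expectation 2 * freq under HWE. An individual with every SNP missing under
    ``skip`` gets a NaN raw score.
    """
    panel_idx = {s: j for j, s in enumerate(panel.snp_ids)}
    unknown = [s for s in genotypes.snp_ids if s not in panel_idx]
    if unknown:
        raise ValueError(f"genotype SNPs absent from panel: {unknown[:5]}")
    cols = [panel_idx[s] for s in genotypes.snp_ids]
    weights = panel.weights[cols]
    freqs = panel.freqs[cols]

    dos = genotypes.dosage.astype(float)
    miss = genotypes.dosage == MISSING
    if missing_policy == "skip":
        dos[miss] = 0.0
        raw = dos @ weights
        n_used = (~miss).sum(axis=1)
        all_missing = n_used == 0
        if all_missing.any():
            ids = [genotypes.individual_ids[i] for i in np.flatnonzero(all_missing)]
            logger.warning("%d individuals with all SNPs missing scored NaN: %s",
                           len(ids), ids[:5])
            raw = np.where(all_missing, np.nan, raw)
    elif missing_policy == "mean_impute":
        dos[miss] = 0.0
        dos += miss * (2.0 * freqs)  # expected dosage under HWE
        raw = dos @ weights
        n_used = np.full(genotypes.n_individuals, genotypes.n_snps)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    return ScoreVector(pd.DataFrame({
        "individual_id": genotypes.individual_ids,
        "raw": raw,
        "z": np.nan,
        "n_snps_used": n_used.astype(int),
    }))


def standardize(scores: ScoreVector) -> ScoreVector:
    """Fill z = (raw - mean) / sample SD over non-missing raws; NaN propagates."""
    raw = scores.raw
    ok = np.isfinite(raw)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing scores to standardize")
    sd = np.std(raw[ok], ddof=1)
    if sd == 0:
        raise ValueError("zero-variance scores cannot be standardized")
    z = (raw - np.mean(raw[ok])) / sd
    out = scores.scores.copy()
    out["z"] = z
    return ScoreVector(out)


def write_scores(scores: ScoreVector, path) -> None:
    scores.scores.to_csv(path, index=False)


def read_scores(path) -> ScoreVector:
    df = pd.read_csv(path, dtype={"individual_id": str})
    return ScoreVector(df[["individual_id", "raw", "z", "n_snps_used"]])
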