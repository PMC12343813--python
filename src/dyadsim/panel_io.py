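"""Readers/writers for SNP weight panels, genotype matrices and dyad/phenotype tables.

Genotypes are held as effect-allele dosages (0, 1, 2) with ``MISSING`` (-1) as the
sentinel for no-calls. VCF input is harmonized to the panel's effect allele record
by record; strand-ambiguous variants (A/T, C/G) are dropped by default because
their orientation cannot be resolved without strand information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1

_VALID_NUCLEOTIDES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

PANEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "weight", "freq"]
DYAD_COLUMNS = ["dyad_id", "person_a_id", "person_b_id", "dyad_type", "child_sex"]
PHENOTYPE_COLUMNS = [
    "individual_id",
    "enjoyment",
    "conflict",
    "marital_conflict",
    "depression_flag",
]

DYAD_TYPES = frozenset({"mother_child", "mother_partner"})
CHILD_SEXES = frozenset({"male", "female", "not_applicable"})


class PanelError(ValueError):
    """Raised when a weights panel violates its invariants."""


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


class Orientation(str, Enum):
    """Relationship of a VCF record's (REF, ALT) pair to a panel entry."""

    AS_IS = "as_is"        # REF = other allele, ALT = effect allele
    FLIPPED = "flipped"    # REF = effect allele, ALT = other allele
    AMBIGUOUS = "ambiguous"  # strand-ambiguous pair, orientation undecidable
    MISMATCH = "mismatch"  # alleles do not correspond to the panel entry


@dataclass(frozen=True)
class SNPPanel:
    """A trait's weighted variant set: per-SNP effect allele, weight and frequency.

    ``entries`` keeps file order; snp_ids are unique, alleles are single distinct
    nucleotides and effect-allele frequencies lie strictly inside (0, 1).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelError(f"panel missing columns: {missing_cols}")
        if len(df) < 1:
            raise PanelError("panel must contain at least one entry")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise PanelError(f"duplicate snp_ids in panel: {dups}")
        for col in ("effect_allele", "other_allele"):
            bad = ~df[col].isin(_VALID_NUCLEOTIDES)
            if bad.any():
                raise PanelError(
                    f"non-nucleotide {col} values: {df.loc[bad, col].tolist()}"
                )
        same = df["effect_allele"] == df["other_allele"]
        if same.any():
            raise PanelError(
                f"effect and other allele identical for {df.loc[same, 'snp_id'].tolist()}"
            )
        freq = df["freq"].to_numpy(dtype=float)
        if not np.all((freq > 0.0) & (freq < 1.0)):
            raise PanelError("allele frequencies must lie strictly in (0, 1)")
        if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
            raise PanelError("weights must be finite")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return self.entries["snp_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(dtype=float)

    @property
    def freqs(self) -> np.ndarray:
        return self.entries["freq"].to_numpy(dtype=float)

    def entry(self, snp_id: str) -> pd.Series:
        rows = self.entries.loc[self.entries["snp_id"] == snp_id]
        if rows.empty:
            raise KeyError(snp_id)
        return rows.iloc[0]

    def is_ambiguous(self) -> np.ndarray:
        """Boolean mask of strand-ambiguous (A/T, C/G) panel entries."""
        pairs = zip(self.entries["effect_allele"], self.entries["other_allele"])
        return np.array([p in _AMBIGUOUS_PAIRS for p in pairs], dtype=bool)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosage grid.

    ``dosage`` is an integer array with values in {0, 1, 2, MISSING}; rows follow
    ``individual_ids`` and columns follow ``snp_ids``.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        legal = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not legal.all():
            bad = np.unique(self.dosage[~legal])
            raise GenotypeError(f"illegal dosage values: {bad.tolist()}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise GenotypeError("duplicate individual_ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def row_index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.individual_ids)}

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        col = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [col[s] for s in snp_ids]
        return GenotypeMatrix(list(self.individual_ids), list(snp_ids), self.dosage[:, idx])


def harmonize_alleles(ref: str, alt: str, effect_allele: str, other_allele: str) -> Orientation:
    """Classify a bi-allelic record's orientation relative to a panel entry.

    ``as_is`` means the record's ALT is the effect allele (ALT dosage counts
    effect copies directly); ``flipped`` means REF is the effect allele, so the
    effect dosage is ``2 - alt_count``. Strand-ambiguous pairs are unresolvable.
    """
    for a in (ref, alt):
        if a not in _VALID_NUCLEOTIDES:
            raise GenotypeError(f"allele {a!r} is not a single nucleotide")
    if (ref, alt) in _AMBIGUOUS_PAIRS:
        return Orientation.AMBIGUOUS
    if ref == other_allele and alt == effect_allele:
        return Orientation.AS_IS
    if ref == effect_allele and alt == other_allele:
        return Orientation.FLIPPED
    return Orientation.MISMATCH


# ---------------------------------------------------------------------------
# weights panel


def read_weights(path: str | Path) -> SNPPanel:
    """Read a tab-separated SNP weights panel (snp_id, alleles, weight, freq)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"cannot parse weights file {path}: {exc}") from exc
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelError(f"{path}: missing columns {missing_cols}")
    for col in ("weight", "freq"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(bad.idxmax()) + 2 if bad.any() else "?"
            raise PanelError(f"{path}: malformed {col} value near line {line}") from exc
    if df[PANEL_COLUMNS].isna().any().any():
        row = int(df[PANEL_COLUMNS].isna().any(axis=1).idxmax()) + 2
        raise PanelError(f"{path}: incomplete row at line {row}")
    panel = SNPPanel(df[PANEL_COLUMNS].reset_index(drop=True))
    logger.info("read %d panel SNPs from %s", len(panel), path)
    return panel


def write_weights(panel: SNPPanel, path: str | Path) -> None:
    panel.entries[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes: TSV dosage dialect


def read_genotypes(
    path: str | Path,
    panel: SNPPanel,
    format: str = "tsv",
    drop_ambiguous: bool = True,
) -> GenotypeMatrix:
    """Read genotypes and harmonize dosages to the panel's effect allele.

    Panel SNPs absent from the file are retained as all-MISSING columns so the
    output always spans the full panel (minus dropped ambiguous SNPs). Raises
    if no panel SNP is found at all.
    """
    if format == "tsv":
        gm = _read_dosage_tsv(path, panel)
    elif format == "vcf":
        gm = _read_vcf(path, panel, drop_ambiguous=drop_ambiguous)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return gm


def _panel_snp_order(panel: SNPPanel, drop_ambiguous: bool) -> list[str]:
    if not drop_ambiguous:
        return panel.snp_ids
    keep = ~panel.is_ambiguous()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d strand-ambiguous panel SNPs", n_drop)
    return [s for s, k in zip(panel.snp_ids, keep) if k]


def _read_dosage_tsv(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    found = [s for s in panel.snp_ids if s in df.columns]
    if not found:
        raise GenotypeError(f"{path}: no panel SNP found among columns")
    logger.info("%s: %d of %d panel SNPs present", path, len(found), len(panel))
    n = len(df)
    dosage = np.full((n, len(panel)), MISSING, dtype=np.int16)
    for j, snp in enumerate(panel.snp_ids):
        if snp in df.columns:
            col = df[snp].to_numpy(dtype=float)
            vals = np.where(np.isnan(col), MISSING, col).astype(np.int16)
            dosage[:, j] = vals
    return GenotypeMatrix([str(i) for i in df.index], panel.snp_ids, dosage)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as TSV: individuals as rows, 'NA' for missing."""
    df = pd.DataFrame(
        gm.dosage.astype(object), index=gm.individual_ids, columns=gm.snp_ids
    )
    df = df.where(df != MISSING, other="NA")
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotypes: VCF


def _read_vcf(path: str | Path, panel: SNPPanel, drop_ambiguous: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_order = _panel_snp_order(panel, drop_ambiguous)
    col = {s: j for j, s in enumerate(snp_order)}
    panel_by_id = {
        row.snp_id: row for row in panel.entries.itertuples(index=False)
    }
    dosage = np.full((len(samples), len(snp_order)), MISSING, dtype=np.int16)
    n_found = n_skipped = 0
    for rec in vcf:
        rid = rec.ID
        if rid is None or rid not in panel_by_id:
            continue
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s", rid)
            n_skipped += 1
            continue
        entry = panel_by_id[rid]
        orient = harmonize_alleles(rec.REF, rec.ALT[0], entry.effect_allele, entry.other_allele)
        if orient is Orientation.MISMATCH:
            logger.warning("skipping %s: alleles %s/%s mismatch panel", rid, rec.REF, rec.ALT[0])
            n_skipped += 1
            continue
        if orient is Orientation.AMBIGUOUS:
            if drop_ambiguous:
                n_skipped += 1
                continue
            # kept on request: treated as_is (ALT counted as effect allele)
            orient = Orientation.AS_IS
        if rid not in col:
            n_skipped += 1
            continue
        alt_count = _alt_counts(rec)
        eff = np.where(
            alt_count == MISSING,
            MISSING,
            alt_count if orient is Orientation.AS_IS else 2 - alt_count,
        )
        dosage[:, col[rid]] = eff
        n_found += 1
    if n_found == 0:
        raise GenotypeError(f"{path}: no panel SNP found in VCF")
    logger.info(
        "%s: %d of %d panel SNPs found, %d records skipped", path, n_found, len(panel), n_skipped
    )
    return GenotypeMatrix(samples, snp_order, dosage)


def _alt_counts(rec) -> np.ndarray:
    """Per-sample ALT allele count from the GT field; MISSING for no-calls."""
    out = np.empty(len(rec.genotypes), dtype=np.int16)
    for i, gt in enumerate(rec.genotypes):
        alleles = gt[:-1]  # last element is the phasing flag
        if any(a < 0 for a in alleles):
            out[i] = MISSING
        else:
            out[i] = sum(1 for a in alleles if a == 1)
    return out


def write_vcf(gm: GenotypeMatrix, panel: SNPPanel, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF 4.2 file.

    REF is the panel's other allele and ALT its effect allele, so the ALT count
    equals the stored effect dosage (as_is orientation on read-back).
    """
    by_id = {row.snp_id: row for row in panel.entries.itertuples(index=False)}
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for j, snp in enumerate(gm.snp_ids):
            entry = by_id[snp]
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"1\t{j + 1}\t{snp}\t{entry.other_allele}\t{entry.effect_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# dyad and phenotype tables


def validate_dyads(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in DYAD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dyad table missing columns: {missing_cols}")
    if (df["person_a_id"] == df["person_b_id"]).any():
        raise ValueError("dyad with identical members")
    bad_type = ~df["dyad_type"].isin(DYAD_TYPES)
    if bad_type.any():
        raise ValueError(f"unknown dyad_type values: {df.loc[bad_type, 'dyad_type'].unique()}")
    bad_sex = ~df["child_sex"].isin(CHILD_SEXES)
    if bad_sex.any():
        raise ValueError(f"unknown child_sex values: {df.loc[bad_sex, 'child_sex'].unique()}")
    mp = df["dyad_type"] == "mother_partner"
    if (mp & (df["child_sex"] != "not_applicable")).any():
        raise ValueError("mother_partner dyads must have child_sex = not_applicable")
    if (~mp & (df["child_sex"] == "not_applicable")).any():
        raise ValueError("mother_child dyads require a child_sex")
    return df[DYAD_COLUMNS].reset_index(drop=True)


def read_dyads(path: str | Path) -> pd.DataFrame:
    return validate_dyads(pd.read_csv(path, dtype=str))


def write_dyads(df: pd.DataFrame, path: str | Path) -> None:
    validate_dyads(df).to_csv(path, index=False)


def validate_phenotypes(
    df: pd.DataFrame, cts2_bounds: tuple[float, float] | None = None
) -> pd.DataFrame:
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")
    for col in ("enjoyment", "conflict"):
        vals = pd.to_numeric(df[col], errors="raise")
        if not np.all(np.isfinite(vals.dropna())):
            raise ValueError(f"non-finite {col} factor scores")
    if cts2_bounds is not None:
        lo, hi = cts2_bounds
        mc = pd.to_numeric(df["marital_conflict"], errors="raise").dropna()
        if ((mc < lo) | (mc > hi)).any():
            raise ValueError(f"marital_conflict outside scale bounds [{lo}, {hi}]")
    out = df[PHENOTYPE_COLUMNS].copy().reset_index(drop=True)
    out["depression_flag"] = out["depression_flag"].astype(bool)
    return out


def read_phenotypes(
    path: str | Path, cts2_bounds: tuple[float, float] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    return validate_phenotypes(df, cts2_bounds=cts2_bounds)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)
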