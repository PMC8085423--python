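"""Input/output for trio genotype data, pedigrees, exposures and summary stats.

The in-memory substrate for the whole pipeline is :class:`TrioGenotypeMatrix`:
effect-allele dosages (0/1/2, ``-1`` for missing) stored as an
``(n_snps, n_trios, 3)`` int8 array in child/mother/father order, together
with per-SNP metadata (:class:`SNPRecord`) and per-trio pedigree metadata
(:class:`PedigreeIndex`).

File formats handled here:

* VCF (plain or bgzipped, via :mod:`cyvcf2`) for genotypes — only biallelic
  autosomal records are ingested;
* 6-column pre-MAKEPED pedigree text (family, individual, father, mother,
  sex, phenotype);
* a long-format exposure TSV (``trio_id``, ``exposure_name``, ``exposed``)
  with binary maternal exposures and explicit missingness;
* a tab-delimited per-SNP summary-statistics table that round-trips floats
  at 17 significant digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mendel import MISSING

logger = logging.getLogger(__name__)

#: member axis order in the dosage array
CHILD, MOTHER, FATHER = 0, 1, 2

#: canonical exposure names; anything else is categorised as "other"
CANONICAL_EXPOSURES = ("smoking", "alcohol", "vitamin")

SUMMARY_COLUMNS = [
    "CHR", "POS", "ID", "EA", "OA", "EAF_PARENTS",
    "N_INFORMATIVE", "N_EXPOSED",
    "BETA_G", "SE_G", "BETA_GE", "SE_GE", "COV_G_GE",
    "CHISQ_1DF", "P_1DF", "CHISQ_2DF", "P_2DF",
    "FLAG_GENOMEWIDE", "FLAG_SUGGESTIVE",
]

GENOMEWIDE_P = 5e-8
SUGGESTIVE_P = 1e-6


class PedigreeError(ValueError):
    """Malformed or inconsistent pedigree input."""


@dataclass
class SNPRecord:
    """One biallelic marker: position, alleles and founder allele frequency."""

    chrom: str
    pos: int
    snp_id: str
    effect_allele: str
    other_allele: str
    parental_eaf: float = math.nan
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if not self.effect_allele or not self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must be nonempty")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not math.isnan(self.parental_eaf) and not 0.0 <= self.parental_eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: parental_eaf outside [0, 1]")
        if self.imputation_r2 is not None and not 0.0 <= self.imputation_r2 <= 1.0:
            raise ValueError(f"{self.snp_id}: imputation_r2 outside [0, 1]")


@dataclass
class PedigreeIndex:
    """One complete case-parent trio and its study/population labels."""

    trio_id: str
    child_id: str
    mother_id: str
    father_id: str
    study_label: str = ""
    population_label: str = ""
    cleft_subtype: str = "unknown"

    def __post_init__(self) -> None:
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise PedigreeError(f"trio {self.trio_id}: member IDs not distinct")


@dataclass
class TrioGenotypeMatrix:
    """Effect-allele dosages for complete trios at a set of SNPs."""

    snps: list[SNPRecord]
    trios: list[PedigreeIndex]
    dosage: np.ndarray  # (n_snps, n_trios, 3) int8, MISSING = -1

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        expected = (len(self.snps), len(self.trios), 3)
        if self.dosage.shape != expected:
            raise ValueError(f"dosage shape {self.dosage.shape} != {expected}")
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "TrioGenotypeMatrix":
        index = np.asarray(index)
        return TrioGenotypeMatrix(
            snps=[self.snps[i] for i in index],
            trios=self.trios,
            dosage=self.dosage[index].copy(),
        )


def canonical_exposure(name: str) -> str:
    return name if name in CANONICAL_EXPOSURES else "other"


class ExposureTable:
    """Per-trio binary maternal exposures with explicit missingness.

    Missingness is per (trio, exposure): a trio missing one exposure is
    excluded from that exposure's analysis only.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"trio_id", "exposure_name", "exposed"}
        if not required.issubset(frame.columns):
            raise ValueError(f"exposure table needs columns {sorted(required)}")
        frame = frame.copy()
        frame["trio_id"] = frame["trio_id"].astype(str)
        frame["exposure_name"] = frame["exposure_name"].astype(str)
        frame["exposed"] = pd.to_numeric(frame["exposed"], errors="coerce")
        bad = frame["exposed"].dropna()
        if not bad.isin((0.0, 1.0)).all():
            raise ValueError("exposed must be 0, 1 or NA")
        frame["category"] = frame["exposure_name"].map(canonical_exposure)
        dup = frame.duplicated(subset=["trio_id", "exposure_name"])
        if dup.any():
            pairs = frame.loc[dup, ["trio_id", "exposure_name"]].values.tolist()
            raise ValueError(f"duplicate (trio_id, exposure_name) records: {pairs}")
        self.frame = frame

    @property
    def exposure_names(self) -> list[str]:
        return sorted(self.frame["exposure_name"].unique())

    def vector(self, trios: Sequence[PedigreeIndex], exposure_name: str) -> np.ndarray:
        """Exposure indicator per trio (float array; NaN = missing/absent)."""
        sub = self.frame[self.frame["exposure_name"] == exposure_name]
        lookup = dict(zip(sub["trio_id"], sub["exposed"]))
        return np.array([lookup.get(t.trio_id, math.nan) for t in trios], dtype=float)


@dataclass
class ExposureSummary:
    """Table-1 style accounting for one exposure."""

    exposure_name: str
    n_nonmissing: int
    n_exposed: int
    pct_exposed: int | None  # None when no nonmissing trios
    undefined: bool = field(default=False)


def read_pedigree(path: str, study_label: str = "") -> list[PedigreeIndex]:
    """Parse a 6-column pedigree file into complete case-parent trios.

    One affected child per family with both parents present yields a trio;
    families lacking any member are logged and skipped.  Duplicate
    individual IDs anywhere in the file are an error.
    """
    rows: list[tuple[str, str, str, str, str, str]] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, ind, fa, mo, sex, phen = fields[:6]
            if ind in seen_ids:
                raise PedigreeError(f"{path}: line {lineno}: duplicate individual ID {ind!r}")
            seen_ids.add(ind)
            rows.append((fam, ind, fa, mo, sex, phen))

    trios: list[PedigreeIndex] = []
    by_family: dict[str, list[tuple[str, str, str, str, str, str]]] = {}
    for row in rows:
        by_family.setdefault(row[0], []).append(row)

    for fam, members in by_family.items():
        present = {m[1] for m in members}
        children = [m for m in members if m[2] != "0" and m[3] != "0"]
        affected = [m for m in children if m[5] == "2"] or children
        if not affected:
            logger.warning("pedigree family %s: no child with both parent IDs; skipped", fam)
            continue
        child = affected[0]
        _, child_id, father_id, mother_id, _, _ = child
        if father_id not in present or mother_id not in present:
            logger.warning(
                "pedigree family %s: incomplete trio (missing %s); skipped",
                fam,
                "father" if father_id not in present else "mother",
            )
            continue
        trios.append(
            PedigreeIndex(
                trio_id=fam,
                child_id=child_id,
                mother_id=mother_id,
                father_id=father_id,
                study_label=study_label,
            )
        )
    return trios


_AUTOSOMES = {str(i) for i in range(1, 23)}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in _AUTOSOMES


def read_vcf_to_trios(
    path: str,
    trios: Sequence[PedigreeIndex],
    effect_allele_rule: str = "alt",
) -> TrioGenotypeMatrix:
    """Load biallelic autosomal VCF records as trio dosages.

    ``effect_allele_rule`` is ``"alt"`` (count ALT alleles; VCF-native
    default) or ``"minor-in-founders"`` (count whichever allele is minor
    among the parents; ties resolve to ALT).  Multiallelic and
    non-autosomal records are skipped with counts logged.
    """
    from cyvcf2 import VCF

    if effect_allele_rule not in ("alt", "minor-in-founders"):
        raise ValueError(f"unknown effect_allele_rule {effect_allele_rule!r}")

    vcf = VCF(path)
    sample_pos = {s: i for i, s in enumerate(vcf.samples)}
    needed = [sid for t in trios for sid in (t.child_id, t.mother_id, t.father_id)]
    missing_ids = [s for s in needed if s not in sample_pos]
    if missing_ids:
        raise ValueError(f"{path}: sample IDs absent from VCF header: {missing_ids}")

    member_cols = np.array(
        [[sample_pos[t.child_id], sample_pos[t.mother_id], sample_pos[t.father_id]] for t in trios]
    )  # (n_trios, 3)

    snps: list[SNPRecord] = []
    rows: list[np.ndarray] = []
    skipped = {"multiallelic": 0, "non_autosomal": 0, "non_variant": 0}
    for variant in vcf:
        if not _is_autosome(variant.CHROM):
            skipped["non_autosomal"] += 1
            continue
        if len(variant.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not variant.ALT[0] or variant.ALT[0] == variant.REF:
            skipped["non_variant"] += 1
            continue
        gts = np.array([g[:2] for g in variant.genotypes], dtype=np.int16)
        dose_all = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        dose = dose_all[member_cols].astype(np.int8)  # (n_trios, 3)

        founder = dose[:, [MOTHER, FATHER]].ravel()
        founder = founder[founder != MISSING]
        alt_freq = float(founder.mean() / 2.0) if founder.size else math.nan

        effect, other, eaf = variant.ALT[0], variant.REF, alt_freq
        if effect_allele_rule == "minor-in-founders" and not math.isnan(alt_freq) and alt_freq > 0.5:
            effect, other = variant.REF, variant.ALT[0]
            eaf = 1.0 - alt_freq
            dose = np.where(dose == MISSING, MISSING, 2 - dose).astype(np.int8)

        r2 = variant.INFO.get("R2")
        snps.append(
            SNPRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                snp_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                effect_allele=effect,
                other_allele=other,
                parental_eaf=eaf,
                imputation_r2=float(r2) if r2 is not None else None,
            )
        )
        rows.append(dose)

    for reason, count in skipped.items():
        if count:
            logger.info("%s: skipped %d %s records", path, count, reason)

    dosage = (
        np.stack(rows) if rows else np.empty((0, len(trios), 3), dtype=np.int8)
    )
    return TrioGenotypeMatrix(snps=snps, trios=list(trios), dosage=dosage)


def read_exposure_table(path: str) -> ExposureTable:
    """Read a long-format exposure TSV (trio_id, exposure_name, exposed)."""
    frame = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    return ExposureTable(frame)


def summarize_exposure(
    trios: Sequence[PedigreeIndex],
    exposures: ExposureTable,
    exposure_name: str,
) -> ExposureSummary:
    """Count exposed / nonmissing trios and the integer-rounded percentage."""
    vec = exposures.vector(trios, exposure_name)
    nonmissing = ~np.isnan(vec)
    n = int(nonmissing.sum())
    k = int(np.nansum(vec))
    if n == 0:
        logger.warning("exposure %s: no nonmissing trios; percentage undefined", exposure_name)
        return ExposureSummary(exposure_name, 0, 0, None, undefined=True)
    pct = int(round(100.0 * k / n))
    return ExposureSummary(exposure_name, n, k, pct)


def write_summary_stats(results: pd.DataFrame, path: str) -> None:
    """Write the per-SNP summary-statistics table (TSV, NA for missing).

    Floats are serialised at 17 significant digits so a write/read round
    trip is lossless.
    """
    frame = results.reindex(columns=SUMMARY_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_summary_stats(path: str) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", na_values="NA", dtype={"CHR": str, "ID": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing summary-stat columns {missing_cols}")
    return frame


def flag_thresholds(p: float | None) -> tuple[int, int]:
    """Genome-wide / suggestive flags at the conventional strict thresholds."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return 0, 0
    return int(p < GENOMEWIDE_P), int(p < SUGGESTIVE_P)
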