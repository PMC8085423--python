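"""Per-SNP quality control for trio genotype data.

Filters mirror standard trio-GWAS practice: minor allele frequency among
parents, call missingness, per-SNP Mendelian error rate, exact
Hardy-Weinberg equilibrium among founders, and an imputation-quality
(R^2) floor for imputed markers.  All thresholds are strict inequalities
in the failing direction (e.g. a SNP with exactly 5% missingness passes
a 5% cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import CHILD, FATHER, MOTHER, TrioGenotypeMatrix
from .mendel import CONSISTENT, MISSING, mendelian_consistent  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

FAIL_REASONS = ("MAF", "MISS", "MENDEL", "HWE", "INFO")


@dataclass
class QCThresholds:
    maf_min: float = 0.05
    miss_max: float = 0.05
    mendel_max: float = 0.05
    hwe_p_min: float = 1e-4
    r2_min: float = 0.3


@dataclass
class SNPQCReport:
    snp_id: str
    parental_maf: float
    missing_rate: float
    mendel_error_rate: float
    hwe_p: float
    imputation_r2: float | None
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


@dataclass
class QCLog:
    n_snps_in: int
    n_snps_out: int
    n_failed_unique: int
    n_failed_by_reason: dict[str, int]
    n_trio_genotypes_masked: int
    thresholds: QCThresholds


def hwe_exact_founders(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on founder genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count.  Monomorphic markers return p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one founder genotype required")
    n_alt = n_het + 2 * n_hom_alt
    minor = min(n_alt, 2 * n - n_alt)
    if minor == 0:
        return 1.0

    # heterozygote counts share the parity of the minor allele count
    ks = np.arange(minor % 2, minor + 1, 2)
    hom_alt = (n_alt - ks) // 2
    hom_ref = n - ks - hom_alt
    logp = (
        ks * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_ref + 1)
        - gammaln(ks + 1)
        - gammaln(hom_alt + 1)
        + gammaln(n_alt + 1)
        + gammaln(2 * n - n_alt + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[ks == n_het][0]
    return float(min(1.0, probs[probs <= observed * (1.0 + 1e-12)].sum()))


def _founder_counts(dose_parents: np.ndarray) -> tuple[int, int, int]:
    """Genotype counts (hom other, het, hom effect) among non-missing parents."""
    d = dose_parents[dose_parents != MISSING]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def snp_qc(matrix: TrioGenotypeMatrix, thresholds: QCThresholds | None = None) -> list[SNPQCReport]:
    """Compute the full QC report for every SNP in the matrix."""
    th = thresholds or QCThresholds()
    dose = matrix.dosage
    n_snps, n_trios, _ = dose.shape

    parents = dose[:, :, [MOTHER, FATHER]]
    parent_ok = parents != MISSING
    n_founder_alleles = 2 * parent_ok.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        eaf = np.where(parents != MISSING, parents, 0).sum(axis=(1, 2)) / np.where(
            n_founder_alleles > 0, n_founder_alleles, 1
        )
    maf = np.minimum(eaf, 1.0 - eaf)

    missing_rate = (dose == MISSING).sum(axis=(1, 2)) / (3 * n_trios)

    complete = (dose != MISSING).all(axis=2)  # (snps, trios)
    d = dose.clip(min=0)
    inconsistent = ~CONSISTENT[d[:, :, MOTHER], d[:, :, FATHER], d[:, :, CHILD]] & complete
    n_complete = complete.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mendel_rate = np.where(
            n_complete > 0, inconsistent.sum(axis=1) / np.maximum(n_complete, 1), 0.0
        )

    reports: list[SNPQCReport] = []
    for i, snp in enumerate(matrix.snps):
        no_founders = n_founder_alleles[i] == 0
        hwe_p = 1.0 if no_founders else hwe_exact_founders(*_founder_counts(parents[i]))
        reasons: list[str] = []
        if no_founders:
            reasons.append("MISS")
        else:
            if maf[i] < th.maf_min:
                reasons.append("MAF")
            if missing_rate[i] > th.miss_max:
                reasons.append("MISS")
            if mendel_rate[i] > th.mendel_max:
                reasons.append("MENDEL")
            if hwe_p < th.hwe_p_min:
                reasons.append("HWE")
            if snp.imputation_r2 is not None and snp.imputation_r2 < th.r2_min:
                reasons.append("INFO")
        reports.append(
            SNPQCReport(
                snp_id=snp.snp_id,
                parental_maf=float(maf[i]) if not no_founders else float("nan"),
                missing_rate=float(missing_rate[i]),
                mendel_error_rate=float(mendel_rate[i]),
                hwe_p=hwe_p,
                imputation_r2=snp.imputation_r2,
                fail_reasons=reasons,
            )
        )
    return reports


def apply_qc(
    matrix: TrioGenotypeMatrix,
    reports: list[SNPQCReport],
    thresholds: QCThresholds | None = None,
) -> tuple[TrioGenotypeMatrix, QCLog]:
    """Drop failing SNPs (order preserved) and mask residual Mendelian errors.

    At retained SNPs, any trio whose complete genotypes are Mendelian
    inconsistent has all three genotypes set to missing, so pseudo-control
    construction downstream is always well defined.
    """
    if len(reports) != matrix.n_snps:
        raise ValueError("QC reports do not align with matrix SNPs")
    keep = np.array([r.passed for r in reports])
    by_reason = {
        reason: sum(reason in r.fail_reasons for r in reports) for reason in FAIL_REASONS
    }
    filtered = matrix.subset_snps(np.flatnonzero(keep))

    d = filtered.dosage
    complete = (d != MISSING).all(axis=2)
    dc = d.clip(min=0)
    bad = ~CONSISTENT[dc[:, :, MOTHER], dc[:, :, FATHER], dc[:, :, CHILD]] & complete
    n_masked = int(bad.sum())
    if n_masked:
        d[bad] = MISSING

    log = QCLog(
        n_snps_in=matrix.n_snps,
        n_snps_out=filtered.n_snps,
        n_failed_unique=int((~keep).sum()),
        n_failed_by_reason=by_reason,
        n_trio_genotypes_masked=n_masked,
        thresholds=thresholds or QCThresholds(),
    )
    return filtered, log


def write_qc_log(reports: list[SNPQCReport], path: str, thresholds: QCThresholds | None = None) -> None:
    """TSV QC report, one row per SNP, thresholds echoed in a header comment."""
    th = thresholds or QCThresholds()
    with open(path, "w") as fh:
        fh.write(
            f"# thresholds: maf_min={th.maf_min} miss_max={th.miss_max} "
            f"mendel_max={th.mendel_max} hwe_p_min={th.hwe_p_min} r2_min={th.r2_min}\n"
        )
        fh.write("snp_id\tparental_maf\tmissing_rate\tmendel_error_rate\thwe_p\timputation_r2\tpassed\tfail_reasons\n")
        for r in reports:
            r2 = "NA" if r.imputation_r2 is None else f"{r.imputation_r2:.6g}"
            fh.write(
                f"{r.snp_id}\t{r.parental_maf:.6g}\t{r.missing_rate:.6g}\t"
                f"{r.mendel_error_rate:.6g}\t{r.hwe_p:.6g}\t{r2}\t"
                f"{int(r.passed)}\t{','.join(r.fail_reasons) or '.'}\n"
            )
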