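"""Fixed-effect inverse-variance meta-analysis of per-study gTDT estimates.

Two paths are provided:

* scalar — combine the interaction coefficient beta_ge across studies with
  weights w_i = 1/se_i^2:  beta = sum(w_i b_i)/sum(w_i), se = 1/sqrt(sum w_i);
* joint 2 df — combine the vector (beta_g, beta_ge) with matrix weights
  W_i = V_i^{-1} (or diag(V_i)^{-1} when within-study covariance is
  ignored), testing H0: beta_g = beta_ge = 0 on 2 df.

Before combination, summary statistics are harmonized across studies on
(chromosome, position): swapped allele labels flip the signs of both
coefficients, resolvable strand flips are complemented, and palindromic
(A/T, C/G) mismatches are dropped as unresolvable.  SNPs present in a
single study are carried through as single-study results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtdt import TestResult
from .io import flag_thresholds

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = ("as-is", "sign-flipped", "strand-flipped", "dropped")


@dataclass
class StudyEstimate:
    study_label: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_g: float
    beta_ge: float
    se_g: float
    se_ge: float
    cov_g_ge: float

    @property
    def weight(self) -> float:
        """Scalar-path inverse-variance weight for beta_ge."""
        return 1.0 / self.se_ge**2


@dataclass
class MetaResult:
    beta_ge_meta: float
    se_ge_meta: float
    chisq_1df: float
    p_1df: float
    beta_vec_meta: np.ndarray | None
    cov_meta: np.ndarray | None
    chisq_2df: float
    p_2df: float
    n_studies: int
    harmonization_action: dict[str, str] = field(default_factory=dict)


def _complement_alleles(ea: str, oa: str) -> tuple[str, str] | None:
    try:
        return (
            "".join(_COMPLEMENT[b] for b in ea),
            "".join(_COMPLEMENT[b] for b in oa),
        )
    except KeyError:
        return None


def _is_palindromic(ea: str, oa: str) -> bool:
    comp = _complement_alleles(ea, oa)
    return comp is not None and comp == (oa, ea)


def align_alleles(
    ref_ea: str, ref_oa: str, ea: str, oa: str
) -> tuple[str, int] | None:
    """Classify one study's alleles against the reference orientation.

    Returns (action, sign) where sign multiplies both coefficients, or
    None when the pair is unresolvable (palindromic mismatch or foreign
    alleles).
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return "as-is", 1
    if (ea, oa) == (ref_oa, ref_ea):
        if _is_palindromic(ea, oa):
            return None
        return "sign-flipped", -1
    comp = _complement_alleles(ea, oa)
    if comp is not None and not _is_palindromic(ea, oa):
        if comp == (ref_ea, ref_oa):
            return "strand-flipped", 1
        if comp == (ref_oa, ref_ea):
            return "strand-flipped", -1
    return None


def harmonize(
    studies: dict[str, pd.DataFrame],
) -> dict[tuple[str, int], list[StudyEstimate]]:
    """Align per-study summary statistics on (chrom, pos).

    The first study carrying a position defines the reference allele
    orientation; other studies are sign/strand reconciled or dropped.
    Duplicate positions within one study are an error.
    """
    tables: dict[str, dict[tuple[str, int], StudyEstimate]] = {}
    for label, frame in studies.items():
        keyed: dict[tuple[str, int], StudyEstimate] = {}
        for row in frame.itertuples(index=False):
            key = (str(row.CHR), int(row.POS))
            if key in keyed:
                raise ValueError(f"study {label}: duplicate position {key}")
            keyed[key] = StudyEstimate(
                study_label=label,
                chrom=key[0],
                pos=key[1],
                effect_allele=str(row.EA),
                other_allele=str(row.OA),
                beta_g=float(row.BETA_G),
                beta_ge=float(row.BETA_GE),
                se_g=float(row.SE_G),
                se_ge=float(row.SE_GE),
                cov_g_ge=float(row.COV_G_GE),
            )
        tables[label] = keyed

    all_keys: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for keyed in tables.values():
        for key in keyed:
            if key not in seen:
                seen.add(key)
                all_keys.append(key)

    aligned: dict[tuple[str, int], list[StudyEstimate]] = {}
    for key in all_keys:
        present = [tables[label][key] for label in tables if key in tables[label]]
        ref = present[0]
        group: list[StudyEstimate] = [ref]
        for est in present[1:]:
            result = align_alleles(
                ref.effect_allele, ref.other_allele, est.effect_allele, est.other_allele
            )
            if result is None:
                logger.info(
                    "meta: %s at %s:%d dropped (unresolvable alleles %s/%s vs %s/%s)",
                    est.study_label, key[0], key[1],
                    est.effect_allele, est.other_allele,
                    ref.effect_allele, ref.other_allele,
                )
                dropped = StudyEstimate(
                    study_label=est.study_label,
                    chrom=est.chrom,
                    pos=est.pos,
                    effect_allele=est.effect_allele,
                    other_allele=est.other_allele,
                    beta_g=math.nan,
                    beta_ge=math.nan,
                    se_g=math.nan,
                    se_ge=math.nan,
                    cov_g_ge=math.nan,
                )
                dropped.harmonization = "dropped"  # type: ignore[attr-defined]
                group.append(dropped)
                continue
            action, sign = result
            group.append(
                StudyEstimate(
                    study_label=est.study_label,
                    chrom=ref.chrom,
                    pos=ref.pos,
                    effect_allele=ref.effect_allele,
                    other_allele=ref.other_allele,
                    beta_g=sign * est.beta_g,
                    beta_ge=sign * est.beta_ge,
                    se_g=est.se_g,
                    se_ge=est.se_ge,
                    cov_g_ge=est.cov_g_ge,  # both betas negate together: cov unchanged
                )
            )
            group[-1].harmonization = action  # type: ignore[attr-defined]
        ref.harmonization = "as-is"  # type: ignore[attr-defined]
        aligned[key] = group
    return aligned


def meta_scalar(
    estimates: list[tuple[float, float]]
) -> tuple[float, float, TestResult]:
    """Inverse-variance fixed-effect combination of (beta, se) pairs."""
    if not estimates:
        raise ValueError("meta_scalar requires at least one estimate")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if not (ses > 0).all() or not np.isfinite(ses).all():
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta_meta = float((w * betas).sum() / w.sum())
    se_meta = float(1.0 / math.sqrt(w.sum()))
    return beta_meta, se_meta, TestResult.from_chisq((beta_meta / se_meta) ** 2, 1)


def meta_joint_2df(
    estimates: list[tuple[np.ndarray, np.ndarray]],
    use_within_study_cov: bool = True,
) -> MetaResult:
    """Joint fixed-effect combination of (beta_g, beta_ge) vectors.

    Each study contributes weight W_i = V_i^{-1}; with
    ``use_within_study_cov=False`` only the diagonal of V_i is used (the
    published-SEs-only mode).  Singular studies are dropped with a warning.
    """
    if not estimates:
        raise ValueError("meta_joint_2df requires at least one estimate")
    w_sum = np.zeros((2, 2))
    wb_sum = np.zeros(2)
    n_used = 0
    for beta_vec, cov in estimates:
        beta_vec = np.asarray(beta_vec, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if not use_within_study_cov:
            cov = np.diag(np.diag(cov))
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        if not (np.isfinite(cov).all() and det > 0 and cov[0, 0] > 0):
            logger.warning("meta_joint_2df: dropping study with singular covariance")
            continue
        w = np.linalg.inv(cov)
        w_sum += w
        wb_sum += w @ beta_vec
        n_used += 1
    if n_used == 0:
        raise ValueError("meta_joint_2df: all studies dropped (singular covariances)")
    cov_meta = np.linalg.inv(w_sum)
    beta_meta = cov_meta @ wb_sum
    chisq = float(beta_meta @ w_sum @ beta_meta)
    test = TestResult.from_chisq(chisq, 2)
    return MetaResult(
        beta_ge_meta=float(beta_meta[1]),
        se_ge_meta=float(math.sqrt(cov_meta[1, 1])),
        chisq_1df=math.nan,
        p_1df=math.nan,
        beta_vec_meta=beta_meta,
        cov_meta=cov_meta,
        chisq_2df=test.chisq,
        p_2df=test.p,
        n_studies=n_used,
    )


def cochran_q(estimates: list[tuple[float, float]]) -> float:
    """Heterogeneity Q for the scalar path (diagnostic only)."""
    if len(estimates) < 2:
        return math.nan
    beta_meta, _, _ = meta_scalar(estimates)
    return float(
        sum((b - beta_meta) ** 2 / s**2 for b, s in estimates)
    )


META_COLUMNS = [
    "CHR", "POS", "EA", "OA", "N_STUDIES", "ACTIONS",
    "BETA_GE_META", "SE_GE_META", "CHISQ_1DF", "P_1DF", "Q_GE",
    "BETA_G_META_JOINT", "BETA_GE_META_JOINT", "CHISQ_2DF", "P_2DF",
    "FLAG_GENOMEWIDE", "FLAG_SUGGESTIVE",
]


def meta_analyze(
    studies: dict[str, pd.DataFrame],
    use_within_study_cov: bool = True,
) -> pd.DataFrame:
    """Harmonize study summary statistics and meta-analyze every position.

    Scalar (1 df, interaction) and joint (2 df, gene + interaction) paths
    are reported side by side; flags use the scalar meta p-value.
    """
    aligned = harmonize(studies)
    records = []
    for (chrom, pos), group in aligned.items():
        actions = ",".join(
            f"{est.study_label}:{getattr(est, 'harmonization', 'as-is')}" for est in group
        )
        scalar_inputs = [
            (est.beta_ge, est.se_ge)
            for est in group
            if math.isfinite(est.beta_ge) and est.se_ge > 0
        ]
        joint_inputs = [
            (
                np.array([est.beta_g, est.beta_ge]),
                np.array([[est.se_g**2, est.cov_g_ge], [est.cov_g_ge, est.se_ge**2]]),
            )
            for est in group
            if np.isfinite([est.beta_g, est.beta_ge, est.se_g, est.se_ge, est.cov_g_ge]).all()
        ]
        row: dict = {
            "CHR": chrom,
            "POS": pos,
            "EA": group[0].effect_allele,
            "OA": group[0].other_allele,
            "N_STUDIES": len(scalar_inputs),
            "ACTIONS": actions,
            "BETA_GE_META": math.nan,
            "SE_GE_META": math.nan,
            "CHISQ_1DF": math.nan,
            "P_1DF": math.nan,
            "Q_GE": math.nan,
            "BETA_G_META_JOINT": math.nan,
            "BETA_GE_META_JOINT": math.nan,
            "CHISQ_2DF": math.nan,
            "P_2DF": math.nan,
            "FLAG_GENOMEWIDE": 0,
            "FLAG_SUGGESTIVE": 0,
        }
        if scalar_inputs:
            beta_meta, se_meta, test = meta_scalar(scalar_inputs)
            gw, sug = flag_thresholds(test.p)
            row.update(
                BETA_GE_META=beta_meta,
                SE_GE_META=se_meta,
                CHISQ_1DF=test.chisq,
                P_1DF=test.p,
                Q_GE=cochran_q(scalar_inputs),
                FLAG_GENOMEWIDE=gw,
                FLAG_SUGGESTIVE=sug,
            )
        if joint_inputs:
            try:
                joint = meta_joint_2df(joint_inputs, use_within_study_cov)
            except ValueError:
                joint = None
            if joint is not None:
                row.update(
                    BETA_G_META_JOINT=float(joint.beta_vec_meta[0]),
                    BETA_GE_META_JOINT=float(joint.beta_vec_meta[1]),
                    CHISQ_2DF=joint.chisq_2df,
                    P_2DF=joint.p_2df,
                )
        records.append(row)
    return pd.DataFrame.from_records(records, columns=META_COLUMNS)
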