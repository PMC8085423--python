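"""Genotypic TDT: pseudo-controls and the conditional-logistic G x E model.

The affected child in each trio is matched against the three pseudo-controls
(the genotype combinations it could have inherited but did not).  Under an
additive coding and a binary maternal exposure E the model is

    P(case has g0 | matched set) =
        exp(bG*g0 + bGE*g0*E) / sum_l exp(bG*gl + bGE*gl*E)

where l runs over the case and its three pseudo-controls.  Because E is
constant within a trio, the conditional likelihood factorizes over exposure
strata: fitting the one-parameter model separately in unexposed and exposed
trios gives b_u and b_e, from which

    beta_g = b_u,   beta_ge = b_e - b_u,
    se_ge^2 = se_u^2 + se_e^2,   cov(beta_g, beta_ge) = -se_u^2.

Each one-parameter fit is a Newton-Raphson maximization of a concave
log-likelihood; the kernel is vectorized over SNPs so genome-wide scans and
single-SNP fits share one code path.

A trio is *informative* at a SNP when the four transmission combinations do
not all give the same (recoded) genotype; uninformative trios contribute a
constant to the likelihood and are excluded from the informative counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import (
    CHILD,
    FATHER,
    MOTHER,
    ExposureTable,
    TrioGenotypeMatrix,
    flag_thresholds,
)
from .mendel import COMBOS, CONSISTENT, MISSING, mendelian_consistent

_Z_95 = 1.959964  # two-sided 95% normal quantile as conventionally rounded
_BETA_CAP = 15.0
_SCORE_TOL = 1e-10
_MAX_ITER = 50

GENETIC_MODELS = ("additive", "dominant", "recessive")


@dataclass
class PseudoControlSet:
    """The case genotype and the three untransmitted genotype combinations."""

    g0: int
    g1: int
    g2: int
    g3: int
    informative: bool

    @property
    def genotypes(self) -> tuple[int, int, int, int]:
        return (self.g0, self.g1, self.g2, self.g3)


@dataclass
class MainFit:
    """One-parameter conditional-logistic fit within one exposure stratum."""

    beta: float
    se: float
    loglik: float
    n_informative: int
    converged: bool
    separation_sign: int = 0  # +1/-1 when the likelihood diverges, else 0


@dataclass
class GxEFit:
    beta_g: float
    beta_ge: float
    se_g: float
    se_ge: float
    cov_g_ge: float
    loglik: float
    n_informative_unexposed: int
    n_informative_exposed: int
    converged: bool


@dataclass
class TestResult:
    chisq: float
    df: int
    p: float
    log10_p: float

    @classmethod
    def from_chisq(cls, chisq: float, df: int) -> "TestResult":
        if not math.isfinite(chisq) or chisq < 0:
            return cls(math.nan, df, math.nan, math.nan)
        # log-space survival function keeps extreme statistics finite
        log10_p = chi2.logsf(chisq, df) / math.log(10.0)
        return cls(float(chisq), df, float(chi2.sf(chisq, df)), float(log10_p))

    @classmethod
    def undefined(cls, df: int) -> "TestResult":
        return cls(math.nan, df, math.nan, math.nan)


def build_pseudo_controls(gm: int, gf: int, gc: int) -> PseudoControlSet:
    """Enumerate the 4 ordered transmissions and remove one copy of the case.

    The multiset {case, pseudo-controls} always equals the multiset of the
    four mother-allele x father-allele combinations, so the genotype sum is
    2*(gm + gf).
    """
    if not mendelian_consistent(gm, gf, gc):
        raise ValueError(f"Mendelian-inconsistent trio (gm={gm}, gf={gf}, gc={gc})")
    combos = list(COMBOS[gm, gf])
    combos.remove(gc)
    informative = len(set(combos) | {gc}) > 1
    return PseudoControlSet(gc, *(int(g) for g in combos), informative=informative)


def conditional_prob(
    g0: int, pseudo: PseudoControlSet, e: int, beta_g: float, beta_ge: float
) -> float:
    """Probability the case carries ``g0`` within its matched set of four."""
    if not (math.isfinite(beta_g) and math.isfinite(beta_ge)):
        raise ValueError("model parameters must be finite")
    slope = beta_g + beta_ge * e
    weights = [math.exp(slope * g) for g in (g0,) + tuple(pseudo.genotypes[1:])]
    return weights[0] / sum(weights)


def _recode(dosages: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return dosages.astype(float)
    if model == "dominant":
        return (dosages > 0).astype(float)
    if model == "recessive":
        return (dosages == 2).astype(float)
    raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")


def _stratum_arrays(
    dose: np.ndarray, model: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-(SNP, trio) case value, combo values, validity and informativeness."""
    complete = (dose != MISSING).all(axis=2)
    d = dose.clip(min=0)
    gm, gf, gc = d[:, :, MOTHER], d[:, :, FATHER], d[:, :, CHILD]
    valid = complete & CONSISTENT[gm, gf, gc]
    combos = _recode(COMBOS[gm, gf], model)  # (S, T, 4)
    x_case = _recode(gc, model)
    informative = valid & (combos.max(axis=2) > combos.min(axis=2))
    return x_case, combos, valid, informative


def _score_info_ll(
    beta: np.ndarray, x_case: np.ndarray, combos: np.ndarray, wt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = beta[:, None, None] * combos
    m = z.max(axis=2, keepdims=True)
    w = np.exp(z - m)
    denom = w.sum(axis=2)
    p = w / denom[:, :, None]
    eg = (p * combos).sum(axis=2)
    eg2 = (p * combos**2).sum(axis=2)
    ll = (wt * (beta[:, None] * x_case - (np.log(denom) + m[:, :, 0]))).sum(axis=1)
    score = (wt * (x_case - eg)).sum(axis=1)
    info = (wt * (eg2 - eg**2)).sum(axis=1)
    return score, info, ll


def _newton_many(
    x_case: np.ndarray, combos: np.ndarray, use: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximize the per-SNP one-parameter conditional log-likelihood.

    Newton-Raphson from 0 with step-halving on log-likelihood decrease and
    a hard cap |beta| <= 15 flagging separation.  Returns
    (beta, se, loglik, converged, separation_sign) arrays over SNPs.
    """
    n_snps = x_case.shape[0]
    wt = use.astype(float)
    n_inf = use.sum(axis=1)
    beta = np.zeros(n_snps)
    active = n_inf > 0

    score, info, ll = _score_info_ll(beta, x_case, combos, wt)
    for _ in range(_MAX_ITER):
        pending = active & (np.abs(score) >= _SCORE_TOL)
        if not pending.any():
            break
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        proposal = np.clip(beta + np.where(pending, step, 0.0), -_BETA_CAP, _BETA_CAP)
        # step-halving: never accept a log-likelihood decrease
        for _half in range(30):
            _, _, ll_new = _score_info_ll(proposal, x_case, combos, wt)
            worse = pending & (ll_new < ll - 1e-12)
            if not worse.any():
                break
            proposal = np.where(worse, 0.5 * (beta + proposal), proposal)
        beta = np.where(pending, proposal, beta)
        score, info, ll = _score_info_ll(beta, x_case, combos, wt)

    converged = active & (np.abs(score) < _SCORE_TOL)
    at_cap = np.abs(beta) >= _BETA_CAP - 1e-9
    separation = np.where(at_cap & ~converged, np.sign(beta).astype(int), 0)
    with np.errstate(divide="ignore"):
        se = np.where(converged & (info > 0), 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    beta = np.where(converged, beta, np.nan)
    ll = np.where(active, ll, np.nan)
    return beta, se, ll, converged, separation


def _fit_stratum(dose: np.ndarray, trio_mask: np.ndarray, model: str) -> list[MainFit]:
    """Fit the one-parameter model per SNP, restricted to ``trio_mask`` trios."""
    x_case, combos, _valid, informative = _stratum_arrays(dose, model)
    use = informative & trio_mask[None, :]
    beta, se, ll, conv, sep = _newton_many(x_case, combos, use)
    n_inf = use.sum(axis=1)
    return [
        MainFit(
            beta=float(beta[i]),
            se=float(se[i]),
            loglik=float(ll[i]),
            n_informative=int(n_inf[i]),
            converged=bool(conv[i]),
            separation_sign=int(sep[i]),
        )
        for i in range(dose.shape[0])
    ]


def _as_dose_matrix(
    child: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> np.ndarray:
    child = np.atleast_1d(np.asarray(child, dtype=np.int8))
    mother = np.atleast_1d(np.asarray(mother, dtype=np.int8))
    father = np.atleast_1d(np.asarray(father, dtype=np.int8))
    return np.stack([child, mother, father], axis=1)[None, :, :]


def fit_main_only(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    model: str = "additive",
) -> MainFit:
    """Fit the genotype-only conditional-logistic model on one SNP's trios.

    In the classic single-heterozygous-parent limit this reduces to the
    allelic TDT: beta = ln(b/c) with se^2 = 1/b + 1/c for b transmissions
    and c non-transmissions of the effect allele.
    """
    dose = _as_dose_matrix(child, mother, father)
    return _fit_stratum(dose, np.ones(dose.shape[1], dtype=bool), model)[0]


def fit_gxe(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    exposure: np.ndarray,
    model: str = "additive",
) -> GxEFit:
    """Fit (beta_g, beta_ge) at one SNP by exposure-stratum factorization.

    Trios with missing exposure are excluded.  beta_ge is estimable only
    when both strata contain informative trios and both stratum fits
    converge.
    """
    dose = _as_dose_matrix(child, mother, father)
    e = np.asarray(exposure, dtype=float)
    if e.shape[0] != dose.shape[1]:
        raise ValueError("exposure vector length does not match trios")
    fit_u = _fit_stratum(dose, e == 0.0, model)[0]
    fit_e = _fit_stratum(dose, e == 1.0, model)[0]
    return combine_strata(fit_u, fit_e)


def combine_strata(fit_u: MainFit, fit_e: MainFit) -> GxEFit:
    """Assemble the two-parameter fit from per-stratum one-parameter fits."""
    both_ok = fit_u.converged and fit_e.converged
    beta_ge = fit_e.beta - fit_u.beta if both_ok else math.nan
    se_ge = math.sqrt(fit_u.se**2 + fit_e.se**2) if both_ok else math.nan
    loglik = fit_u.loglik + fit_e.loglik if both_ok else math.nan
    return GxEFit(
        beta_g=fit_u.beta,
        beta_ge=beta_ge,
        se_g=fit_u.se,
        se_ge=se_ge,
        cov_g_ge=-fit_u.se**2 if fit_u.converged else math.nan,
        loglik=loglik,
        n_informative_unexposed=fit_u.n_informative,
        n_informative_exposed=fit_e.n_informative,
        converged=both_ok,
    )


def wald_1df(fit: GxEFit) -> TestResult:
    """1 df Wald chi-square of H0: beta_ge = 0 (interaction only)."""
    if not fit.converged or not math.isfinite(fit.beta_ge) or not fit.se_ge > 0:
        return TestResult.undefined(1)
    return TestResult.from_chisq((fit.beta_ge / fit.se_ge) ** 2, 1)


def wald_2df(fit: GxEFit) -> TestResult:
    """2 df Wald chi-square of H0: beta_g = 0 and beta_ge = 0."""
    if not fit.converged:
        return TestResult.undefined(2)
    v_gg, v_ee, cov = fit.se_g**2, fit.se_ge**2, fit.cov_g_ge
    det = v_gg * v_ee - cov**2
    if not (math.isfinite(det) and det > 0):
        return TestResult.undefined(2)
    b_g, b_ge = fit.beta_g, fit.beta_ge
    chisq = (b_g**2 * v_ee - 2.0 * b_g * b_ge * cov + b_ge**2 * v_gg) / det
    return TestResult.from_chisq(chisq, 2)


def wald_from_rr_ci(rr: float, ci_low: float, ci_high: float) -> tuple[float, float, TestResult]:
    """Reconstruct (beta, se, 1 df Wald test) from a published RR and 95% CI.

    beta = ln(RR), se = (ln U - ln L) / (2 * 1.959964); useful for checking
    published interaction relative risks against their reported p-values.
    """
    if not (0 < ci_low <= rr <= ci_high):
        raise ValueError("require 0 < L <= RR <= U")
    beta = math.log(rr)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z_95)
    return beta, se, TestResult.from_chisq((beta / se) ** 2, 1)


def scan_genome(
    matrix: TrioGenotypeMatrix,
    exposures: ExposureTable,
    exposure_name: str,
    model: str = "additive",
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Per-SNP G x E fits and 1 df / 2 df Wald tests across the genome.

    Returns one row per SNP in input order in the summary-statistics layout;
    non-estimable SNPs are carried with NA fields, never dropped.  Flags use
    the 1 df interaction p-value at the strict p < 5e-8 / p < 1e-6 cuts.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if exposure_name not in exposures.exposure_names:
        raise ValueError(
            f"unknown exposure {exposure_name!r}; table has {exposures.exposure_names}"
        )
    e = exposures.vector(matrix.trios, exposure_name)
    if np.isnan(e).all():
        raise ValueError(f"exposure {exposure_name!r} is missing for every trio")
    mask_u, mask_e = e == 0.0, e == 1.0

    records: list[dict] = []
    for start in range(0, matrix.n_snps, chunk_size):
        stop = min(start + chunk_size, matrix.n_snps)
        dose = matrix.dosage[start:stop]
        fits_u = _fit_stratum(dose, mask_u, model)
        fits_e = _fit_stratum(dose, mask_e, model)
        for i, snp in enumerate(matrix.snps[start:stop]):
            fit = combine_strata(fits_u[i], fits_e[i])
            t1, t2 = wald_1df(fit), wald_2df(fit)
            gw, sug = flag_thresholds(t1.p)
            records.append(
                {
                    "CHR": snp.chrom,
                    "POS": snp.pos,
                    "ID": snp.snp_id,
                    "EA": snp.effect_allele,
                    "OA": snp.other_allele,
                    "EAF_PARENTS": snp.parental_eaf,
                    "N_INFORMATIVE": fit.n_informative_unexposed + fit.n_informative_exposed,
                    "N_EXPOSED": fit.n_informative_exposed,
                    "BETA_G": fit.beta_g,
                    "SE_G": fit.se_g,
                    "BETA_GE": fit.beta_ge,
                    "SE_GE": fit.se_ge,
                    "COV_G_GE": fit.cov_g_ge,
                    "CHISQ_1DF": t1.chisq,
                    "P_1DF": t1.p,
                    "CHISQ_2DF": t2.chisq,
                    "P_2DF": t2.p,
                    "FLAG_GENOMEWIDE": gw,
                    "FLAG_SUGGESTIVE": sug,
                }
            )
    return pd.DataFrame.from_records(records)
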