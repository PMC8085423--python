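import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triogxe import (
    build_pseudo_controls,
    conditional_prob,
    fit_gxe,
    fit_main_only,
    scan_genome,
    simulate_study,
    wald_1df,
    wald_2df,
    wald_from_rr_ci,
)
from triogxe.io import SUMMARY_COLUMNS

from conftest import make_exposures, make_matrix
from helpers import joint_newton_gxe, transmission_combinations

CONSISTENT_TRIPLES = [
    (gm, gf, gc)
    for gm, gf, gc in itertools.product(range(3), repeat=3)
    if gc in transmission_combinations(gm, gf)
]


# ------------------------------------------------------- pseudo-controls


def test_pseudo_control_sum_rule_all_consistent_triples():
    """g0+g1+g2+g3 = 2(gm+gf) and the multiset matches the 4 transmissions."""
    for gm, gf, gc in CONSISTENT_TRIPLES:
        pc = build_pseudo_controls(gm, gf, gc)
        assert sum(pc.genotypes) == 2 * (gm + gf)
        assert sorted(pc.genotypes) == sorted(transmission_combinations(gm, gf))
        assert pc.g0 == gc


@pytest.mark.parametrize(
    "trio, controls, informative",
    [
        ((1, 1, 2), [0, 1, 1], True),
        ((0, 0, 0), [0, 0, 0], False),
        ((2, 1, 1), [1, 2, 2], True),
        ((2, 2, 2), [2, 2, 2], False),
    ],
)
def test_pseudo_control_examples(trio, controls, informative):
    gm, gf, gc = trio
    pc = build_pseudo_controls(gm, gf, gc)
    assert sorted(pc.genotypes[1:]) == controls
    assert pc.informative is informative


def test_pseudo_controls_reject_mendelian_inconsistency():
    with pytest.raises(ValueError, match="inconsistent"):
        build_pseudo_controls(0, 0, 1)


# ---------------------------------------------------- conditional model


def test_conditional_prob_uniform_at_null():
    pc = build_pseudo_controls(1, 1, 2)
    assert conditional_prob(pc.g0, pc, 0, 0.0, 0.0) == pytest.approx(0.25)


def test_conditional_prob_arithmetic_example():
    # weights (2, 1, 4, 4) at bG = ln 2, e = 0 with genotypes (1; 0, 2, 2)
    from triogxe.gtdt import PseudoControlSet

    pc = PseudoControlSet(1, 0, 2, 2, True)
    assert conditional_prob(1, pc, 0, math.log(2.0), 0.0) == pytest.approx(2.0 / 11.0)


def test_conditional_prob_exposure_main_effect_symmetry():
    pc = build_pseudo_controls(1, 1, 1)
    a = conditional_prob(pc.g0, pc, 1, 0.0, math.log(2.0))
    b = conditional_prob(pc.g0, pc, 0, math.log(2.0), 0.0)
    assert a == pytest.approx(b)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    idx=st.integers(0, len(CONSISTENT_TRIPLES) - 1),
    beta_g=st.floats(-3, 3),
    beta_ge=st.floats(-3, 3),
    e=st.integers(0, 1),
)
def test_conditional_probs_sum_to_one(idx, beta_g, beta_ge, e):
    gm, gf, gc = CONSISTENT_TRIPLES[idx]
    pc = build_pseudo_controls(gm, gf, gc)
    from triogxe.gtdt import PseudoControlSet

    total = 0.0
    for g in pc.genotypes:
        others = list(pc.genotypes)
        others.remove(g)
        total += conditional_prob(g, PseudoControlSet(g, *others, True), e, beta_g, beta_ge)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_conditional_prob_rejects_nonfinite_parameters():
    pc = build_pseudo_controls(1, 1, 1)
    with pytest.raises(ValueError):
        conditional_prob(pc.g0, pc, 0, math.inf, 0.0)


# -------------------------------------------------------- main-only fit


def _single_het_trios(b, c):
    """b transmissions and c non-transmissions from one heterozygous parent."""
    child = np.array([1] * b + [0] * c)
    mother = np.ones(b + c, dtype=int)
    father = np.zeros(b + c, dtype=int)
    return child, mother, father


def test_tdt_limit_recovers_ln_b_over_c():
    fit = fit_main_only(*_single_het_trios(20, 10))
    assert fit.converged and fit.n_informative == 30
    assert fit.beta == pytest.approx(math.log(2.0), abs=1e-9)
    assert fit.se == pytest.approx(math.sqrt(1 / 20 + 1 / 10), abs=1e-9)


def test_symmetric_transmissions_give_zero_beta():
    fit = fit_main_only(*_single_het_trios(15, 15))
    assert fit.beta == pytest.approx(0.0, abs=1e-12)


def test_separation_flagged_with_sign():
    # a single trio with both parents het and a homozygous-effect child:
    # likelihood increases without bound in +beta
    fit = fit_main_only(np.array([2]), np.array([1]), np.array([1]))
    assert not fit.converged
    assert fit.separation_sign == 1
    assert math.isnan(fit.beta)


def test_no_informative_trios_flagged():
    fit = fit_main_only(np.array([0, 2]), np.array([0, 2]), np.array([0, 2]))
    assert fit.n_informative == 0 and not fit.converged


# -------------------------------------------------------------- G x E fit


def test_gxe_stratified_closed_form_example():
    # unexposed b=30, c=30; exposed b=40, c=20
    cu, mu, fu = _single_het_trios(30, 30)
    ce, me, fe = _single_het_trios(40, 20)
    child = np.concatenate([cu, ce])
    mother = np.concatenate([mu, me])
    father = np.concatenate([fu, fe])
    e = np.array([0] * 60 + [1] * 60)
    fit = fit_gxe(child, mother, father, e)
    assert fit.beta_g == pytest.approx(0.0, abs=1e-9)
    assert fit.beta_ge == pytest.approx(math.log(2.0), abs=1e-9)
    assert fit.cov_g_ge == pytest.approx(-fit.se_g**2)
    assert fit.n_informative_unexposed == 60 and fit.n_informative_exposed == 60


def test_gxe_all_unexposed_degenerate():
    child, mother, father = _single_het_trios(20, 10)
    fit = fit_gxe(child, mother, father, np.zeros(30))
    assert not fit.converged
    assert math.isnan(fit.beta_ge)
    assert fit.beta_g == pytest.approx(fit_main_only(child, mother, father).beta)


def test_gxe_missing_exposure_trios_excluded():
    child, mother, father = _single_het_trios(20, 10)
    e = np.full(30, np.nan)
    e[:20] = np.array([0] * 10 + [1] * 10)
    fit = fit_gxe(child, mother, father, e)
    assert fit.n_informative_unexposed + fit.n_informative_exposed == 20


def test_gxe_recovers_truth_within_monte_carlo_error(causal_config):
    study = simulate_study(causal_config(n_trios=5000, beta_g=0.3, beta_ge=0.5, seed=17))
    d = study.matrix.dosage[0]
    e = study.exposures.vector(study.matrix.trios, "smoking")
    fit = fit_gxe(d[:, 0], d[:, 1], d[:, 2], e)
    assert abs(fit.beta_g - 0.3) < 3 * fit.se_g
    assert abs(fit.beta_ge - 0.5) < 3 * fit.se_ge


def test_stratified_fit_matches_joint_newton_oracle():
    """Closed-form stratified route equals direct 2-parameter maximization."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = 300
        mother = rng.binomial(2, 0.3, n)
        father = rng.binomial(2, 0.3, n)
        child = rng.binomial(1, mother / 2) + rng.binomial(1, father / 2)
        e = rng.binomial(1, 0.5, n).astype(float)
        fit = fit_gxe(child, mother, father, e)
        if not fit.converged:
            continue
        beta_vec, cov = joint_newton_gxe(child, mother, father, e)
        assert fit.beta_g == pytest.approx(beta_vec[0], abs=1e-6)
        assert fit.beta_ge == pytest.approx(beta_vec[1], abs=1e-6)
        assert fit.se_g == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-6)
        assert fit.se_ge == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-6)
        assert fit.cov_g_ge == pytest.approx(cov[0, 1], abs=1e-6)


# ------------------------------------------------------------- Wald tests


def _fit_from(child, mother, father, e):
    return fit_gxe(child, mother, father, e)


def test_wald_2df_equals_stratum_z_squares():
    cu, mu, fu = _single_het_trios(25, 40)
    ce, me, fe = _single_het_trios(35, 15)
    fit = fit_gxe(
        np.concatenate([cu, ce]),
        np.concatenate([mu, me]),
        np.concatenate([fu, fe]),
        np.array([0] * 65 + [1] * 50),
    )
    fit_u = fit_main_only(cu, mu, fu)
    fit_e = fit_main_only(ce, me, fe)
    expected = (fit_u.beta / fit_u.se) ** 2 + (fit_e.beta / fit_e.se) ** 2
    assert wald_2df(fit).chisq == pytest.approx(expected, rel=1e-9)


def test_wald_identities_zero_and_quantile():
    from triogxe.gtdt import GxEFit

    fit = GxEFit(0.0, 0.0, 0.2, 0.3, -0.04, 0.0, 50, 50, True)
    assert wald_1df(fit).chisq == 0.0 and wald_1df(fit).p == 1.0
    assert wald_2df(fit).chisq == 0.0 and wald_2df(fit).p == 1.0

    fit2 = GxEFit(0.0, 1.959964 * 0.3, 0.2, 0.3, 0.0, 0.0, 50, 50, True)
    assert wald_1df(fit2).p == pytest.approx(0.05, rel=1e-6)
    # diagonal covariance: 2 df statistic is the sum of squared z-scores
    fit3 = GxEFit(0.4, 0.6, 0.2, 0.3, 0.0, 0.0, 50, 50, True)
    assert wald_2df(fit3).chisq == pytest.approx((0.4 / 0.2) ** 2 + (0.6 / 0.3) ** 2)


def test_wald_undefined_for_non_estimable_fit():
    from triogxe.gtdt import GxEFit

    fit = GxEFit(0.1, math.nan, 0.2, math.nan, math.nan, math.nan, 50, 0, False)
    assert math.isnan(wald_1df(fit).p) and math.isnan(wald_2df(fit).p)


def test_wald_reconstruction_from_rr_ci():
    beta, se, test = wald_from_rr_ci(2.0, 1.5, 8.0 / 3.0)
    assert beta == pytest.approx(math.log(2.0))
    assert se == pytest.approx((math.log(8.0 / 3.0) - math.log(1.5)) / (2 * 1.959964))
    assert 0 < test.p < 1


# ------------------------------------------------------------ genome scan


@pytest.fixture
def small_null_scan():
    rng = np.random.default_rng(11)
    n_snps, n_trios = 30, 200
    mother = rng.binomial(2, 0.3, (n_snps, n_trios))
    father = rng.binomial(2, 0.3, (n_snps, n_trios))
    child = rng.binomial(1, mother / 2) + rng.binomial(1, father / 2)
    dose = np.stack([child, mother, father], axis=2)
    m = make_matrix(dose)
    e = rng.binomial(1, 0.4, n_trios).astype(float)
    return m, e


def test_scan_shape_and_estimability(small_null_scan):
    m, e = small_null_scan
    results = scan_genome(m, make_exposures(m.trios, e), "smoking")
    assert list(results.columns) == SUMMARY_COLUMNS
    assert len(results) == m.n_snps
    assert results["P_1DF"].notna().all()
    assert ((results["P_1DF"] > 0) & (results["P_1DF"] <= 1)).all()


def test_scan_invariant_to_trio_order(small_null_scan):
    m, e = small_null_scan
    res1 = scan_genome(m, make_exposures(m.trios, e), "smoking")
    perm = np.random.default_rng(0).permutation(m.n_trios)
    from triogxe import TrioGenotypeMatrix

    m2 = TrioGenotypeMatrix(
        snps=m.snps, trios=[m.trios[i] for i in perm], dosage=m.dosage[:, perm, :]
    )
    res2 = scan_genome(m2, make_exposures(m2.trios, e[perm]), "smoking")
    np.testing.assert_allclose(
        res1[["BETA_G", "BETA_GE", "CHISQ_1DF", "CHISQ_2DF"]],
        res2[["BETA_G", "BETA_GE", "CHISQ_1DF", "CHISQ_2DF"]],
        rtol=1e-9,
    )


def test_scan_identical_under_exposure_rename(small_null_scan):
    m, e = small_null_scan
    res1 = scan_genome(m, make_exposures(m.trios, e, "smoking"), "smoking")
    res2 = scan_genome(m, make_exposures(m.trios, e, "caffeine"), "caffeine")
    np.testing.assert_array_equal(
        res1[["CHISQ_1DF", "CHISQ_2DF"]].to_numpy(),
        res2[["CHISQ_1DF", "CHISQ_2DF"]].to_numpy(),
    )


def test_scan_unknown_exposure_errors(small_null_scan):
    m, e = small_null_scan
    with pytest.raises(ValueError, match="unknown exposure"):
        scan_genome(m, make_exposures(m.trios, e), "vitamin")


def test_scan_dominant_model_differs_from_additive(small_null_scan):
    m, e = small_null_scan
    table = make_exposures(m.trios, e)
    res_add = scan_genome(m, table, "smoking", model="additive")
    res_dom = scan_genome(m, table, "smoking", model="dominant")
    assert not np.allclose(
        res_add["CHISQ_1DF"].to_numpy(), res_dom["CHISQ_1DF"].to_numpy(), equal_nan=True
    )
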