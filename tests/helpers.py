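"""Independent oracles used by the test suite.

These deliberately re-derive results along different computational paths
from the package: a direct 2-parameter Newton maximizer of the conditional
likelihood (vs the stratified closed-form route), an exact-rational
Hardy-Weinberg enumeration (vs the gammaln log-space route), and explicit
allele-by-allele transmission enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

_ALLELES = ((0, 0), (0, 1), (1, 1))


def transmission_combinations(gm: int, gf: int) -> list[int]:
    """All 4 ordered child dosages from one allele per parent."""
    return [am + af for am in _ALLELES[gm] for af in _ALLELES[gf]]


def consistent_by_enumeration(gm: int, gf: int, gc: int) -> bool:
    return gc in transmission_combinations(gm, gf)


def hwe_exact_rational(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test via integer arithmetic (conditional on allele counts)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    if min(n_alt, 2 * n - n_alt) == 0:
        return 1.0

    def weight(k: int) -> int:
        hom_alt = (n_alt - k) // 2
        hom_ref = n - k - hom_alt
        if hom_alt < 0 or hom_ref < 0:
            return 0
        return comb(n, hom_ref) * comb(n - hom_ref, k) * 2**k

    ks = range(min(n_alt, 2 * n - n_alt) % 2, min(n_alt, 2 * n - n_alt) + 1, 2)
    weights = {k: weight(k) for k in ks}
    total = sum(weights.values())
    observed = weights[n_het]
    selected = sum(w for w in weights.values() if w <= observed)
    return float(Fraction(selected, total))


def joint_newton_gxe(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    exposure: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly maximize the 2-parameter conditional log-likelihood.

    Returns (beta_vec, covariance) where beta_vec = (beta_g, beta_ge) and
    the covariance is the inverse observed information at the maximum.
    """
    child = np.asarray(child, dtype=int)
    mother = np.asarray(mother, dtype=int)
    father = np.asarray(father, dtype=int)
    e = np.asarray(exposure, dtype=float)
    keep = (
        (child >= 0) & (mother >= 0) & (father >= 0) & np.isfinite(e)
    )
    child, mother, father, e = child[keep], mother[keep], father[keep], e[keep]
    combos = np.array(
        [transmission_combinations(gm, gf) for gm, gf in zip(mother, father)],
        dtype=float,
    )  # (n, 4)
    gc = child.astype(float)

    x = np.zeros(2)
    hess = np.eye(2)
    for _ in range(max_iter):
        slope = x[0] + x[1] * e
        z = slope[:, None] * combos
        z -= z.max(axis=1, keepdims=True)
        w = np.exp(z)
        w /= w.sum(axis=1, keepdims=True)
        eg = (w * combos).sum(axis=1)
        varg = (w * combos**2).sum(axis=1) - eg**2
        resid = gc - eg
        grad = np.array([resid.sum(), (e * resid).sum()])
        hess = np.array(
            [
                [varg.sum(), (e * varg).sum()],
                [(e * varg).sum(), (e**2 * varg).sum()],
            ]
        )
        step = np.linalg.solve(hess, grad)
        x = x + step
        if np.abs(grad).max() < tol:
            break
    return x, np.linalg.inv(hess)
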