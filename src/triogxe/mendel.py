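"""Biallelic transmission tables for case-parent trios.

Everything downstream (Mendelian checks, pseudo-control construction, the
conditional likelihood) reduces to the four ordered transmission
combinations a parent pair can produce: the mother contributes one of her
two alleles, the father one of his.  With additive dosage coding
(0/1/2 copies of the effect allele) these tables are tiny and precomputed.
"""

from __future__ import annotations

import numpy as np

MISSING = -1

#: the two alleles carried at each dosage, as effect-allele indicators
_ALLELES = ((0, 0), (0, 1), (1, 1))

#: COMBOS[gm, gf] -> 4 ordered child dosages (mother allele x father allele)
COMBOS = np.array(
    [
        [[am + af for am in _ALLELES[gm] for af in _ALLELES[gf]] for gf in range(3)]
        for gm in range(3)
    ],
    dtype=np.int8,
)

#: CONSISTENT[gm, gf, gc] -> child dosage gc attainable from (gm, gf)
CONSISTENT = np.zeros((3, 3, 3), dtype=bool)
for _gm in range(3):
    for _gf in range(3):
        for _gc in COMBOS[_gm, _gf]:
            CONSISTENT[_gm, _gf, _gc] = True

#: MENDEL_PROBS[gm, gf, gc] -> P(child dosage = gc | gm, gf), each ordered
#: transmission combination having probability 1/4
MENDEL_PROBS = np.zeros((3, 3, 3), dtype=float)
for _gm in range(3):
    for _gf in range(3):
        for _gc in COMBOS[_gm, _gf]:
            MENDEL_PROBS[_gm, _gf, _gc] += 0.25


def _check_dosage(*values: int) -> None:
    for v in values:
        if v not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2 (missing not allowed); got {v!r}")


def mendelian_consistent(gm: int, gf: int, gc: int) -> bool:
    """True iff child dosage ``gc`` is producible by one allele from each parent."""
    _check_dosage(gm, gf, gc)
    return bool(CONSISTENT[gm, gf, gc])
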