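from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from triogxe import (
    CausalSNP,
    ExposureTable,
    PedigreeIndex,
    Population,
    SimConfig,
    SNPRecord,
    TrioGenotypeMatrix,
)


def make_matrix(
    dosage: np.ndarray,
    chroms: list[str] | None = None,
    r2: list[float | None] | None = None,
) -> TrioGenotypeMatrix:
    """Wrap a raw (n_snps, n_trios, 3) dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_snps, n_trios, _ = dosage.shape
    snps = [
        SNPRecord(
            chrom=(chroms[j] if chroms else "1"),
            pos=1000 * (j + 1),
            snp_id=f"s{j + 1}",
            effect_allele="G",
            other_allele="A",
            imputation_r2=(r2[j] if r2 else None),
        )
        for j in range(n_snps)
    ]
    trios = [
        PedigreeIndex(f"T{i + 1}", f"T{i + 1}_c", f"T{i + 1}_m", f"T{i + 1}_f")
        for i in range(n_trios)
    ]
    return TrioGenotypeMatrix(snps=snps, trios=trios, dosage=dosage)


def make_exposures(trios, values: np.ndarray, name: str = "smoking") -> ExposureTable:
    rows = [
        (t.trio_id, name, v if not np.isnan(v) else np.nan)
        for t, v in zip(trios, np.asarray(values, dtype=float))
    ]
    return ExposureTable(pd.DataFrame(rows, columns=["trio_id", "exposure_name", "exposed"]))


@pytest.fixture
def single_pop_config():
    def build(n_trios=500, n_snps=20, maf=0.3, exposure_rate=0.3, seed=1, **kw):
        return SimConfig(
            n_trios=n_trios,
            n_snps=n_snps,
            populations=[Population("pop1", 1.0, maf, {"smoking": exposure_rate})],
            seed=seed,
            **kw,
        )

    return build


@pytest.fixture
def causal_config():
    def build(n_trios=2000, beta_g=0.3, beta_ge=0.5, maf=0.3, exposure_rate=0.5, seed=1, **kw):
        return SimConfig(
            n_trios=n_trios,
            n_snps=1,
            populations=[Population("pop1", 1.0, maf, {"smoking": exposure_rate})],
            causal=[CausalSNP(0, beta_g, beta_ge, "smoking")],
            seed=seed,
            **kw,
        )

    return build


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    "##contig=<ID=2>\n"
    "##contig=<ID=X>\n"
    '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, records: list[str], samples: list[str]) -> str:
    """Write a small plain-text VCF with the given body records."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            fh.write(rec + "\n")
    return str(path)
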