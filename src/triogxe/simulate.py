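"""Ascertained case-parent trio simulator.

Generates trio studies with exactly the statistical structure the gTDT
analysis assumes: founders drawn under Hardy-Weinberg equilibrium with
population-specific allele frequencies, a binary maternal exposure per trio
with population-specific rates (allowing gene-exposure confounding across
sub-populations), and the affected child's genotype drawn under
ascertainment from the Mendelian transmission law tilted by the
multiplicative relative-risk model exp(bG*g + bGE*g*E).

Two ascertainment samplers are available:

* ``conditional`` (default) — the child genotype is drawn directly from the
  conditional law P(g | parents, affected) ∝ mendel(g) * exp(bG*g + bGE*g*E);
  this reproduces the retrospective likelihood exactly and needs no
  penetrance constant;
* ``rejection`` — the child is drawn from the plain Mendelian law and the
  trio is accepted with probability baseline * exp(bG*g + bGE*g*E)
  (resampling until acceptance), demonstrating the rare-disease sampling
  mechanism; both samplers target the same conditional distribution.

SNPs are simulated in linkage equilibrium.  Genotype missingness and
Mendelian-error contamination are injected post hoc and fully logged so a
perturbed study can be restored exactly.  All randomness flows from one
seed through named sub-streams (population, parents, exposure, child,
errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CHILD,
    FATHER,
    MOTHER,
    ExposureTable,
    PedigreeIndex,
    SNPRecord,
    TrioGenotypeMatrix,
)
from .mendel import MENDEL_PROBS, MISSING

_STREAMS = ("population", "parents", "exposure", "child", "errors")


@dataclass
class Population:
    label: str
    fraction: float
    maf: float | Sequence[float]  # effect-allele frequency, scalar or per SNP
    exposure_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class CausalSNP:
    snp_index: int
    beta_g: float
    beta_ge: float
    exposure: str


@dataclass
class SimConfig:
    n_trios: int
    n_snps: int
    populations: list[Population]
    causal: list[CausalSNP] = field(default_factory=list)
    genotype_missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    seed: int = 0
    mode: str = "conditional"
    penetrance_baseline: float = 0.01
    study_label: str = "SIM"

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.n_trios < 1:
            out.append("n_trios must be >= 1")
        if self.n_snps < 1:
            out.append("n_snps must be >= 1")
        if not self.populations:
            out.append("at least one population required")
        else:
            total = sum(p.fraction for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                out.append(f"population fractions sum to {total}, not 1")
        causal_idx = {c.snp_index for c in self.causal}
        for pop in self.populations:
            maf = np.broadcast_to(np.asarray(pop.maf, dtype=float), (self.n_snps,))
            if ((maf <= 0) | (maf >= 1)).any():
                out.append(f"population {pop.label}: maf outside (0, 1)")
            else:
                noncausal = np.ones(self.n_snps, dtype=bool)
                for i in causal_idx:
                    if 0 <= i < self.n_snps:
                        noncausal[i] = False
                if (maf[noncausal] > 0.5).any():
                    out.append(f"population {pop.label}: non-causal SNP maf > 0.5")
            for name, rate in pop.exposure_rates.items():
                if not 0.0 <= rate <= 1.0:
                    out.append(f"population {pop.label}: exposure rate {name} outside [0, 1]")
        for c in self.causal:
            if not 0 <= c.snp_index < self.n_snps:
                out.append(f"causal snp_index {c.snp_index} out of range")
            if not any(c.exposure in p.exposure_rates for p in self.populations):
                out.append(f"causal exposure {c.exposure!r} has no rate in any population")
        for name, rate in (
            ("genotype_missing_rate", self.genotype_missing_rate),
            ("mendel_error_rate", self.mendel_error_rate),
        ):
            if not 0.0 <= rate < 1.0:
                out.append(f"{name} outside [0, 1)")
        if self.mode not in ("conditional", "rejection"):
            out.append(f"unknown mode {self.mode!r}")
        if not 0.0 < self.penetrance_baseline <= 1.0:
            out.append("penetrance_baseline outside (0, 1]")
        return out

    def validate(self) -> None:
        problems = self.violations()
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def exposure_names(self) -> list[str]:
        names: list[str] = []
        for pop in self.populations:
            for name in pop.exposure_rates:
                if name not in names:
                    names.append(name)
        return names


@dataclass
class Truth:
    """Generative ground truth aligned with the simulated matrix."""

    population: np.ndarray  # (n_trios,) population index
    population_labels: list[str]
    beta_g: np.ndarray  # (n_snps,)
    beta_ge: np.ndarray  # (n_snps,)
    causal_exposure: list[str | None]
    missing_log: np.ndarray  # (k, 4): snp, trio, member, original dosage
    mendel_log: np.ndarray  # (m, 5): snp, trio, member, original, replacement


@dataclass
class SimulatedStudy:
    matrix: TrioGenotypeMatrix
    exposures: ExposureTable
    truth: Truth
    config: SimConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _maf_matrix(config: SimConfig) -> np.ndarray:
    return np.stack(
        [
            np.broadcast_to(np.asarray(p.maf, dtype=float), (config.n_snps,))
            for p in config.populations
        ]
    )  # (n_pops, n_snps)


def simulate_parents(
    config: SimConfig, population: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Founder dosages ~ Binomial(2, maf) per population, SNPs independent."""
    maf = _maf_matrix(config)[population].T  # (n_snps, n_trios)
    gm = rng.binomial(2, maf).astype(np.int8)
    gf = rng.binomial(2, maf).astype(np.int8)
    return gm, gf


def sample_case_genotype(
    gm: np.ndarray,
    gf: np.ndarray,
    e: np.ndarray,
    beta_g: float,
    beta_ge: float,
    rng: np.random.Generator,
    mode: str = "conditional",
    penetrance_baseline: float = 0.01,
) -> np.ndarray:
    """Draw affected-child dosages given parents and exposure.

    Conditional mode samples from mendel(g | gm, gf) tilted by
    exp((bG + bGE*e) * g); rejection mode draws Mendelian children and
    accepts with probability baseline * exp((bG + bGE*e) * g), which
    targets the identical conditional law.
    """
    gm = np.atleast_1d(np.asarray(gm))
    gf = np.atleast_1d(np.asarray(gf))
    e = np.atleast_1d(np.asarray(e, dtype=float))
    slope = beta_g + beta_ge * e
    base = MENDEL_PROBS[gm, gf]  # (n, 3)
    if mode == "conditional":
        tilt = base * np.exp(slope[:, None] * np.arange(3.0))
        tilt /= tilt.sum(axis=1, keepdims=True)
        u = rng.random(gm.shape[0])
        return (tilt.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int8)
    if mode == "rejection":
        max_risk = penetrance_baseline * math.exp(
            2.0 * max(0.0, float(np.max(slope, initial=0.0)))
        )
        if max_risk > 1.0:
            raise ValueError(
                "acceptance probability exceeds 1 at these parameters; "
                "use a smaller penetrance_baseline"
            )
        n = gm.shape[0]
        gc = np.zeros(n, dtype=np.int8)
        pending = np.ones(n, dtype=bool)
        while pending.any():
            idx = np.flatnonzero(pending)
            u = rng.random((idx.size, 2))
            draw = (base[idx].cumsum(axis=1) < u[:, :1]).sum(axis=1)
            risk = penetrance_baseline * np.exp(slope[idx] * draw)
            accept = u[:, 1] < risk
            gc[idx[accept]] = draw[accept]
            pending[idx[accept]] = False
        return gc
    raise ValueError(f"unknown mode {mode!r}")


def _mendelian_children(gm: np.ndarray, gf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Null transmission: one allele from each parent, all SNPs at once."""
    return (
        rng.binomial(1, gm / 2.0) + rng.binomial(1, gf / 2.0)
    ).astype(np.int8)


def inject_errors(study: SimulatedStudy, config: SimConfig | None = None) -> SimulatedStudy:
    """Inject genotype missingness and Mendelian-error contamination in place.

    Every perturbation is appended to the truth logs: Mendelian errors
    replace one member's genotype with a uniform draw from the other two
    values, then missingness masks calls to MISSING.  ``restore_clean``
    replays the logs to recover the clean study exactly.
    """
    cfg = config or study.config
    rng = _streams(cfg.seed)["errors"]
    dose = study.matrix.dosage
    n_snps, n_trios, _ = dose.shape

    mendel_rows = []
    if cfg.mendel_error_rate > 0:
        hit = rng.random((n_snps, n_trios)) < cfg.mendel_error_rate
        snp_i, trio_i = np.nonzero(hit)
        member = rng.integers(0, 3, snp_i.size)
        original = dose[snp_i, trio_i, member]
        replacement = (original + 1 + rng.integers(0, 2, snp_i.size)) % 3
        dose[snp_i, trio_i, member] = replacement.astype(np.int8)
        mendel_rows = np.column_stack([snp_i, trio_i, member, original, replacement])

    missing_rows = []
    if cfg.genotype_missing_rate > 0:
        mask = rng.random(dose.shape) < cfg.genotype_missing_rate
        snp_i, trio_i, member = np.nonzero(mask)
        original = dose[snp_i, trio_i, member]
        dose[snp_i, trio_i, member] = MISSING
        missing_rows = np.column_stack([snp_i, trio_i, member, original])

    study.truth.mendel_log = (
        np.asarray(mendel_rows, dtype=np.int64).reshape(-1, 5)
    )
    study.truth.missing_log = (
        np.asarray(missing_rows, dtype=np.int64).reshape(-1, 4)
    )
    return study


def restore_clean(study: SimulatedStudy) -> TrioGenotypeMatrix:
    """Undo logged perturbations (missingness first, then Mendelian errors)."""
    dose = study.matrix.dosage.copy()
    log = study.truth.missing_log
    if log.size:
        dose[log[:, 0], log[:, 1], log[:, 2]] = log[:, 3].astype(np.int8)
    log = study.truth.mendel_log
    if log.size:
        dose[log[:, 0], log[:, 1], log[:, 2]] = log[:, 3].astype(np.int8)
    return TrioGenotypeMatrix(snps=study.matrix.snps, trios=study.matrix.trios, dosage=dose)


def _snp_records(config: SimConfig, gm: np.ndarray, gf: np.ndarray) -> list[SNPRecord]:
    records = []
    for j in range(config.n_snps):
        chrom = str(1 + (j * 22) // config.n_snps)
        founders = np.concatenate([gm[j], gf[j]])
        eaf = float(founders.mean() / 2.0)
        records.append(
            SNPRecord(
                chrom=chrom,
                pos=1000 * (j + 1),
                snp_id=f"sim{j + 1}",
                effect_allele="G",
                other_allele="A",
                parental_eaf=eaf,
            )
        )
    return records


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate one complete ascertained trio study from a config.

    Deterministic given ``config.seed``; genotype matrix, exposure table
    and ground-truth record are aligned by construction.
    """
    config.validate()
    rngs = _streams(config.seed)
    n_pops = len(config.populations)
    fractions = np.array([p.fraction for p in config.populations])
    population = rngs["population"].choice(n_pops, size=config.n_trios, p=fractions)

    gm, gf = simulate_parents(config, population, rngs["parents"])

    exposure_rows = []
    exposure_vectors: dict[str, np.ndarray] = {}
    for name in config.exposure_names:
        rates = np.array(
            [p.exposure_rates.get(name, 0.0) for p in config.populations]
        )[population]
        vec = rngs["exposure"].binomial(1, rates)
        exposure_vectors[name] = vec.astype(float)
        for i in range(config.n_trios):
            exposure_rows.append((f"T{i + 1:05d}", name, int(vec[i])))

    gc = _mendelian_children(gm, gf, rngs["child"])
    beta_g = np.zeros(config.n_snps)
    beta_ge = np.zeros(config.n_snps)
    causal_exposure: list[str | None] = [None] * config.n_snps
    for c in config.causal:
        beta_g[c.snp_index] = c.beta_g
        beta_ge[c.snp_index] = c.beta_ge
        causal_exposure[c.snp_index] = c.exposure
        gc[c.snp_index] = sample_case_genotype(
            gm[c.snp_index],
            gf[c.snp_index],
            exposure_vectors[c.exposure],
            c.beta_g,
            c.beta_ge,
            rngs["child"],
            mode=config.mode,
            penetrance_baseline=config.penetrance_baseline,
        )

    trios = [
        PedigreeIndex(
            trio_id=f"T{i + 1:05d}",
            child_id=f"T{i + 1:05d}_c",
            mother_id=f"T{i + 1:05d}_m",
            father_id=f"T{i + 1:05d}_f",
            study_label=config.study_label,
            population_label=config.populations[population[i]].label,
        )
        for i in range(config.n_trios)
    ]
    dosage = np.stack([gc, gm, gf], axis=2).astype(np.int8)
    matrix = TrioGenotypeMatrix(
        snps=_snp_records(config, gm, gf), trios=trios, dosage=dosage
    )
    exposures = ExposureTable(
        pd.DataFrame(exposure_rows, columns=["trio_id", "exposure_name", "exposed"])
    )
    truth = Truth(
        population=population,
        population_labels=[p.label for p in config.populations],
        beta_g=beta_g,
        beta_ge=beta_ge,
        causal_exposure=causal_exposure,
        missing_log=np.empty((0, 4), dtype=np.int64),
        mendel_log=np.empty((0, 5), dtype=np.int64),
    )
    study = SimulatedStudy(matrix=matrix, exposures=exposures, truth=truth, config=config)
    if config.mendel_error_rate > 0 or config.genotype_missing_rate > 0:
        inject_errors(study, config)
    return study


_GT = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_study(study: SimulatedStudy, outdir: str) -> dict[str, str]:
    """Emit VCF + pedigree + exposure TSV + truth TSVs for a simulated study.

    The VCF carries all trio members as samples so the full pipeline can be
    exercised end to end through the public file interfaces.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    matrix, trios = study.matrix, study.matrix.trios
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "pedigree": os.path.join(outdir, "pedigree.ped"),
        "exposures": os.path.join(outdir, "exposures.tsv"),
        "truth_snps": os.path.join(outdir, "truth_snps.tsv"),
        "truth_trios": os.path.join(outdir, "truth_trios.tsv"),
    }

    samples = [sid for t in trios for sid in (t.child_id, t.mother_id, t.father_id)]
    contigs = sorted({s.chrom for s in matrix.snps}, key=int)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triogxe-simulator\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, snp in enumerate(matrix.snps):
            gts = "\t".join(
                _GT[int(matrix.dosage[j, i, m])]
                for i in range(len(trios))
                for m in (CHILD, MOTHER, FATHER)
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.other_allele}\t"
                f"{snp.effect_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    with open(paths["pedigree"], "w") as fh:
        for t in trios:
            fh.write(f"{t.trio_id} {t.father_id} 0 0 1 1\n")
            fh.write(f"{t.trio_id} {t.mother_id} 0 0 2 1\n")
            fh.write(f"{t.trio_id} {t.child_id} {t.father_id} {t.mother_id} 1 2\n")

    study.exposures.frame[["trio_id", "exposure_name", "exposed"]].to_csv(
        paths["exposures"], sep="\t", index=False
    )

    truth = study.truth
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in matrix.snps],
            "chrom": [s.chrom for s in matrix.snps],
            "pos": [s.pos for s in matrix.snps],
            "beta_g": truth.beta_g,
            "beta_ge": truth.beta_ge,
            "exposure": [e or "NA" for e in truth.causal_exposure],
        }
    ).to_csv(paths["truth_snps"], sep="\t", index=False)
    pd.DataFrame(
        {
            "trio_id": [t.trio_id for t in trios],
            "population": [truth.population_labels[p] for p in truth.population],
        }
    ).to_csv(paths["truth_trios"], sep="\t", index=False)
    return paths
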