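# Methods

## The conditional-logistic gTDT

At a biallelic autosomal marker, each case–parent trio contributes a
matched set of four genotypes: the affected child's observed dosage G₀
and the three pseudo-controls G₁–G₃. The pseudo-controls are defined by
enumerating the four *ordered* transmission combinations (each parent
contributes each of its two alleles once) and removing one instance equal
to the observed child genotype. Two identities follow and are enforced by
tests: the multiset {G₀,…,G₃} equals the multiset of the four
combinations, and G₀+G₁+G₂+G₃ = 2(G_m+G_f). When both parents are
heterozygous the child's genotype may be attainable by two transmission
paths; the matched set is still "four combinations minus one observed
instance" with no extra path weighting. A trio is *informative* when the
four combinations are not all equal (at least one heterozygous parent
under the additive coding); uninformative trios contribute a constant
to the conditional likelihood and are excluded from informative counts.

The model for a binary maternal exposure E is

    P(Y₀=1 | matched set, E) = exp(β_G G₀ + β_GE G₀E) / Σ_l exp(β_G G_l + β_GE G_l E).

### Estimation by exposure-stratum factorization

E is constant within a trio, so the conditional likelihood factorizes
into an unexposed block (slope β_G) and an exposed block (slope
β_G + β_GE). Each block is a concave one-parameter conditional-logistic
likelihood maximized by Newton–Raphson; writing β̂_u, β̂_e for the two
stratum estimates and se_u, se_e for their inverse-information standard
errors,

    β̂_G = β̂_u,            β̂_GE = β̂_e − β̂_u,
    se_G = se_u,           se_GE = (se_u² + se_e²)^{1/2},
    cov(β̂_G, β̂_GE) = −se_u².

This reproduces the maximum of the two-parameter likelihood exactly (the
test suite checks agreement with a direct 2-parameter Newton maximizer to
1e-6) and yields the covariance analytically. In the classic limit where
every informative trio has a single heterozygous parent, β̂ reduces to the
allelic TDT: ln(b/c) with se² = 1/b + 1/c for b transmissions and c
non-transmissions of the effect allele.

Newton settings: start at 0; convergence |score| < 1e-10; at most 50
iterations; step-halving whenever a step would decrease the
log-likelihood; |β| capped at 15, and hitting the cap without a vanishing
score is flagged as separation with the sign of divergence. Strata with
no informative trios are non-estimable; β̂_GE (and both Wald tests) are
then reported as missing — non-estimable SNPs are carried through scans
as NA rows, never dropped. The same vectorized kernel serves single-SNP
fits and genome-wide scans (SNP chunks of 512), so there is one code path
to validate.

### Tests

* 1 df interaction: χ² = (β̂_GE/se_GE)², df 1.
* 2 df joint: χ² = β̂ᵀV⁻¹β̂ with V the 2×2 covariance above, df 2. With
  the stratified parameterization this equals β̂_u²/se_u² + β̂_e²/se_e².

Survival probabilities are evaluated with the χ² log-survival function so
extreme statistics keep finite −log₁₀ p. Dosages can be recoded dominant
or recessive before likelihood evaluation; additive is the default and
the analyzed model.

## Quality control

Per SNP, with all thresholds strict in the failing direction:

| filter | statistic | fails when | default |
|---|---|---|---|
| MAF | minor allele frequency among non-missing parental genotypes (each parent counted once; trios assumed unrelated) | maf < 0.05 | 0.05 |
| MISS | missing calls / (3 × trios) | rate > 0.05 | 0.05 |
| MENDEL | Mendelian-inconsistent trios / complete trios | rate > 0.05 | 0.05 |
| HWE | exact two-sided test on founder genotype counts | p < 1e-4 | 1e-4 |
| INFO | imputation R² (imputed SNPs only) | R² < 0.3 | 0.3 |

The HWE test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts whose conditional probability
does not exceed the observed one (monomorphic markers give p = 1); an
exact test is used rather than a chi-square because it is well defined at
low counts. Enumeration is done in log space (gammaln) and is checked
against an exact rational-arithmetic oracle in the tests.

After filtering, any residual Mendelian-inconsistent trio at a retained
SNP has its three genotypes set to missing so pseudo-control construction
is always defined; the trio remains in the analysis at other SNPs. QC is
idempotent in the operating regime (a second pass removes nothing); a SNP
sitting simultaneously at the Mendelian and missingness boundaries could
in principle cross the missingness threshold after masking, which is
accepted as a pathological corner.

## Meta-analysis

Scalar path: β̂ = Σωᵢβ̂ᵢ/Σωᵢ, SE = (Σωᵢ)^{-1/2}, ωᵢ = 1/SEᵢ², with a 1 df
Wald test. Joint path: matrix weights Wᵢ = Vᵢ⁻¹, β̂ = (ΣWᵢ)⁻¹ΣWᵢβ̂ᵢ,
χ²(2 df) = β̂ᵀ(ΣWᵢ)β̂. The within-study covariance of (β̂_G, β̂_GE) is
available analytically and used by default; a diagonal-only mode
(published-SEs-only) is provided since reported summary statistics often
lack the covariance. With diagonal weights the joint meta reduces to
coordinate-wise scalar meta (a tested identity). Fixed effects only;
Cochran's Q is emitted as a diagnostic column and not used for inference.

Harmonization matches studies on (chromosome, position), with the first
study carrying a position defining the reference orientation: swapped
EA/OA labels negate both coefficients (covariance unchanged — both betas
negate), resolvable strand flips are complemented first, palindromic
(A/T, C/G) mismatches and irreconcilable allele pairs are dropped with a
recorded action, and positions present in a single study are carried
through as single-study results.

## Diagnostics

λ = median(χ²) / median of the null χ² (0.45494 at 1 df, 2 ln 2 at 2 df);
the median form is robust to a small number of true signals. QQ tables
use expected quantiles (k−0.5)/n; Manhattan tables accumulate observed
per-chromosome maxima. Significance flags are strict: p exactly at
5×10⁻⁸ or 10⁻⁶ is not flagged.

## The simulator

The generator emulates the structure the analysis assumes:

* founders: dosage ~ Binomial(2, maf) per population, SNPs in linkage
  equilibrium — the tests are single-SNP, so LD adds nothing to
  calibration and is out of scope;
* exposure: one Bernoulli draw per trio per exposure with
  population-specific rates, so allele frequency and exposure rate can be
  correlated across populations, reproducing the confounding scenario the
  trio design is meant to absorb;
* ascertainment: the child's genotype at a causal SNP is drawn from the
  Mendelian law tilted by exp((β_G + β_GE E) g) — exactly the conditional
  law given an affected child under the multiplicative model, requiring
  no penetrance constant. A rejection sampler (Mendelian draw accepted
  with probability baseline·exp(·), default baseline 0.01) demonstrates
  the rare-disease sampling mechanism and targets the same conditional
  law; the two are checked to agree distributionally. Under the
  multiplicative model with independent loci, causal SNPs tilt
  independently, so per-SNP sampling is exact;
* contamination: genotype calls are masked at a configurable missingness
  rate, and Mendelian errors replace one member's genotype with a uniform
  draw from the other two values at a configurable per-(SNP, trio) rate.
  Every perturbation is logged so the clean study can be restored
  exactly, which the tests exploit.

All randomness derives from a single seed through named sub-streams
(population, parents, exposure, child, errors), so each component is
independently reproducible.

Default study conditions used in calibration and recovery checks: MAF
0.3, exposure rate 0.3 (0.5 where power is the question), 1,000 trios and
10,000 SNPs for null calibration, 5,000 trios × 200 replicates for
coefficient recovery, two populations at MAF 0.1/0.5 with exposure rates
0.1/0.5 for the confounded null. These match the sample sizes and rates
of large multi-site trio consortia (studies of ~1,400–1,900 trios with
exposure rates from a few percent to ~70% across subgroups). What the
simulator does not emulate — LD, genotyping-batch structure,
self-reporting error in exposures, parent-of-origin or maternal-genotype
effects, relatedness between trios — bounds what passing tests show: they
establish correctness and calibration of the estimator under its own
sampling assumptions, not robustness to every artifact of real array
data.

## Interfaces and conventions

VCF (plain or bgzipped) with 1-based coordinates; only biallelic
autosomal records are ingested, multiallelic records are skipped rather
than split. The effect allele defaults to ALT (deterministic and
VCF-native); a minor-in-founders mode exists because MAF-based filters
are defined among parents. Pedigrees are 6-column pre-MAKEPED text; only
complete trios (all three members genotyped and present) are loaded, and
incomplete families are logged and skipped. Exposures are long-format
TSV with explicit NA; a trio missing one exposure is excluded from that
exposure's analysis only. Summary statistics are TSV with floats at 17
significant digits (lossless round trip). The `triogxe` CLI
(simulate/scan/meta/diagnostics) writes a manifest and stage-count JSON
per run and uses exit codes 0/2/1 (success/validation/runtime).

## Known limitations

* No X/Y/MT handling, haplotype or parent-of-origin tests, maternal-
  genotype effects, or robust variance.
* Non-integer (dosage) genotypes are not supported; imputed markers enter
  as hard calls with an R² filter.
* Separation (e.g. rare exposure × rare genotype) yields flagged NA
  results rather than penalized estimates; how the original genome-wide
  analyses handled such SNPs is not documented, and NA-propagation is
  this package's choice.
* Duplicate-sample detection across studies is out of scope beyond a
  warning on identical sample IDs.
* Effect-allele orientation of published markers is not always printed
  with the summary tables; reconstructions from printed RR/CI are
  orientation-agnostic (the 1 df Wald p is invariant to sign).
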