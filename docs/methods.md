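# Methods

This note documents the models behind `mtcnkit`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing its output.

## Relative copy number from depth ratios

In capture (exome-style) sequencing, mtDNA is covered by off-target reads
while the nuclear genome is enriched, so only *relative* copy number is
identifiable. The estimator is the ratio of mean mtDNA depth over the
16,569 rCRS positions to mean depth at an equal number of sampled autosomal
sites; no factor of two is applied, and the log (natural) is taken before
modeling. Zero-depth autosomal or mtDNA means raise errors rather than
propagating infinities. All sampled autosomal sites enter the mean,
including zero-depth ones: dropping them would bias the denominator at low
coverage.

A coverage-spike artifact on the mitochondrial reference is masked as the
closed 1-based interval **[2,500, 3,000]** (501 positions) before averaging.
The interval endpoints are a package convention for the well-known "2.5–3
kbp" artifact; masking a region of inflated depth can only lower the mtDNA
mean, and the simulator's Poisson oracle confirms the masked estimator is
unbiased while the unmasked one is biased upward by
`(501 × (multiplier − 1))/16,569`.

### Cell-composition residualization

lrmtCN is regressed on the saturated model

    intercept; sex; age, age²; {count, count²} for neutrophils, platelets,
    lymphocytes, basophils, monocytes, eosinophils (12 columns); and all
    pairwise products of {sex, age, age²} with those 12 (36 columns)

— 52 columns in total, fit by OLS on the combined cohort (a per-model-label
option allows per-cohort fits). Raw polynomials are used: residuals depend
only on the column span, so any orthogonalized basis gives identical
rlrmtCN (tested), and raw coefficients stay interpretable. The design is
column-normalized and solved by QR: the raw products span ~10 orders of
magnitude and a naive normal-equation solve loses the orthogonality of the
residuals. Rank deficiency is reported with the names of the collapsing
columns; rows with missing covariates are dropped with a logged count.

The validation logic for the adjustment is the Duffy attenuation property:
in a cohort where a Duffy-null-like allele affects copy number *only*
through neutrophil count, its association with rlrmtCN must be a small
fraction of its association with lrmtCN. This is a property test, not a
numeric reproduction, because it depends on the simulated effect sizes.

## Phenotype preparation

Phecode status: case iff the code appears ≥2 times, control iff never,
missing iff exactly once; a phecode is analyzed only with **strictly more
than 20 cases** in every cohort. "At least twice" counts occurrence records
(synthetic data have no dates; a distinct-date switch is reserved for real
exports).

Labs: per-individual median, then a **single-pass** 7-SD trim computed on
the full sample — deliberately not iterated, since re-trimming on the
trimmed sample can cascade; the order (trim, then transform) follows the
removal-first convention. Box-Cox λ maximizes the profile log-likelihood of
the linear model on {age, age², sex, 20 PCs},

    ll(λ) = −(n/2) log(RSS_λ/n) + (λ−1) Σ log y,

searched on λ ∈ [−3, 3] in steps of 0.01 with a local quadratic refinement.
Residual sums of squares are computed from explicit residual vectors (the
`‖y‖² − ‖Qᵀy‖²` shortcut cancels catastrophically for large λ and scaled
y). λ is scale-invariant and recovered within 0.1 at n ≥ 5,000 (tested
against scipy's intercept-only MLE). Nonpositive values are an error: the
caller decides on offsets, never the transform.

## Association machinery

Linear fits are OLS, binary fits are maximum-likelihood logistic, both with
Wald two-sided p-values; logistic fits refuse fewer than 20 cases
(consistent with the phecode filter) and flag non-convergence/separation
with p = NaN instead of returning a spurious estimate. BH discovery flags
are computed at FDR 0.005 and 0.05 jointly across all traits of a scan, per
cohort; flagged (NaN) fits never enter the step-up ranking.

Direction-consistency uses the exact two-sided binomial test at p = 0.5
with the "minlike" two-sided convention (sum of outcome probabilities no
larger than the observed one) — this reproduces 14/14 → 1.2×10⁻⁴,
8/8 → 0.008 and 713/1,158 → 3.25×10⁻¹⁵ and equals brute-force enumeration
of the pmf for n ≤ 25.

Replication power for a known additive association uses
`SE = σ/√(2nf(1−f))` — the factor 2 is the Hardy–Weinberg variance of a
0/1/2 dosage — noncentrality `λ = (β/SE)²`, and power
`P(χ²₁(λ) > q₁₋α)` with q the central quantile. A 10,000-rep Monte-Carlo
regression oracle agrees within 2% absolute; σ defaults to 0.8, the
residual phenotype SD after covariate adjustment typical for this trait.

PRS scoring is the weighted sum of effect-allele dosages (a per-allele
average is available as a switch); weights matched by variant id with
ref/alt flips harmonized via the complemented dosage, unmatched weights
dropped with a logged count. Clumping is greedy smallest-p-first within a
1 Mb window at p < 0.05, distance-only by design (no LD model), ties broken
by lowest position.

## Admixture mapping and the effective number of tests

The scan regresses rlrmtCN on the local African-allele count per marker
with global ancestry and the Duffy-null genotype (additive column plus
heterozygote indicator) as covariates; markers with monomorphic ancestry or
degenerate designs are flagged, and markers with posterior ≤ 0.9 are
excluded from both the scan and the burden estimate (one rule).

The multiple-testing burden is empirical: for each individual and
chromosome, the diploid ancestry fraction (count/2) in map order is treated
as a stationary series; Yule–Walker autoregressive fits (Levinson–Durbin,
order selected by AIC up to ~10·log₁₀N) give the spectral density at
frequency zero `s(0) = σ²/(1−Σφ)²` and `ESS = N·var/s(0)`. ESS values are
summed over chromosomes per individual and averaged over individuals into
N_eff; the genome-wide threshold is 0.05/N_eff. A **constant series has
ESS = 1**: the perfect-autocorrelation limit, which keeps ESS monotone in
tract length down to zero generations (an alternative convention, ESS = N,
breaks that monotonicity; the R implementation this convention is usually
compared against returns 0). The diploid count/2 series was chosen over
per-haplotype series — the two differ only in how much within-individual
averaging happens before the AR fit.

## Heritability

GRM entries are `(1/m) Σ (x−2f)(x'−2f)/(2f(1−f))` with in-sample
frequencies and a MAF > 0.01 filter. Haseman–Elston regression (phenotype
cross-products on off-diagonal GRM entries, after residualizing on fixed
covariates and scaling to unit variance) is the primary estimator: closed
form, fast, and its slope is h²_g directly. Standard errors come from a
50-block jackknife over *individuals*, which respects the dependence of
pairs sharing an individual — a pair-level bootstrap would understate the
error severalfold.

AI-REML is the secondary estimator: EM first step, average-information
updates afterwards, components floored at 10⁻⁶ of the phenotypic variance,
convergence at 10⁻⁶ relative change within 100 iterations (non-convergence
raises with the trace). The per-component h² and the delta-method SE of
their sum come from the inverse AI matrix. HE and REML agree within joint
2-SE on single-component simulated data, per-chromosome components localize
planted signal, and covariate-attenuation runs share one GRM across an
ordered list of fixed-effect designs, reporting deltas against the first.

At the package's test scale (n = 2,000, m = 5,000) the h² = 0.30 vs 0.10
cohort contrast has a joint SE near 0.10, so the two cohorts separate
clearly in order but only marginally at 2 SE — matching what desk-scale
sample sizes can support; the estimates themselves are unbiased.

## Mito-nuclear incompatibility

Haplogroups are classified by top-level letter (L\* African; H, I, J, K, N,
R, T, U, V, W, X European; everything else excluded). The test is the joint
regression of the phenotype on nuclear ancestry z, haplogroup x ∈ {−1,+1}
(African lineage = +1, the reference in reporting) and x·z, with sex, age,
age² as covariates; swapping the coding negates the interaction beta and
leaves its p unchanged (tested).

Power simulations draw a fresh cohort per replicate (z ~ Beta(mean 0.8,
sd 0.1); haplogroup Bernoulli(0.8) independent of z — no coupling is
assumed), build `y = covariates + β₁xz + N(0, σ)` for quantitative traits
or Bernoulli(expit(β₀ + β₁xz)) for binary traits with β₀ assembled from
covariate coefficients at their means (or a target prevalence), and count
interaction rejections at **α = 3.5×10⁻⁵**. That constant is taken as
authoritative even though a per-trait Bonferroni over ~1,100 traits would
give ≈4.4×10⁻⁵; the two differ by ~25% and the constant is what the power
curves are defined against. A per-design analytic oracle (noncentral χ²
from the interaction column's partial variance) tracks the Monte-Carlo
power within 3% absolute.

The discordance statistic — the fraction of nuclear ancestry whose
continental origin differs from the mtDNA lineage — reduces to 1−z for
African-lineage carriers and z for European-lineage carriers. With
imbalanced haplogroups it therefore inherits the ancestry main effect: the
artifact demonstration simulates a pure z effect with zero interaction at
n = 8,311 and 80/20 haplogroups and shows the discordance regression
rejecting far above the 5% level (≈0.58 at the default 1-SD ancestry
effect) while the interaction test stays at α. With balanced haplogroups
the confounding cancels by symmetry and both tests are calibrated.

## The synthetic cohort: what it does and does not emulate

The generator reproduces the statistical *structure* the analyses rely on:
Beta(0.8, 0.1) ancestry (method-of-moments parameterization), 80/20
haplogroup imbalance with ~3% other lineages, per-haplotype Markov ancestry
tracts (redraw probability 1−e^{−g·d} per d Morgans, g = 8 generations
by default, no interference), Hardy–Weinberg genotypes conditional on the
local background, a Duffy-like null allele at frequencies 0.98/0.006 on
African/European backgrounds shifting log neutrophil count by −0.18 per
allele, log-normal blood counts centered on typical adult values, Poisson
depths at 2.8× with a 3× spike artifact, and phenotypes through
linear/logistic laws with a 5% phecode singleton rate. Haplogroup is
independent of nuclear ancestry by default (the null of no mito-nuclear
coupling); an optional coupling parameter links them, since real admixed
cohorts are coupled.

It does **not** emulate: linkage disequilibrium within ancestry backgrounds
(markers are conditionally independent given the tract), recombination
interference, real haplogroup phylogenies, EHR visit/date structure,
genotyping or local-ancestry-inference error (posteriors default to 1), or
the true — unpublished — ancestry distribution of any real cohort. Power
results that depend on that distribution (notably the binary and
quantitative interaction power at a given effect size) are therefore
qualitative: the shapes and calibration transfer, specific percentages do
not. Passing tests certify the estimators against the generator's
assumptions, not against real-data pathologies such as batch effects or
time-varying cell counts.

## Problem sizes and determinism

Simulation-heavy checks run at deliberately desk-scale sizes chosen to keep
estimator standard errors informative: HE/REML at n = 800–2,000 with
2,000–5,000 markers, power curves at n = 8,311 with 150–1,000 replicates,
null-phenome calibration at 1,000 traits × 5,000 individuals. Every
`simulate_*` function and the pipeline are deterministic given their seed;
one global seed expands into per-stage substreams via `SeedSequence.spawn`,
so stages can be re-run independently without disturbing each other's
draws. The end-to-end pipeline writes byte-identical tables for identical
configuration and seed, and every output carries the configuration hash.
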