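# mtcnkit

Analysis toolkit for **relative mitochondrial DNA copy number (mtCN)**
estimated from off-target sequencing depth, built for multi-ancestry
biobank-style studies. It covers the full path from raw per-site depths to
population-genetic inference — and ships a synthetic-cohort generator so the
entire pipeline runs and is tested without any restricted individual-level
data.

## What it does

Blood mtDNA content is dominated by cell composition (platelets carry
mitochondria but no nucleus; neutrophils are mtDNA-poor), and in capture
sequencing the mitochondrial genome is covered only by off-target reads.
`mtcnkit` implements the resulting analysis chain:

1. **Copy-number estimation** (`copynumber`): mask the known coverage-spike
   artifact on the rCRS (positions 2,500–3,000), then
   `rmtCN = mean depth(mtDNA) / mean depth(autosomal sites)`, `lrmtCN = log
   rmtCN`, and **rlrmtCN** = residual of lrmtCN from the saturated
   composition model
   `lrmtCN ~ (sex + age + age²) × (count + count² for six cell types)`
   (52 design columns).
2. **Phenotype preparation** (`pheno`): phecode occurrence counts → case
   (≥2), control (0), missing (1); phecodes kept only with >20 cases per
   cohort; labs median-collapsed, 7-SD trimmed, Box-Cox transformed with λ
   by profile likelihood of `y ~ age + age² + sex + 20 PCs`.
3. **Association scans** (`assoc`): linear/logistic PheWAS with
   Benjamini–Hochberg control; exact binomial direction-consistency tests;
   replication power via the noncentral χ²₁ with
   `SE = σ/√(2nf(1−f))`, `λ = (β/SE)²`; heritability explained
   `h² = 2Σβ̂²f(1−f)`; polygenic scores; distance-based clumping;
   cross-cohort effect-size correlation.
4. **Admixture mapping** (`admixture`): per-marker regression of rlrmtCN on
   local African-ancestry count with global ancestry and Duffy-null
   (additive + dominance) covariates; empirical multiple-testing burden
   `N_eff` from autoregressive fits to each individual's per-chromosome
   ancestry series (spectral density at frequency zero), threshold
   `0.05/N_eff`.
5. **Heritability** (`heritability`): GRM from standardized dosages,
   Haseman–Elston regression (primary), AI-REML with one or many variance
   components (per-chromosome partition), and covariate-attenuation
   experiments.
6. **Mito-nuclear tests** (`mitonuclear`): haplogroup → continental lineage
   (L\* African; H,I,J,K,N,R,T,U,V,W,X European; others excluded), the
   haplogroup×ancestry interaction test, Monte-Carlo power for quantitative
   and binary traits (logistic law `π = expit(β₀ + β₁xz)` with the intercept
   built from fitted covariate coefficients), and a demonstration that the
   older "ancestry discordance" statistic manufactures incompatibility
   signal from a pure ancestry main effect when haplogroups are imbalanced.
7. **Synthetic cohorts** (`simulate`): admixed individuals (Beta-distributed
   ancestry, Markov ancestry tracts at g generations/Morgan, ancestry-
   conditional genotypes, a Duffy-like differentiated allele acting on
   neutrophils), latent copy number with configurable genetics, Poisson
   depth profiles with the spike artifact, and binary/quantitative phenomes.

## Worked example

```python
import numpy as np
from mtcnkit import simulate, copynumber

cfg = simulate.SimulationConfig(n_individuals=800, seed=7)
cohort = simulate.simulate_cohort(cfg)
true_lrmtcn = simulate.simulate_copy_number(cohort, seed=8)
profiles = simulate.simulate_depth(true_lrmtcn, simulate.CoverageConfig(), seed=9,
                                   individual_ids=cohort["individual_id"].to_numpy())

records = copynumber.estimate_cohort(profiles)        # masks [2500, 3000]
records = copynumber.residualize(records, cohort)     # 52-column model
```

Running `python examples/02_estimate_copy_number.py` (the script above plus
diagnostics) prints:

```
corr(estimated lrmtCN, true lrmtCN) = 1.000 at 2.8x coverage
unmasked/masked rmtCN ratio = 1.0605 (the spike inflates the unmasked estimate)
sd(lrmtCN) = 0.327  ->  sd(rlrmtCN) = 0.300
```

With 16,569 mtDNA and autosomal sites at 2.8× the ratio estimator is
essentially noiseless; skipping the spike mask biases rmtCN up by ~6% here;
and the drop from sd 0.327 to 0.300 is the variance attributable to cell
composition, sex and age. The other scripts in `examples/` walk through the
PheWAS, admixture mapping with `N_eff`, Haseman–Elston/REML heritability,
and the mito-nuclear power/artifact analyses, each printing a short
interpretation of its numbers.

A single-command pipeline is also available:

```sh
mtcnkit run --seed 3 --out out/        # simulate -> estimate -> scans -> report.json
mtcnkit estimate-mtcn --depths depths.tsv --cohort cohort.tsv --out cn.tsv
```

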