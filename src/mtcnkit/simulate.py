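"""Synthetic admixed-cohort generator.

Every downstream stage of the package (copy-number estimation, phenotype
preparation, association scans, admixture mapping, heritability, mito-nuclear
tests) is driven by cohorts generated here, so the whole pipeline is testable
without restricted biobank data. The generator emulates:

* an admixed cohort whose nuclear African-ancestry fraction follows a Beta
  law (default mean 0.8, sd 0.1, resembling an African-American biobank
  cohort);
* mtDNA haplogroups drawn ~80/20 African/European-lineage with a small
  fraction of other lineages;
* a Duffy-like highly differentiated allele (null allele nearly fixed on
  African background, nearly absent on European background) that lowers
  neutrophil counts;
* complete blood counts from log-normal laws, with the Duffy effect on
  neutrophils;
* per-haplotype local-ancestry tracts as a Markov process along a genetic
  map (rate = generations since admixture per Morgan);
* genotypes drawn conditional on the local-ancestry background;
* a latent log relative mtDNA copy number (lrmtCN) with nonlinear blood-count
  effects (neutrophils negative, platelets positive by default) and an
  optional additive genetic component with a target heritability;
* per-site sequencing depths (Poisson) over the 16,569 rCRS positions and an
  equal number of autosomal sites, with an optional coverage-spike artifact
  between positions 2,500 and 3,000;
* binary (phecode-like) and quantitative (lab-like) phenotypes through a
  logistic/linear law with configurable effects of copy number, nuclear
  ancestry, haplogroup, and their interaction.

All ``simulate_*`` operations are deterministic given their seed; one global
seed expands into per-operation substreams (see :func:`mtcnkit._util.substreams`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ConfigError, InputError, substreams
from .copynumber import MT_LENGTH, DepthProfile
from .mitonuclear import classify_origin

AFRICAN_HAPLOGROUPS = ("L0", "L1a", "L2a1", "L3e")
EUROPEAN_HAPLOGROUPS = ("H1", "I2", "J1c", "K1a", "T2b", "U5a", "V7", "W1", "X2")
OTHER_HAPLOGROUPS = ("M7b", "A2", "B2", "C1", "D4")

BLOOD_COUNT_COLUMNS = (
    "neutrophils",
    "lymphocytes",
    "monocytes",
    "eosinophils",
    "basophils",
    "platelets",
)

#: (mean, sd) of log counts, in 1,000 cells/uL; typical adult ranges
_DEFAULT_BLOOD_LOGNORMAL = {
    "neutrophils": (np.log(4.0), 0.35),
    "lymphocytes": (np.log(1.9), 0.30),
    "monocytes": (np.log(0.5), 0.30),
    "eosinophils": (np.log(0.15), 0.50),
    "basophils": (np.log(0.04), 0.45),
    "platelets": (np.log(240.0), 0.25),
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults are the study conditions the rest of the package assumes:
    80/20 African/European haplogroup imbalance, Beta(mean 0.8, sd 0.1)
    African-ancestry fractions, 8 generations since admixture, and a
    Duffy-null allele at frequency 0.98 on African vs 0.006 on European
    background.
    """

    n_individuals: int = 1000
    seed: int = 0
    haplogroup_freq_african: float = 0.8
    other_haplogroup_fraction: float = 0.03
    ancestry_distribution: tuple[float, float] = (0.8, 0.1)  # (mean, sd) of Beta
    generations_since_admixture: float = 8.0
    duffy_freq_by_ancestry: tuple[float, float] = (0.98, 0.006)  # (African, European)
    #: additive shift of log neutrophil count per Duffy-null allele
    duffy_neutrophil_effect: float = -0.18
    #: 0 = haplogroup independent of nuclear ancestry (null of no coupling);
    #: 1 = P(African lineage) equals the individual's ancestry fraction
    haplogroup_ancestry_coupling: float = 0.0
    sex_male_fraction: float = 0.45
    age_mean: float = 55.0
    age_sd: float = 15.0
    age_min: float = 18.0
    blood_lognormal: dict = field(default_factory=lambda: dict(_DEFAULT_BLOOD_LOGNORMAL))
    n_pcs: int = 20

    def validate(self) -> "SimulationConfig":
        if not self.n_individuals >= 2:
            raise ConfigError("n_individuals must be >= 2")
        for name in ("haplogroup_freq_african", "other_haplogroup_fraction",
                     "haplogroup_ancestry_coupling", "sex_male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        m, s = self.ancestry_distribution
        if not (0.0 < m < 1.0):
            raise ConfigError(f"ancestry_distribution mean must be in (0,1), got {m}")
        if not (0.0 < s**2 < m * (1.0 - m)):
            raise ConfigError(
                f"ancestry_distribution sd {s} incompatible with a Beta law of mean {m}"
            )
        for i, f in enumerate(self.duffy_freq_by_ancestry):
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"duffy_freq_by_ancestry[{i}] must be in [0, 1], got {f}")
        if self.generations_since_admixture < 0:
            raise ConfigError("generations_since_admixture must be >= 0")
        if self.age_mean <= 0 or self.age_sd <= 0:
            raise ConfigError("age_mean and age_sd must be positive")
        return self


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a Beta law with given mean/sd."""
    v = sd * sd
    common = mean * (1.0 - mean) / v - 1.0
    return mean * common, (1.0 - mean) * common


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a cohort table: demographics, blood counts, ancestry, haplogroup.

    Deterministic given ``config.seed``. Haplogroup lineage is drawn with
    P(African lineage) = ``haplogroup_freq_african`` (optionally coupled to
    nuclear ancestry); the Duffy genotype is binomial under Hardy-Weinberg at
    the ancestry-weighted null-allele frequency; blood counts are log-normal
    and positive by construction.
    """
    config.validate()
    (rng_anc, rng_hap, rng_duffy, rng_demo, rng_blood, rng_pc) = substreams(config.seed, 6)
    n = config.n_individuals

    a, b = _beta_params(*config.ancestry_distribution)
    ancestry = rng_anc.beta(a, b, size=n)

    c = config.haplogroup_ancestry_coupling
    p_afr = (1.0 - c) * config.haplogroup_freq_african + c * ancestry
    p_afr = p_afr * (1.0 - config.other_haplogroup_fraction)
    p_other = config.other_haplogroup_fraction
    u = rng_hap.uniform(size=n)
    lineage = np.where(u < p_afr, "African", np.where(u < p_afr + p_other, "other", "European"))
    labels = np.empty(n, dtype=object)
    for cls, pool in (("African", AFRICAN_HAPLOGROUPS),
                      ("European", EUROPEAN_HAPLOGROUPS),
                      ("other", OTHER_HAPLOGROUPS)):
        idx = np.where(lineage == cls)[0]
        labels[idx] = rng_hap.choice(pool, size=idx.size)
    origin = np.array([classify_origin(h) for h in labels], dtype=object)

    f_afr, f_eur = config.duffy_freq_by_ancestry
    q_null = ancestry * f_afr + (1.0 - ancestry) * f_eur
    duffy = rng_duffy.binomial(2, q_null)

    sex = (rng_demo.uniform(size=n) < config.sex_male_fraction).astype(int)
    age = np.clip(rng_demo.normal(config.age_mean, config.age_sd, size=n),
                  config.age_min, None)

    data = {
        "individual_id": [f"ind{i:06d}" for i in range(n)],
        "sex": sex,
        "age": age,
    }
    for col in BLOOD_COUNT_COLUMNS:
        mu, sigma = config.blood_lognormal[col]
        logv = rng_blood.normal(mu, sigma, size=n)
        if col == "neutrophils":
            logv = logv + config.duffy_neutrophil_effect * duffy
        data[col] = np.exp(logv)
    data["african_ancestry"] = ancestry
    data["mt_haplogroup"] = labels
    data["mt_origin"] = origin
    data["duffy_genotype"] = duffy

    # PC1 tracks ancestry (as in a real admixed cohort); the rest are noise
    anc_std = (ancestry - ancestry.mean()) / ancestry.std()
    for k in range(1, config.n_pcs + 1):
        if k == 1:
            data["pc1"] = 0.95 * anc_std + 0.31 * rng_pc.normal(size=n)
        else:
            data[f"pc{k}"] = rng_pc.normal(size=n)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# local ancestry


@dataclass
class LocalAncestryMatrix:
    """Per-haplotype African-ancestry states along a marker map.

    ``hap0``/``hap1`` hold 0/1 states (1 = African background) of shape
    (individuals, markers); ``counts`` is their sum in {0,1,2}. ``markers``
    carries chromosome, 1-based physical position and genetic position in
    Morgans, sorted by (chromosome, position).
    """

    individual_ids: np.ndarray
    markers: pd.DataFrame  # columns: chrom, pos, gpos
    hap0: np.ndarray
    hap1: np.ndarray
    posterior: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return self.hap0 + self.hap1

    @property
    def n_individuals(self) -> int:
        return self.hap0.shape[0]

    @property
    def n_markers(self) -> int:
        return self.hap0.shape[1]


def uniform_marker_map(n_chromosomes: int = 3, markers_per_chromosome: int = 200,
                       morgans_per_chromosome: float = 1.0,
                       bp_per_chromosome: int = 100_000_000) -> pd.DataFrame:
    """Evenly spaced marker map used throughout the examples and tests."""
    frames = []
    for c in range(1, n_chromosomes + 1):
        g = np.linspace(0.0, morgans_per_chromosome, markers_per_chromosome)
        pos = np.linspace(1, bp_per_chromosome, markers_per_chromosome).astype(int)
        frames.append(pd.DataFrame({"chrom": c, "pos": pos, "gpos": g}))
    return pd.concat(frames, ignore_index=True)


def simulate_local_ancestry(cohort: pd.DataFrame, marker_map: pd.DataFrame,
                            config: SimulationConfig,
                            seed: int | None = None) -> LocalAncestryMatrix:
    """Simulate per-haplotype ancestry tracts as a Markov chain along the map.

    Between adjacent markers separated by ``d`` Morgans the chain redraws its
    state with probability 1 - exp(-g*d) (g = generations since admixture),
    drawing African with the individual's ancestry fraction, so the
    stationary African frequency of each haplotype equals that fraction.
    """
    for c, grp in marker_map.groupby("chrom"):
        g = grp["gpos"].to_numpy()
        if np.any(np.diff(g) < 0):
            raise InputError(f"genetic positions decrease within chromosome {c}")
    markers = marker_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(cohort)
    m = len(markers)
    anc = cohort["african_ancestry"].to_numpy()
    g_rate = config.generations_since_admixture

    haps = []
    for _ in range(2):
        states = np.empty((n, m), dtype=np.int8)
        col = 0
        for _, grp in markers.groupby("chrom", sort=True):
            gpos = grp["gpos"].to_numpy()
            k = len(gpos)
            state = (rng.uniform(size=n) < anc).astype(np.int8)
            states[:, col] = state
            for j in range(1, k):
                d = gpos[j] - gpos[j - 1]
                p_switch = -np.expm1(-g_rate * d)
                redraw = rng.uniform(size=n) < p_switch
                fresh = (rng.uniform(size=n) < anc).astype(np.int8)
                state = np.where(redraw, fresh, state)
                states[:, col + j] = state
            col += k
        haps.append(states)

    posterior = np.ones((n, m))
    return LocalAncestryMatrix(
        individual_ids=cohort["individual_id"].to_numpy(),
        markers=markers[["chrom", "pos", "gpos"]].copy(),
        hap0=haps[0], hap1=haps[1], posterior=posterior,
    )


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``variants`` columns: variant_id, chrom, pos, ref, alt, effect_allele,
    freq (in-sample effect-allele frequency).
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray  # float, values in [0, 2]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def _variant_frame(chrom, pos, freq) -> pd.DataFrame:
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    ids = [f"chr{c}:{p}:A:G" for c, p in zip(chrom, pos)]
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "ref": "A", "alt": "G", "effect_allele": "G",
        "freq": np.asarray(freq, dtype=float),
    })


def simulate_genotypes(local: LocalAncestryMatrix,
                       variant_freqs_by_ancestry: np.ndarray,
                       seed: int = 0) -> GenotypeMatrix:
    """Draw alleles conditional on each haplotype's local-ancestry background.

    ``variant_freqs_by_ancestry`` has shape (n_markers, 2): column 0 is the
    effect-allele frequency on the African background, column 1 on the
    European background. One variant is placed at each marker of ``local``.
    """
    freqs = np.asarray(variant_freqs_by_ancestry, dtype=float)
    if freqs.ndim != 2 or freqs.shape != (local.n_markers, 2):
        raise InputError(
            f"variant_freqs_by_ancestry must have shape ({local.n_markers}, 2)"
        )
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise InputError("allele frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = np.zeros(local.hap0.shape, dtype=np.int8)
    for hap in (local.hap0, local.hap1):
        p = np.where(hap == 1, freqs[:, 0][None, :], freqs[:, 1][None, :])
        dosage += (rng.uniform(size=p.shape) < p).astype(np.int8)
    dosage = dosage.astype(float)
    realized = dosage.mean(axis=0) / 2.0
    variants = _variant_frame(local.markers["chrom"], local.markers["pos"], realized)
    return GenotypeMatrix(local.individual_ids.copy(), variants, dosage)


def simulate_genotypes_hw(n_individuals: int, freqs: np.ndarray, seed: int = 0,
                          chrom: np.ndarray | None = None) -> GenotypeMatrix:
    """Unlinked Hardy-Weinberg genotypes at the given allele frequencies.

    Convenience generator for heritability/GRM experiments where ancestry
    structure is not wanted.
    """
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, freqs[None, :], size=(n_individuals, freqs.size)).astype(float)
    m = freqs.size
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    pos = np.arange(1, m + 1) * 10_000
    variants = _variant_frame(chrom, pos, dosage.mean(axis=0) / 2.0)
    ids = np.array([f"ind{i:06d}" for i in range(n_individuals)])
    return GenotypeMatrix(ids, variants, dosage)


# ---------------------------------------------------------------------------
# copy number


@dataclass
class CopyNumberEffects:
    """Contributions of covariates to the latent log copy number.

    Each blood-count entry is (linear, quadratic) on the raw count scale;
    neutrophils negative and platelets positive are the documented default
    signs. ``noise_sd`` is the residual standard deviation of lrmtCN.
    """

    sex: float = 0.03
    age: float = -0.002
    age2: float = 0.0
    blood: dict = field(default_factory=lambda: {
        "neutrophils": (-0.10, 0.004),
        "lymphocytes": (0.03, 0.0),
        "monocytes": (-0.05, 0.0),
        "eosinophils": (-0.04, 0.0),
        "basophils": (-0.10, 0.0),
        "platelets": (0.0012, -6e-7),
    })
    noise_sd: float = 0.30

    def systematic(self, cohort: pd.DataFrame) -> np.ndarray:
        y = (self.sex * cohort["sex"].to_numpy()
             + self.age * cohort["age"].to_numpy()
             + self.age2 * cohort["age"].to_numpy() ** 2)
        for col, (b1, b2) in self.blood.items():
            if col not in cohort.columns:
                raise ConfigError(f"effect specification names unknown column {col!r}")
            x = cohort[col].to_numpy()
            y = y + b1 * x + b2 * x * x
        return y


def simulate_copy_number(cohort: pd.DataFrame,
                         effects: CopyNumberEffects | None = None,
                         h2_target: float = 0.0,
                         genotypes: GenotypeMatrix | None = None,
                         seed: int = 0,
                         return_components: bool = False):
    """Latent true lrmtCN: covariate effects + optional genetics + noise.

    When ``h2_target`` > 0 a genetic value is built from standardized causal
    dosages with N(0,1) weights and rescaled so its realized variance
    fraction (relative to the non-covariate part genetic + noise) equals
    ``h2_target``; HE regression downstream recovers it.
    The output is centered so mean lrmtCN is 0 (rmtCN ~ 1 on average).
    """
    if not 0.0 <= h2_target < 1.0:
        raise ConfigError(f"h2_target must be in [0, 1), got {h2_target}")
    if h2_target > 0 and genotypes is None:
        raise ConfigError("h2_target > 0 requires genotypes")
    effects = effects or CopyNumberEffects()
    rng = np.random.default_rng(seed)
    n = len(cohort)

    cov_part = effects.systematic(cohort)
    noise = rng.normal(0.0, effects.noise_sd, size=n)
    genetic = np.zeros(n)
    if h2_target > 0:
        X = genotypes.dosages
        f = X.mean(axis=0) / 2.0
        keep = (f > 0) & (f < 1)
        Z = (X[:, keep] - 2 * f[keep]) / np.sqrt(2 * f[keep] * (1 - f[keep]))
        raw = Z @ rng.normal(size=keep.sum())
        target_var = h2_target / (1.0 - h2_target) * effects.noise_sd**2
        genetic = raw * np.sqrt(target_var) / raw.std()

    lrmtcn = cov_part + genetic + noise
    lrmtcn = lrmtcn - lrmtcn.mean()
    if return_components:
        return lrmtcn, {"covariate": cov_part, "genetic": genetic, "noise": noise}
    return lrmtcn


# ---------------------------------------------------------------------------
# sequencing depth


@dataclass
class CoverageConfig:
    """Sequencing-depth law: Poisson per site.

    mtDNA site mean = ``autosomal_mean_depth * exp(true lrmtCN)`` (times
    ``spike_multiplier`` inside ``spike_region``); autosomal site mean =
    ``autosomal_mean_depth``. Defaults emulate off-target exome coverage of
    about 2.8x with the known coverage-spike artifact between rCRS positions
    2,500 and 3,000.
    """

    autosomal_mean_depth: float = 2.8
    spike_region: tuple[int, int] | None = (2500, 3000)
    spike_multiplier: float = 3.0
    n_sites: int = MT_LENGTH

    def validate(self) -> "CoverageConfig":
        if self.autosomal_mean_depth <= 0:
            raise ConfigError("autosomal_mean_depth must be positive")
        if self.spike_multiplier <= 0:
            raise ConfigError("spike_multiplier must be positive")
        return self


def simulate_depth(true_lrmtcn: np.ndarray, coverage: CoverageConfig | None = None,
                   seed: int = 0,
                   individual_ids: np.ndarray | None = None) -> list[DepthProfile]:
    """Per-site Poisson depths for each individual (mtDNA + autosomal)."""
    coverage = (coverage or CoverageConfig()).validate()
    rng = np.random.default_rng(seed)
    true_lrmtcn = np.asarray(true_lrmtcn, dtype=float)
    n = true_lrmtcn.size
    if individual_ids is None:
        individual_ids = np.array([f"ind{i:06d}" for i in range(n)])
    L = coverage.n_sites
    positions = np.arange(1, L + 1)
    spike_scale = np.ones(L)
    if coverage.spike_region is not None:
        lo, hi = coverage.spike_region
        spike_scale[(positions >= lo) & (positions <= hi)] = coverage.spike_multiplier

    profiles = []
    for i in range(n):
        mt_mean = coverage.autosomal_mean_depth * np.exp(true_lrmtcn[i]) * spike_scale
        mt = rng.poisson(mt_mean)
        auto = rng.poisson(coverage.autosomal_mean_depth, size=L)
        profiles.append(DepthProfile(str(individual_ids[i]), mt, auto))
    return profiles


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class TraitSpec:
    """One simulated trait: a phecode-like binary trait or a lab-like
    quantitative trait.

    Effects are on the linear predictor: log-odds (binary) or phenotype-SD
    (quantitative, before scaling by ``noise_sd``). ``beta_interaction``
    multiplies haplogroup-code x ancestry, the mito-nuclear interaction term
    with haplogroup coded -1 (European lineage) / +1 (African lineage).
    """

    name: str
    kind: str = "binary"  # or "quantitative"
    prevalence: float = 0.1
    beta_rlrmtcn: float = 0.0
    beta_ancestry: float = 0.0
    beta_haplogroup: float = 0.0
    beta_interaction: float = 0.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    noise_sd: float = 1.0
    baseline: float = 100.0  # quantitative trait location (raw positive scale)
    cv: float = 0.15         # quantitative coefficient of variation
    p_case_detected: float = 1.0
    singleton_rate: float = 0.05
    measurement_reps_lambda: float = 1.0


def _haplogroup_code(cohort: pd.DataFrame) -> np.ndarray:
    """+1 African lineage, -1 European lineage, 0 other (excluded downstream)."""
    origin = cohort["mt_origin"].to_numpy()
    return np.where(origin == "African", 1.0, np.where(origin == "European", -1.0, 0.0))


def simulate_phenotypes(cohort: pd.DataFrame, rlrmtcn: np.ndarray,
                        specs: list[TraitSpec], seed: int = 0):
    """Draw a phecode occurrence-count matrix and a long-format lab table.

    Binary traits follow the logistic law on the linear predictor; case
    individuals receive >= 2 occurrence records with probability
    ``p_case_detected`` (else 1, i.e. missing under the phecode rule), and a
    configurable fraction of controls are singletons. Quantitative traits are
    positive (log-normal around the linear predictor) with repeated
    measurements for the median-collapsing rule.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    rl = np.asarray(rlrmtcn, dtype=float)
    rl_std = (rl - rl.mean()) / rl.std() if rl.std() > 0 else rl
    z = cohort["african_ancestry"].to_numpy()
    x = _haplogroup_code(cohort)
    sex = cohort["sex"].to_numpy()
    age_std = (cohort["age"] - cohort["age"].mean()).to_numpy() / cohort["age"].std()

    counts = {}
    lab_rows = []
    for spec in specs:
        eta = (spec.beta_rlrmtcn * rl_std + spec.beta_ancestry * z
               + spec.beta_haplogroup * x + spec.beta_interaction * x * z
               + spec.beta_sex * sex + spec.beta_age * age_std)
        if spec.kind == "binary":
            if not 0.0 < spec.prevalence < 1.0:
                raise ConfigError(f"prevalence for {spec.name!r} must be in (0,1)")
            b0 = np.log(spec.prevalence / (1.0 - spec.prevalence))
            pi = 1.0 / (1.0 + np.exp(-(b0 + eta)))
            case = rng.uniform(size=n) < pi
            cnt = np.zeros(n, dtype=int)
            detected = case & (rng.uniform(size=n) < spec.p_case_detected)
            cnt[detected] = 2 + rng.poisson(1.0, size=int(detected.sum()))
            cnt[case & ~detected] = 1
            singles = (~case) & (rng.uniform(size=n) < spec.singleton_rate)
            cnt[singles] = 1
            counts[spec.name] = cnt
        elif spec.kind == "quantitative":
            log_true = np.log(spec.baseline) + spec.cv * (eta + rng.normal(0, spec.noise_sd, n))
            reps = 1 + rng.poisson(spec.measurement_reps_lambda, size=n)
            for i in range(n):
                vals = np.exp(log_true[i] + rng.normal(0, spec.cv * 0.2, size=reps[i]))
                for v in vals:
                    lab_rows.append((cohort["individual_id"].iloc[i], spec.name, v))
        else:
            raise ConfigError(f"unknown trait kind {spec.kind!r} for {spec.name!r}")

    phecodes = pd.DataFrame(counts, index=cohort["individual_id"].to_numpy())
    phecodes.index.name = "individual_id"
    labs = pd.DataFrame(lab_rows, columns=["individual_id", "lab", "value"])
    return phecodes, labs
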