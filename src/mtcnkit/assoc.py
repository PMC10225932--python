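"""Regression-based association scans and related statistics.

Covers the PheWAS/GWAS-style machinery: linear and logistic single-predictor
fits with covariates, Benjamini-Hochberg FDR control, exact binomial
direction-consistency tests, noncentral-chi-square replication power,
Bonferroni thresholds, heritability explained by a set of variants,
polygenic-score computation, distance-based clumping, and cross-cohort
effect-size correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import ConfigError, InputError, check_full_rank

logger = logging.getLogger(__name__)


@dataclass
class AssocRecord:
    predictor_id: str
    trait_id: str
    beta: float
    se: float
    p: float
    n: int
    model: str  # "linear" or "logistic"
    covariate_set: str = ""
    flagged: bool = False  # e.g. perfect separation


def _design(x, covariates, names=None):
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x), x]
    labels = ["intercept", "x"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
        labels.extend(names or [f"cov{i}" for i in range(C.shape[1])])
    return np.column_stack(cols), labels


def fit_assoc(y, x, covariates=None, model: str = "linear",
              predictor_id: str = "x", trait_id: str = "y",
              covariate_set: str = "", min_cases: int = 20) -> AssocRecord:
    """Single-predictor Wald test with optional covariates.

    Linear: OLS. Logistic: maximum likelihood, requiring both classes and at
    least ``min_cases`` cases (mirroring the phecode case filter; pass 0 to
    disable). Rows with missing y/x/covariates are dropped. Perfect
    separation yields a flagged record with p = NaN rather than a spurious
    estimate.
    """
    if model not in ("linear", "logistic"):
        raise InputError(f"model must be 'linear' or 'logistic', got {model!r}")
    y = np.asarray(y, dtype=float)
    X, labels = _design(x, covariates)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    n = int(ok.sum())
    check_full_rank(X, labels)

    if model == "linear":
        res = sm.OLS(y, X).fit()
        return AssocRecord(predictor_id, trait_id, float(res.params[1]),
                           float(res.bse[1]), float(res.pvalues[1]), n,
                           "linear", covariate_set)

    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise InputError("logistic model requires binary y with both classes present")
    n_cases = int((y == 1).sum())
    if n_cases < min_cases:
        raise InputError(
            f"logistic fit refused: {n_cases} cases < minimum {min_cases}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            separated = not res.mle_retvals.get("converged", True)
        except Exception:
            separated = True
            res = None
    if separated or res is None or not np.isfinite(res.bse[1]) or res.bse[1] > 1e3:
        logger.warning("possible separation for trait %s; p set to NaN", trait_id)
        return AssocRecord(predictor_id, trait_id, np.nan, np.nan, np.nan, n,
                           "logistic", covariate_set, flagged=True)
    return AssocRecord(predictor_id, trait_id, float(res.params[1]),
                       float(res.bse[1]), float(res.pvalues[1]), n,
                       "logistic", covariate_set)


def run_phewas(rlrmtcn: np.ndarray, status: pd.DataFrame | None = None,
               labs: pd.DataFrame | None = None, covariates=None,
               cohort_label: str = "all", min_cases: int = 20,
               fdr_levels=(0.005, 0.05)) -> pd.DataFrame:
    """Scan copy number against a phenome: logistic per phecode status column
    (case=1/control=0/missing=NaN), linear per quantitative lab column.

    Returns one row per trait with BH discovery flags at each FDR level
    (computed jointly across all traits in the scan, per cohort).
    """
    if (status is None or status.shape[1] == 0) and (labs is None or labs.shape[1] == 0):
        raise ConfigError("empty phenotype set")
    x = np.asarray(rlrmtcn, dtype=float)
    rows = []
    if status is not None:
        for code in status.columns:
            rec = fit_assoc(status[code].to_numpy(dtype=float), x, covariates,
                            model="logistic", predictor_id="rlrmtcn",
                            trait_id=str(code), min_cases=min_cases)
            rows.append(rec)
    if labs is not None:
        for lab in labs.columns:
            rec = fit_assoc(labs[lab].to_numpy(dtype=float), x, covariates,
                            model="linear", predictor_id="rlrmtcn",
                            trait_id=str(lab))
            rows.append(rec)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["cohort"] = cohort_label
    for q in fdr_levels:
        out[f"fdr_{q}"] = bh_fdr(out["p"].to_numpy(), q)
    return out


def bh_fdr(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at level q.

    NaN p-values (flagged fits) are never discoveries and do not enter the
    step-up ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    flags = np.zeros(p.size, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return flags
    flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def sign_consistency_test(k_same_direction: int, n_total: int) -> float:
    """Exact two-sided binomial test of direction consistency at null p=0.5.

    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed count (the "minlike" convention).
    """
    if not (0 <= k_same_direction <= n_total) or n_total < 1:
        raise InputError("require 0 <= k <= n and n >= 1")
    return float(stats.binomtest(k_same_direction, n_total, 0.5).pvalue)


@dataclass
class ReplicationPowerInput:
    """Inputs for noncentral-chi-square replication power of a GWAS variant."""

    beta_gwas: float
    f: float          # effect-allele frequency
    n: int            # replication sample size
    sigma: float = 0.8  # residual phenotype SD after covariate adjustment
    alpha: float = 4.5e-4

    def validate(self):
        if not 0.0 < self.f < 1.0:
            raise InputError(f"allele frequency must be in (0,1), got {self.f}")
        if self.sigma <= 0:
            raise InputError("sigma must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0,1)")
        return self


def replication_power(inp: ReplicationPowerInput) -> float:
    """Power to replicate a known additive association.

    SE = sigma / sqrt(2 n f (1-f)) (Hardy-Weinberg variance of a 0/1/2
    dosage), noncentrality lambda = (beta/SE)^2, and power is the survival
    probability of the noncentral chi-square(1, lambda) beyond the central
    chi-square quantile at 1 - alpha.
    """
    inp.validate()
    se = inp.sigma / np.sqrt(2.0 * inp.n * inp.f * (1.0 - inp.f))
    ncp = (inp.beta_gwas / se) ** 2
    crit = stats.chi2.ppf(1.0 - inp.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else inp.alpha


def bonferroni_threshold(n_tests: int, alpha: float = 0.05,
                         sig_digits: int | None = None) -> float:
    """alpha / n_tests; optionally rounded to 2-3 significant digits for
    reporting."""
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    t = alpha / n_tests
    if sig_digits is not None:
        t = float(f"{t:.{sig_digits - 1}e}")
    return t


def h2_explained(betas: np.ndarray, freqs: np.ndarray) -> float:
    """Variance fraction explained by variants on a unit-variance phenotype:
    2 * sum(beta_i^2 * f_i * (1 - f_i))."""
    betas = np.asarray(betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if betas.shape != freqs.shape:
        raise InputError("betas and freqs must have equal length")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise InputError("frequencies must be in (0,1)")
    return float(2.0 * np.sum(betas**2 * freqs * (1.0 - freqs)))


# ---------------------------------------------------------------------------
# polygenic scores


def prs_score(genotypes, weights: pd.DataFrame,
              average: bool = False) -> np.ndarray:
    """Polygenic score: weighted sum of effect-allele dosages.

    ``weights`` columns: variant_id, effect_allele, weight. Variants are
    matched by id; a weight whose effect allele is the genotype record's
    *other* allele contributes via the complemented dosage (2 - d), i.e. the
    score is invariant to ref/alt label flips. Unmatched or allele-mismatched
    weights are dropped with a logged count. ``average=True`` divides by the
    number of matched alleles (2 x matched variants), the per-allele-mean
    convention of some scoring tools.
    """
    req = {"variant_id", "effect_allele", "weight"}
    if not req.issubset(weights.columns):
        raise InputError(f"weights table needs columns {sorted(req)}")
    if weights["variant_id"].duplicated().any():
        raise InputError("each variant may appear once in the weights table")
    meta = genotypes.variants.set_index("variant_id")
    scores = np.zeros(genotypes.n_individuals)
    matched = 0
    col_of = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    for _, w in weights.iterrows():
        vid = w["variant_id"]
        if vid not in col_of:
            continue
        rec = meta.loc[vid]
        d = genotypes.dosages[:, col_of[vid]]
        if w["effect_allele"] == rec["alt"]:
            scores += w["weight"] * d
        elif w["effect_allele"] == rec["ref"]:
            scores += w["weight"] * (2.0 - d)
        else:
            continue
        matched += 1
    dropped = len(weights) - matched
    if dropped:
        logger.info("prs_score: dropped %d unmatched weights", dropped)
    if matched == 0:
        raise InputError("no weight variants matched the genotypes")
    if average:
        scores = scores / (2.0 * matched)
    return scores


def clump_hits(records: pd.DataFrame, p_thresh: float = 0.05,
               window: float = 1_000_000.0) -> pd.DataFrame:
    """Greedy distance-based clumping: repeatedly emit the smallest-p record
    below threshold and drop records within ``window`` bp on its chromosome.
    Ties in p are broken by lowest position."""
    req = {"chrom", "pos", "p"}
    if not req.issubset(records.columns):
        raise InputError(f"records need columns {sorted(req)}")
    df = records[records["p"] < p_thresh].sort_values(
        ["p", "pos"], kind="stable").reset_index(drop=True)
    kept = []
    alive = np.ones(len(df), dtype=bool)
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        same = (df["chrom"] == df.loc[i, "chrom"]) & \
               (np.abs(df["pos"] - df.loc[i, "pos"]) <= window)
        alive &= ~same.to_numpy()
        alive[i] = False
    return df.loc[kept].reset_index(drop=True)


def effect_correlation(records_a: pd.DataFrame, records_b: pd.DataFrame):
    """Pearson correlation (and regression slope b-on-a) of matched effect
    sizes across two sets of association records.

    Records are matched on predictor_id; if both tables carry an
    ``effect_allele`` column, discordant rows have beta_b negated (allele
    harmonization) before comparison.
    """
    m = records_a.merge(records_b, on="predictor_id", suffixes=("_a", "_b"))
    if len(m) < 3:
        raise InputError("need at least 3 matched predictors")
    beta_b = m["beta_b"].to_numpy(dtype=float).copy()
    if "effect_allele_a" in m.columns and "effect_allele_b" in m.columns:
        flip = m["effect_allele_a"] != m["effect_allele_b"]
        beta_b[flip.to_numpy()] *= -1.0
    beta_a = m["beta_a"].to_numpy(dtype=float)
    r = float(np.corrcoef(beta_a, beta_b)[0, 1])
    slope = float(np.polyfit(beta_a, beta_b, 1)[0])
    return r, slope
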