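"""Mito-nuclear incompatibility tests and power simulations.

In an admixed cohort, each individual carries a nuclear genome that is a
mosaic of African and European ancestry (fraction z in [0,1]) and an mtDNA
haplogroup of a single maternal lineage (coded x = +1 African, -1 European).
A mito-nuclear incompatibility — a deleterious mismatch between the two
genomes — would show up as an x-by-z interaction on a phenotype.

An older test statistic, "discordance" (the fraction of nuclear ancestry
whose continental origin differs from the mtDNA lineage), is confounded: when
haplogroups are imbalanced in the sample (say 80% African lineages),
discordance is essentially a relabeling of nuclear ancestry itself for the
majority class, so any main effect of ancestry masquerades as an
incompatibility signal. The artifact demonstration here makes that concrete,
and the interaction test is the correct replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ConfigError, InputError, ols_fit
from .assoc import AssocRecord, bh_fdr

EUROPEAN_TOP_LEVELS = frozenset("HIJKNRTUVWX")

#: default per-test significance level of the interaction power simulations
POWER_ALPHA = 3.5e-5


def classify_origin(haplogroup: str) -> str:
    """Top-level haplogroup letter -> continental lineage class.

    L* is African; H, I, J, K, N, R, T, U, V, W, X are European; anything
    else is "other" and excluded from mito-nuclear analyses.
    """
    if not haplogroup:
        raise InputError("empty haplogroup label")
    top = haplogroup[0].upper()
    if top == "L":
        return "African"
    if top in EUROPEAN_TOP_LEVELS:
        return "European"
    return "other"


def discordance(ancestry_fractions: dict, mt_origin: str) -> float:
    """Fraction of nuclear ancestry discordant with the mtDNA lineage.

    ``ancestry_fractions`` maps continent labels (e.g. "African",
    "European", "NativeAmerican") to nonnegative fractions; the discordance
    is the sum over continents other than the mtDNA origin's.
    """
    if mt_origin not in ("African", "European"):
        raise InputError(f"mt_origin must be African or European, got {mt_origin!r}")
    if any(v < 0 for v in ancestry_fractions.values()):
        raise InputError("ancestry fractions must be nonnegative")
    return float(sum(v for k, v in ancestry_fractions.items() if k != mt_origin))


def haplogroup_code(mt_origin) -> np.ndarray:
    """+1 for African lineage, -1 for European; raises on 'other' entries."""
    origin = np.asarray(mt_origin, dtype=object)
    if np.any(~np.isin(origin, ("African", "European"))):
        raise InputError("remove 'other' haplogroups before coding")
    return np.where(origin == "African", 1.0, -1.0)


def interaction_test(y: np.ndarray, z: np.ndarray, x: np.ndarray,
                     covariates=None, model: str = "linear") -> dict:
    """Joint fit of y on nuclear ancestry z, haplogroup x and their product.

    x is coded -1/+1 with the African lineage as the reference (+1) in
    reporting; sex/age/age^2 (or any covariates) enter as nuisance columns.
    Returns AssocRecords keyed "z", "x", "z_x" with Wald two-sided p-values.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise InputError("both haplogroup classes must be present")
    terms = np.column_stack([z, x, z * x])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(len(z)), terms, C])
    else:
        X = np.column_stack([np.ones(len(z)), terms])
    y = np.asarray(y, dtype=float)
    out = {}
    names = ["z", "x", "z_x"]
    if model == "linear":
        beta, se, _, pv, _, _ = ols_fit(X, y)
        for i, nm in enumerate(names, start=1):
            out[nm] = AssocRecord(nm, "y", float(beta[i]), float(se[i]),
                                  float(pv[i]), len(y), "linear")
    elif model == "logistic":
        import statsmodels.api as sm
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        for i, nm in enumerate(names, start=1):
            out[nm] = AssocRecord(nm, "y", float(res.params[i]), float(res.bse[i]),
                                  float(res.pvalues[i]), len(y), "logistic")
    else:
        raise InputError(f"model must be 'linear' or 'logistic', got {model!r}")
    return out


# ---------------------------------------------------------------------------
# cohort draws for the simulations


def _beta_ab(mean: float, sd: float) -> tuple[float, float]:
    v = sd * sd
    c = mean * (1 - mean) / v - 1.0
    return mean * c, (1 - mean) * c


def _draw_cohort(n: int, haplogroup_freq: float, ancestry_beta: tuple[float, float],
                 rng: np.random.Generator):
    """(z, x, sex, age) draws for the power/artifact simulations; haplogroup
    independent of z (the procedure's stated null coupling)."""
    a, b = _beta_ab(*ancestry_beta)
    z = rng.beta(a, b, size=n)
    x = np.where(rng.uniform(size=n) < haplogroup_freq, 1.0, -1.0)
    sex = (rng.uniform(size=n) < 0.45).astype(float)
    age = np.clip(rng.normal(55.0, 15.0, size=n), 18.0, None)
    return z, x, sex, age


@dataclass
class PowerCurve:
    effects: np.ndarray       # beta grid (SD units) or odds ratios
    power: np.ndarray
    mc_se: np.ndarray
    alpha: float
    reps: int
    n: int
    trait_type: str           # "quantitative" or "binary"
    analytic: np.ndarray | None = None  # noncentral-chi-square oracle, if computed

    def to_frame(self) -> pd.DataFrame:
        d = {"effect": self.effects, "power": self.power, "mc_se": self.mc_se}
        if self.analytic is not None:
            d["analytic_power"] = self.analytic
        return pd.DataFrame(d)


def power_quantitative(n: int, effect_grid, sigma: float = 0.8,
                       alpha: float = POWER_ALPHA, reps: int = 1000,
                       haplogroup_freq: float = 0.8,
                       ancestry_beta: tuple[float, float] = (0.8, 0.1),
                       seed: int = 0, analytic: bool = True) -> PowerCurve:
    """Monte-Carlo power of the interaction test for a quantitative trait.

    Per replicate: draw a fresh cohort, simulate
    y = covariate terms + beta1 * x * z + N(0, sigma) — the effect of
    ancestry reversed in direction between the two haplogroups, in units of
    phenotype SD — fit the linear interaction model, and count rejections of
    the interaction term at ``alpha``. When ``analytic`` is set, the
    noncentral-chi-square power implied by each realized design's
    interaction-column partial variance is averaged alongside.
    """
    effect_grid = np.sort(np.asarray(effect_grid, dtype=float))
    if np.any(effect_grid < 0):
        raise ConfigError("effect grid must be nonnegative")
    if reps < 100:
        raise ConfigError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    b_sex, b_age, b_age2 = 0.1, 0.01, -1e-4  # nuisance effects, SD units
    power = np.empty(effect_grid.size)
    mc_se = np.empty(effect_grid.size)
    analytic_power = np.empty(effect_grid.size) if analytic else None
    crit_chi2 = stats.chi2.ppf(1.0 - alpha, df=1)
    for gi, b1 in enumerate(effect_grid):
        rej = 0
        an_sum = 0.0
        for _ in range(reps):
            z, x, sex, age = _draw_cohort(n, haplogroup_freq, ancestry_beta, rng)
            X = np.column_stack([np.ones(n), z, x, z * x, sex, age, age**2])
            eta = b_sex * sex + b_age * age + b_age2 * age**2 + b1 * x * z
            y = eta + rng.normal(0.0, sigma, size=n)
            _, _, t, pv, _, _ = ols_fit(X, y)
            if pv[3] < alpha:
                rej += 1
            if analytic:
                # partial variance of the interaction column given the rest
                others = np.delete(X, 3, axis=1)
                w = X[:, 3]
                bhat, *_ = np.linalg.lstsq(others, w, rcond=None)
                r = w - others @ bhat
                ncp = (b1**2) * (r @ r) / sigma**2
                an_sum += stats.ncx2.sf(crit_chi2, df=1, nc=ncp) if ncp > 0 else alpha
        p_hat = rej / reps
        power[gi] = p_hat
        mc_se[gi] = np.sqrt(p_hat * (1 - p_hat) / reps)
        if analytic:
            analytic_power[gi] = an_sum / reps
    return PowerCurve(effect_grid, power, mc_se, alpha, reps, n, "quantitative",
                      analytic_power)


def power_binary(n: int, or_grid, alpha: float = POWER_ALPHA, reps: int = 1000,
                 prevalence: float | None = None,
                 prevalence_model: tuple[float, float, float, float] | None = None,
                 haplogroup_freq: float = 0.8,
                 ancestry_beta: tuple[float, float] = (0.8, 0.1),
                 seed: int = 0, max_redraws: int = 20) -> PowerCurve:
    """Monte-Carlo power of the logistic interaction test for a binary trait.

    The intercept is built either from a target ``prevalence`` (logit) or
    from fitted coefficients (beta_intercept, beta_sex, beta_age, beta_age2)
    evaluated at the covariate means:
    beta0 = b_int + b_sex*mean(sex) + b_age*mean(age) + b_age2*mean(age^2).
    Case status is Bernoulli with pi = expit(beta0 + beta1 * x * z), with
    beta1 = log(OR). Replicates where a draw is all-case or all-control are
    redrawn (count tracked).
    """
    or_grid = np.sort(np.asarray(or_grid, dtype=float))
    if np.any(or_grid <= 1.0):
        raise ConfigError("odds-ratio grid must be > 1")
    if prevalence is None and prevalence_model is None:
        raise ConfigError("supply prevalence or prevalence_model")
    import statsmodels.api as sm
    rng = np.random.default_rng(seed)
    power = np.empty(or_grid.size)
    mc_se = np.empty(or_grid.size)
    redraws = 0
    for gi, orr in enumerate(or_grid):
        b1 = np.log(orr)
        rej = 0
        for _ in range(reps):
            for _try in range(max_redraws):
                z, x, sex, age = _draw_cohort(n, haplogroup_freq, ancestry_beta, rng)
                if prevalence_model is not None:
                    b_int, b_sex, b_age, b_age2 = prevalence_model
                    b0 = b_int + b_sex * sex.mean() + b_age * age.mean() + b_age2 * (age**2).mean()
                else:
                    b0 = np.log(prevalence / (1.0 - prevalence))
                pi = 1.0 / (1.0 + np.exp(-(b0 + b1 * x * z)))
                y = (rng.uniform(size=n) < pi).astype(float)
                if 0 < y.sum() < n:
                    break
                redraws += 1
            X = np.column_stack([np.ones(n), z, x, z * x, sex, age, age**2])
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if res.pvalues[3] < alpha and np.isfinite(res.bse[3]):
                    rej += 1
            except Exception:
                pass  # non-convergence counts as a non-rejection
        p_hat = rej / reps
        power[gi] = p_hat
        mc_se[gi] = np.sqrt(p_hat * (1 - p_hat) / reps)
    curve = PowerCurve(or_grid, power, mc_se, alpha, reps, n, "binary")
    curve.redraws = redraws
    return curve


def discordance_artifact_demo(n: int = 8311, haplogroup_freq: float = 0.8,
                              ancestry_beta: tuple[float, float] = (0.8, 0.1),
                              beta_ancestry: float = 1.0, alpha: float = 0.05,
                              reps: int = 500, seed: int = 0) -> dict:
    """Show that the discordance statistic manufactures incompatibility
    signal from a pure nuclear-ancestry effect.

    Simulates y with an ancestry main effect and *zero* interaction, then
    compares rejection rates at ``alpha`` of (a) the regression of y on
    discordance and (b) the interaction test. With imbalanced haplogroups
    (a) rejects far above alpha while (b) stays at alpha.
    """
    rng = np.random.default_rng(seed)
    rej_disc = 0
    rej_int = 0
    for _ in range(reps):
        z, x, sex, age = _draw_cohort(n, haplogroup_freq, ancestry_beta, rng)
        y = beta_ancestry * z + rng.normal(0.0, 1.0, size=n)
        # discordance: African-lineage carriers -> 1 - z, European -> z
        d = np.where(x > 0, 1.0 - z, z)
        Xd = np.column_stack([np.ones(n), d, sex, age, age**2])
        _, _, _, pv_d, _, _ = ols_fit(Xd, y)
        if pv_d[1] < alpha:
            rej_disc += 1
        Xi = np.column_stack([np.ones(n), z, x, z * x, sex, age, age**2])
        _, _, _, pv_i, _, _ = ols_fit(Xi, y)
        if pv_i[3] < alpha:
            rej_int += 1
    return {
        "n": n, "reps": reps, "alpha": alpha,
        "haplogroup_freq": haplogroup_freq, "beta_ancestry": beta_ancestry,
        "discordance_rejection_rate": rej_disc / reps,
        "interaction_rejection_rate": rej_int / reps,
    }


def run_mitonuclear_phewas(status: pd.DataFrame | None, labs: pd.DataFrame | None,
                           z: np.ndarray, x: np.ndarray, covariates=None,
                           min_cases: int = 20,
                           fdr_levels=(0.005, 0.05)) -> pd.DataFrame:
    """Phenome-wide z / x / z-by-x scan with BH control per term family.

    Each phenotype gets the joint interaction model (logistic for phecode
    status columns, linear for lab columns); BH flags are computed separately
    within the z family, the x family and the interaction family, at 0.005
    and 0.05.
    """
    frames = []

    def one(y, trait, model):
        try:
            if model == "logistic" and (np.nansum(y == 1.0) < min_cases):
                return
            ok = np.isfinite(y)
            recs = interaction_test(y[ok], z[ok], x[ok],
                                    covariates=None if covariates is None
                                    else np.asarray(covariates)[ok],
                                    model=model)
        except Exception:
            return
        for term, rec in recs.items():
            frames.append({"trait": trait, "term": term, "beta": rec.beta,
                           "se": rec.se, "p": rec.p, "n": rec.n, "model": model})

    if status is not None:
        for code in status.columns:
            one(status[code].to_numpy(dtype=float), str(code), "logistic")
    if labs is not None:
        for lab in labs.columns:
            one(labs[lab].to_numpy(dtype=float), str(lab), "linear")
    out = pd.DataFrame(frames)
    if out.empty:
        return out
    for q in fdr_levels:
        col = np.zeros(len(out), dtype=bool)
        for term in out["term"].unique():
            m = (out["term"] == term).to_numpy()
            col[m] = bh_fdr(out.loc[m, "p"].to_numpy(), q)
        out[f"fdr_{q}"] = col
    return out
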