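"""Admixture mapping and the empirical multiple-testing burden.

In an admixed cohort, local ancestry is correlated over long genomic
distances (tracts), so per-marker ancestry-association tests are far from
independent. The effective number of tests N_eff is estimated empirically:
for each individual and chromosome, the ordered local-ancestry series is
treated as a stationary process, its effective sample size is computed from
an autoregressive fit's spectral density at frequency zero, summed over
chromosomes per individual, and averaged over individuals. The genome-wide
significance threshold is then 0.05 / N_eff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import InputError, ols_fit
from .simulate import LocalAncestryMatrix


def global_ancestry(local: LocalAncestryMatrix, posterior_min: float = 0.9) -> np.ndarray:
    """Per-individual African-ancestry fraction: mean of count/2 over markers
    called with posterior probability above ``posterior_min``."""
    qual = local.posterior > posterior_min
    n_qual = qual.sum(axis=1)
    if np.any(n_qual == 0):
        bad = local.individual_ids[n_qual == 0]
        raise InputError(f"no markers above posterior {posterior_min} for: {list(bad)}")
    frac = np.where(qual, local.counts / 2.0, 0.0).sum(axis=1) / n_qual
    return frac


def local_ancestry_assoc(rlrmtcn: np.ndarray, local: LocalAncestryMatrix,
                         global_fraction: np.ndarray | None = None,
                         duffy: np.ndarray | None = None,
                         posterior_min: float = 0.9) -> pd.DataFrame:
    """Per-marker linear scan of the phenotype on local African-allele count,
    with global ancestry (and optionally Duffy-null genotype, coded additive
    + heterozygote indicator) as covariates.

    Markers with monomorphic local ancestry are flagged with p = NaN. Markers
    are tested on the individuals whose call passes the posterior cutoff.
    """
    y = np.asarray(rlrmtcn, dtype=float)
    if global_fraction is None:
        global_fraction = global_ancestry(local, posterior_min)
    covs = [np.ones(local.n_individuals), np.asarray(global_fraction, dtype=float)]
    if duffy is not None:
        duffy = np.asarray(duffy, dtype=float)
        covs.append(duffy)
        covs.append((duffy == 1).astype(float))
    C = np.column_stack(covs)
    counts = local.counts
    rows = []
    for j in range(local.n_markers):
        ok = local.posterior[:, j] > posterior_min
        g = counts[ok, j].astype(float)
        marker = f"{local.markers['chrom'].iloc[j]}:{local.markers['pos'].iloc[j]}"
        if g.min() == g.max():
            rows.append({"predictor_id": marker, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "n": int(ok.sum()), "flagged": True})
            continue
        X = np.column_stack([C[ok], g])
        try:
            beta, se, _, pv, _, _ = ols_fit(X, y[ok])
        except np.linalg.LinAlgError:
            # e.g. global fraction collinear with the intercept
            rows.append({"predictor_id": marker, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "n": int(ok.sum()), "flagged": True})
            continue
        rows.append({"predictor_id": marker, "beta": beta[-1], "se": se[-1],
                     "p": pv[-1], "n": int(ok.sum()), "flagged": False})
    out = pd.DataFrame(rows)
    out["chrom"] = local.markers["chrom"].to_numpy()
    out["pos"] = local.markers["pos"].to_numpy()
    return out


def _ar_yule_walker(x: np.ndarray, order: int):
    """Yule-Walker AR coefficients and innovation variance via
    Levinson-Durbin; returns (phi, sigma2) with the biased autocovariance
    convention (as R's ar.yw)."""
    n = x.size
    xc = x - x.mean()
    acov = np.array([xc[: n - k] @ xc[k:] for k in range(order + 1)]) / n
    sigma2 = acov[0]
    phi = np.zeros(order)
    if order == 0:
        return phi, sigma2
    phi_prev = np.zeros(order)
    for k in range(1, order + 1):
        num = acov[k] - phi_prev[: k - 1] @ acov[1:k][::-1]
        rho_k = num / sigma2
        phi[:k] = np.concatenate([phi_prev[: k - 1] - rho_k * phi_prev[: k - 1][::-1],
                                  [rho_k]])
        sigma2 = sigma2 * (1.0 - rho_k**2)
        phi_prev[:k] = phi[:k]
    return phi, sigma2


def effective_sample_size(series: np.ndarray, max_order: int | None = None) -> float:
    """Effective sample size of an ordered, autocorrelated series.

    Fits an autoregressive model (Yule-Walker, AIC order selection up to
    ~10*log10(N)) and evaluates the spectral density at frequency zero,
    s(0) = sigma^2 / (1 - sum phi)^2; then ESS = N * var(series) / s(0).
    A constant series has ESS = 1: it is the limit of perfect
    autocorrelation (one effective observation), which keeps ESS monotone
    in tract length down to the no-recombination case.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise InputError(f"series too short for an AR fit ({n} < 10)")
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")
    v = x.var()
    if v == 0:
        return 1.0
    if max_order is None:
        max_order = int(min(n - 1, np.floor(10.0 * np.log10(n))))
    best_aic, best = np.inf, (np.zeros(0), v)
    for order in range(max_order + 1):
        phi, sigma2 = _ar_yule_walker(x, order)
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * order
        if aic < best_aic:
            best_aic, best = aic, (phi, sigma2)
    phi, sigma2 = best
    spec0 = sigma2 / (1.0 - phi.sum()) ** 2
    ess = n * v / spec0
    return float(min(ess, n)) if ess > 0 else float(n)


def effective_tests(local: LocalAncestryMatrix, posterior_min: float = 0.9,
                    alpha: float = 0.05) -> dict:
    """Admixture-mapping multiple-testing burden.

    For each individual and chromosome the diploid ancestry fraction
    (count/2) series in map order (markers passing the posterior cutoff)
    gets an AR-spectral effective sample size; per-individual genome sums are
    averaged into N_eff, and the derived threshold is ``alpha`` / N_eff.
    """
    counts = local.counts / 2.0
    chroms = local.markers["chrom"].to_numpy()
    per_chrom_cols = {c: np.where(chroms == c)[0] for c in np.unique(chroms)}
    n = local.n_individuals
    per_ind = np.zeros(n)
    per_ind_chrom = {}
    for c, cols in per_chrom_cols.items():
        ess_c = np.empty(n)
        for i in range(n):
            ok = local.posterior[i, cols] > posterior_min
            series = counts[i, cols[ok]]
            ess_c[i] = effective_sample_size(series)
        per_ind_chrom[c] = ess_c
        per_ind += ess_c
    n_eff = float(per_ind.mean())
    return {
        "n_eff": n_eff,
        "threshold": alpha / n_eff,
        "per_individual": per_ind,
        "per_chromosome": per_ind_chrom,
    }
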