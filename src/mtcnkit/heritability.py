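"""Desk-scale SNP-heritability machinery.

GRM construction from standardized dosages, Haseman-Elston (HE) regression
as the primary estimator (closed form: regress phenotype cross-products on
off-diagonal relatedness; slope = h_g^2), average-information REML on one or
more variance components as the secondary estimator, per-chromosome
partitioning, and covariate-attenuation experiments (re-estimating h_g^2
after adding candidate fixed effects, to ask whether specific loci or scores
carry the heritability).

All estimators residualize the phenotype on the fixed covariates and scale
it to unit variance first, so h^2 is a fraction of the residual phenotypic
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import InputError

logger = logging.getLogger(__name__)


@dataclass
class GRMMatrix:
    values: np.ndarray          # n x n symmetric
    m: int                      # markers used
    freqs: np.ndarray           # per-variant effect-allele frequencies
    individual_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class H2Estimate:
    h2: float
    se: float
    ci95: tuple[float, float]
    method: str                 # "HE" or "REML"
    covariate_set: str = ""
    components: dict | None = None  # per-component h2 for multi-GRM REML


def build_grm(genotypes, maf_min: float = 0.01) -> GRMMatrix:
    """GRM entry (j,k) = (1/m) sum_i (x_ij - 2f_i)(x_ik - 2f_i) / (2 f_i (1-f_i)).

    Frequencies are computed in-sample; variants with MAF below ``maf_min``
    (including monomorphic ones) are excluded with a logged count.
    """
    X = genotypes.dosages
    f = X.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = maf > maf_min
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_grm: excluded %d variants below MAF %g", dropped, maf_min)
    if keep.sum() == 0:
        raise InputError("no variants left after the MAF filter")
    f = f[keep]
    Z = (X[:, keep] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    m = int(keep.sum())
    A = (Z @ Z.T) / m
    return GRMMatrix(A, m, f, getattr(genotypes, "individual_ids", None))


def _residualize_scale(y: np.ndarray, covariates) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(len(y)), C])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    else:
        y = y - y.mean()
    sd = y.std()
    if sd == 0:
        raise InputError("phenotype has zero variance after residualization")
    return y / sd


def estimate_h2_he(y: np.ndarray, grm: GRMMatrix, covariates=None,
                   n_blocks: int = 50, covariate_set: str = "") -> H2Estimate:
    """Haseman-Elston regression of phenotype cross-products on relatedness.

    After residualizing/standardizing y, regress y_j*y_k on the off-diagonal
    GRM entries A_jk; the slope estimates h_g^2. The standard error comes
    from a block jackknife over individuals (default 50 blocks), which
    respects the dependence among pairs sharing an individual.
    """
    n = grm.n
    if len(y) != n:
        raise InputError("phenotype length does not match the GRM")
    if n < 100:
        logger.warning("estimate_h2_he: n=%d < 100, estimate will be unstable", n)
    yy = _residualize_scale(y, covariates)
    iu, ju = np.triu_indices(n, k=1)
    a = grm.values[iu, ju]
    if np.allclose(a.var(), 0):
        raise InputError("degenerate GRM: off-diagonal entries have zero variance")
    prod = yy[iu] * yy[ju]

    def slope(mask_pairs: np.ndarray) -> float:
        av, pv = a[mask_pairs], prod[mask_pairs]
        am, pm = av.mean(), pv.mean()
        return float(((av - am) @ (pv - pm)) / ((av - am) @ (av - am)))

    full = slope(np.ones(a.size, dtype=bool))
    blocks = np.array_split(np.arange(n), n_blocks)
    theta = []
    for blk in blocks:
        in_blk = np.zeros(n, dtype=bool)
        in_blk[blk] = True
        keep = ~(in_blk[iu] | in_blk[ju])
        theta.append(slope(keep))
    theta = np.array(theta)
    g = len(blocks)
    se = float(np.sqrt((g - 1) / g * np.sum((theta - theta.mean()) ** 2)))
    ci = (full - 1.96 * se, full + 1.96 * se)
    return H2Estimate(full, se, ci, "HE", covariate_set)


# ---------------------------------------------------------------------------
# AI-REML


def estimate_h2_reml(y: np.ndarray, grms, covariates=None, max_iter: int = 100,
                     tol: float = 1e-6, covariate_set: str = "") -> H2Estimate:
    """Average-information REML for one or more variance components.

    Model: y = Xb + sum_k g_k + e with g_k ~ N(0, sigma_k^2 A_k). The first
    iteration uses an EM step for stability, then AI updates; components are
    projected back to a small positive floor when they go negative. Reports
    h_k^2 = sigma_k^2 / total variance per component plus their sum; the SE
    of the summed h^2 comes from the inverse AI matrix by the delta method.
    """
    if isinstance(grms, GRMMatrix):
        grms = [grms]
    K = len(grms)
    if K > 25:
        raise InputError("at most 25 variance components are supported")
    n = grms[0].n
    if n < 200:
        logger.warning("estimate_h2_reml: n=%d < 200, estimate will be unstable", n)
    yv = np.asarray(y, dtype=float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    else:
        X = np.ones((n, 1))
    A = [g.values for g in grms]
    vp = yv.var()
    sig = np.full(K + 1, vp / (K + 1))  # components..., residual last
    floor = 1e-6 * vp

    trace = []
    for it in range(max_iter):
        V = sig[K] * np.eye(n)
        for k in range(K):
            V += sig[k] * A[k]
        Vinv = np.linalg.inv(V)
        VinvX = Vinv @ X
        XtVinvX_inv = np.linalg.inv(X.T @ VinvX)
        P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
        Py = P @ yv
        # score vector and average-information matrix
        PA = [P @ A[k] for k in range(K)] + [P]
        score = np.empty(K + 1)
        AI = np.empty((K + 1, K + 1))
        APy = [A[k] @ Py for k in range(K)] + [Py]
        for k in range(K + 1):
            score[k] = -0.5 * (np.trace(PA[k]) - Py @ APy[k])
        for k in range(K + 1):
            PAk_Py = P @ APy[k]
            for l in range(k, K + 1):
                AI[k, l] = AI[l, k] = 0.5 * (APy[l] @ PAk_Py)
        if it == 0:  # EM step: robust far from the optimum
            new = np.array([
                sig[k] + sig[k]**2 / n * (Py @ APy[k] - np.trace(PA[k]))
                for k in range(K + 1)
            ])
        else:
            try:
                new = sig + np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                new = sig + score * 1e-4
        new = np.maximum(new, floor)
        delta = np.max(np.abs(new - sig)) / vp
        trace.append((it, *new))
        sig = new
        if delta < tol:
            break
    else:
        raise InputError(f"REML did not converge in {max_iter} iterations; trace: {trace[-5:]}")

    total = sig.sum()
    h2_parts = {f"component_{k}": float(sig[k] / total) for k in range(K)}
    h2 = float(sig[:K].sum() / total)
    # delta-method SE of h2 = s_g / (s_g + s_e) from the AI covariance
    try:
        cov = np.linalg.inv(AI)
        grad = np.empty(K + 1)
        sg = sig[:K].sum()
        grad[:K] = (total - sg) / total**2
        grad[K] = -sg / total**2
        se = float(np.sqrt(grad @ cov @ grad))
    except np.linalg.LinAlgError:
        se = np.nan
    ci = (h2 - 1.96 * se, h2 + 1.96 * se)
    return H2Estimate(h2, se, ci, "REML", covariate_set,
                      components=h2_parts if K > 1 else None)


def covariate_attenuation(y: np.ndarray, grm: GRMMatrix,
                          covariate_sets: list[tuple[str, np.ndarray | None]],
                          method: str = "HE") -> pd.DataFrame:
    """h_g^2 under an ordered list of labeled fixed-effect designs.

    Shares the GRM across fits; reports each estimate and its delta against
    the first set. Adding fixed effects that tag the causal variants should
    pull h^2 toward zero; adding effects orthogonal to the genetic value
    should leave it unchanged.
    """
    est = estimate_h2_he if method == "HE" else estimate_h2_reml
    rows = []
    base = None
    for label, cov in covariate_sets:
        e = est(y, grm, covariates=cov, covariate_set=label)
        if base is None:
            base = e.h2
        rows.append({"covariate_set": label, "h2": e.h2, "se": e.se,
                     "ci_low": e.ci95[0], "ci_high": e.ci95[1],
                     "delta_vs_first": e.h2 - base, "method": e.method})
    return pd.DataFrame(rows)
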