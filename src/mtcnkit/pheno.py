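"""Phenotype preparation: phecode case/control matrices and lab transforms.

Phecode (billing-code-derived) occurrence counts become case/control status
by the standard rule: an individual is a case for a phecode if it was
recorded at least twice, a control if never, and missing if exactly once
(a single mention is considered too unreliable to call either way).
Phecodes are analyzed only if they have strictly more than ``min_cases``
cases in every cohort.

Quantitative lab measurements are collapsed to the per-individual median,
trimmed of gross outliers (more than 7 SD from the mean, one pass on the raw
scale), and Box-Cox power-transformed with the transform parameter chosen by
profile likelihood of the covariate model  y ~ age + age^2 + sex + 20 PCs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from ._util import InputError

logger = logging.getLogger(__name__)

CASE, CONTROL, MISSING = 1.0, 0.0, np.nan


def assign_case_control(counts: pd.DataFrame) -> pd.DataFrame:
    """Map occurrence counts to status: >=2 case (1), 0 control (0), 1 missing (NaN)."""
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise InputError("occurrence counts must be nonnegative integers")
    status = np.where(arr >= 2, CASE, np.where(arr == 0, CONTROL, MISSING))
    return pd.DataFrame(status, index=counts.index, columns=counts.columns)


def filter_phecodes(status_by_cohort, min_cases: int = 20) -> list:
    """Phecodes with strictly more than ``min_cases`` cases in every cohort.

    ``status_by_cohort`` is a single status DataFrame or a list of them (one
    per cohort, same columns).
    """
    if isinstance(status_by_cohort, pd.DataFrame):
        status_by_cohort = [status_by_cohort]
    kept = None
    for status in status_by_cohort:
        n_cases = (status == CASE).sum(axis=0)
        ok = set(n_cases.index[n_cases > min_cases])
        kept = ok if kept is None else (kept & ok)
    cols = status_by_cohort[0].columns
    return [c for c in cols if c in kept]


def collapse_median(labs: pd.DataFrame) -> pd.DataFrame:
    """Per-(individual, lab) median of repeated measurements.

    ``labs`` is long-format with columns individual_id, lab, value; returns
    one row per (individual, lab) with the median value.
    """
    out = (labs.groupby(["individual_id", "lab"], sort=True)["value"]
           .median().reset_index())
    return out


def trim_outliers(values: np.ndarray, k: float = 7.0):
    """Single-pass trim: drop x with |x - mean| > k*sd (mean/sd on full input).

    Deliberately not iterated: a second pass, computed on the trimmed sample,
    could remove further values. Returns (kept values, boolean keep mask).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InputError("need at least 3 values to trim")
    if k == 0:
        warnings.warn("trim_outliers with k=0 removes every non-mean value")
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        return values, np.ones(values.size, dtype=bool)
    keep = np.abs(values - mu) <= k * sd
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("trim_outliers: removed %d of %d values", n_removed, values.size)
    return values[keep], keep


def boxcox_transform(y: np.ndarray, covariates: np.ndarray,
                     grid: tuple[float, float, float] = (-3.0, 3.0, 0.01)):
    """Box-Cox transform with lambda chosen by profile likelihood of a
    linear covariate model.

    For each candidate lambda the transform (y^lambda - 1)/lambda (log y at
    lambda = 0) is regressed on the covariates and the profile log-likelihood

        ll(lambda) = -(n/2) log(RSS/n) + (lambda - 1) * sum(log y)

    is evaluated; the grid optimum is refined by a local quadratic fit.
    Returns (lambda, transformed y). All y must be strictly positive — offset
    or exclude nonpositive values before calling (no silent shifting).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise InputError(
            "Box-Cox requires strictly positive values; offset or exclude y <= 0"
        )
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(y)), X])
    n = len(y)
    Q, _ = np.linalg.qr(X)
    logy = np.log(y)
    sum_logy = logy.sum()

    def profile_ll(lam: float) -> float:
        yt = logy if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
        r = yt - Q @ (Q.T @ yt)
        rss = r @ r
        if not np.isfinite(rss) or rss <= 0:
            return -np.inf
        return -0.5 * n * np.log(rss / n) + (lam - 1.0) * sum_logy

    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    lls = np.array([profile_ll(l) for l in lams])
    i = int(np.argmax(lls))
    lam = lams[i]
    if 0 < i < len(lams) - 1:  # quadratic refinement through the bracketing points
        x0, x1, x2 = lams[i - 1], lams[i], lams[i + 1]
        f0, f1, f2 = lls[i - 1], lls[i], lls[i + 1]
        denom = (f0 - 2 * f1 + f2)
        if denom < 0:
            lam = x1 - 0.5 * step * (f2 - f0) / denom
    yt = logy if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
    return float(lam), yt


def prepare_labs(labs: pd.DataFrame, cohort: pd.DataFrame,
                 covariate_columns: list[str] | None = None,
                 trim_sd: float = 7.0) -> pd.DataFrame:
    """Full lab pipeline: median collapse -> trim -> Box-Cox per lab.

    Each lab is handled independently. The covariate model defaults to
    age + age^2 + sex + all pc* columns present in ``cohort``. Returns a long
    table (individual_id, lab, value, transformed, boxcox_lambda, trimmed);
    trimmed rows carry NaN in ``transformed`` and are excluded from fits.
    """
    if covariate_columns is None:
        covariate_columns = ["age", "sex"] + [c for c in cohort.columns
                                              if c.startswith("pc")]
    med = collapse_median(labs)
    med = med.merge(cohort[["individual_id"] + covariate_columns],
                    on="individual_id", how="inner", validate="m:1")
    pieces = []
    for lab, grp in med.groupby("lab", sort=True):
        vals = grp["value"].to_numpy()
        _, keep = trim_outliers(vals, k=trim_sd)
        sub = grp[keep]
        X = np.column_stack(
            [sub["age"].to_numpy(), sub["age"].to_numpy() ** 2, sub["sex"].to_numpy()]
            + [sub[c].to_numpy() for c in covariate_columns if c.startswith("pc")]
        )
        lam, yt = boxcox_transform(sub["value"].to_numpy(), X)
        out = grp[["individual_id", "lab", "value"]].copy()
        out["trimmed"] = ~keep
        out["boxcox_lambda"] = lam
        out["transformed"] = np.nan
        out.loc[out.index[keep], "transformed"] = yt
        pieces.append(out)
    return pd.concat(pieces, ignore_index=True)
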