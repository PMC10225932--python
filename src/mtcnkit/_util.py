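"""Shared helpers: seeded substreams, design-matrix checks, fast OLS."""

from __future__ import annotations

import numpy as np
from scipy import stats


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; message names the field."""


class InputError(ValueError):
    """Raised when input data violate a documented precondition."""


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into ``n`` independent generator substreams.

    Uses SeedSequence spawning so each stage of a pipeline can be rerun
    independently without perturbing the streams of other stages.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise InputError naming (approximately) collinear columns.

    Columns are normalized first so wildly different scales (e.g. raw
    quadratic terms) are not mistaken for collinearity.
    """
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = np.where(norms == 0)[0]
        labels = [names[i] for i in bad] if names is not None else [str(i) for i in bad]
        raise InputError(f"design matrix is rank deficient; collinear columns: {labels}")
    X = X / norms
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # identify columns whose R diagonal collapses in a pivoted-free QR
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = np.where(diag / scale < 1e-10)[0]
    if names is not None:
        labels = [names[i] for i in bad]
    else:
        labels = [str(i) for i in bad]
    raise InputError(f"design matrix is rank deficient; collinear columns: {labels}")


def ols_fit(X: np.ndarray, y: np.ndarray):
    """Least-squares fit returning (beta, se, t, p, resid, sigma2).

    Plain dense OLS with Wald t p-values; used on hot paths (power
    simulations, per-marker scans) where statsmodels overhead dominates.
    """
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pvals, resid, sigma2
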