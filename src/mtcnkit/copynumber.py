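"""Relative mtDNA copy number from off-target read depth.

In exome (or similar capture) sequencing the mitochondrial genome is covered
by off-target reads, so the ratio of mean mtDNA depth to mean autosomal depth
at an equal number of sampled sites tracks the *relative* number of mtDNA
copies per cell (rmtCN) — not the absolute count, since capture enriches the
nuclear genome. The pipeline here is:

1. mask the known coverage-spike artifact on the mitochondrial reference
   (default: the closed interval [2,500, 3,000] of the 16,569-bp rCRS);
2. rmtCN = mean(unmasked mtDNA depth) / mean(autosomal depth);
   lrmtCN = log(rmtCN) (natural log);
3. residualize lrmtCN on sex, age and complete-blood-count composition with
   the saturated quadratic-interaction model

       lrmtCN ~ (sex + age + age^2) x (count + count^2 for each of six
                 cell types)

   — 52 design columns including the intercept — yielding rlrmtCN, the
   cell-composition-adjusted copy number used by every downstream analysis.

Blood mtDNA content is dominated by cell composition (platelets carry
mitochondria but no nucleus; neutrophils are mtDNA-poor), so the adjustment
is what makes rlrmtCN interpretable as a per-cell copy-number phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import InputError, check_full_rank

logger = logging.getLogger(__name__)

#: length of the revised Cambridge Reference Sequence (rCRS), bp
MT_LENGTH = 16_569

#: default coverage-spike artifact interval (1-based, closed)
SPIKE_REGION = (2500, 3000)

CELL_TYPES = ("neutrophils", "platelets", "lymphocytes", "basophils",
              "monocytes", "eosinophils")


@dataclass
class DepthProfile:
    """Per-site read depths for one individual.

    ``mt_depths`` covers rCRS positions 1..L (1-based); ``auto_depths`` an
    equal number of sampled autosomal sites. ``mask`` holds mtDNA positions
    excluded from averaging.
    """

    individual_id: str
    mt_depths: np.ndarray
    auto_depths: np.ndarray
    mask: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.mt_depths = np.asarray(self.mt_depths)
        self.auto_depths = np.asarray(self.auto_depths)
        if self.mt_depths.shape != self.auto_depths.shape:
            raise InputError("mt and autosomal depth vectors must have equal length")
        if np.any(self.mt_depths < 0) or np.any(self.auto_depths < 0):
            raise InputError("depths must be nonnegative")

    @property
    def n_sites(self) -> int:
        return self.mt_depths.size


@dataclass
class CopyNumberRecord:
    individual_id: str
    rmtcn: float
    lrmtcn: float
    rlrmtcn: float = np.nan
    model_label: str = ""


def mask_spike(profile: DepthProfile,
               region: tuple[int, int] | None = SPIKE_REGION) -> DepthProfile:
    """Mask a closed 1-based position interval; depths are left unchanged."""
    if region is None:
        return profile
    lo, hi = region
    if lo > hi:  # empty interval
        return profile
    if lo < 1 or hi > profile.n_sites:
        raise InputError(
            f"spike region {region} outside mtDNA coordinates 1..{profile.n_sites}"
        )
    new_mask = profile.mask | frozenset(range(lo, hi + 1))
    return replace(profile, mask=new_mask)


def estimate_rmtcn(profile: DepthProfile) -> CopyNumberRecord:
    """Depth-ratio estimator: rmtCN and its natural log.

    No factor of two is applied: capture enrichment makes the scale relative,
    so only variation among individuals is meaningful.
    """
    if profile.mask:
        idx = np.fromiter(profile.mask, dtype=int) - 1
        keep = np.ones(profile.n_sites, dtype=bool)
        keep[idx] = False
    else:
        keep = np.ones(profile.n_sites, dtype=bool)
    if not keep.any():
        raise InputError("no unmasked sites")
    auto_mean = profile.auto_depths.mean()
    if auto_mean == 0:
        raise InputError("mean autosomal depth is zero; rmtCN undefined")
    mt_mean = profile.mt_depths[keep].mean()
    if mt_mean == 0:
        raise InputError("mean mtDNA depth is zero; lrmtCN undefined (rmtcn=0)")
    rmtcn = mt_mean / auto_mean
    return CopyNumberRecord(profile.individual_id, rmtcn, float(np.log(rmtcn)))


def estimate_cohort(profiles, spike_region=SPIKE_REGION) -> pd.DataFrame:
    """Mask + ratio for every profile; returns a records table."""
    recs = [estimate_rmtcn(mask_spike(p, spike_region)) for p in profiles]
    return pd.DataFrame(
        {"individual_id": [r.individual_id for r in recs],
         "rmtcn": [r.rmtcn for r in recs],
         "lrmtcn": [r.lrmtcn for r in recs]}
    )


# ---------------------------------------------------------------------------
# residualization

ADJUSTMENT_MODELS = ("none", "linear", "full", "full+duffy")


def _composition_design(cohort: pd.DataFrame, model: str = "full"):
    """Build the covariate design for a given adjustment model.

    "full" is the saturated model: intercept; sex; age, age^2; linear and
    quadratic terms of the six cell counts (12 columns); and all pairwise
    products of {sex, age, age^2} with those 12 (36 columns) — 52 in total.
    Raw (non-orthogonal) polynomials are used; the residuals only depend on
    the column span, so this matches any polynomial basis of the same model.
    """
    n = len(cohort)
    sex = cohort["sex"].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    demo = {"sex": sex, "age": age, "age2": age**2}
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if model == "none":
        return cols
    cols.update(demo)
    cells: dict[str, np.ndarray] = {}
    for ct in CELL_TYPES:
        x = cohort[ct].to_numpy(dtype=float)
        cells[ct] = x
        if model != "linear":
            cells[f"{ct}^2"] = x * x
    cols.update(cells)
    if model in ("full", "full+duffy"):
        for dname, d in demo.items():
            for cname, c in cells.items():
                cols[f"{dname}:{cname}"] = d * c
    if model == "full+duffy":
        duffy = cohort["duffy_genotype"].to_numpy(dtype=float)
        cols["duffy_add"] = duffy
        cols["duffy_het"] = (duffy == 1).astype(float)
    return cols


def residualize(records: pd.DataFrame, cohort: pd.DataFrame,
                model: str = "full") -> pd.DataFrame:
    """OLS-residualize lrmtCN on the composition design; fills ``rlrmtcn``.

    Rows with missing covariates are excluded (count logged); the design must
    be full rank and the fit needs at least twice as many individuals as
    design columns. Residuals are orthogonal to every design column and have
    mean zero (the design includes an intercept).
    """
    if model not in ADJUSTMENT_MODELS:
        raise InputError(f"unknown adjustment model {model!r}; choose from {ADJUSTMENT_MODELS}")
    merged = records.merge(cohort, on="individual_id", how="left", validate="1:1")
    needed = ["sex", "age"] + list(CELL_TYPES)
    if model == "full+duffy":
        needed.append("duffy_genotype")
    complete = merged[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("residualize: excluded %d rows with missing covariates", n_dropped)
    sub = merged.loc[complete]
    cols = _composition_design(sub, model)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if len(sub) < 2 * X.shape[1]:
        raise InputError(
            f"need at least {2 * X.shape[1]} individuals to fit {X.shape[1]} design columns"
        )
    check_full_rank(X, names)
    y = sub["lrmtcn"].to_numpy(dtype=float)
    # column-scale for numerical conditioning (raw quadratic x count products
    # span ~10 orders of magnitude); residuals depend only on the span
    scale = np.linalg.norm(X, axis=0)
    Xs = X / scale
    Q, _ = np.linalg.qr(Xs)
    resid = y - Q @ (Q.T @ y)
    out = records.copy()
    out["rlrmtcn"] = np.nan
    out.loc[complete.to_numpy(), "rlrmtcn"] = resid
    out["model_label"] = model
    return out


def standardize(records: pd.DataFrame, column: str = "rlrmtcn") -> pd.DataFrame:
    """Scale a copy-number column to mean 0, sd 1 (effect sizes in SD units)."""
    v = records[column].to_numpy(dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 2:
        raise InputError("need at least 2 records to standardize")
    sd = v[ok].std()
    if sd == 0:
        raise InputError(f"{column} has zero variance")
    out = records.copy()
    out[column] = (v - v[ok].mean()) / sd
    return out


def compare_adjustment_models(records: pd.DataFrame, cohort: pd.DataFrame,
                              phenotypes: pd.DataFrame,
                              model_set=("none", "linear", "full", "full+duffy")
                              ) -> pd.DataFrame:
    """Per-phenotype association of copy number across adjustment models.

    Copy-number/phenotype associations in blood are notoriously sensitive to
    how cell composition is modeled; this re-runs the same scan under each
    covariate model and flags phenotypes whose effect sign flips. Under model
    "none" the predictor is (centered) lrmtCN itself.

    ``phenotypes``: columns = quantitative traits, indexed/aligned to
    ``records`` row order.
    """
    from .assoc import fit_assoc  # deferred: avoids import cycle

    if len(model_set) == 0:
        raise InputError("model_set must not be empty")
    rows = []
    for model in model_set:
        if model == "none":
            res = records.copy()
            v = res["lrmtcn"].to_numpy(dtype=float)
            res["rlrmtcn"] = v - v.mean()
            res["model_label"] = "none"
        else:
            res = residualize(records, cohort, model=model)
        x = res["rlrmtcn"].to_numpy(dtype=float)
        for trait in phenotypes.columns:
            y = phenotypes[trait].to_numpy(dtype=float)
            rec = fit_assoc(y, x, model="linear", predictor_id="rlrmtcn", trait_id=trait)
            rows.append({"trait": trait, "model": model, "beta": rec.beta,
                         "se": rec.se, "p": rec.p, "n": rec.n})
    out = pd.DataFrame(rows)
    signs = out.pivot(index="trait", columns="model", values="beta")
    flip = (np.sign(signs).nunique(axis=1) > 1)
    out["sign_flip"] = out["trait"].map(flip)
    return out
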