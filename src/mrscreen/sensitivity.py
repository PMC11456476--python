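"""Heterogeneity, pleiotropy and influence diagnostics for MR estimates.

* Cochran's Q against the fixed-effect IVW fit (df = J - 1) or the Egger
  line (df = J - 2), chi-square upper-tail p-values;
* the MR-Egger intercept test for directional pleiotropy;
* leave-one-out re-estimation to expose single-SNP influence;
* MR-PRESSO: a simulation-based global pleiotropy test on the
  leave-one-out residual sum of squares, per-SNP outlier detection with
  Bonferroni-adjusted empirical p-values, and an outlier-corrected estimate
  with a distortion test.

All Monte-Carlo p-values use the add-one position (1 + #{>= obs}) / (n + 1),
so they are valid and never exactly zero. Residual sums are weighted by
1/se_y^2, which makes the null distribution free of the outcome sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .estimators import (EggerRegression, MREstimate, _ivw_core, ivw,
                         _two_sided_p)
from .harmonization import HarmonizedSet, orient_positive_exposure


@dataclass
class HeterogeneityResult:
    method: str  # "ivw_q" | "egger_q"
    Q: float
    df: int
    pval: float


@dataclass
class LeaveOneOutResult:
    rows: pd.DataFrame  # columns: excluded_snp, theta, se, pval
    full_estimate: MREstimate
    stable: bool


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    per_snp_pvals: np.ndarray
    outlier_ids: set[str]
    theta_raw: float
    theta_corrected: float | None
    distortion_pct: float | None
    distortion_pval: float | None
    n_sim: int
    seed: int
    notes: list[str] = field(default_factory=list)


def cochran_q(hset: HarmonizedSet, reference: str = "ivw",
              ) -> HeterogeneityResult:
    """Heterogeneity of per-SNP ratio estimates about a reference fit."""
    J = hset.n_snp
    if reference == "ivw":
        if J < 2:
            raise InsufficientInstrumentsError("ivw Q needs >= 2 SNPs")
        _, _, q = _ivw_core(hset.beta_x, hset.beta_y, hset.se_y)
        df = J - 1
    elif reference == "egger":
        if J < 3:
            raise InsufficientInstrumentsError("egger Q needs >= 3 SNPs")
        fit = EggerRegression().fit(orient_positive_exposure(hset))
        q = fit.extras_["rss"]
        df = J - 2
    else:
        raise ValueError(f"unknown reference: {reference!r}")
    return HeterogeneityResult(method=f"{reference}_q", Q=float(q), df=df,
                               pval=float(max(stats.chi2.sf(q, df), 1e-300)))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept (directional pleiotropy) with SE and p-value."""
    fit = EggerRegression().fit(orient_positive_exposure(hset))
    return fit.intercept_, fit.intercept_se_, fit.intercept_pval_


def leave_one_out(hset: HarmonizedSet, method: str = "ivw",
                  ) -> LeaveOneOutResult:
    """Re-estimate J times, each omitting one SNP (default method: IVW)."""
    if method != "ivw":
        raise ValueError("only ivw leave-one-out is supported")
    J = hset.n_snp
    if J < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    full = ivw(hset)
    rows = []
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        est = ivw(hset.subset(mask))
        rows.append({"excluded_snp": hset.snp_ids[j], "theta": est.theta,
                     "se": est.se, "pval": est.pval})
    rows = pd.DataFrame(rows)
    stable = bool(np.all(np.sign(rows["theta"]) == np.sign(full.theta)))
    return LeaveOneOutResult(rows=rows, full_estimate=full, stable=stable)


def _loo_theta_and_resid(bx, by, w):
    """Per-SNP leave-one-out fixed-effect IVW slopes and residuals."""
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    theta_loo = (s_xy - w * bx * by) / (s_xx - w * bx * bx)
    return theta_loo, by - theta_loo * bx


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed: int = 0) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted leave-one-out residual sum of
    squares; its null distribution is simulated by redrawing both effect
    vectors from normals centred on the observed exposure effects and the
    leave-one-out predictions.
    """
    J = hset.n_snp
    if J < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 SNPs")
    rng = np.random.default_rng(seed)
    # canonical SNP order makes the result invariant to input row order
    order = np.argsort(hset.snp_ids, kind="mergesort")
    hset = hset.subset(order)
    bx, sx = hset.beta_x, hset.se_x
    by, sy = hset.beta_y, hset.se_y
    w = 1.0 / sy**2

    theta_loo, d = _loo_theta_and_resid(bx, by, w)
    theta_loo, d = theta_loo.ravel(), d.ravel()
    rss_obs = float(np.sum(w * d**2))

    bx_s = rng.normal(bx, sx, size=(n_sim, J))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    _, d_s = _loo_theta_and_resid(bx_s, by_s, w[None, :])
    rss_s = np.sum(w[None, :] * d_s**2, axis=1)
    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))

    exceed = np.sum(d_s**2 >= d[None, :] ** 2, axis=0)
    per_snp = (1 + exceed) / (n_sim + 1)
    adjusted = np.minimum(per_snp * J, 1.0)
    out_mask = adjusted < outlier_alpha
    outlier_ids = set(str(s) for s in hset.snp_ids[out_mask])

    theta_raw = float(ivw(hset).theta)
    theta_corrected = distortion_pct = distortion_pval = None
    notes: list[str] = []
    n_out = int(out_mask.sum())
    if n_out and J - n_out >= 2:
        theta_corrected = float(ivw(hset.subset(~out_mask)).theta)
        if theta_corrected != 0:
            distortion_pct = float(
                100.0 * (theta_raw - theta_corrected) / abs(theta_corrected))
            dist_rand = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(J, size=n_out, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                t = float(ivw(hset.subset(mask)).theta)
                dist_rand[s] = (100.0 * (theta_raw - t) / abs(t)
                                if t != 0 else np.inf)
            distortion_pval = float(
                (1 + np.sum(np.abs(dist_rand) >= abs(distortion_pct)))
                / (n_sim + 1))
        else:
            notes.append("corrected estimate is exactly zero; "
                         "distortion undefined")
    elif n_out:
        notes.append("all but <2 SNPs flagged as outliers; "
                     "correction skipped")
    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval,
        per_snp_pvals=adjusted, outlier_ids=outlier_ids,
        theta_raw=theta_raw, theta_corrected=theta_corrected,
        distortion_pct=distortion_pct, distortion_pval=distortion_pval,
        n_sim=n_sim, seed=seed, notes=notes)
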