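"""Causal-effect estimators for two-sample summary-data MR.

Five estimators over J harmonized SNPs with exposure effects (beta_x, se_x)
and outcome effects (beta_y, se_y), the outcome on the log-odds scale:

* :class:`IVW` — inverse-variance-weighted meta-analysis of per-SNP Wald
  ratios, equivalently weighted least squares of beta_y on beta_x through
  the origin with weights 1/se_y^2. Unbiased only when horizontal pleiotropy
  is absent. Default variance model is multiplicative random effects with
  the residual scale floored at 1 (never anti-conservative vs fixed effects).
* :class:`EggerRegression` — weighted regression with a free intercept; the
  intercept estimates directional pleiotropy (zero intercept means Egger and
  IVW agree), the slope is the causal effect under InSIDE.
* :class:`WeightedMedian` — weighted median of the Wald ratios; consistent
  with up to 50% invalid instruments by weight. SE by parametric bootstrap.
* :class:`WeightedMode` — mode of a weighted kernel density over the Wald
  ratios (largest cluster of agreeing instruments). SE by the same bootstrap.
* :class:`MaximumLikelihood` — profile likelihood of a bivariate normal
  measurement model; resembles IVW, with smaller SEs when its assumptions
  hold, and accounts for exposure-side sampling error.

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit`` on data, read fitted attributes (``theta_``, ``se_``, ``pval_``,
``estimate_``). ``fit`` accepts either a :class:`~mrscreen.harmonization.HarmonizedSet`
as ``X``, or per-SNP arrays ``fit(beta_x, beta_y, se_x=..., se_y=...)``.
Module-level functions are thin wrappers over the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import DomainError, EstimationError, InsufficientInstrumentsError
from .harmonization import HarmonizedSet, orient_positive_exposure

_MIN_P = 1e-300
Z95 = 1.96  # conventional 95% normal quantile, used exactly for reporting

METHODS = ("ivw", "egger", "weighted_median", "weighted_mode",
           "max_likelihood")


@dataclass
class MREstimate:
    """One method's causal estimate with odds-ratio reporting."""

    method: str
    theta: float
    se: float
    pval: float
    n_snp: int
    or_point: float
    or_ci95: tuple[float, float]
    extras: dict = field(default_factory=dict)


def _two_sided_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _MIN_P, 1.0))


def to_odds_ratio(theta: float, se: float) -> tuple[float, tuple[float, float]]:
    """Log-odds effect -> odds ratio with a 95% Wald CI."""
    if se <= 0:
        raise DomainError(f"se must be positive (got {se!r})")
    return (float(np.exp(theta)),
            (float(np.exp(theta - Z95 * se)), float(np.exp(theta + Z95 * se))))


def p_from_or_ci(or_point: float, ci_low: float, ci_high: float) -> float:
    """Recover the two-sided p-value implied by a reported OR and 95% CI.

    Inverts the Wald construction: beta = ln OR, se = (ln hi - ln lo)/(2*1.96).
    Used to check the internal consistency of published OR/CI/p triples.
    """
    if not 0 < ci_low < or_point < ci_high:
        raise DomainError(
            f"need 0 < ci_low < or < ci_high (got {or_point}, {ci_low}, {ci_high})")
    beta = np.log(or_point)
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95)
    return _two_sided_p(beta / se)


def _extract(X, y, se_x, se_y, need_se_x):
    if isinstance(X, HarmonizedSet):
        bx, sx = X.beta_x, X.se_x
        by, sy = X.beta_y, X.se_y
        ids = X.snp_ids
    else:
        bx = np.asarray(X, dtype=float).reshape(-1)
        by = np.asarray(y, dtype=float).reshape(-1)
        sx = None if se_x is None else np.asarray(se_x, dtype=float).reshape(-1)
        sy = np.asarray(se_y, dtype=float).reshape(-1)
        ids = None
    if sy is None or len(by) != len(bx) or len(sy) != len(bx):
        raise ValueError("beta_x, beta_y, se_y must have equal length")
    if np.any(sy <= 0):
        raise DomainError("se_y must be strictly positive")
    if need_se_x:
        if sx is None:
            raise ValueError("this estimator requires se_x")
        if len(sx) != len(bx) or np.any(sx <= 0):
            raise DomainError("se_x must be strictly positive")
    return bx, sx, by, sy, ids


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               ) -> MREstimate:
    """Single-variant causal estimate beta_y / beta_x (first-order SE)."""
    if beta_x == 0:
        raise DomainError("wald_ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    orp, ci = to_odds_ratio(theta, se)
    return MREstimate(method="wald_ratio", theta=float(theta), se=float(se),
                      pval=_two_sided_p(theta / se), n_snp=1,
                      or_point=orp, or_ci95=ci)


def _ivw_core(bx, by, sy):
    """Fixed-effect IVW point estimate and SE (weights 1/se_y^2)."""
    w = 1.0 / sy**2
    s_xx = np.sum(w * bx * bx)
    if s_xx <= 0:
        raise EstimationError("degenerate exposure effects (sum w*bx^2 = 0)")
    theta = np.sum(w * bx * by) / s_xx
    se_fixed = np.sqrt(1.0 / s_xx)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return float(theta), float(se_fixed), q


class _BaseMREstimator(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_estimate``."""

    method: str = ""
    _min_snps: int = 1
    _needs_se_x: bool = False

    def fit(self, X, y=None, *, se_x=None, se_y=None):
        bx, sx, by, sy, ids = _extract(X, y, se_x, se_y, self._needs_se_x)
        J = len(bx)
        if J == 0:
            raise InsufficientInstrumentsError("empty harmonized set")
        if J < self._min_snps:
            raise InsufficientInstrumentsError(
                f"{self.method} needs >= {self._min_snps} SNPs (got {J})")
        theta, se, extras = self._estimate(bx, sx, by, sy)
        if se <= 0 or not np.isfinite(se):
            raise EstimationError(
                f"{self.method}: non-positive or non-finite SE ({se})")
        orp, ci = to_odds_ratio(theta, se)
        self.theta_ = float(theta)
        self.se_ = float(se)
        self.pval_ = _two_sided_p(theta / se)
        self.n_snp_ = J
        self.or_ = orp
        self.or_ci95_ = ci
        self.extras_ = extras
        self.estimate_ = MREstimate(
            method=self.method, theta=self.theta_, se=self.se_,
            pval=self.pval_, n_snp=J, or_point=orp, or_ci95=ci,
            extras=extras)
        return self

    def _estimate(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError


class IVW(_BaseMREstimator):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    variance_model : {"multiplicative_random", "fixed"}
        Under multiplicative random effects the fixed-effect SE is scaled by
        max(1, sqrt(Q / (J - 1))), Q being Cochran's heterogeneity statistic.
    """

    method = "ivw"
    _min_snps = 1  # J = 1 degenerates to the Wald ratio

    def __init__(self, variance_model: str = "multiplicative_random"):
        self.variance_model = variance_model

    def _estimate(self, bx, sx, by, sy):
        if self.variance_model not in ("fixed", "multiplicative_random"):
            raise ValueError(
                f"unknown variance_model: {self.variance_model!r}")
        theta, se_fixed, q = _ivw_core(bx, by, sy)
        J = len(bx)
        scale = 1.0
        if self.variance_model == "multiplicative_random" and J >= 2:
            scale = max(1.0, np.sqrt(q / (J - 1)))
        return theta, se_fixed * scale, {
            "Q": q, "variance_model": self.variance_model,
            "se_fixed": se_fixed}


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    The input is oriented to non-negative exposure effects internally (the
    orientation the Egger model is defined under). Coefficient SEs are
    inflated by max(1, sigma_hat), the square-root residual scale on J - 2
    degrees of freedom. Fitted pleiotropy attributes: ``intercept_``,
    ``intercept_se_``, ``intercept_pval_``.
    """

    method = "egger"
    _min_snps = 3

    def _estimate(self, bx, sx, by, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        x, yv = bx * sign, by * sign
        w = 1.0 / sy**2
        W, Sx = np.sum(w), np.sum(w * x)
        Sxx, Sy, Sxy = np.sum(w * x * x), np.sum(w * yv), np.sum(w * x * yv)
        den = W * Sxx - Sx**2
        if den <= 0:
            raise EstimationError("Egger design is singular "
                                  "(no spread in exposure effects)")
        slope = (W * Sxy - Sx * Sy) / den
        intercept = (Sxx * Sy - Sx * Sxy) / den
        J = len(x)
        rss = float(np.sum(w * (yv - intercept - slope * x) ** 2))
        sigma = np.sqrt(max(rss, 0.0) / (J - 2))
        infl = max(1.0, sigma)
        se_slope = np.sqrt(W / den) * infl
        se_int = np.sqrt(Sxx / den) * infl
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pval_ = _two_sided_p(intercept / se_int)
        extras = {"intercept": self.intercept_,
                  "intercept_se": self.intercept_se_,
                  "intercept_pval": self.intercept_pval_,
                  "sigma": float(sigma), "rss": rss}
        return float(slope), float(se_slope), extras


def _weighted_median(ratios, weights):
    """Interpolated weighted median of ``ratios``."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def _ratio_weights(bx, sy):
    """First-order inverse-variance weights for Wald ratios: bx^2 / se_y^2."""
    return bx**2 / sy**2


class _BootstrapMixin:
    """Parametric-bootstrap SE: resample beta_x, beta_y from their normals."""

    def _bootstrap_se(self, bx, sx, by, sy, point_fn):
        rng = np.random.default_rng(self.random_state)
        n_boot = int(self.n_boot)
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        est = np.empty(n_boot)
        for b in range(n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            est[b] = point_fn(bxs, bys)
        return float(np.std(est, ddof=1)), n_boot


class WeightedMedian(_BootstrapMixin, _BaseMREstimator):
    """Weighted median of Wald ratios (robust to <50% invalid weight)."""

    method = "weighted_median"
    _min_snps = 3
    _needs_se_x = True

    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def _estimate(self, bx, sx, by, sy):
        theta = _weighted_median(by / bx, _ratio_weights(bx, sy))

        def point(bxs, bys):
            return _weighted_median(bys / bxs, _ratio_weights(bxs, sy))

        se, n_boot = self._bootstrap_se(bx, sx, by, sy, point)
        return theta, se, {"n_boot": n_boot}


def _mode_bandwidth(r, phi):
    """Modified Silverman rule: phi * 0.9 * min(sd, 1.4826 MAD) * J^(-1/5)."""
    J = len(r)
    sd = np.std(r, ddof=1) if J > 1 else 0.0
    mad = 1.4826 * np.median(np.abs(r - np.median(r)))
    h = phi * 0.9 * min(sd, mad) * J ** (-0.2)
    return max(h, 1e-12)


def _weighted_mode(ratios, weights, phi, grid_size=512):
    h = _mode_bandwidth(ratios, phi)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    w = weights / np.sum(weights)
    dens = stats.norm.pdf(grid[:, None], loc=ratios[None, :], scale=h) @ w
    return float(grid[int(np.argmax(dens))])  # argmax: first = smallest x


class WeightedMode(_BootstrapMixin, _BaseMREstimator):
    """Mode-based estimator: argmax of a weighted normal KDE of the ratios.

    ``phi`` scales the kernel bandwidth; larger phi smooths more and can
    only merge, never split, density modes.
    """

    method = "weighted_mode"
    _min_snps = 3
    _needs_se_x = True

    def __init__(self, phi: float = 1.0, n_boot: int = 1000,
                 random_state: int = 0):
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    def _estimate(self, bx, sx, by, sy):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        theta = _weighted_mode(by / bx, _ratio_weights(bx, sy), self.phi)

        def point(bxs, bys):
            return _weighted_mode(bys / bxs, _ratio_weights(bxs, sy), self.phi)

        se, n_boot = self._bootstrap_se(bx, sx, by, sy, point)
        return theta, se, {"n_boot": n_boot, "phi": self.phi}


class MaximumLikelihood(_BaseMREstimator):
    """Profile-likelihood estimator of the bivariate measurement model.

    The likelihood treats each true exposure effect b_j as a nuisance
    parameter with closed-form inner maximizer

        b_j*(theta) = (beta_xj/se_xj^2 + theta beta_yj/se_yj^2)
                      / (1/se_xj^2 + theta^2/se_yj^2),

    and profiles over theta by bounded one-dimensional optimization started
    at the IVW estimate. The SE comes from the numerically differentiated
    curvature of the profile log-likelihood at the optimum.
    """

    method = "max_likelihood"
    _min_snps = 1  # J = 1 degenerates to the Wald ratio
    _needs_se_x = True

    def __init__(self, xatol: float = 1e-10):
        self.xatol = xatol

    def _estimate(self, bx, sx, by, sy):
        wx, wy = 1.0 / sx**2, 1.0 / sy**2

        def negll(theta):
            denom = wx + theta**2 * wy
            b = (bx * wx + theta * by * wy) / denom
            return float(np.sum(wy * (by - theta * b) ** 2
                                + wx * (bx - b) ** 2)) / 2.0

        theta0, se0, _ = _ivw_core(bx, by, sy)
        half_width = max(50.0 * se0, 1.0)
        res = optimize.minimize_scalar(
            negll, bounds=(theta0 - half_width, theta0 + half_width),
            method="bounded", options={"xatol": self.xatol})
        if not res.success:
            raise EstimationError(f"profile optimization failed: {res}")
        theta = float(res.x)
        h = max(1e-6, 1e-4 * se0)
        d2 = (negll(theta + h) - 2.0 * negll(theta) + negll(theta - h)) / h**2
        if d2 <= 0 or not np.isfinite(d2):
            raise EstimationError(
                f"non-positive profile curvature at optimum (d2 = {d2})")
        return theta, float(1.0 / np.sqrt(d2)), {"nit": int(res.nfev)}


def _fit_or_delegate(cls_kwargs, cls, hset, **kwargs):
    if hset.n_snp == 1:
        est = wald_ratio(hset.beta_x[0], hset.se_x[0],
                         hset.beta_y[0], hset.se_y[0])
        est.method = cls.method
        est.extras["delegated"] = "wald_ratio"
        return est
    return cls(**cls_kwargs).fit(hset, **kwargs).estimate_


def ivw(hset: HarmonizedSet,
        variance_model: str = "multiplicative_random") -> MREstimate:
    """IVW estimate; a single-SNP set degenerates to the Wald ratio."""
    return _fit_or_delegate({"variance_model": variance_model}, IVW, hset)


def egger(hset: HarmonizedSet) -> MREstimate:
    return EggerRegression().fit(orient_positive_exposure(hset)).estimate_


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, random_state=seed).fit(hset).estimate_


def weighted_mode(hset: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    return WeightedMode(phi=phi, n_boot=n_boot,
                        random_state=seed).fit(hset).estimate_


def max_likelihood(hset: HarmonizedSet) -> MREstimate:
    """Profile-ML estimate; a single-SNP set degenerates to the Wald ratio."""
    return _fit_or_delegate({}, MaximumLikelihood, hset)
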