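"""Asymptotic regression of diversity profiles and effect metrics.

The mean silent-site diversity of bacterial genes rises from a depressed
value at the translation start to a plateau.  That rise is modeled as a
negative-exponential (asymptotic regression, ASR) curve

    pi(l) = d_max + (d_min - d_max) * exp(-c * l)

where ``d_min`` is the fitted diversity at position 0, ``d_max`` the
asymptote and ``c`` the per-site recovery rate.  Two derived quantities
summarize the pattern:

* Effect Size  ``S_e = log2(d_max / d_min)`` — the log-2 fold reduction at
  the start relative to the plateau;
* Effect Length ``L_e = ln 2 / c`` — the position at which the curve is
  halfway between ``d_min`` and ``d_max``.

Fitting is weighted nonlinear least squares (weights = number of genes per
position, i.e. residual variance sigma^2 / w), run in the ``K = ln c``
parameterization so that ``c`` stays positive and standard errors transfer
to ``L_e`` by the delta method.

``AsymptoticRegression`` is a scikit-learn compatible estimator; the
module-level functions (`self_start`, `fit_asr`, `effect_metrics`,
`observed_effect_size`) are thin wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .diversity import DiversityProfile

LN2 = math.log(2.0)


@dataclass
class ASRFit:
    """Fitted ASR parameters with covariance in (d_min, d_max, K) order."""

    d_min: float
    d_max: float
    c: float
    K: float
    cov: np.ndarray  # 3x3 over (d_min, d_max, K)
    sigma2: float  # residual variance (weighted MSE)
    converged: bool
    n_sites_used: int

    @property
    def se_d_min(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def se_d_max(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def se_K(self) -> float:
        return float(np.sqrt(self.cov[2, 2]))

    @property
    def cov_dmax_dmin(self) -> float:
        return float(self.cov[1, 0])

    def predict(self, positions: np.ndarray) -> np.ndarray:
        l = np.asarray(positions, dtype=float)
        return self.d_max + (self.d_min - self.d_max) * np.exp(-self.c * l)


@dataclass
class EffectMetrics:
    """Effect Size/Length with delta-method standard errors.

    ``saturation`` is the conservative point at which the profile is treated
    as flat, fixed at 4 * L_e (>= 93% of the way to the plateau).
    ``se_L_e`` carries the curvature-corrected factor (1 - se_K^2/4);
    ``se_L_e_first_order`` is the plain first-order delta value.
    """

    S_e: float
    L_e: float
    se_S_e: float
    se_L_e: float
    se_L_e_first_order: float
    saturation: float


def _model(params: np.ndarray, l: np.ndarray) -> np.ndarray:
    d_min, d_max, K = params
    # clip the decay exponent to dodge overflow when the optimizer probes
    # extreme K; e^-700 underflows to 0 harmlessly
    expo = np.clip(np.exp(min(K, 300.0)) * l, 0.0, 700.0)
    return d_max + (d_min - d_max) * np.exp(-expo)


def _profile_arrays(profile: DiversityProfile | tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(profile, DiversityProfile):
        return (
            profile.positions.astype(float),
            profile.mean_pi.astype(float),
            profile.weight.astype(float),
        )
    l, y, w = profile
    return np.asarray(l, float), np.asarray(y, float), np.asarray(w, float)


def self_start(profile: DiversityProfile | tuple) -> tuple[float, float, float]:
    """Initial (d_min, d_max, c) for the ASR fit.

    d_max starts at the mean of the upper quartile of the observed means,
    d_min at the observed value nearest position 0, and c from the slope of a
    weighted linear fit of ln(d_max*1.001 - pi) on position over the points
    where that argument is positive.
    """
    l, y, w = _profile_arrays(profile)
    if len(np.unique(l)) < 4:
        raise ValueError("insufficient profile: need >=4 distinct positions")
    q75 = np.quantile(y, 0.75)
    d_max0 = float(np.mean(y[y >= q75]))
    d_min0 = float(y[np.argmin(l)])
    arg = d_max0 * 1.001 - y
    ok = arg > 0
    if ok.sum() < 2:
        raise ValueError("insufficient profile: no decay information")
    ll, la, lw = l[ok], np.log(arg[ok]), w[ok]
    slope = np.polyfit(ll, la, 1, w=np.sqrt(lw))[0]
    c0 = -float(slope)
    if not np.isfinite(c0) or c0 <= 0:
        raise ValueError("insufficient profile: no positive decay rate (flat profile?)")
    return d_min0, d_max0, c0


class AsymptoticRegression(RegressorMixin, BaseEstimator):
    """Weighted ASR fit pi(l) = d_max + (d_min - d_max)·exp(-c·l).

    scikit-learn style estimator: ``fit(X, y, sample_weight)`` with X the
    positions (n,) or (n, 1), y the observed means, and sample_weight the
    per-position gene counts.  Optimization is Levenberg–Marquardt (damped
    Gauss–Newton) in the (d_min, d_max, K=ln c) parameterization.

    Fitted attributes: ``d_min_``, ``d_max_``, ``c_``, ``K_``, ``cov_``
    (3x3 over (d_min, d_max, K)), ``sigma2_``, ``converged_``,
    ``n_sites_used_``.
    """

    def __init__(self, init: tuple | None = None, max_iter: int = 200, tol: float = 1e-12):
        self.init = init
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None):
        l = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if sample_weight is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if len(l) != len(y) or len(y) != len(w):
            raise ValueError("X, y, sample_weight must be equal length")
        if len(l) < 4:
            raise ValueError("insufficient profile: need >=4 points")

        if self.init is not None:
            d_min0, d_max0, c0 = self.init
        else:
            d_min0, d_max0, c0 = self_start((l, y, w))
        if c0 <= 0:
            raise ValueError("initial c must be positive")
        x0 = np.array([d_min0, d_max0, math.log(c0)])
        sw = np.sqrt(w)

        def resid(p):
            return sw * (y - _model(p, l))

        def jac(p):
            d_min, d_max, K = p
            c = math.exp(min(K, 300.0))
            e = np.exp(-np.clip(c * l, 0.0, 700.0))
            J = np.empty((len(l), 3))
            J[:, 0] = -sw * e
            J[:, 1] = -sw * (1.0 - e)
            J[:, 2] = -sw * (d_min - d_max) * (-l * e) * c
            return J

        res = least_squares(
            resid,
            x0,
            jac=jac,
            method="lm",
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter * 4,
        )
        d_min, d_max, K = res.x
        dof = max(len(l) - 3, 1)
        rss = float(res.fun @ res.fun)
        sigma2 = rss / dof
        JtJ = res.jac.T @ res.jac
        try:
            cov = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError as exc:
            raise ValueError("unidentifiable: singular Jacobian") from exc

        self.d_min_ = float(d_min)
        self.d_max_ = float(d_max)
        self.K_ = float(K)
        self.c_ = float(math.exp(K))
        self.cov_ = cov
        self.sigma2_ = sigma2
        self.converged_ = bool(res.status > 0)
        self.n_sites_used_ = int(len(l))
        return self

    def predict(self, X):
        l = np.asarray(X, dtype=float).reshape(-1)
        return _model(np.array([self.d_min_, self.d_max_, self.K_]), l)

    def to_asrfit(self) -> ASRFit:
        return ASRFit(
            d_min=self.d_min_,
            d_max=self.d_max_,
            c=self.c_,
            K=self.K_,
            cov=self.cov_,
            sigma2=self.sigma2_,
            converged=self.converged_,
            n_sites_used=self.n_sites_used_,
        )


def fit_asr(profile: DiversityProfile | tuple, init: tuple | None = None) -> ASRFit:
    """Fit the ASR model to a diversity profile; see AsymptoticRegression."""
    l, y, w = _profile_arrays(profile)
    est = AsymptoticRegression(init=init).fit(l, y, sample_weight=w)
    return est.to_asrfit()


def effect_metrics(fit: ASRFit, sqrt_se_S: bool = True) -> EffectMetrics:
    """Effect Size/Length and their delta-method standard errors from a fit.

    S_e = log2(d_max/d_min); L_e = ln2/c; saturation = 4·L_e.
    ``sqrt_se_S=False`` drops the radical from se(S_e), matching a variant
    transcription of the delta formula; the default applies it.
    A non-positive d_min leaves S_e/se undefined (NaN); d_min > d_max yields
    a negative S_e (species excluded downstream, not an error).
    """
    L_e = LN2 / fit.c
    se_K = fit.se_K
    first_order = LN2 * se_K * math.exp(-fit.K)
    se_L_e = first_order * (1.0 - se_K**2 / 4.0)
    if fit.d_min <= 0:
        S_e = float("nan")
        se_S_e = float("nan")
    else:
        S_e = math.log2(fit.d_max / fit.d_min)
        var_term = (
            fit.cov[1, 1] / fit.d_max**2
            + fit.cov[0, 0] / fit.d_min**2
            - 2.0 * fit.cov_dmax_dmin / (fit.d_max * fit.d_min)
        )
        var_term = max(var_term, 0.0)
        se_S_e = (math.sqrt(var_term) if sqrt_se_S else var_term) / LN2
    return EffectMetrics(
        S_e=S_e,
        L_e=L_e,
        se_S_e=se_S_e,
        se_L_e=se_L_e,
        se_L_e_first_order=first_order,
        saturation=4.0 * L_e,
    )


def observed_effect_size(profile: DiversityProfile | tuple, max_sites: int = 500) -> float:
    """Model-free effect size: log2(max mean diversity over the first
    ``max_sites`` positions / mean diversity at position 0).

    Returns +inf if the position-0 mean is zero.
    """
    l, y, _ = _profile_arrays(profile)
    if 0 not in l.astype(int):
        raise ValueError("profile lacks position 0")
    y0 = float(y[np.argmin(l)])
    window = y[l < max_sites]
    top = float(window.max())
    if y0 == 0:
        return float("inf")
    return math.log2(top / y0)
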