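"""Cross-species comparative statistics.

Effect Length and its covariates (recombination rate ratios r/m, rRNA counts,
codon-usage bias of highly expressed genes, doubling times, strain counts)
are compared across bacterial species with:

* Spearman rank correlations (average ranks, t-approximation p-values);
* Box-Cox transforms with profile-likelihood lambda selection;
* variance inflation factors to screen collinear predictors;
* multiple linear regression on standardized variables;
* backward elimination ranked by repeated k-fold cross-validated RMSE;
* phylogenetic generalized least squares with Pagel's lambda, which scales
  the off-diagonal entries of the Brownian-motion covariance implied by a
  species tree (lambda = 0: independent tips; lambda = 1: full Brownian
  covariance).  lambda is estimated by maximum likelihood with a
  profile-likelihood confidence interval; mildly negative values are allowed
  while the covariance stays positive definite.

Standard numerics are delegated: scipy for rank statistics and the Box-Cox
log-likelihood, statsmodels for OLS and VIF, scikit-learn for CV splitting.
The lambda-GLS machinery is implemented here on dendropy trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator
from sklearn.model_selection import RepeatedKFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

#: Sentinel reported for predictors that are perfectly collinear.
VIF_INF = float("inf")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Average-rank Spearman rho with its t-approximation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need >=3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def boxcox(x: Sequence[float], lmbda: float) -> np.ndarray:
    """Box-Cox transform: ln x at lambda=0, else (x^lambda - 1)/lambda."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda == 0:
        return np.log(x)
    return (np.power(x, lmbda) - 1.0) / lmbda


def boxcox_lambda(x: Sequence[float], grid: np.ndarray | None = None) -> float:
    """lambda maximizing the Box-Cox profile log-likelihood over a grid
    (default [-2, 2] in steps of 0.05)."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.05)
    ll = [sps.boxcox_llf(lm, x) for lm in grid]
    return float(grid[int(np.argmax(ll))])


def vif(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor 1/(1-R^2) per predictor column.

    Perfectly collinear columns are reported as +inf.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs >=2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs n > p")
    arr = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        with np.errstate(divide="ignore"):
            v = variance_inflation_factor(arr, j + 1)
        out[j] = VIF_INF if (not np.isfinite(v) or v > 1e12) else float(v)
    return out


@dataclass
class RegressionResult:
    """Coefficients on standardized variables plus fit/CV diagnostics."""

    predictors: list[str]
    coef: np.ndarray
    pvalues: np.ndarray
    r2: float
    rmse_cv: float | None = None
    mae_cv: float | None = None
    lambda_: float | None = None
    lambda_ci: tuple[float, float] | None = None
    n_obs: int = 0


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def scaled_ols(
    y: Sequence[float], X: pd.DataFrame | np.ndarray, names: list[str] | None = None
) -> RegressionResult:
    """OLS of z-scored response on z-scored predictors (with intercept).

    With a single predictor the standardized slope equals the Pearson r.
    """
    X = pd.DataFrame(X)
    if names is not None:
        X.columns = names
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    Xz = _zscore(X.to_numpy(dtype=float))
    yz = _zscore(y.reshape(-1, 1)).ravel()
    if np.linalg.matrix_rank(Xz) < p:
        raise ValueError("rank-deficient design")
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return RegressionResult(
        predictors=list(X.columns.astype(str)),
        coef=model.params[1:],
        pvalues=model.pvalues[1:],
        r2=float(model.rsquared),
        n_obs=n,
    )


def _cv_errors(
    y: np.ndarray, X: np.ndarray, k_folds: int, repeats: int, seed: int
) -> tuple[float, float]:
    """Mean out-of-fold RMSE and MAE of an OLS fit under repeated k-fold CV.

    Fold-level RMSE/MAE are averaged across all folds of all repeats.
    """
    splitter = RepeatedKFold(n_splits=k_folds, n_repeats=repeats, random_state=seed)
    rmses, maes = [], []
    Xc = np.column_stack([np.ones(len(y)), X])
    for train, test in splitter.split(Xc):
        beta, *_ = np.linalg.lstsq(Xc[train], y[train], rcond=None)
        resid = y[test] - Xc[test] @ beta
        rmses.append(np.sqrt(np.mean(resid**2)))
        maes.append(np.mean(np.abs(resid)))
    return float(np.mean(rmses)), float(np.mean(maes))


def backward_eliminate(
    y: Sequence[float],
    X: pd.DataFrame,
    k_folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> list[RegressionResult]:
    """Backward elimination ranked by repeated k-fold CV prediction RMSE.

    Starting from the full predictor set, the predictor whose removal yields
    the lowest mean out-of-fold RMSE is dropped at each level.  One result
    per predictor-count level is returned (largest model first), each with
    its CV RMSE/MAE and in-sample R² on standardized variables.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if len(y) < k_folds:
        raise ValueError("need n >= k_folds")
    yz = _zscore(y.reshape(-1, 1)).ravel()
    Xz = pd.DataFrame(_zscore(X.to_numpy(dtype=float)), columns=X.columns)
    # CV errors are reported on the original response scale for interpretability.
    current = list(X.columns)
    results: list[RegressionResult] = []

    def evaluate(cols: list[str]) -> RegressionResult:
        res = scaled_ols(y, X[cols])
        rmse, mae = _cv_errors(y, Xz[cols].to_numpy(), k_folds, repeats, seed)
        res.rmse_cv, res.mae_cv = rmse, mae
        return res

    results.append(evaluate(current))
    while len(current) > 1:
        best: RegressionResult | None = None
        for drop in current:
            cols = [c for c in current if c != drop]
            cand = evaluate(cols)
            if best is None or cand.rmse_cv < best.rmse_cv:
                best = cand
        assert best is not None
        current = best.predictors
        results.append(best)
    return results


def model_table(results: list[RegressionResult], all_predictors: list[str]) -> pd.DataFrame:
    """Flag-style summary table: one row per model with +/- predictor flags."""
    rows = []
    for i, r in enumerate(reversed(results), start=1):
        row = {p: ("+" if p in r.predictors else "-") for p in all_predictors}
        row.update({"model": i, "RMSE": r.rmse_cv, "R2": r.r2, "MAE": r.mae_cv})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phylogenetic GLS with Pagel's lambda
# ---------------------------------------------------------------------------


def tree_vcv(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance of tip values: C[i, j] = shared root-to-MRCA
    path length.  Works for non-ultrametric trees."""
    labels = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(labels[a], labels[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    return C


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    # tiny diagonal jitter guards Cholesky against rounding-level eigenvalues
    np.fill_diagonal(out, np.diag(C) * (1.0 + 1e-10))
    return out


def _gls_loglik(lam: float, C: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Profile log-likelihood of lambda (beta and sigma^2 profiled out)."""
    V = _lambda_cov(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    n = len(y)
    Li_X = np.linalg.solve(L, X)
    Li_y = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Li_X, Li_y, rcond=None)
    r = Li_y - Li_X @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)


def _lambda_lower_bound(C: np.ndarray, floor: float = -1.0) -> float:
    """Most negative lambda keeping the covariance positive definite."""

    def is_pd(lam: float) -> bool:
        try:
            np.linalg.cholesky(_lambda_cov(C, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    if is_pd(floor):
        return floor
    lo, hi = floor, 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if is_pd(mid):
            hi = mid
        else:
            lo = mid
    return hi


class PagelGLS(BaseEstimator):
    """GLS regression under a Pagel's-lambda phylogenetic covariance.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted species tree with branch lengths; tip labels must cover the
        rows of X/y (row order given by ``taxa`` at fit time).
    lam : float or "ml"
        Fix lambda, or estimate it by maximum likelihood over
        [lambda_min(tree)/2, lambda_max].  The default ceiling of 1.0 (full
        Brownian covariance) is deliberate: for ultrametric trees C(lambda)
        loses positive definiteness just above 1 and the profile likelihood
        develops a spurious boundary spike there, which would wreck interval
        calibration.  Mildly negative lambda remains admissible.

    Fitted attributes: ``coef_`` (including intercept first), ``pvalues_``,
    ``lambda_``, ``lambda_ci_``, ``loglik_``, ``sigma2_``,
    ``lambda_identifiable_``.
    """

    def __init__(self, tree: dendropy.Tree, lam: float | str = "ml", lambda_max: float = 1.0):
        self.tree = tree
        self.lam = lam
        self.lambda_max = lambda_max

    def fit(self, X, y, taxa: list[str] | None = None):
        X = pd.DataFrame(X)
        names = list(X.columns.astype(str))
        Xmat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        y = np.asarray(y, float)
        if taxa is None:
            taxa = list(X.index.astype(str))
        C = tree_vcv(self.tree, taxa)
        off = C[~np.eye(len(C), dtype=bool)]
        self.lambda_identifiable_ = bool(np.max(np.abs(off)) > 1e-12 * np.max(np.diag(C)))

        if self.lam == "ml":
            if not self.lambda_identifiable_:
                # star phylogeny: likelihood flat in lambda
                lam_hat = 0.0
                lam_ci = (float("nan"), float("nan"))
            else:
                # The profile likelihood develops a spurious spike as C(lambda)
                # approaches singularity (log-det divergence), so the search is
                # floored halfway between 0 and the positive-definiteness bound.
                lo = 0.5 * _lambda_lower_bound(C)
                # coarse grid guards against multimodal profiles, then a
                # bounded Brent refinement around the best grid cell
                grid = np.linspace(lo, self.lambda_max, 41)
                ll = np.array([_gls_loglik(g, C, Xmat, y) for g in grid])
                k = int(np.argmax(ll))
                b_lo = grid[max(k - 1, 0)]
                b_hi = grid[min(k + 1, len(grid) - 1)]
                res = minimize_scalar(
                    lambda lam: -_gls_loglik(lam, C, Xmat, y),
                    bounds=(b_lo, b_hi),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                # the bounded method never probes the box edges exactly
                candidates = [float(res.x), lo, self.lambda_max]
                lam_hat = max(candidates, key=lambda g: _gls_loglik(g, C, Xmat, y))
                lam_ci = self._profile_ci(C, Xmat, y, lam_hat, lo)
        else:
            lam_hat = float(self.lam)
            lam_ci = (lam_hat, lam_hat)

        V = _lambda_cov(C, lam_hat)
        L = np.linalg.cholesky(V)
        Li_X = np.linalg.solve(L, Xmat)
        Li_y = np.linalg.solve(L, y)
        beta, *_ = np.linalg.lstsq(Li_X, Li_y, rcond=None)
        r = Li_y - Li_X @ beta
        n, p = Xmat.shape
        sigma2 = float(r @ r) / (n - p)
        cov_beta = sigma2 * np.linalg.inv(Li_X.T @ Li_X)
        se = np.sqrt(np.diag(cov_beta))
        tvals = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df=n - p)

        self.predictors_ = names
        self.coef_ = beta
        self.se_ = se
        self.pvalues_ = pvals
        self.lambda_ = lam_hat
        self.lambda_ci_ = lam_ci
        self.sigma2_ = sigma2
        self.loglik_ = _gls_loglik(lam_hat, C, Xmat, y)
        self._C = C
        return self

    def _profile_ci(
        self, C, Xmat, y, lam_hat: float, lo: float, level: float = 0.95
    ) -> tuple[float, float]:
        """Profile-likelihood CI: lambda with logL >= max - chi2_1(level)/2."""
        cut = _gls_loglik(lam_hat, C, Xmat, y) - 0.5 * sps.chi2.ppf(level, 1)

        def bound(a: float, b: float) -> float:
            # find crossing of logL == cut between a (inside) and b (outside)
            fa = _gls_loglik(a, C, Xmat, y) - cut
            fb = _gls_loglik(b, C, Xmat, y) - cut
            if fb > 0:  # never drops below the cut before the box edge
                return b
            for _ in range(60):
                m = 0.5 * (a + b)
                if _gls_loglik(m, C, Xmat, y) - cut > 0:
                    a = m
                else:
                    b = m
            return 0.5 * (a + b)

        return (bound(lam_hat, lo), bound(lam_hat, self.lambda_max))


def pagel_gls(
    y: Sequence[float],
    X: pd.DataFrame,
    tree: dendropy.Tree,
    taxa: list[str] | None = None,
    lam: float | str = "ml",
) -> RegressionResult:
    """Convenience wrapper: fit PagelGLS and return a RegressionResult
    (coefficients exclude the intercept)."""
    est = PagelGLS(tree, lam=lam).fit(X, y, taxa=taxa)
    return RegressionResult(
        predictors=est.predictors_,
        coef=est.coef_[1:],
        pvalues=est.pvalues_[1:],
        r2=float("nan"),
        lambda_=est.lambda_,
        lambda_ci=est.lambda_ci_,
        n_obs=len(np.asarray(y)),
    )


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
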