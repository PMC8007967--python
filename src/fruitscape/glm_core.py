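"""Binomial-logit GLMs fitted by iteratively reweighted least squares.

The response is the per-cell pair (fleshy count, group richness), so cells
are weighted by their species numbers, as modelling percentages of species
with a binomial likelihood implies. Goodness of fit is McFadden's pseudo-R^2
(1 - loglik / null loglik); log-likelihoods include the binomial
normalizing constant so AIC/BIC are comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, expit, logit

from .cell_metrics import ModelFrame
from .spatial_stats import modified_ttest

__all__ = [
    "GLMFit",
    "SeparationError",
    "ConvergenceError",
    "fit_binomial_glm",
    "mcfadden_r2",
    "univariate_scan",
    "residual_diagnostics",
]

_EPS = 1e-12


class SeparationError(RuntimeError):
    """Fitted probabilities collapsed to 0/1; coefficients diverge."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class GLMFit:
    """Result of a binomial-logit GLM fit on standardized predictors."""

    coefficients: np.ndarray   # intercept first
    std_errors: np.ndarray
    names: list
    loglik: float
    loglik_null: float
    deviance: float
    aic: float
    bic: float
    mcfadden_r2: float
    fitted: np.ndarray         # fitted proportions
    deviance_residuals: np.ndarray
    n_cells: int
    n_iter: int

    @property
    def slopes(self) -> dict:
        return dict(zip(self.names[1:], self.coefficients[1:]))


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + k * np.log(p) + (n - k) * np.log(1 - p)))


def _deviance_residuals(k, n, p) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * p)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - p))), 0.0)
    d = 2 * (t1 + t2)
    d = np.maximum(d, 0.0)
    return np.sign(k / n - p) * np.sqrt(d)


def fit_binomial_glm(
    X: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    names: list | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Fit a binomial GLM with logit link by IRLS.

    ``X`` is the (possibly empty) matrix of predictors; an intercept column
    is prepended unless ``add_intercept`` is False. Convergence requires
    max |delta beta| < ``tol``. Raises on rank deficiency, separation, and
    non-convergence (with the iteration trace attached).
    """
    k = np.asarray(successes, float)
    n = np.asarray(totals, float)
    if (n < 1).any():
        raise ValueError("totals must be >= 1")
    if (k < 0).any() or (k > n).any():
        raise ValueError("successes must lie in [0, totals]")
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((len(k), 0))
    D = np.column_stack([np.ones(len(k)), X]) if add_intercept else X
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(X.shape[1])] if add_intercept else [
            f"x{j}" for j in range(X.shape[1])
        ]

    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(D)
        bad = [names[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-10 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient ({rank}/{D.shape[1]}); "
            f"suspect columns: {bad or 'unknown'}"
        )

    obs_p = np.clip((k + 0.5) / (n + 1.0), _EPS, 1 - _EPS)
    eta = logit(obs_p)
    beta = np.zeros(D.shape[1])
    trace = []
    converged = False
    for it in range(max_iter):
        p = expit(eta)
        if np.any(p < _EPS) or np.any(p > 1 - _EPS):
            raise SeparationError(
                "fitted proportions reached 0/1; complete or quasi-separation"
            )
        w = n * p * (1 - p)
        z = eta + (k - n * p) / w
        WD = D * w[:, None]
        beta_new = np.linalg.solve(D.T @ WD, D.T @ (w * z))
        delta = np.max(np.abs(beta_new - beta)) if it > 0 else np.inf
        trace.append(float(delta))
        beta = beta_new
        eta = D @ beta
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge; |delta beta| trace: {trace}")

    p = expit(D @ beta)
    w = n * p * (1 - p)
    cov = np.linalg.inv(D.T @ (D * w[:, None]))
    se = np.sqrt(np.diag(cov))

    ll = _binom_loglik(k, n, p)
    p0 = np.full_like(p, k.sum() / n.sum())
    ll0 = _binom_loglik(k, n, p0)
    ll_sat = _binom_loglik(k, n, np.clip(k / n, _EPS, 1 - _EPS))
    npar = D.shape[1]
    r2 = 0.0 if ll0 == 0 else 1.0 - ll / ll0
    return GLMFit(
        coefficients=beta,
        std_errors=se,
        names=list(names),
        loglik=ll,
        loglik_null=ll0,
        deviance=2 * (ll_sat - ll),
        aic=-2 * ll + 2 * npar,
        bic=-2 * ll + npar * np.log(len(k)),
        mcfadden_r2=r2,
        fitted=p,
        deviance_residuals=_deviance_residuals(k, n, p),
        n_cells=len(k),
        n_iter=it + 1,
    )


def mcfadden_r2(fit: GLMFit) -> float:
    """McFadden pseudo-R^2, 1 - loglik(model)/loglik(null).

    Undefined (returns nan) when the null log-likelihood is zero, i.e. the
    response is degenerate all-0 or all-1.
    """
    if fit.loglik_null == 0:
        return float("nan")
    return 1.0 - fit.loglik / fit.loglik_null


def univariate_scan(frame: ModelFrame, predictors: list | None = None,
                    n_classes: int = 13):
    """Single-predictor GLM per variable with spatially corrected p-values.

    Each row reports the standardized slope, McFadden R^2, and the p-value
    of the observed-proportion-vs-predictor correlation under the modified
    t-test (Dutilleul-corrected degrees of freedom), which replaces the
    naive GLM p in the presence of spatial autocorrelation.
    """
    import pandas as pd

    predictors = predictors or frame.predictors
    if len(frame.cell_ids) < 10:
        raise ValueError("univariate scan needs >= 10 retained cells")
    obs = frame.proportions
    rows = []
    for pname in predictors:
        x = frame.column(pname)
        fit = fit_binomial_glm(x[:, None], frame.successes, frame.totals,
                               names=["intercept", pname])
        mt = modified_ttest(obs, x, frame.centroids, n_classes=n_classes)
        rows.append(
            {
                "predictor": pname,
                "slope": fit.coefficients[1],
                "slope_se": fit.std_errors[1],
                "mcfadden_r2": fit.mcfadden_r2,
                "r_pearson": mt.r,
                "ess": mt.m_hat,
                "p_corrected": mt.p,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def residual_diagnostics(fit: GLMFit) -> dict:
    """Descriptive checks on deviance residuals (no pass/fail gate)."""
    r = fit.deviance_residuals
    f = fit.fitted
    slope = 0.0
    if np.std(f) > 0:
        slope = float(np.polyfit(f, r, 1)[0])
    return {
        "skewness": float(stats.skew(r)),
        "kurtosis_excess": float(stats.kurtosis(r)),
        "resid_vs_fitted_slope": slope,
        "max_abs_residual": float(np.max(np.abs(r))) if len(r) else 0.0,
    }
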