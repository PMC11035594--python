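"""Individual-level fits of the interaction and marginal regression models.

These are the models whose summary statistics the screen consumes:

* interaction model: ``y = b0 + b1*g + b2*e + b3*g*e + covariates + eps``
* marginal model:    ``y = a0 + a*g + covariates + eps``

Used for step-2 confirmation / replication on genotype data and by the
simulation engine's slow (individual-level) path.  Fits are ordinary
least squares with listwise deletion of missing rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionFit",
    "MarginalFit",
    "fit_interaction_model",
    "fit_marginal_model",
    "paired_marginal_main_fit",
    "correlation_main_vs_interaction",
]


@dataclass(frozen=True)
class InteractionFit:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se_beta1: float
    se_beta2: float
    se_beta3: float
    cov_beta1_beta3: float
    sigma2: float
    n: int
    direct: TestResult


@dataclass(frozen=True)
class MarginalFit:
    alpha0: float
    alpha: float
    se_alpha: float
    sigma2: float
    n: int
    p_value: float


def _listwise(arrays):
    stacked = np.column_stack(arrays)
    ok = np.all(np.isfinite(stacked), axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("listwise deletion removed %d row(s)", n_drop)
    return [a[ok] for a in arrays], n_drop


def _ols(y, X):
    """OLS via statsmodels with coefficient covariance; raises on rank
    deficiency (statsmodels silently pinv-fits singular designs)."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} parameters")
    if np.linalg.matrix_rank(X.T @ X) < p:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (constant environment or "
            "monomorphic genotype?)")
    res = sm.OLS(y, X).fit()
    return np.asarray(res.params), np.asarray(res.cov_params()), \
        float(res.mse_resid)


def _build_design(g, e=None, covariates=None):
    cols = [np.ones_like(g, dtype=float), np.asarray(g, dtype=float)]
    if e is not None:
        e = np.asarray(e, dtype=float)
        cols += [e, np.asarray(g, dtype=float) * e]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(g):
            cov = cov.T
        cols += [cov[:, j] for j in range(cov.shape[1])]
    return np.column_stack(cols)


def fit_interaction_model(y, g, e, covariates=None) -> InteractionFit:
    """OLS of the trait on [1, g, e, g*e, covariates] with the direct test.

    The direct interaction test is ``T = beta3_hat^2 / var(beta3_hat)``
    referred to chi-square(1), two-sided.  Returns coefficient estimates
    with SEs and the (beta1, beta3) covariance, which downstream
    consumers need because G and G*E are collinear in proportion to the
    environment mean.
    """
    arrays = [np.asarray(y, float), np.asarray(g, float), np.asarray(e, float)]
    if covariates is not None:
        arrays.append(np.asarray(covariates, float))
    (y, g, e, *rest), _ = _listwise(arrays)
    X = _build_design(g, e, rest[0] if rest else None)
    coef, cov, sigma2 = _ols(y, X)
    se = np.sqrt(np.diag(cov))
    stat = float(coef[3] ** 2 / cov[3, 3])
    p = float(stats.chi2.sf(stat, df=1))
    return InteractionFit(
        beta0=float(coef[0]), beta1=float(coef[1]), beta2=float(coef[2]),
        beta3=float(coef[3]), se_beta1=float(se[1]), se_beta2=float(se[2]),
        se_beta3=float(se[3]), cov_beta1_beta3=float(cov[1, 3]),
        sigma2=sigma2, n=len(y),
        direct=TestResult(stat, 1, p, "direct"))


def fit_marginal_model(y, g, covariates=None) -> MarginalFit:
    """OLS of the trait on [1, g, covariates]: the GWAS marginal model."""
    arrays = [np.asarray(y, float), np.asarray(g, float)]
    if covariates is not None:
        arrays.append(np.asarray(covariates, float))
    (y, g, *rest), _ = _listwise(arrays)
    X = _build_design(g, None, rest[0] if rest else None)
    coef, cov, sigma2 = _ols(y, X)
    z = coef[1] / np.sqrt(cov[1, 1])
    return MarginalFit(alpha0=float(coef[0]), alpha=float(coef[1]),
                       se_alpha=float(np.sqrt(cov[1, 1])), sigma2=sigma2,
                       n=len(y), p_value=float(2 * stats.norm.sf(abs(z))))


def paired_marginal_main_fit(y, g, e):
    """Fit both models on the same sample with their exact covariance.

    Both ``alpha_hat`` and ``beta1_hat`` are linear functionals of the
    same trait vector (``a'y`` and ``b'y``), so conditional on the
    design their sampling covariance is ``sigma^2 * a'b`` exactly.  The
    shared noise variance is taken from the richer interaction model,
    making the returned (se_alpha, se_beta1, r) internally consistent —
    the inputs needed to verify that the marginal-vs-main contrast with
    slope 1 reproduces the direct interaction test in-sample.

    Returns a dict with both fits, the consistent ses, and ``r``.
    """
    y = np.asarray(y, float)
    X1 = _build_design(np.asarray(g, float), np.asarray(e, float))
    X2 = _build_design(np.asarray(g, float))
    _, _, sigma2 = _ols(y, X1)
    a_vec = (np.linalg.inv(X2.T @ X2) @ X2.T)[1]   # alpha extractor
    rows = np.linalg.inv(X1.T @ X1) @ X1.T
    b_vec = rows[1]                                 # beta1 extractor
    c_vec = rows[3]                                 # beta3 extractor
    alpha = float(a_vec @ y)
    beta1 = float(b_vec @ y)
    beta3 = float(c_vec @ y)
    se_alpha = float(np.sqrt(sigma2 * (a_vec @ a_vec)))
    se_beta1 = float(np.sqrt(sigma2 * (b_vec @ b_vec)))
    se_beta3 = float(np.sqrt(sigma2 * (c_vec @ c_vec)))
    r = float((a_vec @ b_vec)
              / np.sqrt((a_vec @ a_vec) * (b_vec @ b_vec)))
    return {
        "alpha_hat": alpha, "se_alpha": se_alpha,
        "beta1_hat": beta1, "se_beta1": se_beta1,
        "beta3_hat": beta3, "se_beta3": se_beta3,
        "overlap_r": r, "sigma2": sigma2,
    }


def correlation_main_vs_interaction(z_beta1, z_beta3) -> float:
    """Empirical correlation of main-effect and interaction z-scores.

    Across replicate fits of the interaction model the two test
    statistics correlate as ``-mu_E / sqrt(mu_E^2 + sigma_E^2)``
    (cf. :func:`mrgxe.theory.main_interaction_corr`); this helper simply
    computes the empirical counterpart from >= 2 replicate z-scores.
    """
    z1 = np.asarray(z_beta1, dtype=float)
    z3 = np.asarray(z_beta3, dtype=float)
    if z1.size != z3.size or z1.size < 2:
        raise ValueError("need matched replicate z-score vectors")
    return float(np.corrcoef(z1, z3)[0, 1])
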