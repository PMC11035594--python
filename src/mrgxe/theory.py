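"""Closed-form expectations for the marginal-vs-main-effect contrast.

The quantities here describe what the inverse-variance-weighted slope
:math:`\\hat\\theta` (fitted by :func:`mrgxe.core.fit_ivw_theta`) and the
marginal/main effect gap look like in expectation, under standardized
genotypes (:math:`\\sigma_G^2 = 1`) and unit phenotype residual variance.
They serve as analytic oracles for the simulation engine: a simulated
cohort design should reproduce these values within Monte-Carlo error.

Notation
--------
alpha      marginal per-allele effect (model without the environment)
beta1..3   main genotype, environment, and interaction effects
rho        mediation contribution of the genotype acting through E
n1, n2, n0 GWAS, GWIS, and overlapping sample sizes
mu_e*, sigma_e*  environment mean / SD in the GWAS cohort (1), the GWIS
           cohort (2), and among the overlapping samples (0)
sigma_beta2  mean per-instrument explained trait variance,
           (1/m) * sum_j beta1_j^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sumstats import EnvProfile

__all__ = [
    "TheoryParams",
    "marginal_main_gap",
    "expected_theta",
    "expected_theta_from_effects",
    "main_interaction_corr",
    "var_alpha_hat",
]


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the expected-slope formulas.

    The closed forms were derived under standardized genotypes, unit
    phenotype residual variance, and valid instruments (no interaction,
    no mediation).  ``in_derivation_regime`` flags whether a parameter
    set satisfies the sample-size nesting the derivation assumes.
    """

    sigma_beta2: float
    n1: float
    n2: float
    n0: float
    env: EnvProfile
    rho: float = 0.0
    sigma_g1: float = 1.0
    m: int = 100

    def in_derivation_regime(self) -> bool:
        return (
            self.n0 <= min(self.n1, self.n2)
            and self.sigma_beta2 >= 0
            and self.rho == 0.0
        )


def marginal_main_gap(
    beta2: float,
    beta3: float,
    mu_e1: float,
    sigma_e1: float,
    sigma_g1: float = 1.0,
    rho: float = 0.0,
):
    """Expected gap ``alpha - beta1`` between marginal and main effects.

    The gap is ``(rho*sigma_e1/sigma_g1)*beta2 +
    (mu_e1 + rho*sigma_e1/sigma_g1)*beta3``: a variant with neither
    interaction (beta3 = 0) nor mediation (rho = 0) has identical
    marginal and main effects, which is what makes the contrast a
    genome-wide screen for the combined interaction + mediation signal.

    Parameters may be scalars or arrays (broadcast).
    """
    if np.any(np.asarray(sigma_g1) <= 0):
        raise ValueError("sigma_g1 must be positive")
    lam = rho * np.asarray(sigma_e1) / np.asarray(sigma_g1)
    return lam * np.asarray(beta2) + (np.asarray(mu_e1) + lam) * np.asarray(beta3)


def expected_theta(
    sigma_beta2,
    n1,
    n2,
    n0,
    mu_e2,
    sigma_e2,
    mu_e0=None,
    sigma_e0=None,
):
    """Expected IVW slope for valid instruments.

    ``E(theta_hat) = (sigma_beta2 + n0/(n1*n2)*(1 + mu_e0^2/sigma_e0^2))
    / (sigma_beta2 + 1/n2*(1 + mu_e2^2/sigma_e2^2))``.

    The denominator exceeds the numerator whenever ``n0 <= min(n1, n2)``,
    so the expected slope never exceeds 1; it converges to 1 as both
    sample sizes grow (weak-instrument attenuation vanishes).  When the
    overlap environment moments are not given they default to the GWIS
    cohort's, the natural case of a GWIS nested in the GWAS.

    All arguments broadcast, enabling dense parameter sweeps.
    """
    if mu_e0 is None:
        mu_e0 = mu_e2
    if sigma_e0 is None:
        sigma_e0 = sigma_e2
    sigma_beta2 = np.asarray(sigma_beta2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    num = sigma_beta2 + n0 / (n1 * n2) * (1.0 + np.square(mu_e0) / np.square(sigma_e0))
    den = sigma_beta2 + 1.0 / n2 * (1.0 + np.square(mu_e2) / np.square(sigma_e2))
    if np.any(den <= 0):
        raise ValueError("denominator of expected theta must be positive")
    out = num / den
    return float(out) if out.ndim == 0 else out


def expected_theta_from_effects(beta1, n1, n2, n0, mu_e2, sigma_e2,
                                mu_e0=None, sigma_e0=None):
    """Expected slope with per-instrument main effects supplied.

    Uses ``sigma_beta2 = mean(beta1_j^2)``, the average trait variance
    explained by one instrument under standardized genotypes.
    """
    beta1 = np.asarray(beta1, dtype=float)
    return expected_theta(np.mean(np.square(beta1)), n1, n2, n0,
                          mu_e2, sigma_e2, mu_e0, sigma_e0)


def main_interaction_corr(mu_e, sigma_e):
    """Correlation between the main-effect and interaction test statistics.

    Equals ``-mu_e / sqrt(mu_e^2 + sigma_e^2)``: the interaction regressor
    G*E is collinear with G in proportion to the environment mean, which
    is why single-model interaction tests lose power when E is far from
    zero-mean.
    """
    sigma_e = np.asarray(sigma_e, dtype=float)
    if np.any(sigma_e <= 0):
        raise ValueError("sigma_e must be positive")
    mu_e = np.asarray(mu_e, dtype=float)
    out = -mu_e / np.sqrt(np.square(mu_e) + np.square(sigma_e))
    return float(out) if out.ndim == 0 else out


def var_alpha_hat(n1, residual_var: float = 1.0):
    """Sampling variance of the marginal effect under standardization.

    ``var(alpha_hat_j) = residual_var / n1`` for standardized genotypes;
    reused by the fast summary-statistics generator.
    """
    return residual_var / np.asarray(n1, dtype=float)
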