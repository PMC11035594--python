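"""Shared fixtures: small summary-statistic tables and the session-scoped
simulation runs reused across calibration and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mrgxe


def make_gwas(rows) -> pd.DataFrame:
    """Build a GWAS table from dicts, filling sensible defaults."""
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, alpha_hat=0.1, se_alpha=0.01, p_value=1e-4,
                    n_eff=200_000)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_gwis(rows) -> pd.DataFrame:
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta1_hat=0.1, se_beta1=0.012, beta2_hat=0.05,
                    se_beta2=0.01, beta3_hat=0.01, se_beta3=0.01,
                    p_beta3=0.3, n_eff=120_000)
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def gwas_builder():
    return make_gwas


@pytest.fixture
def gwis_builder():
    return make_gwis


# --------------------------------------------------------------------------
# session-scoped simulation runs (shared between calibration and acceptance
# tests so each study condition is simulated once)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def design_a_run() -> mrgxe.SimOutput:
    """Design A at its reference condition: n1 = n2 = 20,000 fully
    overlapped, sigma_beta2 = 0.005, environment means 1, 500 replicates."""
    cfg = mrgxe.SimConfigA(n1=20_000, n2=20_000, overlap_fraction=1.0,
                           mu_e1=1.0, mu_e2=1.0, sigma_beta2=0.005)
    return mrgxe.simulate_design_a(cfg, n_reps=500, seed=1001)


@pytest.fixture(scope="session")
def design_b_gamma1_run() -> mrgxe.SimOutput:
    """Design B, mediation + interaction, gamma = 1, nested cohorts of
    equal size, 1000 replicates."""
    cfg = mrgxe.SimConfigB(n1=20_000, n2=20_000, mediation=True,
                           interaction=True, gamma=1.0)
    return mrgxe.simulate_design_b(cfg, n_reps=1000, seed=1002)


@pytest.fixture(scope="session")
def design_b_power_run() -> mrgxe.SimOutput:
    """Design B, mediation + interaction, gamma = sqrt(5), GWAS cohort of
    300,000 nesting the 20,000-sample GWIS cohort, 1000 replicates."""
    cfg = mrgxe.SimConfigB(n1=300_000, n2=20_000, mediation=True,
                           interaction=True, gamma=float(np.sqrt(5)))
    return mrgxe.simulate_design_b(cfg, n_reps=1000, seed=1003)


@pytest.fixture(scope="session")
def null_fast_run():
    """Fast-path null genome for calibration: 100 valid instruments plus a
    pure-null test variant, disjoint cohorts, 2000 replicates.

    Returns ``(sim, theta_hat_per_rep)`` with the slope refitted on the
    instruments in every replicate.
    """
    rng = np.random.default_rng(1004)
    m = 101
    beta1 = rng.normal(0.0, np.sqrt(0.005), m)
    beta1[-1] = 0.0                      # the held-out null test variant
    beta3 = np.zeros(m)
    env = mrgxe.EnvProfile(1.0, 1.0, 1.0, 1.0)
    sim = mrgxe.simulate_sumstats_fast(
        beta1, beta3, n1=20_000, n2=20_000, n0=0, env=env, beta2=0.1,
        n_reps=2000, seed=1005)
    theta = np.empty(sim.n_reps)
    for r in range(sim.n_reps):
        fit = mrgxe.fit_ivw_theta(sim.alpha_hat[r, :-1], sim.se_alpha[r, :-1],
                                  sim.beta1_hat[r, :-1], sim.se_beta1[r, :-1])
        theta[r] = fit.theta_hat
    return sim, theta
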