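"""The interaction/mediation screen: slope fitting and test statistics.

A variant with neither interaction nor mediation satisfies
``alpha = theta * beta1`` in expectation, where ``theta`` is the slope
linking GWIS main effects to GWAS marginal effects (1 when the two
studies measure the phenotype identically, attenuated below 1 by
weak-instrument noise).  Variants departing from that regression line
carry interaction and/or mediation signal — the exact analogue of
horizontally pleiotropic variants in Mendelian randomization.  The
module provides:

* :func:`fit_ivw_theta` — the closed-form inverse-variance-weighted slope;
* :func:`imrp_fit` — iterative refit with pleiotropy-style outlier removal;
* :func:`test_mr_gxe` / :func:`test_diff` — the chi-square(1) contrasts;
* :func:`estimate_interaction_effect` — the interaction effect implied by
  the residual and the GWAS environment mean;
* instrument selection with LD pruning and genomic-control utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MrFit",
    "TestResult",
    "InstrumentSelection",
    "estimate_overlap_correlation",
    "select_instruments",
    "fit_ivw_theta",
    "imrp_fit",
    "test_mr_gxe",
    "test_diff",
    "estimate_interaction_effect",
    "genomic_lambda",
]

_CHI2_1_MEDIAN = float(stats.chi2.median(df=1))


@dataclass
class MrFit:
    """A fitted marginal-on-main slope."""

    theta_hat: float
    se_theta: float
    instruments: list
    removed: list = field(default_factory=list)
    overlap_r: float = 0.0
    n_iter: int = 1

    def __post_init__(self):
        if set(self.instruments) & set(self.removed):
            raise ValueError("instruments and removed sets overlap")
        if not -1.0 <= self.overlap_r <= 1.0:
            raise ValueError("overlap_r outside [-1, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """A chi-square test outcome (`p_value` is the upper-tail probability)."""

    statistic: float
    df: int
    p_value: float
    label: str


@dataclass(frozen=True)
class InstrumentSelection:
    """Instrument-selection rules: genome-wide threshold plus LD pruning."""

    p_threshold: float = 5e-8
    prune_window_bp: int = 500_000
    prune_r2: float = 0.1
    gc_correct: bool = True

    def __post_init__(self):
        if not 0 < self.prune_r2 < 1:
            raise ValueError("prune_r2 must lie in (0, 1)")


def estimate_overlap_correlation(
    z_gwas: np.ndarray,
    z_gwis: np.ndarray,
    null_p_threshold: float = 0.05,
    min_null: int = 200,
) -> float:
    """Correlation between the two effect estimators induced by sample overlap.

    Computed as the Pearson correlation of the marginal and main-effect
    z-scores over the variants that are null in both sources (two-sided
    p above ``null_p_threshold``); for such variants the z-scores are
    pure noise, so their correlation estimates the estimator correlation
    needed by the variance of ``alpha_hat - theta*beta1_hat``.

    Raises ``ValueError`` if fewer than ``min_null`` null variants are
    available (lower the floor, or pass r = 0 explicitly for known
    disjoint cohorts), or if either z-score vector is degenerate.
    """
    z1 = np.asarray(z_gwas, dtype=float)
    z2 = np.asarray(z_gwis, dtype=float)
    p1 = 2.0 * stats.norm.sf(np.abs(z1))
    p2 = 2.0 * stats.norm.sf(np.abs(z2))
    mask = (p1 > null_p_threshold) & (p2 > null_p_threshold)
    if mask.sum() < min_null:
        raise ValueError(
            f"only {int(mask.sum())} null variants (need >= {min_null}); "
            "lower min_null or supply overlap_r directly")
    a, b = z1[mask], z2[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate z-scores: zero variance in null set")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _pairwise_r2(ld_ref, v1, v2) -> float | None:
    """r^2 between two variants from whatever LD source was supplied."""
    if ld_ref is None:
        return None
    if callable(ld_ref):
        return ld_ref(v1, v2)
    if isinstance(ld_ref, pd.DataFrame):  # reference genotype matrix
        if v1 not in ld_ref.columns or v2 not in ld_ref.columns:
            return None
        c = np.corrcoef(ld_ref[v1], ld_ref[v2])[0, 1]
        return float(c * c)
    key = frozenset((v1, v2))
    return ld_ref.get(key)  # dict of precomputed r^2


def select_instruments(
    table: pd.DataFrame,
    sel: InstrumentSelection | None = None,
    ld_ref=None,
) -> list:
    """Greedy p-value-ordered LD pruning of genome-wide significant variants.

    Candidates are variants with GWAS p below ``sel.p_threshold`` (after
    genomic-control correction when ``sel.gc_correct``, dividing the
    chi-square statistics by the inflation factor of the full table).  A
    candidate is kept iff its r^2 with every already-kept variant within
    ``sel.prune_window_bp`` is below ``sel.prune_r2``.  ``ld_ref`` may be
    a reference genotype DataFrame (columns = variant ids), a dict of
    pairwise r^2 keyed by frozenset pairs, or a callable; with no LD
    source, pruning is window-only (one variant per window) with a
    warning.  Ties order by ascending p then ascending position.
    """
    sel = sel or InstrumentSelection()
    p = table["p_value"].to_numpy(dtype=float)
    if sel.gc_correct:
        lam = genomic_lambda(p_values=p)
        if lam > 1.0:
            chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1) / lam
            p = stats.chi2.sf(chi2, df=1)
    cand = table.assign(_p_gc=p).loc[p < sel.p_threshold]
    if cand.empty:
        raise ValueError("no genome-wide significant candidate instruments")
    if ld_ref is None:
        logger.warning("select_instruments: no LD reference; "
                       "falling back to distance-only pruning")
    cand = cand.sort_values(["_p_gc", "pos"], kind="mergesort")

    kept: list = []
    kept_pos: list[tuple[str, int]] = []
    for row in cand.itertuples():
        ok = True
        for kv, (kc, kp) in zip(kept, kept_pos):
            if str(row.chrom) != kc or abs(int(row.pos) - kp) > sel.prune_window_bp:
                continue
            r2 = _pairwise_r2(ld_ref, row.variant_id, kv)
            if r2 is None or r2 >= sel.prune_r2:
                ok = False
                break
        if ok:
            kept.append(row.variant_id)
            kept_pos.append((str(row.chrom), int(row.pos)))
    return kept


def _residual_variance(se_alpha, se_beta1, theta, overlap_r):
    """var(alpha_hat - theta*beta1_hat) under a scalar overlap correlation."""
    se_alpha = np.asarray(se_alpha, dtype=float)
    se_beta1 = np.asarray(se_beta1, dtype=float)
    return (se_alpha**2 + theta**2 * se_beta1**2
            - 2.0 * theta * overlap_r * se_alpha * se_beta1)


def fit_ivw_theta(
    alpha_hat,
    se_alpha,
    beta1_hat,
    se_beta1,
    overlap_r: float = 0.0,
    instruments=None,
) -> MrFit:
    """Closed-form inverse-variance-weighted slope of marginal on main effects.

    Minimizes ``(1/m) * sum_j (alpha_j - theta*beta1_j)^2 / var(alpha_j)``
    whose minimizer is ``theta_hat = sum w_j alpha_j beta1_j /
    sum w_j beta1_j^2`` with ``w_j = 1/var(alpha_j)``.  The standard
    error is the sandwich over instruments, propagating
    ``var(alpha_j - theta*beta1_j)`` (including the overlap covariance)
    through the estimating equation.
    """
    a = np.asarray(alpha_hat, dtype=float)
    sa = np.asarray(se_alpha, dtype=float)
    b = np.asarray(beta1_hat, dtype=float)
    sb = np.asarray(se_beta1, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one instrument")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / sa**2
    denom = np.sum(w * b**2)
    if denom == 0:
        raise ZeroDivisionError("all main effects are zero: slope undefined")
    theta = float(np.sum(w * a * b) / denom)
    v = _residual_variance(sa, sb, theta, overlap_r)
    var_theta = float(np.sum(w**2 * b**2 * v) / denom**2)
    ids = list(instruments) if instruments is not None else list(range(a.size))
    return MrFit(theta_hat=theta, se_theta=float(np.sqrt(max(var_theta, 0.0))),
                 instruments=ids, overlap_r=float(overlap_r))


def ivw_objective(theta, alpha_hat, se_alpha, beta1_hat):
    """The IVW least-squares objective; exposed for numeric cross-checks."""
    a = np.asarray(alpha_hat, float)
    b = np.asarray(beta1_hat, float)
    v = np.asarray(se_alpha, float) ** 2
    return float(np.mean((a - b * theta) ** 2 / v))


def imrp_fit(
    alpha_hat,
    se_alpha,
    beta1_hat,
    se_beta1,
    overlap_r: float = 0.0,
    instruments=None,
    removal_alpha: float = 0.05,
    max_iter: int = 50,
) -> MrFit:
    """Iterative slope refit with pleiotropy-style instrument removal.

    Repeats {fit the IVW slope on the current instrument set; test every
    current instrument for departure from the line; remove those with
    p < removal_alpha / |set| (Bonferroni)} until the set stabilizes or
    ``max_iter`` is reached.  Instruments carrying interaction or
    mediation signal are thereby excluded from the slope, exactly as
    horizontally pleiotropic variants are excluded in MR.
    """
    if not 0 < removal_alpha < 1:
        raise ValueError("removal_alpha must lie in (0, 1)")
    a = np.asarray(alpha_hat, dtype=float)
    sa = np.asarray(se_alpha, dtype=float)
    b = np.asarray(beta1_hat, dtype=float)
    sb = np.asarray(se_beta1, dtype=float)
    ids = np.asarray(list(instruments) if instruments is not None
                     else range(a.size))
    active = np.ones(a.size, dtype=bool)
    fit = None
    for it in range(1, max_iter + 1):
        if not active.any():
            raise ValueError("all instruments removed during iteration")
        fit = fit_ivw_theta(a[active], sa[active], b[active], sb[active],
                            overlap_r=overlap_r)
        stat, p = _mr_gxe_arrays(a[active], sa[active], b[active], sb[active],
                                 fit.theta_hat, overlap_r)
        drop = p < removal_alpha / active.sum()
        if not drop.any():
            break
        idx = np.flatnonzero(active)
        active[idx[drop]] = False
    assert fit is not None
    return MrFit(theta_hat=fit.theta_hat, se_theta=fit.se_theta,
                 instruments=list(ids[active]),
                 removed=list(ids[~active]),
                 overlap_r=float(overlap_r), n_iter=it)


def _mr_gxe_arrays(alpha_hat, se_alpha, beta1_hat, se_beta1, theta, overlap_r):
    v = _residual_variance(se_alpha, se_beta1, theta, overlap_r)
    if np.any(v <= 0):
        raise ValueError(
            f"non-positive residual variance; overlap_r={overlap_r} too "
            "large in magnitude for these standard errors")
    stat = (np.asarray(alpha_hat, float)
            - theta * np.asarray(beta1_hat, float)) ** 2 / v
    return stat, stats.chi2.sf(stat, df=1)


def test_mr_gxe(
    alpha_hat,
    se_alpha,
    beta1_hat,
    se_beta1,
    theta_hat: float,
    overlap_r: float = 0.0,
):
    """The interaction/mediation screen statistic.

    ``T = (alpha - theta*beta1)^2 / var(alpha - theta*beta1)`` referred
    to chi-square(1); the variance is ``se_alpha^2 + theta^2*se_beta1^2
    - 2*theta*r*se_alpha*se_beta1`` with ``r`` the estimator correlation
    induced by sample overlap.  The two-sided p-value is equivalently
    the normal two-tail probability of the signed z-score.  The slope is
    treated as fixed (its estimation error is negligible when fitted on
    many instruments).

    Scalar inputs return a :class:`TestResult`; array inputs return
    ``(statistic, p_value)`` arrays.
    """
    stat, p = _mr_gxe_arrays(alpha_hat, se_alpha, beta1_hat, se_beta1,
                             theta_hat, overlap_r)
    if np.ndim(stat) == 0:
        return TestResult(float(stat), 1, float(p), "MR_GxE")
    return stat, p


def test_diff(alpha_hat, se_alpha, beta1_hat, se_beta1, overlap_r: float = 0.0):
    """Marginal-vs-main contrast with the slope pinned at 1.

    Identical to :func:`test_mr_gxe` with ``theta = 1``; when GWAS and
    GWIS are fitted in the same sample this is equivalent to the direct
    interaction test.
    """
    stat, p = _mr_gxe_arrays(alpha_hat, se_alpha, beta1_hat, se_beta1,
                             1.0, overlap_r)
    if np.ndim(stat) == 0:
        return TestResult(float(stat), 1, float(p), "diff")
    return stat, p


def estimate_interaction_effect(
    alpha_hat,
    se_alpha,
    beta1_hat,
    se_beta1,
    theta_hat: float,
    mu_e1: float,
    overlap_r: float = 0.0,
):
    """Interaction effect implied by the screen residual.

    Under no mediation the residual ``alpha - theta*beta1`` equals
    ``mu_e1 * beta3``, so ``(alpha - theta*beta1)/mu_e1`` estimates the
    interaction coefficient using only summary statistics.  Undefined at
    ``mu_e1 = 0``: a zero-mean environment leaves no interaction imprint
    on the marginal effect.

    Returns ``(estimate, se)`` (arrays broadcast).
    """
    if mu_e1 == 0:
        raise ValueError("mu_e1 = 0: interaction effect not identifiable "
                         "from the marginal-main gap")
    resid = np.asarray(alpha_hat, float) - theta_hat * np.asarray(beta1_hat, float)
    v = _residual_variance(se_alpha, se_beta1, theta_hat, overlap_r)
    est = resid / mu_e1
    se = np.sqrt(v) / abs(mu_e1)
    if np.ndim(est) == 0:
        return float(est), float(se)
    return est, se


def genomic_lambda(statistics=None, p_values=None) -> float:
    """Genomic-control inflation factor.

    ``lambda = median(chi-square statistics) / median(chi-square_1)``.
    Pass 1-df chi-square ``statistics`` directly, or two-sided
    ``p_values`` (converted through the chi-square(1) quantile).
    """
    if statistics is None and p_values is None:
        raise ValueError("provide statistics or p_values")
    if statistics is None:
        p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
        statistics = stats.chi2.isf(p, df=1)
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size == 0:
        raise ValueError("empty input")
    return float(np.median(statistics) / _CHI2_1_MEDIAN)
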