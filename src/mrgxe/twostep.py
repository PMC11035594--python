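"""Genome-wide screen-then-confirm orchestration.

Step 1 screens every variant with the marginal-vs-main contrast at the
genome-wide level (5e-8 by default); step 2 applies the direct
interaction test to the X independent surviving signals at the
Bonferroni level ``0.05/(X * n_exposures)``.  The two steps are not
independent when computed in overlapping data, so in-sample step-2
results are labelled "non-independent confirmation"; only a separate
dataset earns the label "replication".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MrFit, TestResult, _pairwise_r2, genomic_lambda, test_mr_gxe

logger = logging.getLogger(__name__)

__all__ = [
    "LocusCluster",
    "TwoStepConfig",
    "screen_genome",
    "define_loci",
    "step2_confirm",
    "combine_replication_p",
    "cross_population_effect_correlation",
]

_TINY_P = 1e-300  # keeps the chi-square tail representable after -2*ln(p)


@dataclass
class LocusCluster:
    """One screened locus: a lead variant, its +/- 1 Mb members, and the
    LD-independent signals among them."""

    lead_variant: object
    members: list
    independent_signals: list

    def __post_init__(self):
        if not set(self.independent_signals) <= set(self.members):
            raise ValueError("signals must be a subset of members")


@dataclass(frozen=True)
class TwoStepConfig:
    screen_p: float = 5e-8
    step2_family_alpha: float = 0.05
    n_exposures: int = 4
    locus_window_bp: int = 1_000_000
    signal_r2: float = 0.1
    count_loci: bool = False  # X counts signals by default, not loci

    def __post_init__(self):
        if not (0 < self.screen_p < 1 and 0 < self.step2_family_alpha < 1):
            raise ValueError("thresholds must lie in (0, 1)")


def screen_genome(table: pd.DataFrame, fit: MrFit,
                  overlap_r: float | None = None) -> pd.DataFrame:
    """Apply the screen statistic to every harmonized variant.

    Adds ``mr_gxe_stat`` and ``mr_gxe_p`` columns and reports the
    genomic-control lambda of the screen in ``attrs["lambda_gc"]``.
    An empty table passes through empty.
    """
    out = table.copy()
    if out.empty:
        out["mr_gxe_stat"] = pd.Series(dtype=float)
        out["mr_gxe_p"] = pd.Series(dtype=float)
        out.attrs["lambda_gc"] = np.nan
        return out
    r = fit.overlap_r if overlap_r is None else overlap_r
    stat, p = test_mr_gxe(
        out["alpha_hat"].to_numpy(), out["se_alpha"].to_numpy(),
        out["beta1_hat"].to_numpy(), out["se_beta1"].to_numpy(),
        fit.theta_hat, r)
    out["mr_gxe_stat"] = stat
    out["mr_gxe_p"] = p
    out.attrs = dict(table.attrs)
    out.attrs["lambda_gc"] = genomic_lambda(statistics=stat)
    out.attrs["theta_hat"] = fit.theta_hat
    return out


def define_loci(
    screen: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_bp: int = 1_000_000,
    r2_threshold: float = 0.1,
    ld_ref=None,
) -> list[LocusCluster]:
    """Cluster significant variants into loci and LD-independent signals.

    Greedy: the most significant unassigned variant founds a locus and
    absorbs every significant variant within ``window_bp`` on the same
    chromosome; within a locus, signals are retained in ascending-p
    order subject to pairwise r^2 below ``r2_threshold``.  With no LD
    source each locus contributes a single signal (its lead), with a
    warning.  The loci partition the significant variants.
    """
    sig = screen.loc[screen["mr_gxe_p"] < p_threshold]
    if sig.empty:
        return []
    if ld_ref is None:
        logger.warning("define_loci: no LD reference; one signal per locus")
    sig = sig.sort_values(["mr_gxe_p", "pos"], kind="mergesort")
    unassigned = sig.copy()
    loci: list[LocusCluster] = []
    while not unassigned.empty:
        lead = unassigned.iloc[0]
        near = (unassigned["chrom"] == lead["chrom"]) & \
               ((unassigned["pos"] - lead["pos"]).abs() <= window_bp)
        members = unassigned.loc[near]
        signals: list = []
        sig_pos: list[int] = []
        for row in members.itertuples():
            if not signals:
                signals.append(row.variant_id)
                sig_pos.append(int(row.pos))
                continue
            if ld_ref is None:
                continue
            r2s = [_pairwise_r2(ld_ref, row.variant_id, s) for s in signals]
            if all(r2 is not None and r2 < r2_threshold for r2 in r2s):
                signals.append(row.variant_id)
                sig_pos.append(int(row.pos))
        loci.append(LocusCluster(
            lead_variant=lead["variant_id"],
            members=list(members["variant_id"]),
            independent_signals=signals))
        unassigned = unassigned.loc[~near]
    return loci


def step2_confirm(
    signals: pd.DataFrame,
    n_exposures: int = 4,
    family_alpha: float = 0.05,
    p_column: str = "direct_p",
) -> tuple[pd.DataFrame, float]:
    """Direct-test confirmation of the screened signals.

    ``signals`` holds one row per independent screened signal with its
    direct-test p-value in ``p_column``.  The threshold is
    ``family_alpha / (X * n_exposures)`` with X recomputed from the
    realized table — e.g. 17 signals over 4 exposures gives 7.35e-4, and
    an 8-signal replication family over 4 exposures gives 1.56e-3.
    Returns the passing subset and the threshold used.  Results computed
    in data overlapping step 1 are a non-independent confirmation, not a
    replication.
    """
    x = len(signals)
    if x < 1:
        raise ValueError("need at least one screened signal")
    threshold = family_alpha / (x * n_exposures)
    passed = signals.loc[signals[p_column] < threshold].copy()
    return passed, threshold


def combine_replication_p(p_discovery: float, p_replication: float,
                          method: str = "fisher") -> TestResult:
    """Combine discovery and replication direct-test p-values.

    The default is Fisher's method: ``-2*(ln p1 + ln p2)`` referred to
    chi-square with 4 degrees of freedom.  ``method="sum_z2"`` instead
    sums the squared normal quantiles of the two-sided p-values and
    refers the total to chi-square(2); the two combinations agree in
    ordering but not numerically.  Zero p-values are clipped to the
    smallest positive float with a warning.
    """
    ps = []
    for p in (p_discovery, p_replication):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0:
            logger.warning("combine_replication_p: clipping p = 0")
            p = _TINY_P
        ps.append(p)
    if method == "fisher":
        stat = float(-2.0 * (np.log(ps[0]) + np.log(ps[1])))
        df = 4
    elif method == "sum_z2":
        stat = float(stats.norm.isf(ps[0] / 2) ** 2
                     + stats.norm.isf(ps[1] / 2) ** 2)
        df = 2
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return TestResult(stat, df, float(stats.chi2.sf(stat, df=df)), "combined")


@dataclass(frozen=True)
class CrossPopulationCorrelation:
    corr_flagged: float | None
    corr_unflagged: float
    percent_drop: float | None


def cross_population_effect_correlation(
    effects_pop_a,
    effects_pop_b,
    flagged: np.ndarray,
    min_group: int = 10,
) -> CrossPopulationCorrelation:
    """Compare cross-population effect-size correlations by flag status.

    Environment distributions differ between populations, so marginal
    effects of interaction/mediation variants are expected to correlate
    less across populations than those of unflagged variants.  Returns
    Pearson correlations for the flagged and unflagged groups and
    ``percent_drop = 100*(1 - corr_flagged/corr_unflagged)``; with an
    empty flagged set the drop is undefined (None).
    """
    a = np.asarray(effects_pop_a, dtype=float)
    b = np.asarray(effects_pop_b, dtype=float)
    flagged = np.asarray(flagged, dtype=bool)
    if a.shape != b.shape or a.shape != flagged.shape:
        raise ValueError("effect vectors and flag mask must align")

    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("degenerate effect-size variance")
        return float(np.corrcoef(x, y)[0, 1])

    if (~flagged).sum() < min_group:
        raise ValueError(f"need >= {min_group} unflagged variants")
    corr_un = _corr(a[~flagged], b[~flagged])
    if flagged.sum() == 0:
        return CrossPopulationCorrelation(None, corr_un, None)
    if flagged.sum() < min_group:
        raise ValueError(f"need >= {min_group} flagged variants")
    corr_fl = _corr(a[flagged], b[flagged])
    drop = 100.0 * (1.0 - corr_fl / corr_un)
    return CrossPopulationCorrelation(corr_fl, corr_un, drop)
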