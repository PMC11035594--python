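"""Reading, validation, and harmonization of GWAS / GWIS summary statistics.

The screen contrasts marginal effects from a GWAS (model without the
environment) against main effects from a GWIS (model with environment and
interaction terms), so the two summary-statistic tables must first be
placed on a common allele frame.  Harmonization follows the usual rules
for meta-analysis of summary statistics: flip effect signs when the
effect alleles are swapped, drop strand-ambiguous (A/T, C/G) variants,
and discard variants whose minor-allele frequencies disagree between the
two sources.

Tables are plain pandas DataFrames with canonical column names (see
``GWAS_COLUMNS`` / ``GWIS_COLUMNS``); every dropped row is attributed to
exactly one reason code, and the per-reason counts are carried on
``DataFrame.attrs["drop_log"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GWAS_COLUMNS",
    "GWIS_COLUMNS",
    "EnvProfile",
    "QcConfig",
    "read_sumstats",
    "harmonize",
    "exclude_environment_loci",
    "standardize_effects",
    "write_table",
]

#: canonical columns of a GWAS (marginal-effect) table
GWAS_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "alpha_hat", "se_alpha", "p_value", "n_eff",
)

#: canonical columns of a GWIS (main/interaction-effect) table
GWIS_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta1_hat", "se_beta1", "beta2_hat", "se_beta2",
    "beta3_hat", "se_beta3", "p_beta3", "n_eff",
)

_OPTIONAL_GWIS = ("cov_beta1_beta3",)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class EnvProfile:
    """Environment moments in the GWAS cohort (1), the GWIS cohort (2),
    and among their overlapping samples (0)."""

    mu_e1: float
    sigma_e1: float
    mu_e2: float
    sigma_e2: float
    mu_e0: float | None = None
    sigma_e0: float | None = None

    def __post_init__(self):
        for name in ("sigma_e1", "sigma_e2", "sigma_e0"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.mu_e0 is None:
            object.__setattr__(self, "mu_e0", self.mu_e2)
        if self.sigma_e0 is None:
            object.__setattr__(self, "sigma_e0", self.sigma_e2)


@dataclass(frozen=True)
class QcConfig:
    """Row-filtering rules applied during harmonization.

    maf_diff_max
        largest tolerated minor-allele-frequency difference between the
        two sources for id-matched variants.
    maf_diff_positional_max
        stricter MAF bound for variants matched by chromosome position
        only (guards against joining distinct multi-allelic variants).
    min_n_primary / min_n_secondary
        effective-sample-size floors for the GWAS and GWIS source.
    exclusion_window_bp / exclusion_p
        defaults for :func:`exclude_environment_loci`.
    """

    maf_diff_max: float = 0.15
    maf_diff_positional_max: float = 0.01
    min_n_primary: float = 100_000
    min_n_secondary: float = 30_000
    drop_palindromic: bool = True
    exclusion_window_bp: int = 1_000_000
    exclusion_p: float = 5e-7
    adjusted_for_env: bool = False  # carried as metadata, not acted on

    def __post_init__(self):
        if not (0 < self.maf_diff_positional_max <= self.maf_diff_max < 0.5):
            raise ValueError(
                "need 0 < maf_diff_positional_max <= maf_diff_max < 0.5"
            )


def _required_columns(role: str) -> tuple[str, ...]:
    if role == "gwas":
        return GWAS_COLUMNS
    if role == "gwis":
        return GWIS_COLUMNS
    raise ValueError(f"role must be 'gwas' or 'gwis', got {role!r}")


def read_sumstats(
    path: str | Path,
    role: str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Header-bearing delimited text file (tab or whitespace; ``sep``
        overrides auto-detection).
    role
        ``"gwas"`` (marginal effects) or ``"gwis"`` (main/interaction).
    column_map
        Mapping from canonical names to the file's column names, e.g.
        ``{"alpha_hat": "BETA", "se_alpha": "SE"}``.  Unmapped canonical
        names are assumed to appear verbatim.

    Rows violating type invariants (non-positive SEs, allele frequency
    outside (0, 1), p-value outside (0, 1], non-finite effects) are
    dropped; counts are logged and stored in ``attrs["drop_log"]``.
    Missing allele frequencies are retained (NaN) and handled leniently
    downstream.  A missing mandatory column raises ``KeyError``; an
    empty file raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    read_kwargs = dict(sep=sep) if sep is not None else dict(
        sep=None, engine="python")
    df = pd.read_csv(path, **read_kwargs)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    required = _required_columns(role)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"missing mandatory column(s) {missing} in {path}")
    keep = [c for c in required + _OPTIONAL_GWIS if c in df.columns]
    df = df.loc[:, keep].copy()

    numeric = [c for c in keep if c not in
               ("variant_id", "chrom", "effect_allele", "other_allele")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype("Int64")
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    ses = [c for c in keep if c.startswith("se_")]
    ps = [c for c in keep if c.startswith("p_")]
    for c in ps:
        # p printed as exactly 0 is floating underflow, not a bad record
        n_clip = int((df[c] == 0).sum())
        if n_clip:
            logger.info("read_sumstats(%s): clipped %d underflowed "
                        "p-value(s) in %s", path, n_clip, c)
            df.loc[df[c] == 0, c] = np.nextafter(0.0, 1.0)
    effects = [c for c in keep if c.endswith("_hat")]
    ok = df["pos"].notna() & (df["n_eff"] > 0)
    for c in ses:
        ok &= df[c] > 0
    for c in ps:
        ok &= (df[c] > 0) & (df[c] <= 1)
    for c in effects:
        ok &= np.isfinite(df[c])
    # eaf may be missing, but if present must lie strictly in (0, 1)
    ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))

    dropped = int((~ok).sum())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid row(s)", path, dropped)
    out = df.loc[ok].reset_index(drop=True)
    out.attrs["drop_log"] = {"invalid_record": dropped}
    out.attrs["role"] = role
    return out


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(lambda a: "".join(_COMPLEMENT.get(b, "N") for b in a[::-1])
                       if isinstance(a, str) else a)


def _maf(eaf):
    return np.minimum(eaf, 1.0 - eaf)


def harmonize(
    gwas: pd.DataFrame,
    gwis: pd.DataFrame,
    qc: QcConfig | None = None,
) -> pd.DataFrame:
    """Allele-align and QC-join a GWAS table with a GWIS table.

    Join preference is exact ``variant_id`` match; variants unmatched by
    id fall back to a positional ``(chrom, pos)`` join, which requires a
    MAF difference below ``qc.maf_diff_positional_max`` (ties at one
    position resolve to the smallest MAF difference).  GWIS effect signs
    are negated and its EAF complemented when its effect allele is the
    GWAS other allele (directly or on the opposite strand); A/T and C/G
    variants are removed when ``qc.drop_palindromic``; rows whose
    minor-allele frequencies differ by more than ``qc.maf_diff_max``, or
    whose effective sample sizes fall below the per-source floors, are
    removed.

    Returns the harmonized table in GWAS allele orientation, with
    ``flipped`` and ``positional_match`` flags and a ``drop_log`` in
    ``attrs`` in which every dropped GWAS-side row is counted exactly
    once.
    """
    qc = qc or QcConfig()
    if gwas.empty or gwis.empty:
        raise ValueError("both input tables must be non-empty")

    g1 = gwas.reset_index(drop=True).copy()
    g2 = gwis.reset_index(drop=True).copy()
    g2 = g2.rename(columns={
        "effect_allele": "ea_gwis", "other_allele": "oa_gwis",
        "eaf": "eaf_gwis", "chrom": "chrom_gwis", "pos": "pos_gwis",
        "n_eff": "n_eff_gwis",
    })
    g1 = g1.rename(columns={"eaf": "eaf_gwas", "n_eff": "n_eff_gwas"})

    exact = g1.merge(g2, on="variant_id", how="inner")
    exact["positional_match"] = False

    # positional fallback for ids unmatched on either side
    left_rest = g1[~g1["variant_id"].isin(exact["variant_id"])]
    right_rest = g2[~g2["variant_id"].isin(exact["variant_id"])]
    pos_join = left_rest.merge(
        right_rest, left_on=["chrom", "pos"],
        right_on=["chrom_gwis", "pos_gwis"],
        how="inner", suffixes=("", "_y"),
    )
    n_positional_maf = 0
    if not pos_join.empty:
        both_eaf = pos_join["eaf_gwas"].notna() & pos_join["eaf_gwis"].notna()
        maf_diff = (_maf(pos_join["eaf_gwas"]) - _maf(pos_join["eaf_gwis"])).abs()
        pos_join = pos_join.assign(_maf_diff=maf_diff.where(both_eaf, np.inf))
        pos_join = pos_join.sort_values("_maf_diff").drop_duplicates(
            subset=["chrom", "pos"], keep="first")
        close = pos_join["_maf_diff"] < qc.maf_diff_positional_max
        n_positional_maf = int((~close).sum())
        pos_join = pos_join.loc[close].drop(columns="_maf_diff")
        pos_join = pos_join.rename(columns={"variant_id": "variant_id"})
        pos_join["positional_match"] = True
    cols = list(exact.columns)
    tbl = pd.concat([exact, pos_join.reindex(columns=cols)], ignore_index=True) \
        if not pos_join.empty else exact
    if tbl.empty:
        raise ValueError("zero overlapping variants between GWAS and GWIS tables")

    drop_log: dict[str, int] = {
        "unmatched_gwas": int(len(g1) - len(tbl) - n_positional_maf),
        "positional_maf": n_positional_maf,
    }

    # --- allele alignment (GWAS orientation is the reference frame) ---
    ea1, oa1 = tbl["effect_allele"], tbl["other_allele"]
    ea2, oa2 = tbl["ea_gwis"], tbl["oa_gwis"]
    same = (ea1 == ea2) & (oa1 == oa2)
    swapped = (ea1 == oa2) & (oa1 == ea2)
    cea2, coa2 = _complement(ea2), _complement(oa2)
    strand_same = ~same & ~swapped & (ea1 == cea2) & (oa1 == coa2)
    strand_swap = ~same & ~swapped & (ea1 == coa2) & (oa1 == cea2)
    resolvable = same | swapped | strand_same | strand_swap
    flip = swapped | strand_swap

    drop_log["allele_mismatch"] = int((~resolvable).sum())
    tbl = tbl.loc[resolvable].copy()
    flip = flip.loc[resolvable]
    for c in ("beta1_hat", "beta2_hat", "beta3_hat"):
        tbl.loc[flip, c] = -tbl.loc[flip, c]
    if "cov_beta1_beta3" in tbl.columns:
        # both factors of the covariance flip sign, so it is unchanged
        pass
    tbl.loc[flip, "eaf_gwis"] = 1.0 - tbl.loc[flip, "eaf_gwis"]
    tbl["flipped"] = flip.to_numpy()

    if qc.drop_palindromic:
        pal = _is_palindromic(tbl["effect_allele"], tbl["other_allele"])
        drop_log["palindromic"] = int(pal.sum())
        tbl = tbl.loc[~pal]
    else:
        drop_log["palindromic"] = 0

    both_eaf = tbl["eaf_gwas"].notna() & tbl["eaf_gwis"].notna()
    tbl["eaf_missing"] = ~both_eaf.to_numpy()
    maf_diff = (_maf(tbl["eaf_gwas"]) - _maf(tbl["eaf_gwis"])).abs()
    bad_maf = both_eaf & ~tbl["positional_match"] & (maf_diff > qc.maf_diff_max)
    drop_log["maf_diff"] = int(bad_maf.sum())
    tbl = tbl.loc[~bad_maf]

    low1 = tbl["n_eff_gwas"] < qc.min_n_primary
    drop_log["low_n_gwas"] = int(low1.sum())
    tbl = tbl.loc[~low1]
    low2 = tbl["n_eff_gwis"] < qc.min_n_secondary
    drop_log["low_n_gwis"] = int(low2.sum())
    tbl = tbl.loc[~low2]

    tbl = tbl.drop(columns=["ea_gwis", "oa_gwis", "chrom_gwis", "pos_gwis"],
                   errors="ignore").reset_index(drop=True)
    tbl.attrs["drop_log"] = drop_log
    tbl.attrs["qc"] = qc
    for reason, n in drop_log.items():
        if n:
            logger.info("harmonize: dropped %d row(s): %s", n, reason)
    return tbl


def exclude_environment_loci(
    table: pd.DataFrame,
    env_hits: Iterable[tuple[str, int]] | pd.DataFrame,
    window_bp: int = 1_000_000,
    p_threshold: float = 5e-7,
) -> pd.DataFrame:
    """Remove variants near loci associated with the environment itself.

    A variant mediated through E (G -> E -> Y) departs from the
    marginal-vs-main regression line just like a true interaction;
    excluding the strong environment-GWAS loci (p below ``p_threshold``)
    with a closed +/- ``window_bp`` window limits that contamination.

    ``env_hits`` is an iterable of ``(chrom, pos)`` pairs or a DataFrame
    with ``chrom``/``pos`` (and optionally ``p_value``, filtered at
    ``p_threshold``).  Overlapping hit windows act as a union: each
    variant is removed at most once.
    """
    if isinstance(env_hits, pd.DataFrame):
        hits = env_hits
        if "p_value" in hits.columns:
            hits = hits.loc[hits["p_value"] < p_threshold]
        pairs = list(zip(hits["chrom"].astype(str), hits["pos"].astype(int)))
    else:
        pairs = [(str(c), int(p)) for c, p in env_hits]
    if not pairs:
        logger.warning("exclude_environment_loci: empty hit list; "
                       "table returned unchanged")
        out = table.copy()
        out.attrs["n_env_excluded"] = 0
        return out

    by_chrom: dict[str, np.ndarray] = {}
    for c, p in pairs:
        by_chrom.setdefault(c, []).append(p)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    remove = np.zeros(len(table), dtype=bool)
    chroms = table["chrom"].astype(str).to_numpy()
    positions = table["pos"].to_numpy(dtype=np.int64)
    for c, hit_pos in by_chrom.items():
        on_c = chroms == c
        if not on_c.any():
            continue
        pos_c = positions[on_c]
        idx = np.searchsorted(hit_pos, pos_c)
        dist = np.full(pos_c.shape, np.iinfo(np.int64).max)
        left_ok = idx > 0
        dist[left_ok] = np.abs(pos_c[left_ok] - hit_pos[idx[left_ok] - 1])
        right_ok = idx < len(hit_pos)
        dist[right_ok] = np.minimum(
            dist[right_ok], np.abs(hit_pos[idx[right_ok]] - pos_c[right_ok]))
        remove[on_c] = dist <= window_bp
    n_removed = int(remove.sum())
    logger.info("exclude_environment_loci: removed %d variant(s)", n_removed)
    out = table.loc[~remove].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["n_env_excluded"] = n_removed
    return out


def standardize_effects(
    table: pd.DataFrame,
    method: str = "z_over_sqrt_n",
) -> pd.DataFrame:
    """Attach standardized effect sizes ``b* = z/sqrt(n)``, ``SE* = 1/sqrt(n)``.

    Standardization removes trait-scale differences between the two
    consortia so that the IVW slope is fitted on comparable units.  The
    default uses ``z/sqrt(n)``; ``method="z_over_sqrt_n_plus_z2"``
    applies the alternative ``z/sqrt(n + z^2)``, which differs only when
    ``|z|`` is comparable to ``sqrt(n)``.  Rows with ``n_eff <= 1`` in
    either source are dropped.  Original columns are preserved.
    """
    if method not in ("z_over_sqrt_n", "z_over_sqrt_n_plus_z2"):
        raise ValueError(f"unknown standardization method {method!r}")
    out = table.copy()
    ok = (out["n_eff_gwas"] > 1) & (out["n_eff_gwis"] > 1)
    out = out.loc[ok].reset_index(drop=True)

    spec = [("alpha_hat", "se_alpha", "n_eff_gwas"),
            ("beta1_hat", "se_beta1", "n_eff_gwis"),
            ("beta2_hat", "se_beta2", "n_eff_gwis"),
            ("beta3_hat", "se_beta3", "n_eff_gwis")]
    for eff, se, ncol in spec:
        if eff not in out.columns:
            continue
        z = out[eff] / out[se]
        n = out[ncol].astype(float)
        denom = np.sqrt(n + z**2) if method == "z_over_sqrt_n_plus_z2" \
            else np.sqrt(n)
        out[eff + "_std"] = z / denom
        out[se + "_std"] = 1.0 / denom
    out.attrs = dict(table.attrs)
    out.attrs["standardization"] = method
    out.attrs.setdefault("drop_log", {})
    out.attrs["drop_log"] = {**out.attrs["drop_log"],
                             "n_eff_le_1": int((~ok).sum())}
    return out


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (the package's on-disk interchange format)."""
    table.to_csv(path, sep="\t", index=False)
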