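"""Reading, harmonization, and QC of summary-statistic tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrgxe
from mrgxe.sumstats import QcConfig, write_table

from conftest import make_gwas, make_gwis


GWAS_TEXT = """variant_id chrom pos effect_allele other_allele eaf alpha_hat se_alpha p_value n_eff
rs1 1 1000 A G 0.3 0.10 0.01 1e-4 200000
rs2 1 2000 C T 0.2 -0.05 0.02 0.01 200000
rs3 2 3000 G A 0.4 0.00 0.01 0.9 200000
rs4 2 4000 T C 0.1 0.20 0.03 1e-6 200000
rs5 3 5000 A C 0.25 0.07 0.015 0.002 200000
"""


class TestReadSumstats:
    def test_well_formed_table_reads_all_rows(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        f.write_text(GWAS_TEXT)
        df = mrgxe.read_sumstats(f, "gwas")
        assert len(df) == 5
        assert df.attrs["drop_log"]["invalid_record"] == 0

    def test_dialects_parse_identically(self, tmp_path):
        f1 = tmp_path / "space.txt"
        f1.write_text(GWAS_TEXT)
        f2 = tmp_path / "tab.tsv"
        f2.write_text("\n".join("\t".join(line.split())
                                for line in GWAS_TEXT.strip().splitlines()))
        a = mrgxe.read_sumstats(f1, "gwas")
        b = mrgxe.read_sumstats(f2, "gwas")
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_violations_dropped_and_counted(self, tmp_path):
        bad = GWAS_TEXT + "rs6 3 6000 A G 0.3 0.1 0.0 0.5 200000\n"
        f = tmp_path / "g.tsv"
        f.write_text(bad)
        df = mrgxe.read_sumstats(f, "gwas")
        assert len(df) == 5
        assert df.attrs["drop_log"]["invalid_record"] == 1
        assert "rs6" not in set(df["variant_id"])

    def test_column_map_renames(self, tmp_path):
        txt = GWAS_TEXT.replace("alpha_hat", "BETA").replace("se_alpha", "SE")
        f = tmp_path / "g.tsv"
        f.write_text(txt)
        df = mrgxe.read_sumstats(f, "gwas",
                                 column_map={"alpha_hat": "BETA",
                                             "se_alpha": "SE"})
        assert df["alpha_hat"].iloc[0] == pytest.approx(0.10)

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text(GWAS_TEXT.replace("se_alpha", "foo"))
        with pytest.raises(KeyError, match="se_alpha"):
            mrgxe.read_sumstats(f, "gwas")

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("variant_id\tchrom\n")
        with pytest.raises(ValueError):
            mrgxe.read_sumstats(f, "gwas")


class TestHarmonize:
    def test_swapped_alleles_flip_gwis_signs(self):
        gwas = make_gwas([dict(variant_id="rs1", effect_allele="A",
                               other_allele="G", alpha_hat=0.2)])
        gwis = make_gwis([dict(variant_id="rs1", effect_allele="G",
                               other_allele="A", eaf=0.7, beta1_hat=0.1)])
        out = mrgxe.harmonize(gwas, gwis)
        assert len(out) == 1
        assert out["beta1_hat"].iloc[0] == pytest.approx(-0.1)
        assert out["eaf_gwis"].iloc[0] == pytest.approx(0.3)
        assert bool(out["flipped"].iloc[0])

    def test_palindromic_variants_removed(self):
        gwas = make_gwas([dict(variant_id="rs1", effect_allele="A",
                               other_allele="T"),
                          dict(variant_id="rs2", pos=2000)])
        gwis = make_gwis([dict(variant_id="rs1", effect_allele="A",
                               other_allele="T"),
                          dict(variant_id="rs2", pos=2000)])
        out = mrgxe.harmonize(gwas, gwis)
        assert set(out["variant_id"]) == {"rs2"}
        assert out.attrs["drop_log"]["palindromic"] == 1

    def test_identical_tables_fully_retained(self):
        gwas = make_gwas([dict(variant_id=f"rs{i}", pos=1000 * i)
                          for i in range(1, 6)])
        gwis = make_gwis([dict(variant_id=f"rs{i}", pos=1000 * i)
                          for i in range(1, 6)])
        out = mrgxe.harmonize(gwas, gwis)
        assert len(out) == 5
        assert not out["flipped"].any()

    @pytest.mark.parametrize("eaf_gwis,kept", [(0.30, False), (0.24, True)])
    def test_maf_difference_threshold(self, eaf_gwis, kept):
        gwas = make_gwas([dict(variant_id="rs1", eaf=0.10)])
        gwis = make_gwis([dict(variant_id="rs1", eaf=eaf_gwis)])
        out = mrgxe.harmonize(gwas, gwis)
        assert (len(out) == 1) is kept

    def test_positional_fallback_requires_tight_maf(self):
        gwas = make_gwas([dict(variant_id="rs1", pos=5000, eaf=0.30),
                          dict(variant_id="rs2", pos=7000, eaf=0.30)])
        gwis = make_gwis([dict(variant_id="alt1", pos=5000, eaf=0.305),
                          dict(variant_id="alt2", pos=7000, eaf=0.35)])
        out = mrgxe.harmonize(gwas, gwis)
        # rs1 matches positionally (MAF diff 0.005 < 0.01); rs2 fails (0.05)
        assert set(out["variant_id"]) == {"rs1"}
        assert bool(out["positional_match"].iloc[0])
        assert out.attrs["drop_log"]["positional_maf"] == 1

    def test_unresolvable_alleles_dropped(self):
        gwas = make_gwas([dict(variant_id="rs1", effect_allele="A",
                               other_allele="C")])
        gwis = make_gwis([dict(variant_id="rs1", effect_allele="A",
                               other_allele="G")])
        out = mrgxe.harmonize(gwas, gwis)
        assert len(out) == 0
        assert out.attrs["drop_log"]["allele_mismatch"] == 1

    def test_low_effective_sample_size_removed(self):
        gwas = make_gwas([dict(variant_id="rs1", n_eff=50_000),
                          dict(variant_id="rs2", pos=2000)])
        gwis = make_gwis([dict(variant_id="rs1"),
                          dict(variant_id="rs2", pos=2000, n_eff=10_000)])
        out = mrgxe.harmonize(gwas, gwis)
        assert len(out) == 0
        assert out.attrs["drop_log"]["low_n_gwas"] == 1
        assert out.attrs["drop_log"]["low_n_gwis"] == 1

    def test_sign_flip_involution(self):
        """Swapping the GWIS allele order (with negated effects and
        complemented EAF) yields numerically identical aligned output."""
        gwas = make_gwas([dict(variant_id="rs1", effect_allele="A",
                               other_allele="G", alpha_hat=0.2)])
        gwis = make_gwis([dict(variant_id="rs1", effect_allele="A",
                               other_allele="G", beta1_hat=0.1,
                               beta3_hat=0.02, eaf=0.3)])
        gwis_swapped = gwis.copy()
        gwis_swapped[["effect_allele", "other_allele"]] = [["G", "A"]]
        for c in ("beta1_hat", "beta2_hat", "beta3_hat"):
            gwis_swapped[c] = -gwis_swapped[c]
        gwis_swapped["eaf"] = 1 - gwis_swapped["eaf"]
        a = mrgxe.harmonize(gwas, gwis)
        b = mrgxe.harmonize(gwas, gwis_swapped)
        for c in ("beta1_hat", "beta2_hat", "beta3_hat", "eaf_gwis"):
            assert a[c].iloc[0] == pytest.approx(b[c].iloc[0])

    def test_reharmonization_is_idempotent(self):
        rng = np.random.default_rng(3)
        n = 30
        gwas = make_gwas([dict(variant_id=f"rs{i}", pos=1000 * i,
                               eaf=float(rng.uniform(0.05, 0.95)))
                          for i in range(1, n + 1)])
        gwis = make_gwis([dict(variant_id=f"rs{i}", pos=1000 * i,
                               eaf=float(rng.uniform(0.05, 0.95)))
                          for i in range(1, n + 1)])
        once = mrgxe.harmonize(gwas, gwis)
        # rebuild source-shaped tables from the harmonized output
        g1 = once[["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "alpha_hat", "se_alpha", "p_value"]].copy()
        g1["eaf"] = once["eaf_gwas"]
        g1["n_eff"] = once["n_eff_gwas"]
        g2 = once[["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta1_hat", "se_beta1", "beta2_hat",
                   "se_beta2", "beta3_hat", "se_beta3", "p_beta3"]].copy()
        g2["eaf"] = once["eaf_gwis"]
        g2["n_eff"] = once["n_eff_gwis"]
        twice = mrgxe.harmonize(g1, g2)
        assert set(twice["variant_id"]) == set(once["variant_id"])
        assert not twice["flipped"].any()

    def test_drop_reasons_account_for_every_gwas_row(self):
        gwas = make_gwas([
            dict(variant_id="rs1"),                                  # kept
            dict(variant_id="rs2", pos=2000, effect_allele="A",
                 other_allele="T"),                                  # palindromic
            dict(variant_id="rs3", pos=3000, eaf=0.05),              # maf diff
            dict(variant_id="rs4", pos=4000, n_eff=10),              # low n
            dict(variant_id="rs5", pos=5000),                        # unmatched
        ])
        gwis = make_gwis([
            dict(variant_id="rs1"),
            dict(variant_id="rs2", pos=2000, effect_allele="A",
                 other_allele="T"),
            dict(variant_id="rs3", pos=3000, eaf=0.45),
            dict(variant_id="rs4", pos=4000),
        ])
        out = mrgxe.harmonize(gwas, gwis)
        log = out.attrs["drop_log"]
        assert sum(log.values()) + len(out) == len(gwas)
        assert len(out) == 1


class TestExcludeEnvironmentLoci:
    def _table(self, positions, chrom="1"):
        return make_gwas([dict(variant_id=f"rs{i}", chrom=chrom, pos=p)
                          for i, p in enumerate(positions)])

    def test_window_boundaries(self):
        tbl = self._table([4_600_000, 6_100_000])
        out = mrgxe.exclude_environment_loci(tbl, [("1", 5_000_000)],
                                             window_bp=1_000_000)
        assert list(out["pos"]) == [6_100_000]
        assert out.attrs["n_env_excluded"] == 1

    def test_empty_hit_list_is_identity(self):
        tbl = self._table([1, 2, 3])
        out = mrgxe.exclude_environment_loci(tbl, [])
        pd.testing.assert_frame_equal(out, tbl)

    def test_overlapping_windows_apply_as_union(self):
        rng = np.random.default_rng(8)
        positions = rng.integers(0, 20_000_000, 300)
        tbl = self._table(positions)
        hits = [("1", 5_000_000), ("1", 5_400_000), ("2", 1_000_000)]
        out = mrgxe.exclude_environment_loci(tbl, hits, window_bp=1_000_000)
        # brute-force membership oracle
        keep = [not any(c == "1" and abs(p - h) <= 1_000_000
                        for c, h in hits) for p in positions]
        assert list(out["pos"]) == list(positions[np.array(keep)])


class TestStandardizeEffects:
    def _harmonized(self, **kw):
        gwas = make_gwas([dict(variant_id="rs1", **kw.get("gwas", {}))])
        gwis = make_gwis([dict(variant_id="rs1", **kw.get("gwis", {}))])
        qc = QcConfig(min_n_primary=0, min_n_secondary=0)
        return mrgxe.harmonize(gwas, gwis, qc)

    def test_direct_formula(self):
        tbl = self._harmonized(
            gwas=dict(alpha_hat=0.05, se_alpha=0.01, n_eff=10_000))
        out = mrgxe.standardize_effects(tbl)
        assert out["alpha_hat_std"].iloc[0] == pytest.approx(5 / 100)
        assert out["se_alpha_std"].iloc[0] == pytest.approx(0.01)

    def test_zero_effect_stays_zero(self):
        tbl = self._harmonized(gwas=dict(alpha_hat=0.0))
        out = mrgxe.standardize_effects(tbl)
        assert out["alpha_hat_std"].iloc[0] == 0.0

    @given(scale=st.floats(0.1, 30), effect=st.floats(-1, 1),
           se=st.floats(1e-4, 0.5), n=st.integers(100, 10**7))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, scale, effect, se, n):
        """b* depends only on the z-score, so rescaling (effect, se)
        jointly leaves it unchanged."""
        t1 = self._harmonized(gwas=dict(alpha_hat=effect, se_alpha=se,
                                        n_eff=n))
        t2 = self._harmonized(gwas=dict(alpha_hat=effect * scale,
                                        se_alpha=se * scale, n_eff=n))
        a = mrgxe.standardize_effects(t1)["alpha_hat_std"].iloc[0]
        b = mrgxe.standardize_effects(t2)["alpha_hat_std"].iloc[0]
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_alternative_method_close_for_small_z(self):
        tbl = self._harmonized(
            gwas=dict(alpha_hat=0.01, se_alpha=0.01, n_eff=100_000))
        a = mrgxe.standardize_effects(tbl, "z_over_sqrt_n")
        b = mrgxe.standardize_effects(tbl, "z_over_sqrt_n_plus_z2")
        assert a["alpha_hat_std"].iloc[0] == pytest.approx(
            b["alpha_hat_std"].iloc[0], rel=1e-4)


def test_write_read_round_trip(tmp_path):
    gwas = make_gwas([dict(variant_id=f"rs{i}", pos=1000 * i)
                      for i in range(1, 4)])
    f = tmp_path / "t.tsv"
    write_table(gwas, f)
    back = mrgxe.read_sumstats(f, "gwas")
    assert list(back["variant_id"]) == list(gwas["variant_id"])
    np.testing.assert_allclose(back["alpha_hat"], gwas["alpha_hat"])
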