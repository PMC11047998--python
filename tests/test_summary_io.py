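"""Reading, validation, harmonization and Wald-ratio behaviour."""

import numpy as np
import pandas as pd
import pytest

from mr2s import summary_io
from mr2s.summary_io import (
    GwasRecord, SummaryStatsError, estimation_subset, harmonize,
    read_gwas_summary, wald_ratio, write_gwas_summary,
)

from conftest import gwas_frame


def _write(tmp_path, text, name="stats.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


class TestReader:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        text = HEADER + (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-9\t1000\n"
            "rs2\t2\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-12\t1000\n"
            "rs3\t3\t300\tG\tA\t0.1\t0.05\t0.01\t1e-6\t1000\n")
        df = read_gwas_summary(_write(tmp_path, text))
        assert len(df) == 3
        assert df.attrs["n_rejected"] == 0
        assert list(df["snp_id"]) == ["rs1", "rs2", "rs3"]  # order preserved

    def test_unparseable_se_rejects_only_that_row(self, tmp_path):
        text = HEADER + (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-9\t1000\n"
            "rs2\t2\t200\tC\tT\t0.4\t-0.2\tNA\t1e-12\t1000\n"
            "rs3\t3\t300\tG\tA\t0.1\t0.05\t0.01\t1e-6\t1000\n")
        df = read_gwas_summary(_write(tmp_path, text))
        assert len(df) == 2
        assert df.attrs["n_rejected"] == 1
        assert "rs2" not in set(df["snp_id"])

    def test_published_instrument_table_parses(self, table3_frame):
        assert len(table3_frame) == 12
        row = table3_frame.set_index("snp_id").loc["rs12972970"]
        assert row["beta"] == pytest.approx(-0.172)
        assert row["se"] == pytest.approx(0.0030)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        text = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tpvalue\tn\n"
        with pytest.raises(SummaryStatsError, match="se"):
            read_gwas_summary(_write(tmp_path, text))

    def test_column_map_and_comma_delimiter(self, tmp_path):
        text = ("rsid,chr,bp,a1,a2,freq,b,stderr,p,size\n"
                "rs1,1,100,A,G,0.2,0.1,0.02,1e-9,1000\n")
        cmap = {"snp_id": "rsid", "chrom": "chr", "pos": "bp",
                "effect_allele": "a1", "other_allele": "a2", "eaf": "freq",
                "beta": "b", "se": "stderr", "pvalue": "p", "n": "size"}
        df = read_gwas_summary(_write(tmp_path, text, "s.csv"), cmap)
        assert len(df) == 1 and df.at[0, "beta"] == 0.1

    def test_missing_pvalue_recomputed_from_beta_se(self, tmp_path):
        text = ("snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tn\n"
                "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1000\n")
        df = read_gwas_summary(_write(tmp_path, text))
        assert df.at[0, "pvalue"] == pytest.approx(summary_io.pvalue_from_z(5.0))

    def test_round_trip_preserves_six_significant_digits(self, tmp_path, table3_frame):
        out = tmp_path / "rt.tsv"
        write_gwas_summary(table3_frame, out)
        back = read_gwas_summary(out)
        for col in ("eaf", "beta", "se", "pvalue", "n"):
            np.testing.assert_allclose(back[col], table3_frame[col], rtol=1e-5)

    def test_gzip_transparent(self, tmp_path):
        import gzip
        p = tmp_path / "s.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(HEADER + "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-9\t1000\n")
        assert len(read_gwas_summary(p)) == 1


class TestGwasRecord:
    def test_structural_violations_raise(self):
        ok = dict(snp_id="rs1", chrom="1", pos=1, effect_allele="A",
                  other_allele="G", eaf=0.2, beta=0.1, se=0.02, pvalue=1e-6, n=100)
        GwasRecord(**ok).validate()
        for bad in [dict(effect_allele="G"), dict(se=0.0), dict(eaf=1.5),
                    dict(pvalue=0.0), dict(n=0), dict(other_allele="N")]:
            with pytest.raises(SummaryStatsError):
                GwasRecord(**{**ok, **bad}).validate()

    def test_inconsistent_pvalue_warns_not_fails(self, caplog):
        rec = GwasRecord(snp_id="rs1", chrom="1", pos=1, effect_allele="A",
                         other_allele="G", eaf=0.2, beta=0.1, se=0.02,
                         pvalue=0.9, n=100)  # |z|=5 implies p~6e-7
        with caplog.at_level("WARNING"):
            rec.validate()
        assert any("inconsistent" in r.message for r in caplog.records)


def _pair(exp_alleles, out_alleles, beta_out=0.2, eaf_exp=0.2, eaf_out=0.2,
          beta_exp=0.1):
    exposure = gwas_frame([("rs1", "1", 100, *exp_alleles, eaf_exp,
                            beta_exp, 0.02, 1e-9, 1000)])
    outcome = gwas_frame([("rs1", "1", 100, *out_alleles, eaf_out,
                           beta_out, 0.05, 1e-3, 1000)])
    return exposure, outcome


class TestHarmonize:
    def test_identical_alleles_aligned(self):
        h = harmonize(*_pair(("A", "G"), ("A", "G")))
        assert h.at[0, "action_taken"] == "aligned"
        assert h.at[0, "beta_out"] == pytest.approx(0.2)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = harmonize(*_pair(("A", "G"), ("G", "A"), eaf_out=0.3))
        assert h.at[0, "action_taken"] == "flipped"
        assert h.at[0, "beta_out"] == pytest.approx(-0.2)
        assert h.at[0, "eaf_out"] == pytest.approx(0.7)

    def test_strand_complement_matches(self):
        h = harmonize(*_pair(("A", "G"), ("T", "C")))
        assert h.at[0, "action_taken"] == "strand_flipped"
        assert h.at[0, "beta_out"] == pytest.approx(0.2)

    def test_strand_complement_swapped_flips_sign(self):
        h = harmonize(*_pair(("A", "G"), ("C", "T"), eaf_out=0.3))
        assert h.at[0, "action_taken"] == "strand_flipped"
        assert h.at[0, "beta_out"] == pytest.approx(-0.2)
        assert h.at[0, "eaf_out"] == pytest.approx(0.7)

    def test_irreconcilable_alleles_dropped_with_label(self):
        h = harmonize(*_pair(("A", "G"), ("A", "C")))
        assert h.at[0, "action_taken"] == "dropped_mismatch"
        assert estimation_subset(h).empty

    def test_missing_outcome_snp_dropped(self):
        exposure, outcome = _pair(("A", "G"), ("A", "G"))
        outcome = outcome.assign(snp_id=["rs999"])
        h = harmonize(exposure, outcome)
        assert h.at[0, "action_taken"] == "dropped_missing_outcome"

    @pytest.mark.parametrize("eaf_exp,eaf_out,expected", [
        (0.10, 0.12, "aligned"),            # same side, both unambiguous
        (0.10, 0.88, "dropped_palindromic"),  # opposite sides of 0.5
        (0.45, 0.12, "dropped_palindromic"),  # exposure eaf ambiguous
        (0.10, 0.47, "dropped_palindromic"),  # outcome eaf ambiguous
    ])
    def test_palindromic_rule_table(self, eaf_exp, eaf_out, expected):
        h = harmonize(*_pair(("A", "T"), ("A", "T"),
                             eaf_exp=eaf_exp, eaf_out=eaf_out),
                      palindromic_eaf_limit=0.42)
        assert h.at[0, "action_taken"] == expected

    def test_palindromic_label_swap_flips(self):
        # labels swapped, frequencies concordant on the shared allele
        # (outcome reports the T allele at 0.88 = 1 - 0.12) -> flipped
        h = harmonize(*_pair(("A", "T"), ("T", "A"), eaf_exp=0.1, eaf_out=0.88))
        assert h.at[0, "action_taken"] == "flipped"
        assert h.at[0, "beta_out"] == pytest.approx(-0.2)
        assert h.at[0, "eaf_out"] == pytest.approx(0.12)

    def test_harmonization_sign_symmetry(self, exposure_outcome_pair):
        """Pre-flipping every outcome allele pair must yield identical
        Wald ratios (harmonization is involutive in effect)."""
        exposure, outcome, _ = exposure_outcome_pair
        h1 = estimation_subset(harmonize(exposure, outcome))
        flipped = outcome.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1.0 - flipped["eaf"]
        h2 = estimation_subset(harmonize(exposure, flipped))
        assert list(h1["snp_id"]) == list(h2["snp_id"])
        np.testing.assert_allclose(h1["wald_ratio"], h2["wald_ratio"], rtol=1e-12)

    def test_dropped_rows_never_reach_estimation(self, exposure_outcome_pair):
        exposure, outcome, _ = exposure_outcome_pair
        h = harmonize(exposure, outcome)
        sub = estimation_subset(h)
        assert not sub["action_taken"].str.startswith("dropped").any()
        assert sub["wald_ratio"].notna().all()

    def test_bad_limit_rejected(self):
        with pytest.raises(ValueError):
            harmonize(*_pair(("A", "G"), ("A", "G")), palindromic_eaf_limit=0.7)


class TestWaldRatio:
    def test_direct_substitution(self):
        ratio, se = wald_ratio(0.1, 0.2, 0.05)
        assert ratio == pytest.approx(2.0)
        assert se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        ratio, _ = wald_ratio(-0.3, 0.0, 0.05)
        assert ratio == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.2, 0.05)

    def test_first_order_se_matches_bootstrap_for_strong_instrument(self):
        """Delta-method SE within 10% of a parametric bootstrap when the
        instrument is strong (|beta_exp|/se_exp > 10)."""
        rng = np.random.default_rng(2024)
        beta_exp, se_exp = 0.12, 0.008   # z = 15
        beta_out, se_out = 0.03, 0.01
        _, se_first = wald_ratio(beta_exp, beta_out, se_out)
        bx = rng.normal(beta_exp, se_exp, 10_000)
        by = rng.normal(beta_out, se_out, 10_000)
        se_boot = np.std(by / bx, ddof=1)
        assert se_first == pytest.approx(se_boot, rel=0.10)
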