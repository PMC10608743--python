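"""Reading, validation, clumping, harmonization and instrument strength."""

import numpy as np
import pytest

from conftest import make_table
from mrlink.exceptions import ConfigError, InputError
from mrlink.sumstats import (
    LdMatrix,
    harmonize,
    instrument_strength,
    is_palindromic,
    read_sumstats,
    select_instruments,
)


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


HEADER = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "samplesize"]


class TestReadSumstats:
    def test_well_formed_rows_pass_through(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_tsv(path, HEADER, [
            ["rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 5000],
            ["rs2", "C", "T", 0.5, -0.2, 0.02, 1e-8, 5000],
            ["rs3", "G", "A", 0.7, 0.05, 0.01, 0.5, 5000],
        ])
        tab = read_sumstats(path, "t", "continuous")
        assert len(tab) == 3
        assert list(tab.table["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert tab.table.loc[1, "beta"] == -0.2

    def test_invalid_rows_dropped_not_raised(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_tsv(path, HEADER, [
            ["rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 5000],
            ["rs2", "C", "T", 0.5, -0.2, 0.0, 1e-8, 5000],   # se = 0
            ["rs3", "G", "G", 0.7, 0.05, 0.01, 0.5, 5000],   # identical alleles
        ])
        tab = read_sumstats(path, "t", "continuous")
        assert len(tab) == 1

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        header = [c for c in HEADER if c != "beta"]
        write_tsv(path, header, [["rs1", "A", "G", 0.3, 0.01, 1e-10, 5000]])
        with pytest.raises(ConfigError, match="beta"):
            read_sumstats(path, "t", "continuous")

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            read_sumstats(path, "t", "continuous")

    def test_comma_autodetect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "SNP,effect_allele,other_allele,eaf,beta,se,pval,samplesize\n"
            "rs1,A,G,0.3,0.1,0.01,1e-10,5000\n"
        )
        assert len(read_sumstats(path, "t", "continuous")) == 1


class TestSelectInstruments:
    def ld(self, ids, pairs):
        m = np.eye(len(ids))
        idx = {v: i for i, v in enumerate(ids)}
        for a, b, r2 in pairs:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
        return LdMatrix(ids, m)

    def test_greedy_clumping_drops_linked_weaker_variant(self):
        tab = make_table("t", [
            ("v1", "A", "G", 0.2, 0.01, 1e-10),
            ("v2", "A", "G", 0.2, 0.01, 1e-9),
            ("v3", "A", "G", 0.2, 0.01, 1e-8),
        ])
        ld = self.ld(["v1", "v2", "v3"],
                     [("v1", "v2", 0.5), ("v1", "v3", 0.001), ("v2", "v3", 0.001)])
        assert select_instruments(tab, 5e-8, ld, 0.01) == ["v1", "v3"]

    def test_unlinked_variants_all_kept(self):
        tab = make_table("t", [(f"v{i}", "A", "G", 0.2, 0.01, 1e-9) for i in range(4)])
        ld = self.ld([f"v{i}" for i in range(4)], [])
        assert len(select_instruments(tab, 5e-8, ld, 0.01)) == 4

    def test_nothing_below_threshold_gives_empty_set(self):
        tab = make_table("t", [("v1", "A", "G", 0.2, 0.05, 5e-8)])
        assert select_instruments(tab, 5e-8, None, 0.01) == []

    def test_row_order_invariance_with_tie_break(self):
        rows = [
            ("b_snp", "A", "G", 0.2, 0.01, 1e-9),
            ("a_snp", "A", "G", 0.2, 0.01, 1e-9),
            ("c_snp", "A", "G", 0.2, 0.01, 1e-10),
        ]
        ld = self.ld(["a_snp", "b_snp", "c_snp"], [("a_snp", "b_snp", 0.9)])
        out1 = select_instruments(make_table("t", rows), 5e-8, ld, 0.01)
        out2 = select_instruments(make_table("t", rows[::-1]), 5e-8, ld, 0.01)
        assert out1 == out2 == ["c_snp", "a_snp"]

    def test_threshold_one_keeps_all_subthreshold_variants(self):
        tab = make_table("t", [(f"v{i}", "A", "G", 0.2, 0.01, 1e-9) for i in range(3)])
        ld = self.ld(["v0", "v1", "v2"], [("v0", "v1", 0.99), ("v0", "v2", 0.5)])
        assert len(select_instruments(tab, 5e-8, ld, 1.0)) == 3

    def test_threshold_zero_keeps_one_per_ld_component(self):
        tab = make_table("t", [(f"v{i}", "A", "G", 0.2, 0.01, 1e-9) for i in range(4)])
        # components {v0, v1} and {v2, v3}
        ld = self.ld(["v0", "v1", "v2", "v3"],
                     [("v0", "v1", 0.3), ("v2", "v3", 0.2)])
        assert len(select_instruments(tab, 5e-8, ld, 0.0)) == 2

    def test_variant_absent_from_ld_treated_unlinked(self):
        tab = make_table("t", [
            ("v1", "A", "G", 0.2, 0.01, 1e-10),
            ("v_missing", "A", "G", 0.2, 0.01, 1e-9),
        ])
        ld = self.ld(["v1"], [])
        assert select_instruments(tab, 5e-8, ld, 0.01) == ["v1", "v_missing"]


class TestHarmonize:
    def test_allele_swap_flips_outcome_sign(self):
        exp = make_table("X", [("rs1", "A", "G", 0.1, 0.01, 1e-10)])
        out = make_table("Y", [("rs1", "G", "A", 0.05, 0.02, 0.01)])
        h = harmonize(exp, out, ["rs1"])
        assert h.beta_outcome[0] == pytest.approx(-0.05)
        assert h.beta_exposure[0] == pytest.approx(0.1)

    def test_palindromic_removed_when_flag_set(self):
        exp = make_table("X", [
            ("rs1", "A", "T", 0.1, 0.01, 1e-10),
            ("rs2", "A", "G", 0.1, 0.01, 1e-10),
        ])
        out = make_table("Y", [
            ("rs1", "A", "T", 0.05, 0.02, 0.01),
            ("rs2", "A", "G", 0.05, 0.02, 0.01),
        ])
        h = harmonize(exp, out, ["rs1", "rs2"], drop_palindromic=True)
        assert h.variant_ids == ["rs2"]
        assert h.n_removed_palindromic == 1
        assert h.dropped["rs1"] == "palindromic"

    @pytest.mark.parametrize(
        "out_ea,out_oa,expected_sign",
        [
            ("A", "G", +1),   # identical
            ("G", "A", -1),   # swapped
            ("T", "C", +1),   # strand complement
            ("C", "T", -1),   # strand complement, swapped
        ],
    )
    def test_orientation_rules(self, out_ea, out_oa, expected_sign):
        exp = make_table("X", [("rs1", "A", "G", 0.1, 0.01, 1e-10)])
        out = make_table("Y", [("rs1", out_ea, out_oa, 0.05, 0.02, 0.01)])
        h = harmonize(exp, out, ["rs1"])
        assert h.beta_outcome[0] == pytest.approx(expected_sign * 0.05)

    def test_unresolvable_alleles_counted_mismatching(self):
        exp = make_table("X", [
            ("rs1", "A", "G", 0.1, 0.01, 1e-10),
            ("rs2", "A", "G", 0.1, 0.01, 1e-10),
        ])
        out = make_table("Y", [
            ("rs1", "A", "C", 0.05, 0.02, 0.01),
            ("rs2", "A", "G", 0.05, 0.02, 0.01),
        ])
        h = harmonize(exp, out, ["rs1", "rs2"])
        assert h.n_removed_mismatch == 1
        assert h.variant_ids == ["rs2"]

    def test_all_variants_removed_raises_with_counts(self):
        exp = make_table("X", [("rs1", "A", "T", 0.1, 0.01, 1e-10)])
        out = make_table("Y", [("rs1", "A", "T", 0.05, 0.02, 0.01)])
        with pytest.raises(InputError, match="palindromic"):
            harmonize(exp, out, ["rs1"])

    def test_self_harmonization_is_identity_for_non_palindromic(self):
        rows = [
            ("rs1", "A", "G", 0.1, 0.01, 1e-10),
            ("rs2", "C", "A", -0.2, 0.02, 1e-9),
            ("rs3", "G", "C", 0.3, 0.03, 1e-8),  # palindromic, dropped
        ]
        tab = make_table("X", rows)
        h = harmonize(tab, tab, ["rs1", "rs2", "rs3"])
        assert h.variant_ids == ["rs1", "rs2"]
        np.testing.assert_allclose(h.beta_outcome, h.beta_exposure)

    def test_palindromic_eaf_rescue(self):
        exp = make_table("X", [("rs1", "A", "T", 0.1, 0.01, 1e-10, 0.1)])
        out = make_table("Y", [("rs1", "A", "T", 0.05, 0.02, 0.01, 0.12)])
        h = harmonize(exp, out, ["rs1"], palindromic_eaf_window=0.08)
        assert h.variant_ids == ["rs1"]

    def test_is_palindromic(self):
        assert is_palindromic("A", "T") and is_palindromic("G", "C")
        assert not is_palindromic("A", "G")


class TestInstrumentStrength:
    def test_f_statistic_values(self):
        from conftest import make_hset

        h = make_hset([0.1, 0.0], [0.01, 0.01], [0.0, 0.0], 0.1)
        f, mean_f = instrument_strength(h)
        assert f[0] == pytest.approx(100.0)
        assert f[1] == 0.0
        assert mean_f == pytest.approx(50.0)

    def test_f_invariant_under_sign_flip(self):
        from conftest import make_hset

        h1 = make_hset([0.1, -0.2], 0.01, [0.0, 0.0], 0.1)
        h2 = make_hset([-0.1, 0.2], 0.01, [0.0, 0.0], 0.1)
        np.testing.assert_allclose(instrument_strength(h1)[0], instrument_strength(h2)[0])
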