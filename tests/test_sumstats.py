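"""I/O validation, round-trips and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqtlmr.sumstats import (
    ConfigurationError,
    EmptyInputError,
    LDReference,
    SummaryDataset,
    harmonize,
    is_palindromic,
    read_ld_reference,
    read_summary_stats,
    write_ld_reference,
    write_summary_stats,
)

from conftest import make_records


def _write_tsv(tmp_path, df, name="stats.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSummaryStats:
    def test_well_formed_table_is_read_in_full(self, tmp_path):
        path = _write_tsv(tmp_path, make_records([{}, {"position": 2000}, {"position": 3000}]))
        ds = read_summary_stats(path, "quantitative")
        assert len(ds) == 3
        assert ds.n_dropped_on_read == 0

    def test_zero_se_row_is_dropped_and_counted(self, tmp_path):
        path = _write_tsv(tmp_path, make_records([{}, {"se": 0.0, "position": 2000}]))
        ds = read_summary_stats(path, "quantitative")
        assert len(ds) == 1
        assert ds.n_dropped_on_read == 1

    def test_degenerate_alleles_dropped(self, tmp_path):
        path = _write_tsv(
            tmp_path,
            make_records([{}, {"effect_allele": "A", "other_allele": "A", "position": 2000}]),
        )
        ds = read_summary_stats(path, "quantitative")
        assert ds.variant_ids.tolist() == ["rs1"]

    def test_eaf_outside_unit_interval_dropped(self, tmp_path):
        path = _write_tsv(tmp_path, make_records([{"eaf": 1.2}, {"position": 2000}]))
        ds = read_summary_stats(path, "quantitative")
        assert len(ds) == 1

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        df = make_records([{}]).drop(columns=["se"])
        path = _write_tsv(tmp_path, df)
        with pytest.raises(ConfigurationError, match="se"):
            read_summary_stats(path, "quantitative")

    def test_dialect_maps_column_names(self, tmp_path):
        df = make_records([{}]).rename(columns={"variant_id": "SNP", "pvalue": "P"})
        path = _write_tsv(tmp_path, df)
        ds = read_summary_stats(
            path, "quantitative", dialect={"variant_id": "SNP", "pvalue": "P"}
        )
        assert len(ds) == 1

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        path = _write_tsv(tmp_path, make_records([{"se": -1.0}]))
        with pytest.raises(EmptyInputError):
            read_summary_stats(path, "quantitative")

    def test_case_control_requires_case_proportion(self):
        with pytest.raises(ValueError, match="case_proportion"):
            SummaryDataset("t", "case_control", make_records([{}]))


def test_write_read_round_trip_preserves_numbers(tmp_path, rng):
    rows = [
        {
            "position": int(p),
            "eaf": float(f),
            "beta": float(b),
            "se": float(s),
            "pvalue": float(pv),
        }
        for p, f, b, s, pv in zip(
            rng.integers(1, 10**8, 50),
            rng.uniform(0.01, 0.99, 50),
            rng.normal(0, 0.7, 50),
            rng.uniform(1e-6, 2.0, 50),
            rng.uniform(1e-12, 1.0, 50),
        )
    ]
    ds = SummaryDataset("t", "quantitative", make_records(rows))
    path = tmp_path / "roundtrip.tsv"
    write_summary_stats(ds, path)
    back = read_summary_stats(path, "quantitative")
    for col in ("position", "eaf", "beta", "se", "pvalue", "n"):
        np.testing.assert_array_equal(back.records[col].to_numpy(), ds.records[col].to_numpy())


class TestLDReference:
    def test_round_trip(self, tmp_path):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDReference(["a", "b"], r)
        write_ld_reference(ld, tmp_path / "v.txt", tmp_path / "m.tsv")
        back = read_ld_reference(tmp_path / "v.txt", tmp_path / "m.tsv")
        assert back.variant_ids == ["a", "b"]
        np.testing.assert_allclose(back.r_matrix, r)

    @pytest.mark.parametrize(
        "matrix, message",
        [
            (np.array([[1.0, 0.9], [0.2, 1.0]]), "symmetric"),
            (np.array([[2.0, 0.0], [0.0, 1.0]]), "diagonal"),
            (np.array([[1.0, -1.5], [-1.5, 1.0]]), "PSD"),
        ],
    )
    def test_invalid_matrices_rejected(self, matrix, message):
        with pytest.raises(ValueError, match=message):
            LDReference(["a", "b"], matrix)


class TestHarmonize:
    def test_already_aligned_pair_unchanged(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{"beta": 0.1}])
        out = cc_dataset([{"beta": 0.2}])
        hs = harmonize(exp, out)
        assert len(hs) == 1
        assert hs.pairs.loc[0, "beta_out"] == 0.2
        assert hs.pairs.loc[0, "eaf_out"] == 0.3

    def test_swapped_alleles_flip_beta_and_eaf(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = cc_dataset(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.2, "eaf": 0.3}]
        )
        hs = harmonize(exp, out)
        assert hs.pairs.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert hs.pairs.loc[0, "eaf_out"] == pytest.approx(0.7)

    def test_palindromic_near_half_frequency_dropped(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{"effect_allele": "A", "other_allele": "T", "eaf": 0.49}])
        out = cc_dataset([{"effect_allele": "A", "other_allele": "T", "eaf": 0.49}])
        with pytest.raises(EmptyInputError):
            harmonize(exp, out, palindrome_eaf_margin=0.08)

    def test_palindromic_drop_reason_recorded(self, quant_dataset, cc_dataset):
        exp = quant_dataset(
            [
                {"effect_allele": "A", "other_allele": "T", "eaf": 0.49},
                {"position": 2000, "eaf": 0.2},
            ]
        )
        out = cc_dataset(
            [
                {"effect_allele": "A", "other_allele": "T", "eaf": 0.49},
                {"position": 2000, "eaf": 0.2},
            ]
        )
        hs = harmonize(exp, out, palindrome_eaf_margin=0.08)
        assert ("rs1", "palindromic-ambiguous") in hs.dropped
        assert hs.pairs["variant_id"].tolist() == ["rs2"]

    def test_clear_palindromic_kept(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{"effect_allele": "C", "other_allele": "G", "eaf": 0.2}])
        out = cc_dataset([{"effect_allele": "C", "other_allele": "G", "eaf": 0.25}])
        assert len(harmonize(exp, out, palindrome_eaf_margin=0.08)) == 1

    def test_irreconcilable_alleles_dropped_with_reason(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{"effect_allele": "A", "other_allele": "G"},
                             {"position": 2000}])
        out = cc_dataset([{"effect_allele": "A", "other_allele": "C"},
                          {"position": 2000}])
        hs = harmonize(exp, out)
        assert ("rs1", "allele-mismatch") in hs.dropped

    def test_every_variant_accounted_for_once(self, quant_dataset, cc_dataset):
        exp = quant_dataset(
            [{}, {"position": 2000}, {"position": 3000, "effect_allele": "A",
                                      "other_allele": "T", "eaf": 0.5}]
        )
        out = cc_dataset([{}, {"position": 3000, "effect_allele": "A",
                               "other_allele": "T", "eaf": 0.5}])
        hs = harmonize(exp, out)
        seen = set(hs.pairs["variant_id"]) | {v for v, _ in hs.dropped}
        assert seen == set(exp.variant_ids)
        assert len(hs.pairs) + len(hs.dropped) == len(exp)

    def test_idempotent_on_harmonized_pairs(self, quant_dataset, cc_dataset, rng):
        rows_e, rows_o = [], []
        for i in range(20):
            ea, oa = ("A", "G") if i % 2 else ("T", "C")
            rows_e.append({"position": 1000 * (i + 1), "effect_allele": ea,
                           "other_allele": oa, "beta": float(rng.normal()),
                           "eaf": float(rng.uniform(0.05, 0.95))})
            rows_o.append({"position": 1000 * (i + 1), "effect_allele": ea,
                           "other_allele": oa, "beta": float(rng.normal()),
                           "eaf": float(rng.uniform(0.05, 0.95))})
        hs1 = harmonize(quant_dataset(rows_e), cc_dataset(rows_o))
        exp2 = SummaryDataset(
            "p",
            "quantitative",
            hs1.pairs.rename(
                columns={"eaf_exp": "eaf", "beta_exp": "beta", "se_exp": "se",
                         "pvalue_exp": "pvalue", "n_exp": "n"}
            )[list(make_records([{}]).columns)],
        )
        out2 = SummaryDataset(
            "o",
            "case_control",
            hs1.pairs.rename(
                columns={"eaf_out": "eaf", "beta_out": "beta", "se_out": "se",
                         "pvalue_out": "pvalue", "n_out": "n"}
            )[list(make_records([{}]).columns)],
            case_proportion=0.5,
        )
        hs2 = harmonize(exp2, out2)
        pd.testing.assert_frame_equal(hs1.pairs, hs2.pairs)

    def test_flipping_outcome_leaves_beta_products_unchanged(
        self, quant_dataset, cc_dataset
    ):
        rows_e = [{"position": 1000 * (i + 1), "beta": 0.1 * (i + 1)} for i in range(5)]
        rows_o = [{"position": 1000 * (i + 1), "beta": 0.2 - 0.1 * i} for i in range(5)]
        exp = quant_dataset(rows_e)
        out = cc_dataset(rows_o)
        flipped = out.records.copy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        out_flipped = SummaryDataset("o", "case_control", flipped, case_proportion=0.5)
        prod1 = harmonize(exp, out).pairs.eval("beta_exp * beta_out")
        prod2 = harmonize(exp, out_flipped).pairs.eval("beta_exp * beta_out")
        np.testing.assert_allclose(prod1, prod2)

    def test_empty_overlap_names_both_traits(self, quant_dataset, cc_dataset):
        exp = quant_dataset([{}])
        out = cc_dataset([{}])
        out.records.loc[0, "variant_id"] = "other"
        with pytest.raises(EmptyInputError, match="protein.*outcome"):
            harmonize(exp, out)


@given(st.sampled_from(["A", "C", "G", "T"]), st.sampled_from(["A", "C", "G", "T"]))
@settings(derandomize=True)
def test_palindromic_detection_matches_complement_rule(a1, a2):
    assert is_palindromic(a1, a2) == ({a1, a2} in ({"A", "T"}, {"C", "G"}))
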