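"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    SummaryTable,
    classify_palindromic,
    harmonize,
    read_summary_table,
    table_from_arrays,
)
from mrkit.exceptions import (
    ConfigurationError,
    EmptyInputError,
    NoOverlapError,
    ValidationError,
)
from mrkit.summary_gwas import COMPLEMENT, SummaryRecord


def small_table(trait="fev1", n=3):
    return table_from_arrays(
        trait,
        snp_ids=[f"rs{i}" for i in range(1, n + 1)],
        chrom=["1"] * n,
        pos=[1000 * i for i in range(1, n + 1)],
        effect_allele=["A"] * n,
        other_allele=["G"] * n,
        eaf=[0.2 + 0.1 * i for i in range(n)],
        beta=[0.1 * (i + 1) for i in range(n)],
        se=[0.02] * n,
        pval=[1e-9] * n,
        n=[10_000] * n,
    )


class TestReadWrite:
    def test_round_trip_is_exact(self, tmp_path):
        table = small_table()
        path = tmp_path / "t.tsv"
        table.write(path)
        back = read_summary_table(path, trait_name="fev1")
        assert len(back) == 3
        assert back.ids() == table.ids()
        pd.testing.assert_frame_equal(back.to_dataframe(), table.to_dataframe())

    def test_comma_delimiter_and_column_map(self, tmp_path):
        df = small_table().to_dataframe().rename(columns={"SE": "stderr", "P": "pvalue"})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        back = read_summary_table(path, column_map={"SE": "stderr", "P": "pvalue"})
        assert len(back) == 3
        assert back.records[0].se == 0.02

    def test_invalid_rows_rejected_with_line_numbers(self, tmp_path):
        df = small_table().to_dataframe()
        df.loc[1, "SE"] = 0.0  # violates se > 0 (data line 3 of the file)
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_summary_table(path)
        assert len(back) == 2
        assert back.rejected[0][0] == 3
        assert "se" in back.rejected[0][1]

    def test_non_acgt_allele_skips_row(self, tmp_path):
        df = small_table().to_dataframe()
        df.loc[0, "EA"] = "AT"
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_summary_table(path)
        assert len(back) == 2 and len(back.rejected) == 1

    def test_missing_column_names_it(self, tmp_path):
        df = small_table().to_dataframe().drop(columns=["EAF"])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError, match="EAF"):
            read_summary_table(path)

    def test_all_rows_invalid_is_empty_input(self, tmp_path):
        df = small_table().to_dataframe()
        df["SE"] = 0.0
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(EmptyInputError):
            read_summary_table(path)


@pytest.mark.parametrize(
    "ea,oa,eaf,window,expected",
    [
        ("A", "T", 0.50, 0.08, "drop"),
        ("A", "G", 0.50, 0.08, "keep"),
        ("C", "G", 0.10, 0.08, "keep_informative"),
        ("G", "C", 0.44, 0.08, "drop"),  # inside the window on the low side
        ("T", "A", 0.30, 0.08, "keep_informative"),
    ],
)
def test_classify_palindromic(ea, oa, eaf, window, expected):
    assert classify_palindromic(ea, oa, eaf, window) == expected


def test_classify_palindromic_rejects_bad_eaf():
    with pytest.raises(ValidationError):
        classify_palindromic("A", "T", 1.5)


def _one_snp_table(trait, ea, oa, beta, eaf=0.3, se=0.02, pval=1e-8):
    return table_from_arrays(
        trait, ["rs1"], ["1"], [100], [ea], [oa], [eaf], [beta], [se], [pval], [5000]
    )


class TestHarmonize:
    def test_identity_case(self):
        h = harmonize(_one_snp_table("x", "A", "G", 0.1), _one_snp_table("y", "A", "G", 0.05))
        assert h.beta_y[0] == pytest.approx(0.05)
        assert h.dropped == []

    def test_swapped_alleles_negate_and_flip_eaf(self):
        h = harmonize(
            _one_snp_table("x", "A", "G", 0.1),
            _one_snp_table("y", "G", "A", 0.05, eaf=0.3),
        )
        assert h.beta_y[0] == pytest.approx(-0.05)
        # harmonized eaf is carried from the exposure side; outcome eaf was 0.7
        assert h.beta_x[0] == pytest.approx(0.1)

    def test_strand_complement_resolves(self):
        # outcome reported on the opposite strand: A/G vs T/C
        h = harmonize(
            _one_snp_table("x", "A", "G", 0.1),
            _one_snp_table("y", "T", "C", 0.05),
        )
        assert len(h) == 1
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_strand_complement_swapped(self):
        h = harmonize(
            _one_snp_table("x", "A", "G", 0.1),
            _one_snp_table("y", "C", "T", 0.05),
        )
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_palindromic_intermediate_dropped(self):
        h = harmonize(
            _one_snp_table("x", "A", "T", 0.1, eaf=0.49),
            _one_snp_table("y", "A", "T", 0.05, eaf=0.49),
        )
        assert len(h) == 0
        assert h.dropped == [("rs1", "palindromic_intermediate")]

    def test_palindromic_extreme_oriented_by_frequency(self):
        # exposure minor side and outcome major side disagree -> flip
        h = harmonize(
            _one_snp_table("x", "A", "T", 0.1, eaf=0.1),
            _one_snp_table("y", "A", "T", 0.05, eaf=0.9),
        )
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_palindromic_drop_action(self):
        h = harmonize(
            _one_snp_table("x", "A", "T", 0.1, eaf=0.1),
            _one_snp_table("y", "A", "T", 0.05, eaf=0.1),
            palindromic_action="drop",
        )
        assert len(h) == 0

    def test_allele_mismatch_dropped(self):
        h = harmonize(_one_snp_table("x", "A", "G", 0.1), _one_snp_table("y", "A", "C", 0.05))
        assert h.dropped == [("rs1", "allele_mismatch")]

    def test_duplicates_keep_smallest_p(self):
        rec = _one_snp_table("x", "A", "G", 0.1, pval=1e-4).records[0]
        import dataclasses

        better = dataclasses.replace(rec, beta=0.2, pval=1e-10)
        exposure = SummaryTable("x", [rec, better])
        h = harmonize(exposure, _one_snp_table("y", "A", "G", 0.05))
        assert h.beta_x[0] == pytest.approx(0.2)
        assert ("rs1", "duplicate") in h.dropped

    def test_no_overlap_error_names_traits(self):
        t1 = _one_snp_table("fev1", "A", "G", 0.1)
        t2 = table_from_arrays("cog", ["rs99"], ["1"], [5], ["A"], ["G"], [0.2],
                               [0.1], [0.02], [0.5], [100])
        with pytest.raises(NoOverlapError, match="fev1"):
            harmonize(t1, t2)

    def test_every_snp_accounted_for(self):
        exp, out, _ = _sim_pair(seed=7)
        h = harmonize(exp, out)
        n_dupes = sum(1 for _, r in h.dropped if r == "duplicate")
        assert len(h) + len(h.dropped) - n_dupes == len(set(exp.ids()) & set(out.ids()))

    def test_idempotent(self):
        exp, out, _ = _sim_pair(seed=7)
        h1 = harmonize(exp, out)
        # re-express the harmonized result as tables (outcome now shares the
        # exposure's alleles exactly) and harmonize again: nothing changes
        exp2 = _tables_from_h(h1, side="x")
        out2 = _tables_from_h(h1, side="y")
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h2.beta_y, h1.beta_y)
        assert h2.dropped == []


def _sim_pair(seed):
    from mrkit import SimulationConfig, simulate_two_sample

    return simulate_two_sample(SimulationConfig(seed=seed, J=40))


def _tables_from_h(h, side):
    beta = h.beta_x if side == "x" else h.beta_y
    se = h.se_x if side == "x" else h.se_y
    n = h.n_x if side == "x" else h.n_y
    J = len(h)
    from scipy import stats

    p = np.maximum(2 * stats.norm.sf(np.abs(beta / se)), 1e-300)
    return table_from_arrays(
        side, h.snp_ids, ["1"] * J, list(range(1, J + 1)),
        ["A"] * J, ["G"] * J, h.eaf, beta, se, p, n.astype(int),
    )


allele_pairs = st.sampled_from(
    [(a, b) for a in "ACGT" for b in "ACGT" if a != b and COMPLEMENT[a] != b]
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    pair=allele_pairs,
    beta_x=st.floats(-0.5, 0.5),
    beta_y=st.floats(-0.5, 0.5),
    eaf=st.floats(0.05, 0.95),
)
def test_sign_consistency_under_outcome_allele_flip(pair, beta_x, beta_y, eaf):
    """Flipping the outcome's allele labels while negating its beta must give
    an identical harmonized set."""
    ea, oa = pair
    exposure = _one_snp_table("x", ea, oa, beta_x, eaf=eaf)
    outcome = _one_snp_table("y", ea, oa, beta_y, eaf=eaf)
    flipped = _one_snp_table("y", oa, ea, -beta_y, eaf=1 - eaf)
    h1 = harmonize(exposure, outcome)
    h2 = harmonize(exposure, flipped)
    np.testing.assert_allclose(h1.beta_y, h2.beta_y, atol=1e-12)
    np.testing.assert_allclose(h1.eaf, h2.eaf, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    pair=allele_pairs,
    beta_x=st.floats(-0.5, 0.5),
    beta_y=st.floats(-0.5, 0.5),
    eaf=st.floats(0.05, 0.95),
)
def test_complementing_outcome_strand_is_invisible(pair, beta_x, beta_y, eaf):
    """Reporting the (non-palindromic) outcome on the other strand must leave
    retained numeric values unchanged."""
    ea, oa = pair
    exposure = _one_snp_table("x", ea, oa, beta_x, eaf=eaf)
    outcome = _one_snp_table("y", ea, oa, beta_y, eaf=eaf)
    comp = _one_snp_table("y", COMPLEMENT[ea], COMPLEMENT[oa], beta_y, eaf=eaf)
    h1 = harmonize(exposure, outcome)
    h2 = harmonize(exposure, comp)
    np.testing.assert_allclose(h1.beta_y, h2.beta_y, atol=1e-12)


def test_record_validation_catches_bad_fields():
    rec = SummaryRecord("rs1", "1", 100, "A", "A", 0.3, 0.1, 0.02, 1e-8, 100)
    with pytest.raises(ValidationError):
        rec.validate()
    rec = SummaryRecord("rs1", "1", 0, "A", "G", 0.3, 0.1, 0.02, 1e-8, 100)
    with pytest.raises(ValidationError, match="pos"):
        rec.validate()
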