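"""Parsing dialects and detection-threshold filtering."""

import numpy as np
import pandas as pd
import pytest

from dysbio import (
    FilterThresholds,
    apply_filters,
    read_functional_profile,
    read_taxonomic_profile,
)
from dysbio.errors import AlignmentError, EmptyTableError, ProfileParseError
from dysbio.profile_io import (
    TaxonProfileTable,
    write_functional_profile,
    write_taxonomic_profile,
)


def test_metaphlan_dialect_keeps_only_species_rows(tmp_path):
    path = tmp_path / "taxa.tsv"
    path.write_text(
        "clade\ts1\ts2\n"
        "k__Bacteria\t90.0\t80.0\n"
        "k__Bacteria|p__Proteobacteria\t50.0\t40.0\n"
        "k__Bacteria|p__Proteobacteria|c__G|o__E|f__E|g__Escherichia|s__Escherichia_coli\t"
        "30.0\t20.0\n"
    )
    table = read_taxonomic_profile(path)
    assert table.species_ids == ["Escherichia_coli"]
    assert table.abundance.loc["s1", "Escherichia_coli"] == 30.0


def test_metaphlan_dialect_without_species_rows_errors(tmp_path):
    path = tmp_path / "taxa.tsv"
    path.write_text("clade\ts1\nk__Bacteria\t90.0\n")
    with pytest.raises(EmptyTableError):
        read_taxonomic_profile(path)


def test_non_numeric_cell_names_row_and_column(tmp_path):
    path = tmp_path / "taxa.tsv"
    path.write_text("species\ts1\ts2\nSpecies_A\t1.0\tNA\n")
    with pytest.raises(ProfileParseError, match="Species_A.*s2"):
        read_taxonomic_profile(path, dialect="plain-matrix")


def test_plain_matrix_round_trip(tmp_path, toy_tax):
    path = tmp_path / "round.tsv"
    write_taxonomic_profile(toy_tax, path)
    back = read_taxonomic_profile(path, dialect="plain-matrix")
    pd.testing.assert_frame_equal(back.abundance, toy_tax.abundance,
                                  check_exact=False, atol=1e-9)


def test_functional_round_trip(tmp_path, toy_func):
    path = tmp_path / "func.tsv"
    write_functional_profile(toy_func, path)
    back = read_functional_profile(path)
    # round trip renormalizes; community rows already sum to 100 here
    pd.testing.assert_frame_equal(
        back.abundance, toy_func.abundance[sorted(toy_func.abundance.columns)],
        check_exact=False, atol=1e-9,
    )
    assert set(back.stratified.index) == set(toy_func.stratified.index)


def test_functional_profile_drops_special_rows_and_renormalizes(tmp_path):
    path = tmp_path / "func.tsv"
    path.write_text(
        "pathway\ts1\n"
        "UNMAPPED\t40.0\n"
        "PWY-1: some description\t60.0\n"
        "PWY-1: some description|g__X.s__Species_A\t40.0\n"
        "PWY-1: some description|g__X.s__Species_B\t20.0\n"
    )
    table = read_functional_profile(path)
    assert table.pathway_ids == ["PWY-1"]
    assert table.abundance.loc["s1", "PWY-1"] == pytest.approx(100.0)
    assert table.nonzero_contributions("s1") == {
        ("PWY-1", "Species_A"), ("PWY-1", "Species_B"),
    }


def test_orphan_stratified_row_synthesizes_parent(tmp_path):
    path = tmp_path / "func.tsv"
    path.write_text(
        "pathway\ts1\nPWY-1\t95.0\nPWY-9|g__X.s__Species_C\t5.0\n"
    )
    with pytest.warns(UserWarning, match="PWY-9"):
        table = read_functional_profile(path)
    assert table.abundance.loc["s1", "PWY-9"] == pytest.approx(5.0)


def test_no_stratified_rows_leaves_empty_map(tmp_path):
    path = tmp_path / "func.tsv"
    path.write_text("pathway\ts1\nPWY-1\t50.0\nPWY-2\t50.0\n")
    table = read_functional_profile(path)
    assert table.stratified.empty
    assert table.nonzero_pathways("s1") == {"PWY-1", "PWY-2"}


class TestApplyFilters:
    def test_species_threshold_is_inclusive(self, toy_tax, toy_func, toy_cov):
        tax_f, _ = apply_filters(toy_tax, toy_func, toy_cov)
        # 0.05 -> 0; exactly 0.1 retained
        assert tax_f.abundance.loc["s2", "Species_A"] == 0.0
        assert tax_f.abundance.loc["s3", "Species_A"] == 0.1
        # 3 species {0.05, 0.1, 2.0} in s3 -> 2 nonzero (plus Species_D)
        assert int((tax_f.abundance.loc["s3"] > 0).sum()) == 3

    def test_low_coverage_zeroes_community_and_strata(self, toy_tax, toy_func, toy_cov):
        _, func_f = apply_filters(toy_tax, toy_func, toy_cov)
        # PWY-1 in s3 has coverage 0.19 < 0.2
        assert func_f.abundance.loc["s3", "PWY-1"] == 0.0
        assert func_f.stratified.loc[("PWY-1", "Species_A"), "s3"] == 0.0
        # coverage exactly 0.2 retained (PWY-3, s1)
        assert func_f.abundance.loc["s1", "PWY-3"] == 10.0

    def test_function_min_threshold(self, toy_tax, toy_func, toy_cov):
        _, func_f = apply_filters(toy_tax, toy_func, toy_cov)
        assert func_f.abundance.loc["s2", "PWY-2"] == 0.0  # 0.005 < 0.01

    def test_filtering_is_idempotent_and_never_increases(self, toy_tax, toy_func, toy_cov):
        tax1, func1 = apply_filters(toy_tax, toy_func, toy_cov)
        tax2, func2 = apply_filters(tax1, func1, toy_cov)
        pd.testing.assert_frame_equal(tax1.abundance, tax2.abundance)
        pd.testing.assert_frame_equal(func1.abundance, func2.abundance)
        pd.testing.assert_frame_equal(func1.stratified, func2.stratified)
        assert (tax1.abundance.to_numpy() <= toy_tax.abundance.to_numpy()).all()
        assert (func1.abundance.to_numpy() <= toy_func.abundance.to_numpy()).all()

    def test_sample_mismatch_raises(self, toy_tax, toy_func, toy_cov):
        shrunk = TaxonProfileTable(abundance=toy_tax.abundance.iloc[:2])
        with pytest.raises(AlignmentError, match="s3"):
            apply_filters(shrunk, toy_func, toy_cov)

    def test_missing_coverage_treated_as_one_with_warning(self, toy_tax, toy_func):
        with pytest.warns(UserWarning, match="coverage"):
            _, func_f = apply_filters(toy_tax, toy_func, None)
        assert func_f.abundance.loc["s3", "PWY-1"] == 10.0


def test_thresholds_must_be_nonnegative():
    with pytest.raises(ValueError):
        FilterThresholds(species_min=-0.1)
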