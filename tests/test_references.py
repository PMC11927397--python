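"""Prevalence machinery, core-function derivation and pair qualification."""

import numpy as np
import pandas as pd
import pytest

from dysbio import (
    FunctionProfileTable,
    TaxonProfileTable,
    derive_core_functions,
    derive_healthy_pairs,
    prevalence_profile,
)
from dysbio.errors import DysbioError, EmptyTableError
from dysbio.references import _qualify_pairs


def func_table(presence: np.ndarray, pathways, samples) -> FunctionProfileTable:
    return FunctionProfileTable(
        abundance=pd.DataFrame(presence * 1.0, index=samples, columns=pathways)
    )


class TestPrevalence:
    def test_counting(self):
        p1 = func_table(np.array([[1, 1, 0]] * 2 + [[0, 1, 0]] * 3),
                        ["a", "b", "c"], [f"x{i}" for i in range(5)])
        p2 = func_table(np.array([[1, 0, 0]] * 2 + [[0, 0, 0]] * 3),
                        ["a", "b", "c"], [f"y{i}" for i in range(5)])
        prof = prevalence_profile([(p1, "c1"), (p2, "c2")])
        assert prof.prevalence["a"] == pytest.approx(0.4)  # 2/5 and 2/5 pooled
        assert prof.per_cohort.loc["a", "c1"] == pytest.approx(0.4)
        assert prof.per_cohort.loc["a", "c2"] == pytest.approx(0.4)
        assert prof.prevalence["c"] == 0.0
        assert prof.prevalence["b"] == pytest.approx(0.5)

    def test_fully_prevalent_feature(self):
        p = func_table(np.ones((10, 1)), ["a"], [f"s{i}" for i in range(10)])
        assert prevalence_profile([(p, "c")]).prevalence["a"] == 1.0

    def test_zero_samples_error(self):
        empty = func_table(np.empty((0, 1)), ["a"], [])
        with pytest.raises(EmptyTableError):
            prevalence_profile([(empty, "c")])

    def test_cumulative_curve_monotone(self):
        rng = np.random.default_rng(0)
        p = func_table(rng.random((20, 30)) < 0.5, [f"p{i}" for i in range(30)],
                       [f"s{i}" for i in range(20)])
        curve = prevalence_profile([(p, "c")]).cumulative_curve()
        assert (np.diff(curve["fraction_of_features"]) <= 1e-12).all()


class TestCoreFunctions:
    def make(self, n_present, n_samples=10):
        pres = np.zeros((n_samples, 1))
        pres[:n_present] = 1
        return func_table(pres, ["PWY-X"], [f"s{i}" for i in range(n_samples)])

    def test_strictly_above_threshold_included(self):
        core = derive_core_functions([(self.make(9), "c")], threshold=0.8)
        assert "PWY-X" in core

    def test_boundary_excluded_under_strict_inequality(self):
        core = derive_core_functions([(self.make(8), "c")], threshold=0.8)
        assert "PWY-X" not in core

    def test_empty_core_warns(self):
        with pytest.warns(UserWarning, match="no pathway"):
            core = derive_core_functions([(self.make(1), "c")], threshold=0.8)
        assert len(core) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        tables = [(func_table(rng.random((30, 40)) < 0.85,
                              [f"p{i:02d}" for i in range(40)],
                              [f"s{i}" for i in range(30)]), "c")]
        low = set(derive_core_functions(tables, threshold=0.7).pathway_ids)
        high = set(derive_core_functions(tables, threshold=0.9).pathway_ids)
        assert high <= low

    def test_members_sorted(self):
        rng = np.random.default_rng(2)
        t = func_table(rng.random((20, 10)) < 0.95,
                       [f"p{i}" for i in "9543210678"], [f"s{i}" for i in range(20)])
        core = derive_core_functions([(t, "c")])
        assert list(core.pathway_ids) == sorted(core.pathway_ids)


class TestPairQualification:
    """The two-clause rule, tested directly on crafted correlation matrices."""

    def mats(self, rho1, rho2):
        idx = ["A", "B"]
        occ = {"c1": {"A", "B"}, "c2": {"A", "B"}}
        return {
            "c1": pd.DataFrame([[1, rho1], [rho1, 1]], index=idx, columns=idx),
            "c2": pd.DataFrame([[1, rho2], [rho2, 1]], index=idx, columns=idx),
        }, occ

    def test_positive_in_both_included(self):
        mats, occ = self.mats(0.3, 0.3)
        assert _qualify_pairs(mats, occ, 0.1) == {("A", "B")}

    def test_negative_anywhere_excluded(self):
        mats, occ = self.mats(0.5, -0.05)
        assert _qualify_pairs(mats, occ, 0.1) == set()

    def test_never_exceeding_threshold_excluded(self):
        mats, occ = self.mats(0.05, 0.05)
        assert _qualify_pairs(mats, occ, 0.1) == set()

    def test_absent_cohort_does_not_veto(self):
        # pair absent from cohort 2 -> only cohort 1 counts
        mats, occ = self.mats(0.4, -0.5)
        occ["c2"] = {"A"}
        assert _qualify_pairs(mats, occ, 0.1) == {("A", "B")}


class TestDeriveHealthyPairs:
    def test_small_cohort_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        big = TaxonProfileTable(abundance=pd.DataFrame(
            rng.random((30, 5)), columns=list("ABCDE"),
            index=[f"s{i}" for i in range(30)]))
        tiny = TaxonProfileTable(abundance=pd.DataFrame(
            rng.random((4, 5)), columns=list("ABCDE"),
            index=[f"t{i}" for i in range(4)]))
        with pytest.warns(UserWarning, match="skipped"):
            pairs = derive_healthy_pairs([(big, "big"), (tiny, "tiny")], seed=1)
        assert isinstance(len(pairs), int)

    def test_all_cohorts_too_small_errors(self):
        rng = np.random.default_rng(4)
        tiny = TaxonProfileTable(abundance=pd.DataFrame(
            rng.random((4, 5)), columns=list("ABCDE"),
            index=[f"t{i}" for i in range(4)]))
        with pytest.warns(UserWarning):
            with pytest.raises(DysbioError):
                derive_healthy_pairs([(tiny, "tiny")], seed=1)

    def test_invariant_to_cohort_and_species_order(self):
        rng = np.random.default_rng(5)
        cols = list("ABCDEFGH")
        t1 = TaxonProfileTable(abundance=pd.DataFrame(
            rng.random((40, 8)) * 10, columns=cols,
            index=[f"s{i}" for i in range(40)]))
        t2 = TaxonProfileTable(abundance=pd.DataFrame(
            rng.random((40, 8)) * 10, columns=cols,
            index=[f"t{i}" for i in range(40)]))
        fwd = derive_healthy_pairs([(t1, "c1"), (t2, "c2")], seed=2)
        t1r = TaxonProfileTable(abundance=t1.abundance[cols[::-1]])
        rev = derive_healthy_pairs([(t2, "c2"), (t1r, "c1")], seed=2)
        assert fwd.pairs == rev.pairs
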