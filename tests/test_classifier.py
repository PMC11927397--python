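"""Health model fitting, cross-validation protocols and threshold calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from dysbio import (
    HealthIndexModel,
    LabeledCohort,
    calibrate_final_threshold,
    leave_one_cohort_out,
    loocv_scores,
    winning_margins,
    youden_threshold,
    permutation_importance_cv,
)
from dysbio.errors import DysbioError


def gaussian_clouds(n=40, sep=3.0, d=4, seed=0):
    """Two well-separated Gaussian classes in feature space."""
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n // 2, d))
    x1 = rng.standard_normal((n // 2, d)) + sep
    x = pd.DataFrame(np.vstack([x0, x1]), columns=[f"f{i}" for i in range(d)],
                     index=[f"s{i}" for i in range(n)])
    y = pd.Series([0] * (n // 2) + [1] * (n // 2), index=x.index)
    return x, y


class TestFitAndPredict:
    def test_separable_training_accuracy(self):
        x, y = gaussian_clouds(40, seed=1)
        res = HealthIndexModel(x, y).fit(seed=17)
        acc = (res.classify(x) == y).mean()
        assert acc >= 0.95

    def test_identical_features_give_prior_probabilities(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(np.tile(rng.standard_normal(3), (60, 1)),
                         columns=list("abc"))
        y = pd.Series([1] * 40 + [0] * 20)
        res = HealthIndexModel(x, y).fit(seed=17, calibrate=False)
        scores = res.predict_health_score(x)
        assert np.allclose(scores, scores.iloc[0])
        assert abs(scores.iloc[0] - 2 / 3) < 0.15

    def test_same_seed_reproduces_predictions_exactly(self):
        x, y = gaussian_clouds(30, seed=3)
        a = HealthIndexModel(x, y).fit(seed=5).predict_health_score(x)
        b = HealthIndexModel(x, y).fit(seed=5).predict_health_score(x)
        pd.testing.assert_series_equal(a, b)

    def test_scores_in_unit_interval_and_duplicates_identical(self):
        x, y = gaussian_clouds(30, seed=4)
        res = HealthIndexModel(x, y).fit(seed=17, calibrate=False)
        doubled = pd.concat([x, x.iloc[:5].set_axis([f"dup{i}" for i in range(5)])])
        scores = res.predict_health_score(doubled)
        assert scores.between(0, 1).all()
        for i in range(5):
            assert scores[f"dup{i}"] == scores[x.index[i]]

    def test_single_class_labels_error(self):
        x, _ = gaussian_clouds(20, seed=5)
        with pytest.raises(DysbioError):
            HealthIndexModel(x, pd.Series(np.ones(20, dtype=int), index=x.index)).fit()

    def test_column_mismatch_is_named(self):
        x, y = gaussian_clouds(30, seed=6)
        res = HealthIndexModel(x, y).fit(seed=17, calibrate=False)
        with pytest.raises(DysbioError, match="f3"):
            res.predict_health_score(x.drop(columns=["f3"]))

    def test_summary_mentions_threshold_and_features(self):
        x, y = gaussian_clouds(30, seed=7)
        res = HealthIndexModel(x, y).fit(seed=17)
        text = res.summary()
        assert "threshold" in text.lower()
        assert "f0" in text


class TestLOOCV:
    def test_separable_auc(self):
        x, y = gaussian_clouds(30, sep=3.0, seed=8)
        scores = loocv_scores(x, y, seed=17)
        assert roc_auc_score(y, scores) >= 0.9

    def test_scores_invariant_to_row_order(self):
        x, y = gaussian_clouds(24, seed=9)
        fwd = loocv_scores(x, y, seed=17)
        perm = x.index[::-1]
        rev = loocv_scores(x.loc[perm], y.loc[perm], seed=17)
        pd.testing.assert_series_equal(fwd.sort_index(), rev.sort_index())

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame(rng.standard_normal((60, 4)),
                         columns=[f"f{i}" for i in range(4)])
        y = pd.Series(rng.integers(0, 2, 60))
        auc = roc_auc_score(y, loocv_scores(x, y, seed=17))
        assert 0.3 <= auc <= 0.7


class TestYouden:
    def test_perfect_separation_midpoint(self):
        t = youden_threshold([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert t == pytest.approx(0.5)

    def test_identical_distributions_give_zero_j(self):
        scores = np.array([0.3, 0.7, 0.3, 0.7])
        y = np.array([1, 1, 0, 0])
        t = youden_threshold(scores, y)
        pred = scores >= t
        j = pred[y == 1].mean() + (~pred)[y == 0].mean() - 1
        assert j == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(8, 200))
            scores = np.round(rng.random(n), 3)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            t = youden_threshold(scores, y)
            uniq = np.unique(scores)
            cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                                    [uniq[-1] + 1]])
            js = [((scores >= c)[y == 1].mean() + (scores < c)[y == 0].mean() - 1, c)
                  for c in cands]
            best_j = max(j for j, _ in js)
            best_c = min(c for j, c in js if abs(j - best_j) < 1e-12)
            assert t == pytest.approx(best_c)

    def test_single_class_errors(self):
        with pytest.raises(DysbioError):
            youden_threshold([0.1, 0.2], [1, 1])


def test_calibrate_final_threshold_is_the_mean():
    assert calibrate_final_threshold([0.4, 0.36, 0.38]) == pytest.approx(0.38)
    assert calibrate_final_threshold([0.7]) == pytest.approx(0.7)
    with pytest.raises(DysbioError):
        calibrate_final_threshold([])


class TestWinningMargins:
    def test_reference_always_wins(self):
        aucs = pd.DataFrame({"ref": [0.9, 0.8], "other": [0.7, 0.6]},
                            index=["c1", "c2"])
        m = winning_margins(aucs, "ref", competitor="other")
        assert m["winning_margin"] == pytest.approx(0.2)
        assert m["n_losses"] == 0 and np.isnan(m["losing_margin"])

    def test_mixed_wins_and_losses(self):
        aucs = pd.DataFrame({"ref": [0.9, 0.4], "other": [0.7, 0.5]},
                            index=["c1", "c2"])
        m = winning_margins(aucs, "ref", competitor="other")
        assert m["winning_margin"] == pytest.approx(0.2)
        assert m["losing_margin"] == pytest.approx(0.1)

    def test_exact_ties_excluded(self):
        aucs = pd.DataFrame({"ref": [0.8, 0.8], "other": [0.8, 0.8]})
        m = winning_margins(aucs, "ref", competitor="other")
        assert m["n_wins"] == 0 and m["n_losses"] == 0 and m["n_ties"] == 2

    def test_mean_of_others_competitor(self):
        aucs = pd.DataFrame({"ref": [0.9], "a": [0.6], "b": [0.8]})
        m = winning_margins(aucs, "ref")
        assert m["winning_margin"] == pytest.approx(0.2)


class TestLeaveOneCohortOut:
    def make_cohorts(self, n_cohorts=3, n=40, sep=3.0, seed=0, shuffle_last=False):
        cohorts = []
        for c in range(n_cohorts):
            x, y = gaussian_clouds(n, sep=sep, d=4, seed=seed + c)
            if shuffle_last and c == n_cohorts - 1:
                y = pd.Series(np.random.default_rng(seed).permutation(y.to_numpy()),
                              index=y.index)
            cohorts.append(LabeledCohort(x, y, f"c{c}"))
        return cohorts

    def test_one_row_per_cohort_and_high_auc_when_separable(self):
        report = leave_one_cohort_out(self.make_cohorts(seed=12), seed=17)
        assert list(report.per_cohort.index) == ["c0", "c1", "c2"]
        assert (report.per_cohort["auc"] >= 0.85).all()

    def test_shuffled_cohort_scores_near_chance(self):
        report = leave_one_cohort_out(self.make_cohorts(seed=13, shuffle_last=True),
                                      seed=17)
        assert report.per_cohort.loc["c2", "auc"] < 0.75
        assert (report.per_cohort.loc[["c0", "c1"], "auc"] >= 0.85).all()

    def test_needs_two_cohorts(self):
        with pytest.raises(DysbioError):
            leave_one_cohort_out(self.make_cohorts(n_cohorts=1, seed=14))


class TestPermutationImportance:
    def test_determining_feature_ranked_first(self):
        rng = np.random.default_rng(15)
        x = pd.DataFrame(rng.standard_normal((120, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (x["f2"] > 0).astype(int)
        imp = permutation_importance_cv(x, y, seed=17)
        assert imp.loc["f2", "rank"] == 1

    def test_noise_importances_near_zero_and_ranks_are_permutation(self):
        rng = np.random.default_rng(16)
        x = pd.DataFrame(rng.standard_normal((90, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = pd.Series(rng.integers(0, 2, 90))
        imp = permutation_importance_cv(x, y, seed=17)
        assert (imp["importance"].abs() <= 0.1).all()
        assert sorted(imp["rank"]) == [1, 2, 3, 4, 5, 6]
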