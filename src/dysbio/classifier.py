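"""Random-forest health model and its evaluation protocols.

The modelling surface follows the statsmodels convention: a
:class:`HealthIndexModel` is constructed from a feature table plus binary
health labels (1 = healthy, 0 = dysbiotic), and :meth:`HealthIndexModel.fit`
returns a :class:`HealthIndexResults` object carrying the fitted ensemble,
the calibrated decision threshold, feature importances and a ``summary()``
table.  Evaluation protocols — per-sample leave-one-out cross-validation,
leave-one-cohort-out benchmarking, Youden-threshold calibration, winning
margins and permutation importance — are module functions that operate on
the same objects.

The health score is the forest's estimated probability of the healthy class
(``predict_proba``): higher means healthier.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from dysbio.errors import ConfigurationError, DysbioError
from dysbio.features import FEATURE_COLUMNS

__all__ = [
    "DEFAULT_RF_PARAMS",
    "LabeledCohort",
    "HealthIndexModel",
    "HealthIndexResults",
    "EvaluationReport",
    "loocv_scores",
    "leave_one_cohort_out",
    "youden_threshold",
    "calibrate_final_threshold",
    "winning_margins",
    "permutation_importance_cv",
]

#: 500 CART trees on bootstrap samples, sqrt-of-features per split,
#: unlimited depth.  Exposed so every protocol can share one configuration.
DEFAULT_RF_PARAMS: dict = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
}

#: Published operating threshold of the final index (mean of per-iteration
#: training thresholds from the leave-one-cohort-out calibration).
DEFAULT_HEALTH_THRESHOLD = 0.38


def _stable_hash(text: str) -> int:
    return zlib.crc32(str(text).encode()) & 0x7FFFFFFF


def _validate_xy(features: pd.DataFrame, labels) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(labels, index=features.index if len(labels) == len(features) else None)
    if len(y) != len(features):
        raise DysbioError(
            f"feature/label length mismatch: {len(features)} vs {len(y)}"
        )
    if not set(pd.unique(y)) <= {0, 1}:
        raise DysbioError("labels must be binary (1 = healthy, 0 = unhealthy)")
    if features.isna().any().any():
        raise DysbioError("feature table contains missing values")
    return features, y.astype(int)


def _new_forest(seed: int, hyperparams: dict | None = None) -> RandomForestClassifier:
    params = dict(DEFAULT_RF_PARAMS)
    if hyperparams:
        params.update(hyperparams)
    return RandomForestClassifier(random_state=seed, **params)


def _proba_healthy(clf: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    idx = list(clf.classes_).index(1)
    return clf.predict_proba(x)[:, idx]


@dataclass
class LabeledCohort:
    """A cohort's feature table with per-sample health labels."""

    features: pd.DataFrame
    labels: pd.Series
    cohort_id: str

    def __post_init__(self) -> None:
        self.features, self.labels = _validate_xy(self.features, self.labels)


class HealthIndexModel:
    """Health classifier specification: features, labels, hyperparameters.

    Parameters
    ----------
    features
        Samples x features table; column order must match
        :data:`dysbio.features.FEATURE_COLUMNS` when built from profiles.
    labels
        Binary health labels, 1 = healthy.
    cohorts
        Optional per-sample cohort identifiers (enables the
        leave-one-cohort-out protocol through :func:`leave_one_cohort_out`).
    hyperparams
        Overrides for the random-forest defaults.
    """

    def __init__(self, features: pd.DataFrame, labels, cohorts=None,
                 hyperparams: dict | None = None):
        self.features, self.labels = _validate_xy(features, labels)
        self.cohorts = None if cohorts is None else pd.Series(
            cohorts, index=self.features.index
        )
        self.hyperparams = dict(hyperparams or {})
        self.feature_order = tuple(self.features.columns)

    @classmethod
    def from_profiles(cls, tax, func, refs, labels, **kwargs) -> "HealthIndexModel":
        """Featurize filtered profiles and build the model in one step."""
        from dysbio.features import build_feature_table

        return cls(build_feature_table(tax, func, refs), labels, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "health",
                       cohort_col: str | None = None, **kwargs) -> "HealthIndexModel":
        cols = [c for c in frame.columns if c not in {label_col, cohort_col}]
        cohorts = frame[cohort_col] if cohort_col else None
        return cls(frame[cols], frame[label_col], cohorts=cohorts, **kwargs)

    @classmethod
    def from_cohorts(cls, cohorts: list[LabeledCohort], **kwargs) -> "HealthIndexModel":
        """Stack labelled cohorts, prefixing sample ids by cohort id."""
        feats, labs, ids = [], [], []
        for c in cohorts:
            f = c.features.copy()
            f.index = [f"{c.cohort_id}:{s}" for s in f.index]
            feats.append(f)
            labs.append(pd.Series(c.labels.to_numpy(), index=f.index))
            ids.extend([c.cohort_id] * len(f))
        features = pd.concat(feats)
        if features.index.duplicated().any():
            raise DysbioError("duplicate sample ids after cohort prefixing")
        return cls(features, pd.concat(labs), cohorts=ids, **kwargs)

    def fit(self, seed: int = 17, calibrate: bool = True,
            k_folds: int = 5) -> "HealthIndexResults":
        """Fit the forest; calibrate the threshold by Youden on k-fold CV scores.

        With ``calibrate=False`` the published default threshold (0.38) is
        kept.  Deterministic given ``seed``.
        """
        y = self.labels.to_numpy()
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise DysbioError("need >= 2 samples in each class to train")
        clf = _new_forest(seed, self.hyperparams)
        clf.fit(self.features.to_numpy(), y)
        threshold = DEFAULT_HEALTH_THRESHOLD
        cv_scores = None
        if calibrate:
            cv_scores = _cv_scores(self.features, self.labels, seed,
                                   k_folds=k_folds, hyperparams=self.hyperparams)
            threshold = youden_threshold(cv_scores.to_numpy(), y)
        return HealthIndexResults(
            model=self, estimator=clf, threshold=float(threshold), seed=seed,
            cv_scores=cv_scores,
        )


@dataclass
class HealthIndexResults:
    """Fitted health index: estimator + threshold + training provenance."""

    model: HealthIndexModel
    estimator: RandomForestClassifier
    threshold: float
    seed: int
    cv_scores: pd.Series | None = None
    refs_sha256: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ConfigurationError("threshold must lie in [0, 1]")

    @property
    def feature_order(self) -> tuple[str, ...]:
        return self.model.feature_order

    def _check_columns(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_order if c not in features.columns]
        extra = [c for c in features.columns if c not in self.feature_order]
        if missing or extra:
            raise DysbioError(
                f"feature columns mismatch; missing={missing} extra={extra}"
            )
        return features[list(self.feature_order)]

    def predict_health_score(self, features: pd.DataFrame) -> pd.Series:
        """Probability of the healthy class per sample (higher = healthier)."""
        x = self._check_columns(features)
        return pd.Series(_proba_healthy(self.estimator, x.to_numpy()),
                         index=features.index, name="fhi")

    def classify(self, features: pd.DataFrame) -> pd.Series:
        """1 = healthy (score >= threshold), 0 = dysbiotic."""
        return (self.predict_health_score(features) >= self.threshold).astype(int)

    def feature_importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_,
                         index=list(self.feature_order), name="importance")

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured plain text)."""
        y = self.model.labels
        lines = [
            "Functional Health Index — Random Forest".center(58),
            "=" * 58,
            f"No. samples:      {len(y):>6}    healthy: {(y == 1).sum()},"
            f" dysbiotic: {(y == 0).sum()}",
            f"Trees:            {self.estimator.n_estimators:>6}    seed: {self.seed}",
            f"Health threshold: {self.threshold:>9.3f}",
            "-" * 58,
            f"{'feature':<36}{'importance':>12}",
            "-" * 58,
        ]
        for name, imp in self.feature_importances().items():
            lines.append(f"{name:<36}{imp:>12.4f}")
        if self.cv_scores is not None:
            auc = roc_auc_score(y.to_numpy(), self.cv_scores.to_numpy())
            lines += ["-" * 58, f"{'CV AUC (training cohorts)':<36}{auc:>12.3f}"]
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

def _cv_scores(features: pd.DataFrame, labels: pd.Series, seed: int,
               k_folds: int = 5, hyperparams: dict | None = None) -> pd.Series:
    """Out-of-fold health scores from stratified k-fold CV."""
    y = labels.to_numpy()
    k = min(k_folds, int((y == 0).sum()), int((y == 1).sum()))
    if k < 2:
        raise DysbioError("not enough samples per class for cross-validation")
    if k < k_folds:
        warnings.warn(f"fold count reduced to {k}", stacklevel=2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    x = features.to_numpy()
    out = np.empty(len(y))
    for train, test in skf.split(x, y):
        clf = _new_forest(seed, hyperparams)
        clf.fit(x[train], y[train])
        out[test] = _proba_healthy(clf, x[test])
    return pd.Series(out, index=features.index, name="fhi")


def loocv_scores(features: pd.DataFrame, labels, seed: int = 17,
                 hyperparams: dict | None = None) -> pd.Series:
    """Leave-one-out health scores: sample i scored by a forest never shown i.

    Each fold's forest is seeded from ``seed`` plus a stable hash of the
    held-out sample id, so scores do not depend on row order.  Folds whose
    training part loses a class are skipped with a warning and flagged NaN.
    """
    features, y = _validate_xy(features, labels)
    if len(y) < 3:
        raise DysbioError("LOOCV needs >= 3 samples")
    if y.nunique() < 2:
        raise DysbioError("LOOCV needs both classes present")
    input_index = features.index
    order = features.index.argsort()  # canonical row order: scores must not
    features, y = features.iloc[order], y.iloc[order]  # depend on input order
    x = features.to_numpy()
    yv = y.to_numpy()
    scores = np.full(len(yv), np.nan)
    for i, sample in enumerate(features.index):
        mask = np.ones(len(yv), dtype=bool)
        mask[i] = False
        if len(np.unique(yv[mask])) < 2:
            warnings.warn(f"fold for sample '{sample}' lost a class; score flagged",
                          stacklevel=2)
            continue
        clf = _new_forest((seed + _stable_hash(sample)) % (2**31), hyperparams)
        clf.fit(x[mask], yv[mask])
        scores[i] = _proba_healthy(clf, x[i:i + 1])[0]
    return pd.Series(scores, index=features.index, name="fhi").reindex(input_index)


@dataclass
class EvaluationReport:
    """Per-cohort benchmark statistics from leave-one-cohort-out."""

    per_cohort: pd.DataFrame  # index cohort; columns auc, accuracy, threshold, n
    training_thresholds: list[float] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Leave-one-cohort-out evaluation", "-" * 48,
                 self.per_cohort.to_string(float_format=lambda v: f"{v:.3f}")]
        if self.training_thresholds:
            lines.append(
                f"mean training threshold: "
                f"{calibrate_final_threshold(self.training_thresholds):.3f}"
            )
        return "\n".join(lines)


def leave_one_cohort_out(cohorts: list[LabeledCohort], seed: int = 17,
                         k_folds: int = 5,
                         hyperparams: dict | None = None) -> EvaluationReport:
    """Benchmark by holding out each cohort in turn.

    The model is trained on all remaining cohorts; the operating threshold
    for accuracy is Youden's J on k-fold CV scores of the *training* data
    only.  AUC is undefined (NaN) for a single-class held-out cohort.
    """
    if len(cohorts) < 2:
        raise DysbioError("leave_one_cohort_out needs >= 2 cohorts")
    rows = []
    thresholds = []
    for held in cohorts:
        rest = [c for c in cohorts if c.cohort_id != held.cohort_id]
        train_x = pd.concat([c.features for c in rest], ignore_index=True)
        train_y = pd.concat([c.labels for c in rest], ignore_index=True)
        clf = _new_forest(seed, hyperparams)
        clf.fit(train_x.to_numpy(), train_y.to_numpy())
        cv = _cv_scores(train_x, train_y, seed, k_folds=k_folds,
                        hyperparams=hyperparams)
        thr = youden_threshold(cv.to_numpy(), train_y.to_numpy())
        thresholds.append(thr)
        scores = _proba_healthy(clf, held.features.to_numpy())
        yv = held.labels.to_numpy()
        auc = roc_auc_score(yv, scores) if len(np.unique(yv)) == 2 else np.nan
        acc = float(((scores >= thr).astype(int) == yv).mean())
        rows.append({"cohort": held.cohort_id, "auc": auc, "accuracy": acc,
                     "threshold": thr, "n": len(yv)})
    per_cohort = pd.DataFrame(rows).set_index("cohort")
    return EvaluationReport(per_cohort=per_cohort, training_thresholds=thresholds)


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints of consecutive sorted unique scores plus
    sentinels below/above all scores; ties resolve to the smallest
    maximizing candidate.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DysbioError("Youden threshold needs both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def calibrate_final_threshold(thresholds: list[float]) -> float:
    """Arithmetic mean of per-iteration training thresholds."""
    if len(thresholds) == 0:
        raise DysbioError("no thresholds to average")
    return float(np.mean(thresholds))


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def winning_margins(auc_by_method: pd.DataFrame, reference_method: str,
                    competitor: str | None = None) -> dict:
    """Winning/losing AUC margins of a reference method across cohorts.

    ``auc_by_method`` is cohorts x methods.  The competitor is either a named
    method (e.g. the second-best index) or, when None, the mean of all other
    methods.  Cohorts with missing AUCs are dropped with a warning; exact
    ties belong to neither margin set.  A two-sample t-test compares the
    winning against the losing margins.
    """
    if reference_method not in auc_by_method.columns:
        raise DysbioError(f"no AUC column for reference '{reference_method}'")
    df = auc_by_method.copy()
    if competitor is not None:
        if competitor not in df.columns:
            raise DysbioError(f"no AUC column for competitor '{competitor}'")
        comp = df[competitor]
    else:
        comp = df.drop(columns=[reference_method]).mean(axis=1)
    keep = df[reference_method].notna() & comp.notna()
    if (~keep).any():
        warnings.warn(
            f"cohorts dropped for missing AUCs: {list(df.index[~keep])}", stacklevel=2
        )
    diff = (df[reference_method] - comp)[keep]
    wins = diff[diff > 0]
    losses = -diff[diff < 0]
    t_stat = p_value = np.nan
    if len(wins) >= 2 and len(losses) >= 2:
        t_stat, p_value = stats.ttest_ind(wins, losses, equal_var=False)
    return {
        "winning_margin": float(wins.mean()) if len(wins) else np.nan,
        "losing_margin": float(losses.mean()) if len(losses) else np.nan,
        "n_wins": int(len(wins)),
        "n_losses": int(len(losses)),
        "n_ties": int((diff == 0).sum()),
        "t_stat": float(t_stat) if t_stat == t_stat else np.nan,
        "p_value": float(p_value) if p_value == p_value else np.nan,
    }


def permutation_importance_cv(features: pd.DataFrame, labels, k_folds: int = 5,
                              seed: int = 17,
                              hyperparams: dict | None = None) -> pd.DataFrame:
    """Mean validation-AUC drop per permuted feature, averaged over CV folds.

    Returns a frame with ``importance`` (AUC drop) and dense ``rank``
    (1 = most important; ties broken by column order).
    """
    features, y = _validate_xy(features, labels)
    yv = y.to_numpy()
    k = min(k_folds, int((yv == 0).sum()), int((yv == 1).sum()))
    if k < k_folds:
        warnings.warn(f"fold count reduced to {k}", stacklevel=2)
    if k < 2:
        raise DysbioError("not enough samples per class for CV importance")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    x = features.to_numpy()
    drops = np.zeros((k, x.shape[1]))
    for f, (train, test) in enumerate(skf.split(x, yv)):
        clf = _new_forest(seed, hyperparams)
        clf.fit(x[train], yv[train])
        base = roc_auc_score(yv[test], _proba_healthy(clf, x[test]))
        for j in range(x.shape[1]):
            perm = x[test].copy()
            perm[:, j] = rng.permutation(perm[:, j])
            drops[f, j] = base - roc_auc_score(yv[test], _proba_healthy(clf, perm))
    importance = pd.Series(drops.mean(axis=0), index=features.columns,
                           name="importance")
    return pd.DataFrame(
        {"importance": importance, "rank": importance_dense_ranks(importance)}
    )


def importance_dense_ranks(importances: pd.Series) -> pd.Series:
    """Dense ranks by descending importance; ties broken by column order."""
    order = np.lexsort((np.arange(len(importances)), -importances.to_numpy()))
    ranks = np.empty(len(importances), dtype=int)
    ranks[order] = np.arange(1, len(importances) + 1)
    return pd.Series(ranks, index=importances.index, name="rank")
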