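"""Shadow-feature (Boruta) relevance screening.

Each round appends a randomly permuted "shadow" copy of every feature,
fits a random forest, and records permutation importances.  A feature
scores a *hit* when its importance exceeds the round's maximum shadow
importance.  After ``n_rounds`` a two-sided binomial test against p = 0.5
(Bonferroni-corrected over the features under test) assigns each feature
to Confirmed (better than random), Rejected (no better than random) or
Tentative (undecided).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from dysbio.errors import DysbioError
from dysbio.classifier import importance_dense_ranks

__all__ = ["boruta_relevance", "importance_ranks"]

#: forest used inside the shadow rounds; lighter than the scoring forest
#: because it is refitted n_rounds times.
BORUTA_RF_PARAMS: dict = {"n_estimators": 50, "max_features": "sqrt"}


def _round_importances(x: np.ndarray, y: np.ndarray, seed: int,
                       rf_params: dict) -> np.ndarray:
    """Permutation importances for all columns of x.

    Measured as the drop in held-out AUC when a column is permuted: the
    forest is fitted on a random stratified half of the samples and scored
    on the other half, so memorized noise does not masquerade as importance.
    """
    rng = np.random.default_rng(seed)
    perm_idx = rng.permutation(len(y))
    train_mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):  # stratified half/half split
        members = perm_idx[y[perm_idx] == cls]
        train_mask[members[::2]] = True
    train = np.flatnonzero(train_mask)
    test = np.flatnonzero(~train_mask)
    if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
        train = test = np.arange(len(y))
    clf = RandomForestClassifier(random_state=seed, **rf_params)
    clf.fit(x[train], y[train])
    idx = list(clf.classes_).index(1)
    base = roc_auc_score(y[test], clf.predict_proba(x[test])[:, idx])
    imps = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        perm = x[test].copy()
        perm[:, j] = rng.permutation(perm[:, j])
        imps[j] = base - roc_auc_score(y[test], clf.predict_proba(perm)[:, idx])
    return imps


def boruta_relevance(features: pd.DataFrame, labels, n_rounds: int = 100,
                     alpha: float = 0.05, seed: int = 0,
                     rf_params: dict | None = None) -> pd.DataFrame:
    """Run the shadow-feature procedure.

    Returns a frame indexed by feature with columns ``status`` (Confirmed /
    Tentative / Rejected), ``hits``, ``mean_importance`` and ``rank``
    (1 = most important).  Constant features are auto-Rejected; fewer than
    five rounds make the binomial test meaningless and raise an error.
    Deterministic given ``seed``.
    """
    if n_rounds < 5:
        raise DysbioError("n_rounds < 5: binomial test underpowered")
    if features.shape[1] < 2:
        raise DysbioError("need >= 2 features")
    y = pd.Series(labels).to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise DysbioError("labels must be binary")
    params = dict(BORUTA_RF_PARAMS)
    if rf_params:
        params.update(rf_params)

    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    tested = [n for n, c in zip(names, constant) if not c]
    xt = x[:, ~constant]

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(tested), dtype=int)
    imp_history = np.zeros((n_rounds, len(tested)))
    for r in range(n_rounds):
        shadow = np.column_stack(
            [rng.permutation(xt[:, j]) for j in range(xt.shape[1])]
        )
        both = np.hstack([xt, shadow])
        imps = _round_importances(both, y, int(rng.integers(2**31)), params)
        real, sh = imps[: xt.shape[1]], imps[xt.shape[1]:]
        hits += real > sh.max()
        imp_history[r] = real

    # two-sided binomial test vs p=0.5, Bonferroni over features under test
    n_tests = max(len(tested), 1)
    status = {}
    for j, name in enumerate(tested):
        p_hi = stats.binom.sf(hits[j] - 1, n_rounds, 0.5)  # P(X >= hits)
        p_lo = stats.binom.cdf(hits[j], n_rounds, 0.5)     # P(X <= hits)
        if p_hi * n_tests < alpha:
            status[name] = "Confirmed"
        elif p_lo * n_tests < alpha:
            status[name] = "Rejected"
        else:
            status[name] = "Tentative"

    mean_imp = pd.Series(0.0, index=names, name="mean_importance")
    mean_imp[tested] = imp_history.mean(axis=0)
    hit_col = pd.Series(0, index=names, name="hits")
    hit_col[tested] = hits
    out = pd.DataFrame(
        {
            "status": [status.get(n, "Rejected") for n in names],
            "hits": hit_col,
            "mean_importance": mean_imp,
            "rank": importance_dense_ranks(mean_imp),
        },
        index=pd.Index(names, name="feature"),
    )
    return out


def importance_ranks(importances: pd.Series | dict) -> pd.Series:
    """Ranks by descending mean importance, 1 = most important.

    Ties break by feature-name order so ranks are a permutation of 1..n.
    """
    if isinstance(importances, dict):
        importances = pd.Series(importances)
    if len(importances) == 0:
        raise DysbioError("no importances to rank")
    ordered = importances.sort_index()
    return importance_dense_ranks(ordered).reindex(importances.index)
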