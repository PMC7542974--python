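"""Machine-learning marker screening.

Four complementary screens: random-forest permutation importance, SVM
feature ranking (|weight| for the linear kernel, recursive elimination for
nonlinear kernels), Boruta shadow-feature confirmation, and a collaborative
screen that requires resampled significance in PLS-DA, random forest, or
linear SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .tables_io import PeakTable, SampleMetadata
from .stats_multi import _nipals_pls

__all__ = ["ScreenResult", "rf_importance", "svm_rank", "boruta_confirm",
           "joint_screen"]


@dataclass
class ScreenResult:
    method: str
    table: pd.DataFrame            # index = variable_id
    extras: dict = field(default_factory=dict)


def _xy(table: PeakTable, meta: SampleMetadata, max_groups: int | None = None):
    X = table.values
    if np.isnan(X).any():
        raise ValueError("missing values present; impute first")
    meta = meta.aligned_to(table)
    labels = meta.groups().to_numpy()
    levels = sorted(np.unique(labels))
    if len(levels) < 2:
        raise ValueError("screening needs >= 2 groups")
    if max_groups is not None and len(levels) > max_groups:
        raise ValueError(f"at most {max_groups} groups supported")
    y = np.searchsorted(levels, labels)
    return X, y, levels


def _ranks(scores: np.ndarray) -> np.ndarray:
    # descending; ties broken by original position for determinism
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def rf_importance(
    table: PeakTable, meta: SampleMetadata,
    n_trees: int = 500, seed: int | None = None, n_repeats: int = 3,
    cv_folds: int = 3,
) -> ScreenResult:
    """Random-forest permutation importance (mean decrease in accuracy).

    Importance must be measured on data the forest has not memorized, so it
    is estimated by stratified cross-validation: per fold, a seeded forest
    is fitted on the training part and each variable's importance is the
    held-out accuracy drop when that variable's values are permuted,
    averaged across folds.  The out-of-bag error of a forest on the full
    data is reported alongside.
    """
    X, y, levels = _xy(table, meta)
    rng = np.random.RandomState(seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=rng, n_jobs=1)
    forest.fit(X, y)

    cv = StratifiedKFold(min(cv_folds, np.bincount(y).min()), shuffle=True,
                         random_state=rng)
    means = np.zeros(X.shape[1])
    sds = np.zeros(X.shape[1])
    n_folds = 0
    for train, test in cv.split(X, y):
        fold_forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rng,
            n_jobs=1).fit(X[train], y[train])
        imp = permutation_importance(fold_forest, X[test], y[test],
                                     n_repeats=n_repeats, random_state=rng,
                                     n_jobs=1)
        means += imp.importances_mean
        sds += imp.importances_std
        n_folds += 1
    frame = pd.DataFrame({
        "importance": means / n_folds,
        "importance_sd": sds / n_folds,
    }, index=table.variable_ids)
    frame["rank"] = _ranks(frame["importance"].to_numpy())
    frame = frame.sort_values("rank")
    return ScreenResult("rf", frame, {"oob_error": 1.0 - forest.oob_score_,
                                      "group_levels": levels})


def svm_rank(
    table: PeakTable, meta: SampleMetadata,
    kernel: str = "linear", seed: int | None = None, cv_folds: int = 5,
    rfe_drop: float = 0.2,
) -> ScreenResult:
    """Support-vector-machine feature ranking (two groups).

    Features are standardized internally.  The linear kernel ranks by
    |weight|; polynomial, radial, and sigmoid kernels rank by recursive
    feature elimination: at each step the least useful fraction of features
    (those whose removal least hurts cross-validated accuracy, approximated
    by permutation importance of the current model) is eliminated.
    """
    if kernel not in {"linear", "polynomial", "radial", "sigmoid"}:
        raise ValueError(f"unknown kernel {kernel!r}")
    X, y, levels = _xy(table, meta, max_groups=2)
    X = StandardScaler().fit_transform(X)
    sk_kernel = {"linear": "linear", "polynomial": "poly", "radial": "rbf",
                 "sigmoid": "sigmoid"}[kernel]
    cv = StratifiedKFold(min(cv_folds, np.bincount(y).min()), shuffle=True,
                         random_state=seed)
    svc = SVC(kernel=sk_kernel, C=1.0, gamma="scale")
    cv_acc = float(np.mean(cross_val_score(svc, X, y, cv=cv, n_jobs=1)))

    if kernel == "linear":
        svc.fit(X, y)
        scores = np.abs(svc.coef_).ravel()
        frame = pd.DataFrame({"importance": scores}, index=table.variable_ids)
        frame["rank"] = _ranks(scores)
    else:
        # RFE by permutation importance of the fitted kernel machine
        rng = np.random.RandomState(seed)
        remaining = list(range(X.shape[1]))
        elimination_order: list[int] = []
        while len(remaining) > 1:
            sub = X[:, remaining]
            model = SVC(kernel=sk_kernel, C=1.0, gamma="scale").fit(sub, y)
            imp = permutation_importance(model, sub, y, n_repeats=3,
                                         random_state=rng, n_jobs=1)
            n_drop = max(1, int(len(remaining) * rfe_drop))
            worst = np.argsort(imp.importances_mean)[:n_drop]
            for w in sorted(worst, reverse=True):
                elimination_order.append(remaining.pop(w))
        elimination_order.extend(remaining)
        # eliminated last = most important
        ranks = np.empty(X.shape[1], dtype=int)
        for r, j in enumerate(reversed(elimination_order), start=1):
            ranks[j] = r
        frame = pd.DataFrame(
            {"importance": (X.shape[1] - ranks + 1).astype(float)},
            index=table.variable_ids)
        frame["rank"] = ranks
    frame = frame.sort_values("rank")
    return ScreenResult(f"svm_{kernel}", frame,
                        {"cv_accuracy": cv_acc, "group_levels": levels})


def boruta_confirm(
    table: PeakTable, meta: SampleMetadata,
    candidates: list[str] | None = None,
    max_iter: int = 100, n_trees: int = 200,
    alpha: float = 0.01, seed: int | None = None,
) -> ScreenResult:
    """Boruta all-relevant confirmation against shadow features.

    Each iteration appends a row-permuted ("shadow") copy of every candidate,
    fits a seeded forest, and scores a hit for candidates whose importance
    exceeds the maximum shadow importance.  A two-sided binomial test on the
    hit count over iterations (Bonferroni-corrected across candidates)
    declares variables confirmed or rejected; undecided variables at
    ``max_iter`` stay tentative.
    """
    if candidates is None:
        candidates = table.variable_ids
    if not candidates:
        raise ValueError("no candidate variables supplied")
    unknown = set(candidates) - set(table.variable_ids)
    if unknown:
        raise ValueError(f"candidates not in table: {sorted(unknown)}")
    X_all, y, levels = _xy(table, meta)
    col_idx = [table.variable_ids.index(c) for c in candidates]
    X = X_all[:, col_idx]
    rng = np.random.RandomState(seed)
    n, p = X.shape

    active = np.ones(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    decision = np.array(["tentative"] * p, dtype=object)

    for _ in range(max_iter):
        act = np.flatnonzero(active)
        if len(act) == 0:
            break
        shadows = X[:, act].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        Xi = np.hstack([X[:, act], shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rng,
            n_jobs=1)
        forest.fit(Xi, y)
        imp = forest.feature_importances_
        shadow_max = imp[len(act):].max()
        hits[act] += (imp[:len(act)] > shadow_max).astype(int)
        trials[act] += 1
        # binomial decisions, Bonferroni over candidates
        for j in act:
            k, t = hits[j], trials[j]
            if t < 5:
                continue
            p_hi = stats.binomtest(k, t, 0.5, alternative="greater").pvalue
            p_lo = stats.binomtest(k, t, 0.5, alternative="less").pvalue
            if p_hi < alpha / p:
                decision[j] = "confirmed"
                active[j] = False
            elif p_lo < alpha / p:
                decision[j] = "rejected"
                active[j] = False

    frame = pd.DataFrame({
        "hits": hits, "trials": trials,
        "hit_rate": np.divide(hits, np.maximum(trials, 1)),
        "decision": decision,
    }, index=pd.Index(candidates, name="variable_id"))
    frame["rank"] = _ranks(frame["hit_rate"].to_numpy())
    return ScreenResult("boruta", frame, {"alpha": alpha, "max_iter": max_iter,
                                          "group_levels": levels})


def _accuracy_drop(model, X, y, rng) -> np.ndarray:
    """Per-variable accuracy drop when that variable is shuffled."""
    base = np.mean(model.predict(X) == y)
    drops = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        saved = X[:, j].copy()
        rng.shuffle(X[:, j])
        drops[j] = base - np.mean(model.predict(X) == y)
        X[:, j] = saved
    return drops


class _PLSClassifier:
    """Minimal 1-component PLS-DA classifier for the collaborative screen."""

    def fit(self, X, y):
        self.xm_ = X.mean(axis=0)
        self.xs_ = X.std(axis=0, ddof=1)
        self.xs_[self.xs_ == 0] = 1.0
        Xc = (X - self.xm_) / self.xs_
        yc = (y - y.mean()).astype(float)[:, None]
        W, T, P, C = _nipals_pls(Xc, yc, 1)
        self.w_ = W[:, 0]
        self.cut_ = float(np.mean([T[y == g, 0].mean() for g in np.unique(y)]))
        self.sign_ = 1.0 if T[y == 1, 0].mean() > T[y == 0, 0].mean() else -1.0
        return self

    def predict(self, X):
        t = ((X - self.xm_) / self.xs_) @ self.w_
        return (self.sign_ * (t - self.cut_) > 0).astype(int)


def joint_screen(
    table: PeakTable, meta: SampleMetadata,
    bootstraps: int = 50, seed: int | None = None, alpha: float = 0.05,
) -> ScreenResult:
    """Collaborative screening across PLS-DA, random forest and linear SVM.

    For each bootstrap resample, each classifier is fitted and each
    variable's out-of-bag accuracy drop under shuffling is recorded.  A
    variable earns tier A for a classifier when its drop is positive in
    significantly more than half of the bootstraps (one-sided binomial test
    at ``alpha``); the final marker set is the union of tier-A variables
    across the three classifiers.
    """
    if bootstraps <= 0:
        raise ValueError("bootstraps must be positive")
    X, y, levels = _xy(table, meta, max_groups=2)
    n, p = X.shape
    if n < 10:
        raise ValueError("joint screening needs >= 10 samples")
    rng = np.random.RandomState(seed)
    classifiers = {
        "plsda": lambda: _PLSClassifier(),
        "rf": lambda: RandomForestClassifier(n_estimators=100,
                                             max_features="sqrt",
                                             random_state=rng, n_jobs=1),
        "svm": lambda: SVC(kernel="linear", C=1.0),
    }
    positive = {name: np.zeros(p, dtype=int) for name in classifiers}
    for _ in range(bootstraps):
        idx = rng.choice(n, size=n, replace=True)
        if len(np.unique(y[idx])) < 2:
            idx = np.concatenate([idx[:-2], np.flatnonzero(y == 0)[:1],
                                  np.flatnonzero(y == 1)[:1]])
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) < 2 or len(np.unique(y[oob])) < 2:
            oob = np.arange(n)
        for name, make in classifiers.items():
            model = make().fit(X[idx], y[idx])
            drops = _accuracy_drop(model, X[oob].copy(), y[oob], rng)
            positive[name] += (drops > 0).astype(int)

    frame = pd.DataFrame(index=pd.Index(table.variable_ids, name="variable_id"))
    tier_a_any = np.zeros(p, dtype=bool)
    for name in classifiers:
        k = positive[name]
        pvals = np.array([
            stats.binomtest(int(ki), bootstraps, 0.5, alternative="greater").pvalue
            for ki in k])
        tier = np.where(pvals < alpha, "A", np.where(k > bootstraps / 2, "B",
                                                     "rejected"))
        frame[f"{name}_positive"] = k
        frame[f"{name}_p"] = pvals
        frame[f"{name}_tier"] = tier
        tier_a_any |= tier == "A"
    frame["selected"] = tier_a_any
    return ScreenResult("joint", frame,
                        {"bootstraps": bootstraps, "alpha": alpha,
                         "final_set": list(frame.index[tier_a_any])})
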