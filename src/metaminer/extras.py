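"""Clustering, distance analysis, ROC, power analysis, Venn and regression
utilities."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.power import (FTestAnovaPower, NormalIndPower,
                                     TTestIndPower, TTestPower)

from .tables_io import PeakTable, SampleMetadata

__all__ = ["ClusterResult", "DISTANCES", "LINKAGES", "pairwise_distances",
           "hcluster", "roc", "power_analysis", "venn", "linear_regression"]

DISTANCES = ("euclidean", "correlation", "minkowski", "canberra", "binary",
             "manhattan", "maximum")
LINKAGES = ("ward", "single", "complete", "average", "mcquitty", "median",
            "centroid")

_SCIPY_METRIC = {"euclidean": "euclidean", "correlation": "correlation",
                 "minkowski": "minkowski", "canberra": "canberra",
                 "binary": "jaccard", "manhattan": "cityblock",
                 "maximum": "chebyshev"}
_SCIPY_LINKAGE = {"ward": "ward", "single": "single", "complete": "complete",
                  "average": "average", "mcquitty": "weighted",
                  "median": "median", "centroid": "centroid"}


@dataclass
class ClusterResult:
    linkage_tree: np.ndarray           # scipy linkage matrix
    item_ids: list[str]
    distance: str
    linkage: str
    assignments: pd.Series | None = None
    cluster_profiles: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def pairwise_distances(X: np.ndarray, distance: str = "euclidean",
                       minkowski_p: float = 3.0) -> np.ndarray:
    """Condensed pairwise distances under one of the seven supported metrics.

    ``binary`` is the Jaccard distance on the nonzero pattern; ``maximum``
    is the Chebyshev distance; Minkowski defaults to exponent 3 to be
    distinct from both Euclidean and Manhattan.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    if distance == "binary":
        return pdist(X != 0, metric="jaccard")
    if distance == "minkowski":
        return pdist(X, metric="minkowski", p=minkowski_p)
    if distance == "correlation":
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(
                f"correlation distance undefined for constant items at "
                f"positions {bad}")
    return pdist(X, metric=_SCIPY_METRIC[distance])


def hcluster(
    table: PeakTable,
    axis: Literal["samples", "variables"] = "samples",
    distance: str = "euclidean",
    linkage: str = "ward",
    k: int | None = None,
    meta: SampleMetadata | None = None,
    minkowski_p: float = 3.0,
) -> ClusterResult:
    """Agglomerative hierarchical clustering of samples or variables.

    Ward uses the squared-Euclidean update (the ward.D2 convention);
    mcquitty, median and centroid are WPGMA, WPGMC and UPGMC respectively.
    With ``k`` the tree is cut into ``k`` clusters; in sub-cluster mode
    (``axis='variables'`` with metadata) each cluster's mean intensity per
    sample group is reported.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    data = table.data if axis == "samples" else table.data.T
    if data.isna().any().any():
        raise ValueError("missing values present; impute first")
    items = list(data.index)
    if k is not None and k > len(items):
        raise ValueError(f"k = {k} exceeds the {len(items)} items")
    X = data.to_numpy()
    condensed = pairwise_distances(X, distance, minkowski_p)
    tree = hierarchy.linkage(condensed, method=_SCIPY_LINKAGE[linkage])
    assignments = None
    profiles = None
    if k is not None:
        flat = hierarchy.fcluster(tree, t=k, criterion="maxclust")
        assignments = pd.Series(flat, index=items, name="cluster")
        if axis == "variables" and meta is not None:
            groups = meta.aligned_to(table).groups()
            rows = []
            for cluster_id in sorted(assignments.unique()):
                members = assignments.index[assignments == cluster_id]
                sub = table.data[members]
                for level in sorted(groups.unique()):
                    sel = groups.index[groups == level]
                    rows.append({"cluster": cluster_id, "group": level,
                                 "mean_intensity": float(sub.loc[sel].mean().mean()),
                                 "n_variables": len(members)})
            profiles = pd.DataFrame(rows)
    return ClusterResult(tree, items, distance, linkage, assignments, profiles)


def roc(scores: Sequence[float], labels: Sequence[int]
        ) -> tuple[float, pd.DataFrame, float]:
    """ROC analysis of a per-sample score against a binary label.

    AUC is computed by the rank (Mann-Whitney) formulation with midrank tie
    correction.  Returns (auc, curve, youden_cutoff) where curve holds
    (threshold, fpr, tpr) at every distinct score and the cutoff maximizes
    Youden's J = TPR - FPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1, n0 = int(labels.sum()), int((1 - labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    thresholds = np.unique(scores)[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        pred = scores >= t
        rows.append({"threshold": float(t),
                     "fpr": float((pred & (labels == 0)).sum() / n0),
                     "tpr": float((pred & (labels == 1)).sum() / n1)})
    curve = pd.DataFrame(rows)
    j = curve["tpr"] - curve["fpr"]
    best = curve.loc[j.idxmax()]
    return float(auc), curve, float(best["threshold"])


def power_analysis(
    kind: Literal["two_sample_t", "paired_t", "one_way_anova",
                  "two_proportions"],
    effect_size: float,
    alpha: float = 0.05,
    power: float | None = None,
    n: float | None = None,
    k_groups: int = 3,
) -> float:
    """Solve for the missing one of {power, per-group n}.

    ``effect_size`` is standardized (Cohen's d for t-tests, f for ANOVA,
    h for proportions).  Sample sizes are rounded up.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if (power is None) == (n is None):
        raise ValueError("exactly one of power and n must be omitted")
    solvers = {"two_sample_t": TTestIndPower(), "paired_t": TTestPower(),
               "one_way_anova": FTestAnovaPower(),
               "two_proportions": NormalIndPower()}
    if kind not in solvers:
        raise ValueError(f"unknown power-analysis kind {kind!r}")
    solver = solvers[kind]
    kwargs = {"effect_size": effect_size, "alpha": alpha}
    if kind == "one_way_anova":
        kwargs["k_groups"] = k_groups
    # statsmodels' ANOVA solver works in total observations, the others in
    # per-group (or per-pair) observations
    if power is None:
        if kind == "one_way_anova":
            kwargs["nobs"] = n * k_groups
        elif kind == "paired_t":
            kwargs["nobs"] = n
        else:
            kwargs["nobs1"] = n
        return float(solver.power(**kwargs))
    kwargs["power"] = power
    result = float(solver.solve_power(**kwargs))
    if kind == "one_way_anova":
        result = result / k_groups
    return int(np.ceil(result))


def venn(sets: Mapping[str, Sequence]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region counts and element membership for 2-6 named sets.

    Returns (regions, membership).  ``regions`` has one row per non-empty
    combination pattern (2^m - 1 rows) with the count of elements exactly in
    that combination; counts sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 6:
        raise ValueError(f"venn supports 2-6 sets, got {len(names)}")
    as_sets = {name: set(sets[name]) for name in names}
    universe = sorted(set().union(*as_sets.values()), key=str)
    membership = pd.DataFrame(
        {name: [e in as_sets[name] for e in universe] for name in names},
        index=pd.Index(universe, name="element"))
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            in_these = membership[list(combo)].all(axis=1)
            out_others = ~membership[[n for n in names if n not in combo]].any(
                axis=1) if len(combo) < len(names) else pd.Series(
                True, index=membership.index)
            rows.append({"region": "&".join(combo),
                         "n_sets": r,
                         "count": int((in_these & out_others).sum())})
    return pd.DataFrame(rows), membership


def linear_regression(y: Sequence[float], X: pd.DataFrame | np.ndarray
                      ) -> pd.DataFrame:
    """Ordinary least squares with intercept.

    Returns a coefficient table (coef, se, t, p) with R-squared attached in
    ``frame.attrs``; collinear predictors raise an error naming them.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float).T).T,
                         columns=[f"x{i+1}" for i in
                                  range(np.atleast_2d(np.asarray(X).T).T.shape[1])])
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X.astype(float))
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0)
        suspects = sorted(set(
            [corr.index[i] for i, j in zip(*np.where(corr.values > 1 - 1e-10))]))
        raise ValueError(f"rank-deficient design; collinear columns: {suspects}")
    fit = sm.OLS(y, design).fit()
    out = pd.DataFrame({"coef": fit.params, "se": fit.bse,
                        "t": fit.tvalues, "p": fit.pvalues})
    out.attrs["r_squared"] = float(fit.rsquared)
    out.attrs["r_squared_adj"] = float(fit.rsquared_adj)
    return out
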