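"""Univariate differential testing with multiple-testing correction.

Two-group tests (Welch/pooled t, Mann-Whitney, and their paired variants)
and multi-group tests (one-way ANOVA, Kruskal-Wallis) are run per variable;
raw p-values are corrected across variables by Bonferroni, Holm, or the
Benjamini-Hochberg FDR (the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import PeakTable, SampleMetadata

__all__ = ["UniTestSpec", "run_univariate", "adjust_pvalues", "select_differential"]

TWO_GROUP_TESTS = {"t_test", "welch_t", "mann_whitney", "paired_t", "wilcoxon_signed"}
MULTI_GROUP_TESTS = {"anova", "kruskal_wallis"}


@dataclass
class UniTestSpec:
    test: Literal["t_test", "welch_t", "mann_whitney", "anova",
                  "kruskal_wallis", "paired_t", "wilcoxon_signed"] = "welch_t"
    correction: Literal["bonferroni", "holm", "fdr"] = "fdr"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.test not in TWO_GROUP_TESTS | MULTI_GROUP_TESTS:
            raise ValueError(f"unknown test {self.test!r}")


def adjust_pvalues(p: Sequence[float], method: Literal["bonferroni", "holm", "fdr"]
                   ) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``fdr`` is Benjamini-Hochberg step-up with monotonicity enforcement.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "holm": "holm", "fdr": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction {method!r}")
    return multipletests(p, method=key)[1]


def _test_two(x: np.ndarray, y: np.ndarray, test: str) -> tuple[float, float]:
    if test == "t_test":
        return stats.ttest_ind(x, y, equal_var=True)[:2]
    if test == "welch_t":
        return stats.ttest_ind(x, y, equal_var=False)[:2]
    if test == "mann_whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "paired_t":
        return stats.ttest_rel(x, y)[:2]
    if test == "wilcoxon_signed":
        res = stats.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(test)


def run_univariate(
    table: PeakTable, meta: SampleMetadata, spec: UniTestSpec | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable differential test between sample groups.

    Two-group tests compare ``groups[0]`` (reference) against ``groups[1]``;
    the reported fold change is group2/group1 on the raw intensity scale
    (back-transformed when the table is flagged log-transformed).  Variables
    with fewer than two observations in any group are skipped with a warning.
    """
    spec = spec or UniTestSpec()
    meta = meta.aligned_to(table)
    labels = meta.groups()
    levels = list(groups) if groups is not None else sorted(labels.unique())
    unknown = set(levels) - set(labels.unique())
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if spec.test in TWO_GROUP_TESTS and len(levels) != 2:
        raise ValueError(f"{spec.test} requires exactly 2 groups, got {len(levels)}")
    if spec.test in MULTI_GROUP_TESTS and len(levels) < 2:
        raise ValueError(f"{spec.test} requires >= 2 groups")

    group_index = {g: labels.index[labels == g] for g in levels}
    rows, skipped = [], []
    for var in table.variable_ids:
        col = table.data[var]
        samples = [col.loc[group_index[g]].dropna().to_numpy() for g in levels]
        if any(len(s) < 2 for s in samples):
            skipped.append(var)
            continue
        means = {f"mean_{g}": float(np.mean(s)) for g, s in zip(levels, samples)}
        row: dict = {"variable_id": var, **means}
        if len(levels) == 2:
            m1, m2 = np.mean(samples[0]), np.mean(samples[1])
            if table.log_transformed:
                row["fold_change"] = float(np.exp(m2 - m1))
            else:
                row["fold_change"] = float(m2 / m1) if m1 != 0 else np.nan
        if spec.test in TWO_GROUP_TESTS:
            statistic, p = _test_two(samples[0], samples[1], spec.test)
        elif spec.test == "anova":
            statistic, p = stats.f_oneway(*samples)[:2]
        else:
            statistic, p = stats.kruskal(*samples)[:2]
        row["statistic"] = float(statistic)
        row["p"] = float(p)
        rows.append(row)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} variable(s) with < 2 observations per "
            f"group: {skipped[:10]}", stacklevel=2)
    result = pd.DataFrame(rows)
    if len(result):
        result = result.set_index("variable_id")
        result["p_adjusted"] = adjust_pvalues(result["p"].to_numpy(),
                                              spec.correction)
    return result


def select_differential(
    uni: pd.DataFrame, multi: pd.DataFrame,
    p_threshold: float = 0.05, vip_threshold: float = 1.0,
    p_column: str = "p",
) -> list[str]:
    """Variables with p strictly below ``p_threshold`` and VIP strictly above
    ``vip_threshold`` — the conventional joint univariate/OPLS-DA selection
    rule."""
    if "vip" not in multi.columns:
        raise ValueError("multivariate table lacks a 'vip' column")
    shared = uni.index.intersection(multi.index)
    p = uni.loc[shared, p_column]
    vip = multi.loc[shared, "vip"]
    mask = (p < p_threshold) & (vip > vip_threshold)
    return list(shared[mask])
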