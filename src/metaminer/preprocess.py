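"""Peak-table preprocessing: outlier replacement, missing-value imputation,
normalization, transformation and basic statistics.

The preprocessing chain targets the usual pathologies of MS peak tables:
gross outliers from integration failures, missing values concentrated below
the detection limit, per-sample intensity drift with injection order, and
skewed intensity distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tables_io import PeakTable, SampleMetadata

__all__ = [
    "PreprocessReport",
    "replace_outliers",
    "impute_missing",
    "normalize",
    "transform",
    "basic_statistics",
]


@dataclass
class PreprocessReport:
    """Audit record of a preprocessing step."""

    step: str
    parameters: dict = field(default_factory=dict)
    per_variable: pd.DataFrame | None = None
    per_sample: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.per_variable is not None:
            return self.per_variable
        if self.per_sample is not None:
            return self.per_sample
        return pd.DataFrame()


def replace_outliers(
    table: PeakTable, side: Literal["both", "high"] = "both"
) -> tuple[PeakTable, PreprocessReport]:
    """Replace per-variable outliers by the maximum of the remaining data.

    A data point is an outlier when it lies more than three sample standard
    deviations (n-1 divisor) from the variable mean, both computed once over
    the non-missing values.  Flagged points are replaced by the maximum of
    the non-flagged values.  Variables with fewer than three observed values
    are skipped with a warning.  ``side='high'`` restricts flagging to the
    upper tail.
    """
    data = table.data.copy()
    counts = pd.Series(0, index=data.columns, dtype=int)
    skipped = []
    for var in data.columns:
        x = data[var]
        obs = x.dropna()
        if len(obs) < 3:
            skipped.append(var)
            continue
        mean, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        dev = (obs - mean) if side == "high" else (obs - mean).abs()
        flagged = obs.index[dev > 3 * sd]
        if len(flagged) == 0 or len(flagged) == len(obs):
            continue
        replacement = obs.drop(flagged).max()
        data.loc[flagged, var] = replacement
        counts[var] = len(flagged)
    if skipped:
        warnings.warn(
            f"outlier replacement skipped {len(skipped)} variable(s) with "
            f"< 3 observed values: {skipped[:10]}", stacklevel=2)
    report = PreprocessReport(
        step="replace_outliers",
        parameters={"rule": "|x - mean| > 3*SD", "side": side},
        per_variable=pd.DataFrame({"n_outliers_replaced": counts}),
    )
    return PeakTable(data, table.variable_meta, table.log_transformed), report


def impute_missing(
    table: PeakTable,
    method: Literal["minimum", "knn", "qrilc"] = "minimum",
    k: int = 10,
    seed: int | None = None,
) -> PeakTable:
    """Impute missing intensities.

    ``minimum``
        Each missing cell takes the variable's observed minimum — a crude
        detection-limit surrogate.
    ``knn``
        Each missing cell takes the unweighted mean of the ``k`` nearest
        samples (Euclidean distance over variables observed in both samples,
        on z-scored data), with ``k`` capped at n-1.
    ``qrilc``
        Quantile-regression imputation of left-censored data: per variable a
        normal distribution is fitted by regressing the observed upper
        quantiles on standard-normal quantiles, and missing cells are drawn
        from that normal truncated above at the observed minimum.  Draws are
        reproducible given ``seed``.

    Variables with no observed value at all are dropped with a warning.
    """
    if method not in {"minimum", "knn", "qrilc"}:
        raise ValueError(f"unknown imputation method {method!r}")
    data = table.data.copy()
    empty = [v for v in data.columns if data[v].notna().sum() == 0]
    if empty:
        warnings.warn(f"dropping all-missing variables: {empty}", stacklevel=2)
        data = data.drop(columns=empty)
    if data.isna().sum().sum() == 0:
        return PeakTable(data, _meta_for(table, data.columns), table.log_transformed)

    if method == "minimum":
        data = data.fillna(data.min(axis=0))
    elif method == "knn":
        data = _impute_knn(data, k)
    elif method == "qrilc":
        data = _impute_qrilc(data, seed)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return PeakTable(data, _meta_for(table, data.columns), table.log_transformed)


def _meta_for(table: PeakTable, columns) -> pd.DataFrame | None:
    if table.variable_meta is None:
        return None
    return table.variable_meta.reindex(columns)


def _impute_knn(data: pd.DataFrame, k: int) -> pd.DataFrame:
    k_eff = max(1, min(k, data.shape[0] - 1))
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1).replace(0, 1.0).fillna(1.0)
    z = (data - mu) / sd
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    z_imp = pd.DataFrame(imputer.fit_transform(z), index=data.index,
                         columns=data.columns)
    return z_imp * sd + mu


def _impute_qrilc(data: pd.DataFrame, seed: int | None,
                  upper_fraction: float = 0.75) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    out = data.copy()
    for var in data.columns:
        x = data[var]
        obs = np.sort(x.dropna().to_numpy())
        n_missing = int(x.isna().sum())
        if n_missing == 0:
            continue
        n_total = len(x)
        # plotting positions of the observed values assuming the missing
        # ones are the smallest (left censoring)
        ranks = np.arange(n_total - len(obs), n_total) + 0.5
        probs = ranks / n_total
        q_theo = stats.norm.ppf(probs)
        # fit mean/SD on the upper quantiles, where censoring cannot bite
        keep = probs >= 1.0 - upper_fraction
        if keep.sum() < 2:
            keep = np.ones_like(probs, dtype=bool)
        slope, intercept = np.polyfit(q_theo[keep], obs[keep], 1)
        sd = max(slope, 1e-12)
        upper = obs.min() if len(obs) else intercept
        b = (upper - intercept) / sd
        # intensities are non-negative: keep draws physical
        a = (0.0 - intercept) / sd if obs.min() >= 0 else -np.inf
        if a >= b:
            a = -np.inf
        draws = stats.truncnorm.rvs(a, b, loc=intercept, scale=sd,
                                    size=n_missing, random_state=rng)
        out.loc[x.isna(), var] = draws
    return out


def normalize(
    table: PeakTable,
    method: Literal["total_intensity", "internal_standard", "qc_rlsc"],
    is_variable: str | None = None,
    meta: SampleMetadata | None = None,
    loess_span: float = 0.75,
) -> tuple[PeakTable, PreprocessReport]:
    """Normalize per-sample intensity scale.

    ``total_intensity``
        Each sample is divided by its row sum, then rescaled by the median
        of the original row sums so values stay on an intensity-like scale;
        afterwards all row sums are equal.
    ``internal_standard``
        Each sample is divided by its intensity of ``is_variable``.
    ``qc_rlsc``
        QC-based robust LOESS signal correction: per variable, a LOESS curve
        (degree 1, span ``loess_span``) is fitted to the QC intensities as a
        function of injection order, and every sample is divided by the
        curve interpolated at its own injection order.  Requires metadata
        with injection order and at least five QC samples.
    """
    data = table.data
    if method == "total_intensity":
        totals = data.sum(axis=1, skipna=True)
        bad = totals.index[~(totals > 0)].tolist()
        if bad:
            raise ValueError(f"samples with non-positive total intensity: {bad}")
        scale = float(totals.median())
        out = data.div(totals, axis=0) * scale
        factors = totals / scale
    elif method == "internal_standard":
        if is_variable is None or is_variable not in data.columns:
            raise ValueError(f"internal-standard variable {is_variable!r} not found")
        is_col = data[is_variable]
        bad = is_col.index[~(is_col > 0)].tolist()
        if bad:
            raise ValueError(
                f"internal standard {is_variable!r} non-positive in samples: {bad}")
        out = data.div(is_col, axis=0)
        factors = is_col.copy()
    elif method == "qc_rlsc":
        out, factors = _qc_rlsc(data, meta, loess_span)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    report = PreprocessReport(
        step=f"normalize:{method}",
        parameters={"is_variable": is_variable, "loess_span": loess_span},
        per_sample=pd.DataFrame({"divisor": factors}),
    )
    return PeakTable(out, table.variable_meta, table.log_transformed), report


def _qc_rlsc(data: pd.DataFrame, meta: SampleMetadata | None,
             span: float) -> tuple[pd.DataFrame, pd.Series]:
    if meta is None:
        raise ValueError("qc_rlsc requires sample metadata")
    meta_frame = meta.frame.loc[data.index]
    order = meta.injection_order()
    if order is None:
        raise ValueError("qc_rlsc requires an injection_order column")
    order = order.loc[data.index]
    qc_mask = meta.is_qc().loc[data.index]
    n_qc = int(qc_mask.sum())
    if n_qc < 5:
        raise ValueError(f"qc_rlsc requires >= 5 QC samples, found {n_qc}")
    qc_order = order[qc_mask].to_numpy()
    out = data.copy()
    for var in data.columns:
        qc_y = data.loc[qc_mask, var].to_numpy()
        ok = np.isfinite(qc_y)
        if ok.sum() < 5:
            continue
        fitted = lowess(qc_y[ok], qc_order[ok], frac=span, it=3,
                        return_sorted=True)
        curve = np.interp(order.to_numpy(), fitted[:, 0], fitted[:, 1])
        curve = np.where(curve > 0, curve, np.nan)
        ref = np.nanmedian(data.loc[qc_mask, var])
        out[var] = data[var] / curve * ref
    return out, pd.Series(1.0, index=data.index, name="divisor")


def transform(
    table: PeakTable,
    method: Literal["log", "zscore"],
    pseudo: Literal["half_min"] = "half_min",
) -> PeakTable:
    """Linearize the intensity structure.

    ``log`` is the natural logarithm; zeros are offset by half the variable's
    smallest positive value first.  ``zscore`` centers and scales each
    variable to mean 0, SD 1; constant variables become all-zero with a
    warning.
    """
    data = table.data.copy()
    if method == "log":
        if (data < 0).any().any():
            bad = data.columns[(data < 0).any()].tolist()
            raise ValueError(f"log transform on negative values in: {bad}")
        for var in data.columns:
            col = data[var]
            if (col == 0).any():
                positive = col[col > 0]
                offset = positive.min() / 2 if len(positive) else 1.0
                col = col.mask(col == 0, offset)
            data[var] = np.log(col)
        return PeakTable(data, table.variable_meta, log_transformed=True)
    if method == "zscore":
        mu = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            warnings.warn(f"constant variables z-scored to 0: {constant}",
                          stacklevel=2)
        sd = sd.replace(0, np.nan)
        z = (data - mu) / sd
        z[constant] = 0.0
        return PeakTable(z, table.variable_meta, table.log_transformed)
    raise ValueError(f"unknown transform {method!r}")


def basic_statistics(
    table: PeakTable, meta: SampleMetadata | None = None
) -> pd.DataFrame:
    """Per-variable summary statistics, overall and per group."""

    def _summary(frame: pd.DataFrame, prefix: str) -> pd.DataFrame:
        mean = frame.mean(axis=0)
        sd = frame.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = (sd / mean.replace(0, np.nan)).abs() * 100
        return pd.DataFrame({
            f"{prefix}n": frame.notna().sum(axis=0),
            f"{prefix}mean": mean,
            f"{prefix}sd": sd,
            f"{prefix}median": frame.median(axis=0),
            f"{prefix}min": frame.min(axis=0),
            f"{prefix}max": frame.max(axis=0),
            f"{prefix}cv_pct": cv,
            f"{prefix}n_missing": frame.isna().sum(axis=0),
        })

    parts = [_summary(table.data, "")]
    if meta is not None:
        groups = meta.aligned_to(table).groups()
        for level in sorted(groups.unique()):
            sub = table.data.loc[groups[groups == level].index]
            parts.append(_summary(sub, f"{level}."))
    out = pd.concat(parts, axis=1)
    out.index.name = "variable_id"
    return out
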