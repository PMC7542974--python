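"""Intra- and inter-omics correlation analysis.

Classical pairwise methods (Pearson, Spearman, Kendall, partial Spearman)
plus a generalized two-channel procedure for metabolome-microbiome pairs:
after residualizing both features on known confounders, a linear channel
(Pearson) and a nonlinear channel (distance correlation with a permutation
null) compete, and each pair is labeled by the channel with the stronger
evidence.  Microbial abundances are centered-log-ratio transformed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .stats_uni import adjust_pvalues
from .tables_io import PeakTable, SampleMetadata

__all__ = ["MicrobeTable", "correlate", "gramm", "retrieve_pairs",
           "distance_correlation", "clr_transform"]


@dataclass
class MicrobeTable:
    """Samples x taxa abundance matrix (counts or relative abundances)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data.fillna(0) < 0).any().any():
            raise ValueError("abundances must be non-negative")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


def clr_transform(abundances: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform; zeros replaced by half the matrix's
    smallest positive value."""
    mat = abundances.to_numpy(dtype=float)
    positive = mat[mat > 0]
    if positive.size == 0:
        raise ValueError("abundance matrix has no positive entries")
    mat = np.where(mat > 0, mat, positive.min() / 2)
    log = np.log(mat)
    clr = log - log.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=abundances.index, columns=abundances.columns)


def _residualize(x: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """OLS residuals of x on [1, Z] (centering only when Z is None/empty)."""
    if Z is None or Z.size == 0:
        return x - x.mean()
    design = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def _pair_stat(x: np.ndarray, y: np.ndarray, method: str,
               Z: np.ndarray | None = None) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "kendall":
        r, p = stats.kendalltau(x, y)
    elif method == "partial_spearman":
        if Z is None:
            raise ValueError("partial_spearman requires confounders")
        # all margins rank-transformed, then linear residualization
        Zr = np.column_stack([stats.rankdata(Z[:, j])
                              for j in range(Z.shape[1])]) if Z.size else Z
        rx = _residualize(stats.rankdata(x).astype(float), Zr)
        ry = _residualize(stats.rankdata(y).astype(float), Zr)
        r, p = stats.pearsonr(rx, ry)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate(
    table_a: PeakTable,
    table_b: PeakTable | None = None,
    method: Literal["pearson", "spearman", "kendall", "partial_spearman"] = "spearman",
    confounders: SampleMetadata | None = None,
    correction: str = "fdr",
) -> pd.DataFrame:
    """All pairwise correlations within ``table_a`` (or across a x b).

    Returns a long-format table (feature_a, feature_b, r, p, q) with q the
    correction across all computed pairs.  Requires at least four shared
    samples.
    """
    if table_b is not None:
        shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    else:
        shared = table_a.sample_ids
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, found {len(shared)}")
    A = table_a.data.loc[shared]
    B = table_b.data.loc[shared] if table_b is not None else None
    Z = None
    if confounders is not None:
        Z = confounders.frame.loc[shared].pipe(
            lambda f: SampleMetadata(f).confounders()).to_numpy()
    rows = []
    if B is None:
        cols = list(A.columns)
        pairs = [(cols[i], cols[j]) for i in range(len(cols))
                 for j in range(i + 1, len(cols))]
        get_b = A
    else:
        pairs = [(a, b) for a in A.columns for b in B.columns]
        get_b = B
    for fa, fb in pairs:
        x, y = A[fa].to_numpy(), get_b[fb].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4:
            continue
        r, p = _pair_stat(x[ok], y[ok], method,
                          Z[ok] if Z is not None else None)
        rows.append({"feature_a": fa, "feature_b": fb, "r": r, "p": p})
    result = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    if len(result):
        result["q"] = adjust_pvalues(result["p"].to_numpy(), correction)
        result["method"] = method
    return result


# -- distance correlation --------------------------------------------------

def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation via double-centered distance matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    n2 = float(x.size) ** 2
    dcov2 = (A * B).sum() / n2
    dvar_x = (A * A).sum() / n2
    dvar_y = (B * B).sum() / n2
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def _dcor_perm_p(x: np.ndarray, y: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    obs = distance_correlation(x, y)
    count = 0
    for _ in range(n_perm):
        if distance_correlation(x, rng.permutation(y)) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


def gramm(
    metab: PeakTable,
    microbe: MicrobeTable,
    confounders: SampleMetadata | None = None,
    nonlinear_alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generalized metabolome-microbiome correlation.

    Per metabolite-taxon pair: both features are residualized on the known
    confounders, then classified by a two-stage rule.  First a
    nonlinearity test: distance correlation between the taxon and the
    residuals of the metabolite's linear fit on the taxon, with a
    permutation null (``n_permutations`` shuffles).  If that test is
    significant at ``nonlinear_alpha`` the pair is labeled nonlinear and
    reported with the full distance correlation and its own permutation p;
    otherwise it is labeled linear and reported with the Pearson r and p.
    q is the FDR across all pairs.  Both sides are brought to their natural
    correlation scale first: metabolite intensities are log-transformed
    (skipped when the table is already log-scale) and microbial abundances
    are CLR-transformed.  Requires at least 20 shared samples.

    Testing nonlinearity on the linear-fit residuals (rather than comparing
    channel p-values) keeps a genuinely curved relationship labeled
    nonlinear even when it also carries an incidental linear component.
    """
    shared = [s for s in metab.sample_ids if s in set(microbe.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between tables")
    if len(shared) < 20:
        raise ValueError(f"generalized correlation needs >= 20 shared samples, "
                         f"found {len(shared)}")
    M = metab.data.loc[shared]
    if not metab.log_transformed:
        mat = M.to_numpy(dtype=float)
        positive = mat[np.isfinite(mat) & (mat > 0)]
        if positive.size == 0:
            raise ValueError("metabolite table has no positive intensities")
        mat = np.where(np.isfinite(mat) & (mat > 0), mat, positive.min() / 2)
        M = pd.DataFrame(np.log(mat), index=M.index, columns=M.columns)
    T = clr_transform(microbe.data.loc[shared])
    Z = None
    if confounders is not None:
        Z = confounders.frame.loc[shared].pipe(
            lambda f: SampleMetadata(f).confounders()).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for met in M.columns:
        for taxon in T.columns:
            x, y = M[met].to_numpy(), T[taxon].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            rx = _residualize(x[ok], Z[ok] if Z is not None else None)
            ry = _residualize(y[ok], Z[ok] if Z is not None else None)
            lin_r, lin_p = stats.pearsonr(rx, ry)
            # nonlinearity beyond the linear fit: dcor(taxon, residuals)
            denom = rx @ rx
            slope = (rx @ ry) / denom if denom > 0 else 0.0
            resid = ry - slope * rx
            nl_stat, nl_p = _dcor_perm_p(rx, resid, n_permutations, rng)
            if nl_p < nonlinear_alpha:
                dcor_full, dcor_p = _dcor_perm_p(rx, ry, n_permutations, rng)
                ctype, r, p = "nonlinear", float(dcor_full), float(dcor_p)
            else:
                dcor_full, dcor_p = nl_stat, nl_p
                ctype, r, p = "linear", float(lin_r), float(lin_p)
            rows.append({"feature_a": met, "feature_b": taxon, "type": ctype,
                         "r": r, "p": p, "pearson_r": float(lin_r),
                         "pearson_p": float(lin_p), "dcor": float(dcor_full),
                         "dcor_p": float(dcor_p), "nonlinearity_p": float(nl_p)})
    result = pd.DataFrame(rows)
    result["q"] = adjust_pvalues(result["p"].to_numpy(), "fdr")
    result["method"] = "gramm"
    return result


def retrieve_pairs(
    results: pd.DataFrame,
    r_min: float = 0.6,
    q_max: float = 0.05,
    use_abs: bool = True,
) -> pd.DataFrame:
    """Filter correlation results into a network edge list.

    Edges (feature_a, interaction, feature_b, r, q) pass when |r| >= r_min
    (r >= r_min if ``use_abs`` is False) and q < q_max; self-pairs are always
    excluded and edges are sorted by |r| descending.  The output loads
    directly into network tools (SIF-like layout).
    """
    cols = ["feature_a", "interaction", "feature_b", "r", "q"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    frame = results[results["feature_a"] != results["feature_b"]].copy()
    strength = frame["r"].abs() if use_abs else frame["r"]
    frame = frame[(strength >= r_min) & (frame["q"] < q_max)]
    frame["interaction"] = np.where(frame["r"] >= 0, "positive", "negative")
    frame = frame.reindex(columns=cols)
    frame = frame.sort_values(by="r", key=lambda s: s.abs(), ascending=False)
    return frame.reset_index(drop=True)
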