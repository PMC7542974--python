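"""Latent-variable modeling: PCA, PLS-DA and OPLS-DA.

PLS-DA is fitted by NIPALS on a dummy-coded group response.  OPLS-DA first
strips ``n_orthogonal`` components of class-orthogonal variation from X
(orthogonal signal correction), then fits a single predictive component —
the standard two-group formulation.  Variable influence on projection (VIP)
scores are normalized so that mean(VIP^2) = 1; predictive performance is
summarized by cross-validated Q2 and a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import PeakTable, SampleMetadata

__all__ = ["LatentModel", "fit_pca", "fit_plsda", "vip_scores"]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class LatentModel:
    method: str
    n_components: int
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    n_orthogonal: int = 0
    weights: pd.DataFrame | None = None
    vip: pd.Series | None = None
    orthogonal_scores: pd.DataFrame | None = None
    q2: float | None = None
    r2y: float | None = None
    permutation_p: float | None = None
    permutation_q2: np.ndarray | None = None
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _preprocess(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "unit_variance":
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    elif scaling == "none":
        scale = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / scale, mean, scale


def fit_pca(
    table: PeakTable, n_components: int | None = None,
    scaling: str = "unit_variance",
) -> LatentModel:
    """Principal component analysis of the centered (optionally unit-variance
    scaled) intensity matrix, via SVD.

    Sign convention: the largest-magnitude loading of each component is
    positive, making the decomposition deterministic.
    """
    X = table.values
    if np.isnan(X).any():
        raise ValueError("missing values present; run impute_missing first")
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = min(max_rank, 10)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds min(n-1, p) = {max_rank}")
    Xc, mean, scale = _preprocess(X, scaling)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention
    for a in range(n_components):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U * s
    total_var = np.sum(Xc ** 2)
    explained = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    comps = [f"PC{a+1}" for a in range(n_components)]
    return LatentModel(
        method="pca", n_components=n_components,
        scores=pd.DataFrame(scores, index=table.sample_ids, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=table.variable_ids, columns=comps),
        explained_variance=explained, mean_=mean, scale_=scale)


# -- NIPALS PLS ------------------------------------------------------------

def _nipals_pls(X: np.ndarray, Y: np.ndarray, n_components: int):
    """NIPALS PLS2 on centered X (n x p) and Y (n x m).

    Returns weights W, x-scores T, x-loadings P, y-loadings C
    (columns = components).  Deterministic: the iteration starts from the
    first response column.
    """
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    Xa, Ya = X.copy(), Y.copy()
    for a in range(n_components):
        u = Ya[:, 0].copy()
        if np.allclose(u, 0):
            u = Ya.sum(axis=1)
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = Xa.T @ u / (u @ u)
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t = Xa @ w
            c = Ya.T @ t / (t @ t)
            cnorm = c @ c
            if cnorm == 0:
                break
            u = Ya @ c / cnorm
            if t_old is not None and np.linalg.norm(t - t_old) < _NIPALS_TOL * max(
                    np.linalg.norm(t), 1e-300):
                break
            t_old = t
        tt = t @ t
        if tt == 0:
            break
        pvec = Xa.T @ t / tt
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pvec, c
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, c)
    return W, T, P, C


def _osc_filter(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Remove class-orthogonal variation from centered X (single response)."""
    w = X.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    T_o, P_o, W_o = [], [], []
    Xf = X.copy()
    for _ in range(n_orthogonal):
        t = Xf @ w
        pvec = Xf.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        T_o.append(t_o)
        P_o.append(p_o)
        W_o.append(w_o)
    return Xf, (np.column_stack(T_o) if T_o else np.zeros((X.shape[0], 0)))


def vip_scores(W: np.ndarray, T: np.ndarray, C: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ), SSY_a the
    response variance explained by component a."""
    p = W.shape[0]
    ssy = np.array([(T[:, a] @ T[:, a]) * (C[:, a] @ C[:, a])
                    for a in range(W.shape[1])])
    total = ssy.sum()
    if total == 0:
        return np.ones(p)
    w2 = W ** 2
    return np.sqrt(p * (w2 @ ssy) / total)


def _dummy_response(labels: np.ndarray, levels: list) -> np.ndarray:
    if len(levels) == 2:
        y = np.where(labels == levels[1], 1.0, 0.0)[:, None]
    else:
        y = np.column_stack([(labels == g).astype(float) for g in levels])
    return y


def _q2_cv(X: np.ndarray, Y: np.ndarray, n_components: int, n_orthogonal: int,
           folds: list[np.ndarray]) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS on the centered response."""
    press, ss = 0.0, np.sum((Y - Y.mean(axis=0)) ** 2)
    for test_idx in folds:
        train = np.ones(len(X), dtype=bool)
        train[test_idx] = False
        Xtr, Ytr = X[train], Y[train]
        Xte, Yte = X[test_idx], Y[test_idx]
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        xs = Xtr.std(axis=0, ddof=1)
        xs[xs == 0] = 1.0
        Xtr_c, Xte_c = (Xtr - xm) / xs, (Xte - xm) / xs
        Ytr_c = Ytr - ym
        if n_orthogonal > 0 and Ytr_c.shape[1] == 1:
            yv = Ytr_c[:, 0]
            w = Xtr_c.T @ yv / (yv @ yv)
            w /= np.linalg.norm(w)
            Xf = Xtr_c.copy()
            Xte_f = Xte_c.copy()
            for _ in range(n_orthogonal):
                t = Xf @ w
                pvec = Xf.T @ t / (t @ t)
                w_o = pvec - (w @ pvec) * w
                norm = np.linalg.norm(w_o)
                if norm < 1e-12:
                    break
                w_o /= norm
                t_o = Xf @ w_o
                p_o = Xf.T @ t_o / (t_o @ t_o)
                Xf = Xf - np.outer(t_o, p_o)
                Xte_f = Xte_f - np.outer(Xte_f @ w_o, p_o)
            Xtr_c, Xte_c = Xf, Xte_f
        W, T, P, C = _nipals_pls(Xtr_c, Ytr_c, n_components)
        # regression prediction: B = W (P'W)^-1 C'
        PtW = P.T @ W
        try:
            B = W @ np.linalg.solve(PtW, C.T)
        except np.linalg.LinAlgError:
            B = W @ np.linalg.pinv(PtW) @ C.T
        Yhat = Xte_c @ B + ym
        press += np.sum((Yte - Yhat) ** 2)
    return 1.0 - press / ss if ss > 0 else 0.0


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for level in np.unique(labels):
        idx = np.flatnonzero(labels == level)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.array(sorted(f)) for f in folds if f]


def fit_plsda(
    table: PeakTable,
    meta: SampleMetadata,
    n_components: int = 2,
    orthogonal: int = 0,
    n_permutations: int = 200,
    cv_folds: int = 7,
    seed: int | None = None,
    scaling: str = "unit_variance",
) -> LatentModel:
    """Fit PLS-DA (``orthogonal=0``) or OPLS-DA (``orthogonal>0``).

    OPLS-DA requires exactly two groups and fits one predictive component
    after removing ``orthogonal`` orthogonal components.  Set
    ``n_permutations=0`` to skip the permutation test.
    """
    X = table.values
    if np.isnan(X).any():
        raise ValueError("missing values present; run impute_missing first")
    meta = meta.aligned_to(table)
    labels = meta.groups().to_numpy()
    levels = sorted(np.unique(labels))
    if len(levels) < 2:
        raise ValueError("discriminant analysis needs >= 2 groups")
    if orthogonal > 0:
        if len(levels) != 2:
            raise ValueError("OPLS-DA requires exactly 2 groups")
        n_components = 1  # single predictive component, two classes
    rng = np.random.default_rng(seed)

    Xc, mean, scale = _preprocess(X, scaling)
    Y = _dummy_response(labels, levels)
    Yc = Y - Y.mean(axis=0)

    ortho_scores = None
    Xp = Xc
    if orthogonal > 0:
        Xp, T_o = _osc_filter(Xc, Yc[:, 0], orthogonal)
        ortho_scores = pd.DataFrame(
            T_o, index=table.sample_ids,
            columns=[f"to{a+1}" for a in range(T_o.shape[1])])

    W, T, P, C = _nipals_pls(Xp, Yc, n_components)
    vip = vip_scores(W, T, C)

    total_x = np.sum(Xc ** 2)
    explained = np.array([
        (T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / total_x
        for a in range(n_components)]) if total_x > 0 else np.zeros(n_components)

    # R2Y on the training data
    PtW = P.T @ W
    try:
        B = W @ np.linalg.solve(PtW, C.T)
    except np.linalg.LinAlgError:
        B = W @ np.linalg.pinv(PtW) @ C.T
    resid = Yc - Xp @ B
    ssy = np.sum(Yc ** 2)
    r2y = 1.0 - np.sum(resid ** 2) / ssy if ssy > 0 else 0.0

    folds = _stratified_folds(labels, min(cv_folds, len(labels)), rng)
    q2 = _q2_cv(X, Y, n_components, orthogonal, folds)

    perm_p, perm_q2 = None, None
    if n_permutations > 0:
        perm_q2 = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(len(labels))
            Yp = Y[perm]
            lp = labels[perm]
            pfolds = _stratified_folds(lp, min(cv_folds, len(labels)), rng)
            perm_q2[b] = _q2_cv(X, Yp, n_components, orthogonal, pfolds)
        perm_p = (1 + np.sum(perm_q2 >= q2)) / (1 + n_permutations)

    comps = [f"t{a+1}" for a in range(n_components)]
    return LatentModel(
        method="oplsda" if orthogonal > 0 else "plsda",
        n_components=n_components, n_orthogonal=orthogonal,
        scores=pd.DataFrame(T, index=table.sample_ids, columns=comps),
        loadings=pd.DataFrame(P, index=table.variable_ids, columns=comps),
        weights=pd.DataFrame(W, index=table.variable_ids, columns=comps),
        vip=pd.Series(vip, index=table.variable_ids, name="vip"),
        orthogonal_scores=ortho_scores,
        explained_variance=explained, q2=q2, r2y=r2y,
        permutation_p=perm_p, permutation_q2=perm_q2,
        mean_=mean, scale_=scale,
        extras={"group_levels": levels})
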