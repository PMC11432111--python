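"""PLS-DA modelling of pre-filtered omics matrices.

Partial least-squares discriminant analysis against a binary age class:
NIPALS component extraction on autoscaled features, explained variance
(R2X per component, cumulative R2Y), predicted variance Q2 by stratified
cross-validation, label-permutation validation of both statistics, VIP
feature ranking with the VIP >= 1 selection rule, and a Ward hierarchical
clustering class-purity check of the discriminant feature heatmap.

Feature matrices follow the pipeline's features-x-samples orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

DEFAULT_N_COMPONENTS = 2
DEFAULT_N_FOLDS = 7
DEFAULT_N_PERM = 500
DEFAULT_VIP_THRESHOLD = 1.0


@dataclass
class PLSDAModel:
    feature_ids: list[str]
    classes: tuple[str, str]
    n_components: int
    weights: np.ndarray        # (n_features, A)
    x_loadings: np.ndarray     # (n_features, A)
    y_loadings: np.ndarray     # (A,)
    scores: np.ndarray         # (n_samples, A)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x: np.ndarray            # per component
    r2y: float                 # cumulative
    q2: float | None = None
    vip: pd.Series | None = None
    perm_p_r2y: float | None = None
    perm_p_q2: float | None = None
    dropped_features: list[str] = field(default_factory=list)

    def predict_score(self, X_new: np.ndarray) -> np.ndarray:
        """Continuous class score for samples-x-features input."""
        W, P, c = self.weights, self.x_loadings, self.y_loadings
        b = W @ np.linalg.solve(P.T @ W, c)
        Xs = (X_new - self.x_mean) / self.x_scale
        return Xs @ b + self.y_mean


def _encode_y(groups: pd.Series) -> tuple[np.ndarray, tuple[str, str]]:
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 classes, got {levels}")
    return (groups == levels[1]).to_numpy(float), (levels[0], levels[1])


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 component extraction on pre-scaled X and centered y."""
    n, p = Xs.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    c = np.zeros(n_components)
    T = np.zeros((n, n_components))
    X, y = Xs.copy(), yc.copy()
    for a in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate component: no covariance left")
        w /= nw
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        c_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - c_a * t
        W[:, a], P[:, a], c[a], T[:, a] = w, p_a, c_a, t
    return W, P, c, T


def fit_plsda(
    X: pd.DataFrame,
    groups: pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> PLSDAModel:
    """Fit a two-class PLS-DA model on a features-x-samples matrix.

    Features are autoscaled (centered, unit variance); constant features
    are dropped with a warning.  The class is dummy-coded 0/1 in sorted
    label order, so positive scores/loadings point at the second class
    (S+3 when labels are S1/S3).
    """
    groups = groups.reindex(X.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    y, classes = _encode_y(groups)
    n_samples = X.shape[1]
    if not 1 <= n_components < n_samples:
        raise ValueError(
            f"n_components must be in [1, {n_samples - 1}], got {n_components}"
        )
    mat = X.to_numpy(float).T  # samples x features
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(X.index, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s) before scaling",
            RuntimeWarning,
            stacklevel=2,
        )
    mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ValueError("no non-constant features left")
    mean, scale = mat.mean(axis=0), mat.std(axis=0, ddof=1)
    Xs = (mat - mean) / scale
    y_mean = y.mean()
    yc = y - y_mean

    W, P, c, T = _nipals(Xs, yc, n_components)
    ssx = (Xs**2).sum()
    r2x = np.array(
        [(T[:, a] ** 2).sum() * (P[:, a] ** 2).sum() / ssx for a in range(n_components)]
    )
    resid = yc - T @ c
    tss = (yc**2).sum()
    r2y = float(1 - (resid**2).sum() / tss) if tss > 0 else 0.0

    model = PLSDAModel(
        feature_ids=[f for f, k in zip(X.index, keep) if k],
        classes=classes,
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=c,
        scores=T,
        x_mean=mean,
        x_scale=scale,
        y_mean=float(y_mean),
        r2x=r2x,
        r2y=r2y,
        dropped_features=dropped,
    )
    model.vip = vip_scores(model, yc, T, c)
    return model


def vip_scores(
    model: PLSDAModel,
    yc: np.ndarray | None = None,
    T: np.ndarray | None = None,
    c: np.ndarray | None = None,
) -> pd.Series:
    """Variable Importance in the Projection.

    ``VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a )`` with
    SSY_a the y-variance explained by component a.  The squared scores
    average to 1 over features.
    """
    if T is None or c is None:
        T, c = model.scores, model.y_loadings
    W = model.weights
    p = W.shape[0]
    ssy = np.array([(c[a] ** 2) * (T[:, a] ** 2).sum() for a in range(W.shape[1])])
    if ssy.sum() == 0:
        return pd.Series(np.ones(p), index=model.feature_ids, name="vip")
    wnorm2 = W**2 / (W**2).sum(axis=0)
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_ids, name="vip")


def select_vip(model: PLSDAModel, threshold: float = DEFAULT_VIP_THRESHOLD) -> list[str]:
    """Feature ids with VIP >= threshold (the discriminant set)."""
    assert model.vip is not None
    return list(model.vip.index[model.vip.to_numpy() >= threshold])


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index folds containing both classes (classes interleaved round-robin)."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds = min(n_folds, len(y))
    rng.shuffle(idx0)
    rng.shuffle(idx1)
    order = np.concatenate([idx0, idx1])
    folds = [order[i::n_folds] for i in range(n_folds)]
    return [np.sort(f) for f in folds if f.size]


def q2_cross_validation(
    X: pd.DataFrame,
    groups: pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Predicted variance Q2 = 1 - PRESS/TSS under stratified k-fold CV.

    Each fold is held out, the model (including autoscaling) is refit on
    the rest, and squared prediction error on the held-out dummy-coded y
    accumulates into PRESS.  ``n_folds = n_samples`` gives leave-one-out.
    """
    groups = groups.reindex(X.columns)
    y, _ = _encode_y(groups)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    folds = _stratified_folds(y, n_folds, rng)
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    mat = X.to_numpy(float).T
    press = 0.0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("training fold lost a class; reduce n_folds")
        Xtr = mat[train_idx]
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        Xtr = Xtr[:, keep]
        mean, scale = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        ytr = y[train_idx]
        ym = ytr.mean()
        ncomp = min(n_components, len(train_idx) - 1)
        W, P, c, _ = _nipals((Xtr - mean) / scale, ytr - ym, ncomp)
        b = W @ np.linalg.solve(P.T @ W, c)
        Xte = (mat[np.ix_(test_idx, np.flatnonzero(keep))] - mean) / scale
        yhat = Xte @ b + ym
        press += float(((y[test_idx] - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(
    X: pd.DataFrame,
    groups: pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_perm: int = DEFAULT_N_PERM,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Label-permutation p-values for R2Y and Q2.

    The class labels are permuted ``n_perm`` times, the model and its CV
    are recomputed, and ``p = (1 + #{perm >= observed}) / (n_perm + 1)``
    (add-one estimator, so the smallest attainable p is 1/(n_perm+1)).
    """
    rng = np.random.default_rng(seed)
    groups = groups.reindex(X.columns)
    obs = fit_plsda(X, groups, n_components)
    obs_q2 = q2_cross_validation(X, groups, n_components, n_folds, rng)
    labels = groups.to_numpy().copy()
    ge_r2y = 0
    ge_q2 = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(labels), index=X.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = fit_plsda(X, perm, n_components)
            q2 = q2_cross_validation(X, perm, n_components, n_folds, rng)
        if m.r2y >= obs.r2y:
            ge_r2y += 1
        if q2 >= obs_q2:
            ge_q2 += 1
    p_r2y = (1 + ge_r2y) / (n_perm + 1)
    p_q2 = (1 + ge_q2) / (n_perm + 1)
    return p_r2y, p_q2


def fit_validated_plsda(
    X: pd.DataFrame,
    groups: pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_folds: int = DEFAULT_N_FOLDS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> PLSDAModel:
    """Fit, cross-validate and permutation-validate a PLS-DA model."""
    model = fit_plsda(X, groups, n_components)
    model.q2 = q2_cross_validation(X, groups, n_components, n_folds, seed)
    model.perm_p_r2y, model.perm_p_q2 = permutation_test(
        X, groups, n_components, n_perm, n_folds, seed
    )
    return model


def z_score(X: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-score across samples (constant features -> 0)."""
    mat = X.to_numpy(float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((mat - mean) / sd, index=X.index, columns=X.columns)


def cluster_purity(
    X: pd.DataFrame, groups: pd.Series
) -> tuple[bool, list[str]]:
    """Do the two Ward clusters of samples coincide with the age groups?

    Features are z-scored across samples, samples are clustered with Ward
    linkage on Euclidean distance, and the dendrogram is cut at k = 2.
    Returns (purity, leaf order); purity is true iff each cluster holds
    samples of a single group.
    """
    groups = groups.reindex(X.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    Z = z_score(X).to_numpy().T  # samples x features
    link = hierarchy.linkage(Z, method="ward")
    assign = hierarchy.fcluster(link, t=2, criterion="maxclust")
    leaves = hierarchy.leaves_list(link)
    leaf_order = [X.columns[i] for i in leaves]
    purity = all(
        len(set(groups.iloc[assign == k])) == 1 for k in np.unique(assign)
    )
    return bool(purity), leaf_order
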