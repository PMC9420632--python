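"""Latent-variable models for scaled metabolomics matrices.

Implements PCA (for unsupervised overviews), two-class OPLS-DA and
multi-class PLS-DA by NIPALS-style deflation, and VIP (variable importance
in projection) scores. OPLS-DA splits the predictor variation into a single
class-predictive component and ``n_orthogonal`` components that are exactly
uncorrelated with the class response; this is what lets a dominant nuisance
direction (e.g. a per-sample dilution factor) be absorbed without polluting
the discriminant axis.

Conventions
-----------
* Two-class response: one column, +1/-1 coding, centred. The predictive
  block therefore has exactly one component.
* Multi-class response: one centred indicator column per class; the model
  is a plain PLS2 regression of X on that dummy block (no orthogonal
  filtering), with ``n_components`` defaulting to n_classes - 1.
* R2X and R2Y are sum-of-squares ratios against the centred X and dummy Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PcaModel",
    "OplsdaModel",
    "VipScores",
    "fit_pca",
    "fit_oplsda",
    "fit_plsda_multiclass",
    "auto_orthogonal",
    "compute_vip",
]

_CONV_TOL = 1e-12
_MAX_ITER = 500


def _as_array(x) -> tuple[np.ndarray, list[str]]:
    """Accept a ScaledMatrix, DataFrame, or ndarray; return (array, feature ids)."""
    from .preprocess import ScaledMatrix

    if isinstance(x, ScaledMatrix):
        return x.values.to_numpy(dtype=float), list(x.values.columns)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValueError("x must be a 2-D samples x features matrix")
    return a, [f"x{j}" for j in range(a.shape[1])]


def dummy_matrix(groups) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Centred class dummy for a label vector.

    Returns ``(Y_centred, Y_means, class_labels)``. Two classes give one
    +1/-1 column; G >= 3 classes give G indicator columns. ``Y_means`` holds
    the column means removed by centring (needed to move held-out
    predictions onto a common scale during cross-validation).
    """
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 distinct group labels")
    if len(labels) == 2:
        y0 = np.where(g == labels[1], 1.0, -1.0)[:, None]
    else:
        y0 = np.stack([(g == lab).astype(float) for lab in labels], axis=1)
    means = y0.mean(axis=0)
    return y0 - means, means, labels


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray
    r2x_per_component: np.ndarray
    r2x_cum: float
    feature_ids: list[str] = field(default_factory=list)


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA (two-class) or PLS-DA (multi-class) model.

    ``predictive_*`` blocks hold the class-predictive components;
    ``orthogonal_*`` blocks the Y-uncorrelated ones (empty for multi-class).
    ``y_loadings`` maps predictive scores back to the centred dummy.
    """

    kind: str  # "oplsda" | "plsda"
    class_labels: list[str]
    predictive_scores: np.ndarray
    predictive_weights: np.ndarray
    predictive_loadings: np.ndarray
    orthogonal_scores: np.ndarray
    orthogonal_weights: np.ndarray
    orthogonal_loadings: np.ndarray
    y_loadings: np.ndarray  # classes x Ap
    r2x: float
    r2y: float
    dummy_coding: dict
    feature_ids: list[str]
    ssy_per_component: np.ndarray  # explained SS of Y, per predictive component
    ssx_orthogonal: np.ndarray  # explained SS of X, per orthogonal component

    @property
    def n_predictive(self) -> int:
        return self.predictive_scores.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]

    def predict(self, x_new) -> np.ndarray:
        """Predict centred dummy rows for new samples (regression scale)."""
        xn, _ = _as_array(x_new)
        xn = xn.copy()
        for k in range(self.n_orthogonal):
            t_o = xn @ self.orthogonal_weights[:, k]
            xn -= np.outer(t_o, self.orthogonal_loadings[:, k])
        yhat = np.zeros((xn.shape[0], self.y_loadings.shape[0]))
        for a in range(self.n_predictive):
            t = xn @ self.predictive_weights[:, a]
            yhat += np.outer(t, self.y_loadings[:, a])
            xn -= np.outer(t, self.predictive_loadings[:, a])
        return yhat

    def predict_scores(self, x_new) -> np.ndarray:
        """Predictive score(s) for new samples after orthogonal filtering."""
        xn, _ = _as_array(x_new)
        xn = xn.copy()
        for k in range(self.n_orthogonal):
            t_o = xn @ self.orthogonal_weights[:, k]
            xn -= np.outer(t_o, self.orthogonal_loadings[:, k])
        scores = np.empty((xn.shape[0], self.n_predictive))
        for a in range(self.n_predictive):
            t = xn @ self.predictive_weights[:, a]
            scores[:, a] = t
            xn -= np.outer(t, self.predictive_loadings[:, a])
        return scores


def fit_pca(x, n_components: int) -> PcaModel:
    """PCA by SVD of the (already centred) scaled matrix.

    ``r2x_per_component[k]`` is the share of total sum of squares carried by
    component k, so the cumulative R2X tracks reconstruction quality of the
    best rank-A approximation.
    """
    X, feat = _as_array(x)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_ss = float((Xc**2).sum())
    A = n_components
    r2 = (s[:A] ** 2) / total_ss if total_ss > 0 else np.zeros(A)
    return PcaModel(
        scores=U[:, :A] * s[:A],
        loadings=Vt[:A].T,
        r2x_per_component=r2,
        r2x_cum=float(r2.sum()),
        feature_ids=feat,
    )


def _check_class_sizes(groups, labels) -> None:
    g = np.asarray(groups)
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")


def fit_oplsda(x, groups, n_orthogonal: int = 1) -> OplsdaModel:
    """Two-class OPLS-DA with one predictive and ``n_orthogonal`` components.

    The predictive weight is w = X'y/||X'y||. Each orthogonal component is
    extracted from the predictive loading's part orthogonal to w and
    deflated from X; by construction its score is exactly uncorrelated with
    the centred dummy, and deflation leaves X'y (hence w) unchanged. With
    ``n_orthogonal=0`` the model is an ordinary one-component PLS-DA.
    """
    X0, feat = _as_array(x)
    Y, y_means, labels = dummy_matrix(groups)
    if len(labels) != 2:
        raise ValueError("fit_oplsda requires exactly 2 classes; use fit_plsda_multiclass")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    _check_class_sizes(groups, labels)
    y = Y[:, 0]
    ssy = float(y @ y)
    if ssy <= 0:
        raise ValueError("class dummy is constant")

    Xd = X0.copy()
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with the class dummy")
    w = w / nw

    W_o, P_o, T_o, ssx_o = [], [], [], []
    for _ in range(int(n_orthogonal)):
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = Xd.T @ t / tt
        w_o = p_load - float(w @ p_load) * w
        n_o = np.linalg.norm(w_o)
        if n_o <= 1e-12 * max(np.linalg.norm(p_load), 1.0):
            break  # nothing orthogonal left to remove
        w_o = w_o / n_o
        t_o = Xd @ w_o
        tto = float(t_o @ t_o)
        if tto <= 0:
            break
        p_o = Xd.T @ t_o / tto
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        ssx_o.append(tto * float(p_o @ p_o))

    t = Xd @ w
    tt = float(t @ t)
    if tt <= 0:
        raise ValueError("degenerate predictive component (X has no variance left)")
    p_load = Xd.T @ t / tt
    c = float(y @ t) / tt

    ssx_total = float((X0**2).sum())
    ssx_expl = tt * float(p_load @ p_load) + float(np.sum(ssx_o))
    ssy_expl = c * c * tt
    Ao = len(W_o)
    return OplsdaModel(
        kind="oplsda",
        class_labels=labels,
        predictive_scores=t[:, None],
        predictive_weights=w[:, None],
        predictive_loadings=p_load[:, None],
        orthogonal_scores=np.column_stack(T_o) if Ao else np.empty((X0.shape[0], 0)),
        orthogonal_weights=np.column_stack(W_o) if Ao else np.empty((X0.shape[1], 0)),
        orthogonal_loadings=np.column_stack(P_o) if Ao else np.empty((X0.shape[1], 0)),
        y_loadings=np.array([[c]]),
        r2x=ssx_expl / ssx_total if ssx_total > 0 else 0.0,
        r2y=min(ssy_expl / ssy, 1.0),
        dummy_coding={"type": "pm1", "positive_class": labels[1], "y_means": y_means},
        feature_ids=feat,
        ssy_per_component=np.array([ssy_expl]),
        ssx_orthogonal=np.asarray(ssx_o, dtype=float),
    )


def fit_plsda_multiclass(x, groups, n_components: int | None = None) -> OplsdaModel:
    """Multi-class PLS-DA: NIPALS PLS2 of X against G centred indicators."""
    X0, feat = _as_array(x)
    Y, y_means, labels = dummy_matrix(groups)
    G = len(labels)
    if G < 3:
        raise ValueError("fit_plsda_multiclass requires >= 3 classes; use fit_oplsda")
    _check_class_sizes(groups, labels)
    A = int(n_components) if n_components is not None else G - 1
    if A < 1:
        raise ValueError("n_components must be >= 1")
    A = min(A, min(X0.shape[0] - 1, X0.shape[1]))

    E = X0.copy()
    F = Y.copy()
    W, T, P, C = [], [], [], []
    for _ in range(A):
        if float((E**2).sum()) <= 1e-300 or float((F**2).sum()) <= 1e-300:
            break
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t = np.zeros(E.shape[0])
        for _it in range(_MAX_ITER):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w = w / nw
            t_new = E @ w
            c = F.T @ t_new / float(t_new @ t_new)
            u = F @ c / float(c @ c)
            if np.linalg.norm(t_new - t) <= _CONV_TOL * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = E.T @ t / tt
        c = F.T @ t / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, c)
        W.append(w)
        T.append(t)
        P.append(p_load)
        C.append(c)

    if not T:
        raise ValueError("no PLS component could be extracted")
    Tm, Wm, Pm = (np.column_stack(b) for b in (T, W, P))
    Cm = np.column_stack(C)  # G x A
    ssy_total = float((Y**2).sum())
    ssx_total = float((X0**2).sum())
    ssy_per = np.array([float(t @ t) * float(c @ c) for t, c in zip(T, C)])
    return OplsdaModel(
        kind="plsda",
        class_labels=labels,
        predictive_scores=Tm,
        predictive_weights=Wm,
        predictive_loadings=Pm,
        orthogonal_scores=np.empty((X0.shape[0], 0)),
        orthogonal_weights=np.empty((X0.shape[1], 0)),
        orthogonal_loadings=np.empty((X0.shape[1], 0)),
        y_loadings=Cm,
        r2x=1.0 - float((E**2).sum()) / ssx_total if ssx_total > 0 else 0.0,
        r2y=1.0 - float((F**2).sum()) / ssy_total if ssy_total > 0 else 0.0,
        dummy_coding={"type": "indicator", "classes": labels, "y_means": y_means},
        feature_ids=feat,
        ssy_per_component=ssy_per,
        ssx_orthogonal=np.empty(0),
    )


def auto_orthogonal(
    x,
    groups,
    validator,
    q2_gain_min: float = 0.01,
    max_orthogonal: int = 5,
) -> tuple[OplsdaModel, list[tuple[int, float]]]:
    """Grow the orthogonal block while cross-validated Q2 keeps improving.

    ``validator(x, groups, n_orthogonal) -> q2`` supplies the cross-validated
    predictability for a candidate component count. Starting at 0, a further
    orthogonal component is kept only if it raises Q2 by >= ``q2_gain_min``.
    Returns the selected model and the ``(n_orthogonal, q2)`` trace.
    """
    if validator is None:
        raise ValueError("a cross-validation callback is required")
    if q2_gain_min < 0:
        raise ValueError("q2_gain_min must be >= 0")
    best_ao = 0
    best_q2 = float(validator(x, groups, 0))
    trace = [(0, best_q2)]
    for ao in range(1, int(max_orthogonal) + 1):
        q2 = float(validator(x, groups, ao))
        trace.append((ao, q2))
        if q2 - best_q2 >= q2_gain_min:
            best_ao, best_q2 = ao, q2
        else:
            break
    return fit_oplsda(x, groups, n_orthogonal=best_ao), trace


@dataclass
class VipScores:
    vip: pd.Series
    component_basis: str  # "predictive_only" | "all_components"

    def __iter__(self):
        return iter(self.vip)


def compute_vip(model: OplsdaModel, component_basis: str | None = None) -> VipScores:
    """VIP scores: vip_j = sqrt(p * sum_a w_aj^2 * omega_a / sum_a omega_a).

    Component weights omega_a are the explained response sum of squares of
    each predictive component. For OPLS-DA the default basis is the
    predictive component only (the discriminatory importance); the
    ``all_components`` basis additionally pools orthogonal weights, weighted
    by their explained X sum of squares. Because each weight vector has unit
    norm, mean(vip^2) over features is exactly 1 under any basis.
    """
    if component_basis is None:
        component_basis = "predictive_only" if model.kind == "oplsda" else "all_components"
    if component_basis not in ("predictive_only", "all_components"):
        raise ValueError("component_basis must be 'predictive_only' or 'all_components'")
    if float(model.ssy_per_component.sum()) <= 0:
        raise ValueError("model explains no response variance; VIP undefined")

    W = model.predictive_weights
    omega = model.ssy_per_component.astype(float).copy()
    if component_basis == "all_components" and model.n_orthogonal:
        W = np.column_stack([W, model.orthogonal_weights])
        omega = np.concatenate([omega, model.ssx_orthogonal])
    p = W.shape[0]
    vip2 = p * (W**2 @ omega) / float(omega.sum())
    return VipScores(
        vip=pd.Series(np.sqrt(vip2), index=model.feature_ids),
        component_basis=component_basis,
    )
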