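"""PCA and orthogonal PLS discriminant analysis with VIP scoring.

The OPLS-DA decomposition follows the orthogonal-signal-correction scheme:
class-orthogonal components are extracted and removed from X first, then a
single predictive PLS component is fitted on the deflated matrix. The class
vector is coded {-1, +1} and centred. Per-feature importance is the VIP
score over the predictive component; mean squared VIP equals 1 by
construction, so VIP > 1 marks above-average contributors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: np.ndarray            # n x k
    loadings: np.ndarray          # p x k, orthonormal columns
    explained_variance_ratio: np.ndarray


@dataclass
class OplsModel:
    t_pred: np.ndarray            # predictive scores, n x 1
    w_pred: np.ndarray            # predictive weights, p
    p_pred: np.ndarray            # predictive loadings, p
    q_pred: float                 # y loading of the predictive component
    t_ortho: np.ndarray           # orthogonal scores, n x n_ortho
    w_ortho: np.ndarray           # orthogonal weights, p x n_ortho
    p_ortho: np.ndarray           # orthogonal loadings, p x n_ortho
    r2y: float
    r2x_pred: float
    x_mean: np.ndarray = field(default=None)
    y_mean: float = 0.0


def pca(matrix: np.ndarray, n_components: int) -> PcaResult:
    """SVD-based PCA of an already centred (and scaled) matrix.

    Sign convention: each loading's largest-magnitude element is positive.
    Requesting more components than the rank truncates with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d: truncated",
                       n_components, rank)
        n_components = rank
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign: largest |loading| element positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2
    total = np.sum(np.linalg.svd(X, compute_uv=False) ** 2)
    ratio = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(scores=U * s, loadings=Vt.T, explained_variance_ratio=ratio)


def _code_y(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes.size}")
    coded = np.where(y == classes[1], 1.0, -1.0)
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError("each class needs >= 2 samples")
    return coded


def oplsda_fit(X: np.ndarray, y, n_ortho: int = 1) -> OplsModel:
    """Fit OPLS-DA: ``n_ortho`` orthogonal components then one predictive.

    X is centred internally; y may be any two-level labelling and is coded
    {-1, +1} then centred. With ``n_ortho=0`` the model coincides with a
    one-component PLS-DA (NIPALS first component).
    """
    X = np.asarray(X, dtype=float)
    yc = _code_y(y)
    x_mean = X.mean(axis=0)
    y_mean = float(yc.mean())
    E = X - x_mean
    f = yc - y_mean
    ssx_total = float(np.sum(E**2))

    # y-predictive weight direction (stable across deflations)
    t_os, w_os, p_os = [], [], []
    for _ in range(n_ortho):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y carries no covariance with X")
        w = w / nw
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            logger.warning("no orthogonal variation left; stopping early")
            break
        w_o = w_o / n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        t_os.append(t_o)
        w_os.append(w_o)
        p_os.append(p_o)

    w = E.T @ f
    w = w / np.linalg.norm(w)
    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(f @ t / (t @ t))
    resid = f - q * t
    r2y = 1.0 - float(resid @ resid) / float(f @ f)
    r2x = float(t @ t * (p @ p)) / ssx_total if ssx_total > 0 else 0.0

    stack = (lambda lst, width: np.column_stack(lst) if lst
             else np.zeros((X.shape[0] if width == 0 else X.shape[1], 0)))
    return OplsModel(
        t_pred=t, w_pred=w, p_pred=p, q_pred=q,
        t_ortho=stack(t_os, 0), w_ortho=stack(w_os, 1), p_ortho=stack(p_os, 1),
        r2y=r2y, r2x_pred=r2x, x_mean=x_mean, y_mean=y_mean,
    )


def vip_scores(model: OplsModel) -> np.ndarray:
    """VIP over the predictive component: sqrt(p) * |w| with ||w|| = 1.

    With a single predictive component the SSY weighting cancels, and the
    normalization identity mean(VIP^2) = 1 holds exactly.
    """
    w = model.w_pred
    p = w.size
    return np.sqrt(p) * np.abs(w)


def predict_scores(model: OplsModel, X: np.ndarray) -> np.ndarray:
    """Predictive scores for new samples (orthogonal filtering then t)."""
    E = np.asarray(X, dtype=float) - model.x_mean
    for k in range(model.t_ortho.shape[1]):
        w_o = model.w_ortho[:, k]
        p_o = model.p_ortho[:, k]
        t_o = E @ w_o
        E = E - np.outer(t_o, p_o)
    return E @ model.w_pred
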