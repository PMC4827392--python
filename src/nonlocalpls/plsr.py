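"""Computationally tractable partial least squares regression on voxel data.

Two paired blocks ``X`` (subjects x N_x voxels) and ``Y`` (subjects x N_y
voxels) are decomposed into latent components that maximise cross-block
covariance: for each component, unit weight vectors ``w`` and ``c`` maximise
``cov(X w, Y c)``, i.e. they are the leading singular pair of the voxels x
voxels cross-covariance ``Xᵀ Y``.  For imaging data that matrix is far too
large to materialise, so the singular pair is obtained from a subjects-space
eigen-problem instead: with Gram matrices ``G_x = X Xᵀ`` and ``G_y = Y Yᵀ``
(both K x K for K subjects), the x-score ``t = X w`` is the leading
eigenvector of ``G_x G_y``; we solve the symmetric reformulation
``G_x^{1/2} G_y G_x^{1/2}`` for numerical robustness and back-project to the
voxel-space weights.  Peak additional storage is O(K² + K·N + m·N); nothing
of size N x N is ever allocated.

Successive components are extracted by deflating both blocks on the x-score
(standard PLS2 regression deflation), which makes the score vectors ``t_i``
mutually orthogonal.  A scalar inner coefficient ``b_i = tᵀu/(tᵀt)`` links
the x- and y-scores of each component; prediction uses the regression
operator in factored form,

    T_new = X_new W (Pᵀ W)^{-1},        Y_hat = T_new diag(b) Cᵀ + y_mean,

which is algebraically the usual PLSR coefficient matrix
``B = W (PᵀW)^{-1} diag(b) Cᵀ`` applied without ever forming it densely.

A principal-component-regression comparator with the same predict interface
is provided for head-to-head comparisons: PCR picks its latent space to
maximise predictor variance alone, so a high-variance predictor pattern that
is uncorrelated with the target can crowd out the predictive directions —
the failure mode PLSR avoids by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .dataset_io import MultimodalDataset

__all__ = [
    "LatentModel",
    "FactoredRegression",
    "PCRModel",
    "leading_covariance_pair",
    "deflate",
    "fit_pls",
    "regression_operator",
    "predict",
    "project",
    "fit_pcr",
    "save_model",
    "load_model",
]


@dataclass
class LatentModel:
    """A fitted PLS decomposition in factored form.

    ``W`` (N_x x m) and ``C`` (N_y x m) hold unit-norm weight vectors,
    ``P``/``Q`` the loadings used for deflation, ``T``/``U`` the subject
    scores, ``b`` the scalar inner coefficients, and ``x_mean``/``y_mean``
    the centering vectors of the training data.
    """

    W: np.ndarray
    C: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    U: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def m(self) -> int:
        return self.W.shape[1]


class FactoredRegression:
    """The linear map X_new -> Y_hat, kept in factored form.

    ``W_star = W (PᵀW)^{-1}`` maps centered inputs to scores; prediction is
    ``scores @ diag(b) @ Cᵀ`` plus the training target mean.  Equivalent to
    the dense PLSR coefficient matrix without materialising it.
    """

    def __init__(self, model: LatentModel):
        PtW = model.P.T @ model.W
        cond = np.linalg.cond(PtW)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"PᵀW is numerically singular (condition number {cond:.3e})"
            )
        self.W_star = model.W @ np.linalg.inv(PtW)
        self.b = model.b
        self.C = model.C
        self.x_mean = model.x_mean
        self.y_mean = model.y_mean

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.W_star.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} voxels, model expects {self.W_star.shape[0]}"
            )
        return (X_new - self.x_mean) @ self.W_star

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        scores = self.transform(X_new)
        return (scores * self.b) @ self.C.T + self.y_mean


# ---------------------------------------------------------------------------
# single-component extraction in subjects space
# ---------------------------------------------------------------------------

def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    lam, V = eigh(G)
    lam = np.clip(lam, 0.0, None)
    return (V * np.sqrt(lam)) @ V.T


def leading_covariance_pair(
    Xc: np.ndarray, Yc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Leading singular pair of ``Xcᵀ Yc`` via the subjects-space trick.

    Returns unit weight vectors ``(w, c)`` and the scores ``t = Xc w``,
    ``u = Yc c``.  Only K x K matrices are formed.  The sign is fixed so the
    largest-magnitude entry of ``w`` is positive; ``t``, ``c`` and ``u``
    inherit that sign coherently.
    """
    Xc = np.asarray(Xc, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if Xc.shape[0] != Yc.shape[0]:
        raise ValueError("Xc and Yc must have equal row counts")
    if Xc.shape[0] < 2:
        raise ValueError("need at least two subjects")

    Gx = Xc @ Xc.T
    Gy = Yc @ Yc.T
    S = _psd_sqrt(Gx)
    try:
        evals, evecs = eigh(S @ Gy @ S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise np.linalg.LinAlgError(
            f"subjects-space eigen-solver failed on a {Gx.shape[0]}x{Gx.shape[0]} problem: {exc}"
        ) from exc
    if evals[-1] <= 0 or not np.isfinite(evals[-1]):
        raise ValueError("cross-covariance is zero; no covariance pair exists")

    t0 = S @ evecs[:, -1]
    # back-project: w ∝ Xᵀ Y Yᵀ t = Xᵀ (G_y t); then recompute scores.
    w = Xc.T @ (Gy @ t0)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("degenerate weight vector (all-zero back-projection)")
    w /= nw
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    t = Xc @ w
    c = Yc.T @ t
    nc = np.linalg.norm(c)
    if nc == 0:
        raise ValueError("degenerate target weight vector")
    c /= nc
    u = Yc @ c
    return w, c, t, u


def deflate(
    Xc: np.ndarray, Yc: np.ndarray, t: np.ndarray, w: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Remove the extracted component from both blocks on the x-score ``t``.

    Loadings are ``p = Xcᵀt/(tᵀt)`` and ``q = Ycᵀt/(tᵀt)``; the deflated
    blocks ``Xc - t pᵀ`` and ``Yc - t qᵀ`` are orthogonal to ``t``.  Returns
    ``(Xc', Yc', p, q)``.
    """
    tt = float(t @ t)
    if tt <= 0 or not np.isfinite(tt):
        raise ValueError("cannot deflate on a zero-norm score vector")
    p = Xc.T @ t / tt
    q = Yc.T @ t / tt
    return Xc - np.outer(t, p), Yc - np.outer(t, q), p, q


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _require_centered(dataset: MultimodalDataset) -> None:
    if not dataset.is_centered:
        raise ValueError("dataset must be centered first (see center_dataset)")


def fit_pls(dataset: MultimodalDataset, m: int) -> LatentModel:
    """Extract ``m`` latent components from a centered dataset.

    Repeats single-pair extraction + scalar inner-coefficient estimation +
    deflation.  If the residual blocks become numerically zero before ``m``
    components are found, extraction stops early with a warning and the
    model carries fewer components.
    """
    _require_centered(dataset)
    K = dataset.n_subjects
    if not 1 <= m <= K - 1:
        raise ValueError(f"m must be in [1, subjects-1] = [1, {K - 1}], got {m}")

    Xr, Yr = dataset.X.copy(), dataset.Y.copy()
    tol = 1e-12 * max(np.linalg.norm(Xr), np.linalg.norm(Yr))
    Ws, Cs, Ps, Qs, Ts, Us, bs = [], [], [], [], [], [], []
    for i in range(m):
        if min(np.linalg.norm(Xr), np.linalg.norm(Yr)) < tol:
            warnings.warn(
                f"residual exhausted after {i} components (requested {m})",
                stacklevel=2,
            )
            break
        try:
            w, c, t, u = leading_covariance_pair(Xr, Yr)
        except ValueError:
            warnings.warn(
                f"no further covariance structure after {i} components (requested {m})",
                stacklevel=2,
            )
            break
        Xr, Yr, p, q = deflate(Xr, Yr, t, w, c)
        Ws.append(w); Cs.append(c); Ps.append(p); Qs.append(q)
        Ts.append(t); Us.append(u); bs.append(float(t @ u) / float(t @ t))

    if not Ws:
        raise ValueError("no components could be extracted (zero data?)")
    return LatentModel(
        W=np.column_stack(Ws),
        C=np.column_stack(Cs),
        P=np.column_stack(Ps),
        Q=np.column_stack(Qs),
        T=np.column_stack(Ts),
        U=np.column_stack(Us),
        b=np.asarray(bs),
        x_mean=dataset.x_mean,
        y_mean=dataset.y_mean,
    )


def regression_operator(model: LatentModel) -> FactoredRegression:
    """The fitted linear map X_new -> Y_hat in factored form."""
    return FactoredRegression(model)


def predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the target modality for new predictor images (original units)."""
    return regression_operator(model).predict(X_new)


def project(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Latent scores of new predictor images: ``(X_new - x_mean) W (PᵀW)^{-1}``."""
    return regression_operator(model).transform(X_new)


# ---------------------------------------------------------------------------
# principal component regression comparator
# ---------------------------------------------------------------------------

class PCRModel:
    """PCA on the predictor block followed by least squares on the scores."""

    def __init__(self, components: np.ndarray, beta: np.ndarray,
                 x_mean: np.ndarray, y_mean: np.ndarray):
        self.components = components  # m x N_x principal axes
        self.beta = beta              # m x N_y regression coefficients
        self.x_mean = x_mean
        self.y_mean = y_mean

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return (X_new - self.x_mean) @ self.components.T

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return self.transform(X_new) @ self.beta + self.y_mean


def fit_pcr(dataset: MultimodalDataset, m: int) -> PCRModel:
    """Top-``m`` PCA of X, then least-squares regression of Y on the scores."""
    _require_centered(dataset)
    U, s, Vt = np.linalg.svd(dataset.X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if not 1 <= m <= rank:
        raise ValueError(f"m must be in [1, rank(X)] = [1, {rank}], got {m}")
    scores = U[:, :m] * s[:m]
    # scores are orthogonal, so the LS solution is diagonal in score space
    beta = (scores.T @ dataset.Y) / (s[:m] ** 2)[:, None]
    return PCRModel(Vt[:m], beta, dataset.x_mean, dataset.y_mean)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_model(model: LatentModel, path: str | Path) -> None:
    """Serialise a fitted model to a single ``.npz`` archive."""
    np.savez_compressed(
        path,
        W=model.W, C=model.C, P=model.P, Q=model.Q,
        T=model.T, U=model.U, b=model.b,
        x_mean=model.x_mean, y_mean=model.y_mean,
    )


def load_model(path: str | Path) -> LatentModel:
    with np.load(path) as npz:
        return LatentModel(**{k: npz[k] for k in
                              ("W", "C", "P", "Q", "T", "U", "b", "x_mean", "y_mean")})
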