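"""Affine-invariant Riemannian geometry on symmetric positive definite matrices.

Covariance matrices live on the SPD manifold.  Under the affine-invariant
metric the geodesic distance is
``d(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F``, the Frechet (geometric) mean
is the point minimizing the sum of squared distances, and the tangent space
at a reference matrix linearizes the manifold so Euclidean classifiers
apply.  All matrix functions go through symmetric eigendecompositions; most
routines accept stacked arrays ``(..., D, D)`` and are vectorized over the
leading axes, which keeps the decoding pipeline fast.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "is_spd",
    "check_spd",
    "spd_logm",
    "spd_expm",
    "spd_powm",
    "airm_distance",
    "frechet_mean",
    "tangent_map",
    "tangent_unmap",
    "FrechetConvergenceError",
]

EIG_FLOOR = 1e-12
SYM_TOL = 1e-10


class FrechetConvergenceError(RuntimeError):
    """The Frechet-mean fixed-point iteration did not converge."""


def is_spd(mat: np.ndarray, sym_tol: float = SYM_TOL) -> bool:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if np.max(np.abs(mat - mat.T)) > sym_tol * max(1.0, np.max(np.abs(mat))):
        return False
    return bool(np.linalg.eigvalsh(mat).min() > 0)


def check_spd(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate (stacked) SPD input; returns the array unchanged."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape[-1] != mat.shape[-2]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    scale = max(1.0, float(np.max(np.abs(mat))))
    if np.max(np.abs(mat - np.swapaxes(mat, -1, -2))) > SYM_TOL * scale:
        raise ValueError(f"{name} is not symmetric to tolerance {SYM_TOL}")
    w = np.linalg.eigvalsh(mat)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite (min eig {w.min():.3e})")
    return mat


def _eigh_floor(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(mat)
    if np.any(w < EIG_FLOOR):
        logger.debug("eigenvalue floor %g triggered (min %g)", EIG_FLOOR, w.min())
        w = np.maximum(w, EIG_FLOOR)
    return w, v


def _spectral(w: np.ndarray, v: np.ndarray, fw: np.ndarray) -> np.ndarray:
    """Rebuild ``V diag(fw) V'`` for stacked eigendecompositions."""
    return (v * fw[..., None, :]) @ np.swapaxes(v, -1, -2)


def spd_logm(mat: np.ndarray) -> np.ndarray:
    """Matrix logarithm of (stacked) SPD matrices."""
    w, v = _eigh_floor(mat)
    return _spectral(w, v, np.log(w))


def spd_expm(sym: np.ndarray) -> np.ndarray:
    """Matrix exponential of (stacked) symmetric matrices."""
    w, v = np.linalg.eigh(sym)
    return _spectral(w, v, np.exp(w))


def spd_powm(mat: np.ndarray, p: float) -> np.ndarray:
    """Matrix power of (stacked) SPD matrices."""
    w, v = _eigh_floor(mat)
    return _spectral(w, v, w ** p)


def _whiten(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """``(ref^{-1/2}, ref^{1/2})`` from one eigendecomposition."""
    w, v = _eigh_floor(ref)
    isq = (v * (w ** -0.5)) @ v.T
    sq = (v * (w ** 0.5)) @ v.T
    return isq, sq


def airm_distance(a: np.ndarray, b: np.ndarray, *, validate: bool = True) -> float:
    """Affine-invariant distance ``||logm(A^{-1/2} B A^{-1/2})||_F``.

    Invariant under congruence: ``d(WAW', WBW') = d(A, B)`` for any
    invertible W.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    if validate:
        check_spd(a, "A")
        check_spd(b, "B")
    isq, _ = _whiten(a)
    # generalized eigenvalues of (B, A) through whitening
    w = np.linalg.eigvalsh(isq @ b @ isq)
    w = np.maximum(w, EIG_FLOOR)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _frechet_mean_logs(mats: np.ndarray, tol: float, max_iter: int,
                       init: np.ndarray | None, *,
                       raise_on_maxiter: bool = True):
    """Karcher fixed-point iteration with adaptive step size.

    Returns ``(mean, logs)`` where ``logs[i] = logm(mean^{-1/2} X_i
    mean^{-1/2})`` evaluated at the converged mean (convergence is declared
    *before* the final update, so the logs are exact tangent images at the
    returned point).  The step size grows 5% on every criterion decrease
    and halves on an increase, which keeps the iteration stable for widely
    spread matrix sets where the unit step converges slowly.
    """
    m = np.asarray(init, dtype=float) if init is not None else mats.mean(axis=0)
    nu = 1.0
    prev = np.inf
    crit = np.inf
    for it in range(max_iter):
        isq, sq = _whiten(m)
        w, v = _eigh_floor(isq @ mats @ isq)
        logs = _spectral(w, v, np.log(w))
        step = logs.mean(axis=0)
        crit = float(np.linalg.norm(step))
        if crit < tol:
            return m, logs
        if it == max_iter - 1:
            break
        nu = nu * 1.05 if crit < prev else nu * 0.5
        prev = crit
        s = nu * step
        if crit * nu < 0.3:
            # third-order Taylor expm: error O(1e-5) relative, self-corrected
            # by later iterations since the convergence test uses exact logs
            s2 = s @ s
            e = np.eye(len(s)) + s + 0.5 * s2 + (s2 @ s) / 6.0
        else:
            e = spd_expm(s)
        m = sq @ e @ sq
        m = 0.5 * (m + m.T)
    if raise_on_maxiter:
        raise FrechetConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(last step norm {crit:.3e}, n={mats.shape[0]}, "
            f"D={mats.shape[1]}, tol={tol})"
        )
    # best-effort mode: the last evaluated iterate with its exact logs
    return m, logs


def frechet_mean(mats: np.ndarray, tol: float = 1e-8, max_iter: int = 50,
                 init: np.ndarray | None = None, *,
                 validate: bool = True) -> np.ndarray:
    """Frechet (geometric) mean under the affine-invariant metric.

    Fixed-point iteration: at the current estimate M, average the tangent
    logs of all matrices and step along the exponential map,
    ``M <- M^{1/2} expm(nu * mean_i logm(M^{-1/2} X_i M^{-1/2})) M^{1/2}``,
    with an adaptive step size nu, until the Frobenius norm of the mean
    tangent log falls below ``tol``.  Initialized at the arithmetic mean
    unless ``init`` is given.  Raises :class:`FrechetConvergenceError` with
    diagnostics if ``max_iter`` is exhausted.
    """
    mats = np.asarray(mats, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.shape[0] == 0:
        raise ValueError("frechet_mean of an empty set")
    if validate:
        check_spd(mats, "matrices")
    if mats.shape[0] == 1:
        return mats[0].copy()
    mean, _ = _frechet_mean_logs(mats, tol, max_iter, init)
    return mean


def _triu_weights(d: int) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    iu = np.triu_indices(d)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return iu, w


def _vectorize_logs(logs: np.ndarray) -> np.ndarray:
    """Upper-triangle vectorization with sqrt(2) off-diagonal weights."""
    d = logs.shape[-1]
    iu, w = _triu_weights(d)
    return logs[..., iu[0], iu[1]] * w


def tangent_map(mats: np.ndarray, ref: np.ndarray, *,
                validate: bool = True) -> np.ndarray:
    """Project (stacked) SPD matrices to the tangent space at ``ref``.

    Each matrix C maps to ``S = logm(ref^{-1/2} C ref^{-1/2})``, vectorized
    as the upper triangle with off-diagonal entries scaled by sqrt(2) so the
    Euclidean norm of the vector equals ``||S||_F`` and, in particular,
    ``||tangent_map(C, ref)|| = airm_distance(C, ref)``.  Output shape is
    ``(..., D(D+1)/2)``.
    """
    mats = np.asarray(mats, dtype=float)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    if validate:
        check_spd(ref, "reference")
        check_spd(mats, "matrices")
    if mats.shape[-1] != ref.shape[-1]:
        raise ValueError("dimension mismatch between matrices and reference")
    isq, _ = _whiten(np.asarray(ref, dtype=float))
    vec = _vectorize_logs(spd_logm(isq @ mats @ isq))
    return vec[0] if single else vec


def tangent_unmap(vec: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_map`: tangent vector back to an SPD matrix."""
    vec = np.asarray(vec, dtype=float)
    d = ref.shape[-1]
    iu, w = _triu_weights(d)
    s = np.zeros((d, d))
    s[iu] = vec / w
    s = s + s.T - np.diag(np.diag(s))
    isq, sq = _whiten(np.asarray(ref, dtype=float))
    return sq @ spd_expm(s) @ sq
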