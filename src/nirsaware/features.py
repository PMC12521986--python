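"""Prototype-augmented, spatially filtered, shrunk trial covariances.

Each trial is represented as a point on the SPD manifold by:

1. computing per-class prototype responses P (the arithmetic mean trial of
   each class over the *training* subset only);
2. fitting per-class xDAWN spatial filters -- the leading generalized
   eigenvectors maximizing the ratio of evoked-response power to total
   signal power -- again on the training subset;
3. reducing each prototype with its own class's f filters and each trial
   with all 2f filters, concatenating rows to the augmented matrix
   ``X~_i = [V_A P_A; V_B P_B; V X_i]`` with 4f rows, so the covariance of
   ``X~_i`` encodes the similarity of trial i to both class templates;
4. estimating the covariance of ``X~_i`` with oracle-approximating
   shrinkage (OAS) toward the scaled identity ``mu I`` (``mu = tr(S)/D``),
   which preserves the trace and guarantees positive definiteness even when
   the trial is shorter than the augmented channel count.

The row order of the augmented matrix is fixed: IMAGERY prototype,
NO-IMAGERY prototype, trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .paradigm import Condition
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClassPrototype",
    "SpatialFilters",
    "SPDSet",
    "compute_prototypes",
    "fit_xdawn",
    "augment_and_covary",
    "oas_shrinkage",
    "oas_from_sample",
    "erp_covariances",
]

XDAWN_FILTER_GRID = (2, 4, 6)


@dataclass
class ClassPrototype:
    """Arithmetic-mean trial of one class over a training subset."""

    mean: np.ndarray          # (n_channels, n_samples)
    label: str
    n_trials: int


@dataclass
class SpatialFilters:
    """Per-class xDAWN filters, each of shape ``(f, n_channels)``."""

    filters: dict[str, np.ndarray]
    n_filters: int
    metadata: dict = field(default_factory=dict)

    def stacked(self, order: tuple[str, str]) -> np.ndarray:
        """All filters stacked in the given class order: ``(2f, n_channels)``."""
        return np.vstack([self.filters[k] for k in order])


@dataclass
class SPDSet:
    """Per-trial SPD matrices with labels and shrinkage intensities."""

    matrices: np.ndarray      # (n_trials, D, D)
    labels: np.ndarray
    shrinkage: np.ndarray     # (n_trials,), OAS rho in [0, 1]

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_trials, D, D)")
        if len(self.labels) != len(self.matrices):
            raise ValueError("labels length mismatch")

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]

    def save(self, path) -> None:
        """Write to an ``.npz`` container with a JSON metadata header."""
        import json

        header = json.dumps({"shape": list(self.matrices.shape)})
        np.savez(path, matrices=self.matrices,
                 labels=self.labels.astype("U"),
                 shrinkage=self.shrinkage, header=np.array(header))

    @classmethod
    def load(cls, path) -> "SPDSet":
        with np.load(path, allow_pickle=False) as f:
            return cls(matrices=f["matrices"], labels=f["labels"],
                       shrinkage=f["shrinkage"])


_CLASS_ORDER = (Condition.IMAGERY.value, Condition.NO_IMAGERY.value)


def compute_prototypes(epochs: EpochSet, train_idx: np.ndarray,
                       ) -> dict[str, ClassPrototype]:
    """Per-class mean trials ``P = (1/m) sum_i X_i`` over the training subset."""
    train_idx = np.asarray(train_idx)
    labels = epochs.labels[train_idx]
    out = {}
    for cls in _CLASS_ORDER:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} absent from training subset")
        out[cls] = ClassPrototype(
            mean=epochs.data[train_idx][mask].mean(axis=0),
            label=cls, n_trials=int(mask.sum()),
        )
    return out


def _signal_whitener(cov_signal: np.ndarray) -> np.ndarray:
    """``Cs^{-1/2}`` of the average signal covariance (floored spectrum)."""
    w, v = np.linalg.eigh(cov_signal)
    floor = 1e-12 * max(w.max(), 1e-30)
    if w.min() < floor:
        logger.warning("rank-deficient signal covariance; flooring spectrum")
        w = np.maximum(w, floor)
    return (v * w ** -0.5) @ v.T


def _xdawn_filters(p_mean: np.ndarray, cov_signal: np.ndarray,
                   n_filters: int,
                   isq_signal: np.ndarray | None = None) -> np.ndarray:
    """Leading generalized eigenvectors of (evoked power, signal power).

    Solved in whitened coordinates: with ``W = Cs^{-1/2}`` the generalized
    problem ``Ce v = lambda Cs v`` becomes a standard symmetric
    eigenproblem for ``W Ce W``; ``isq_signal`` lets callers reuse a
    precomputed whitener (it does not depend on the trial labels).
    """
    n_s = p_mean.shape[1]
    cov_evoked = (p_mean @ p_mean.T) / n_s
    isq = _signal_whitener(cov_signal) if isq_signal is None else isq_signal
    _, u = np.linalg.eigh(isq @ cov_evoked @ isq)
    filt = (isq @ u[:, ::-1][:, :n_filters]).T    # descending eigenvalues
    norms = np.linalg.norm(filt, axis=1, keepdims=True)
    return filt / np.where(norms > 0, norms, 1.0)


def fit_xdawn(epochs: EpochSet, train_idx: np.ndarray,
              n_filters: int) -> SpatialFilters:
    """Fit per-class xDAWN spatial filters on the training subset.

    For each class the filters maximize ``(w' Ce w) / (w' Cs w)`` where Ce
    is the covariance of the class-average evoked response and Cs the
    average per-trial signal covariance over all training trials.
    """
    train_idx = np.asarray(train_idx)
    if n_filters > epochs.n_channels:
        raise ValueError("more filters than channels requested")
    protos = compute_prototypes(epochs, train_idx)
    for cls in _CLASS_ORDER:
        if protos[cls].n_trials < 2:
            raise ValueError(f"need >= 2 training trials per class, got "
                             f"{protos[cls].n_trials} for {cls!r}")
    x = epochs.data[train_idx]
    n_s = x.shape[2]
    cov_signal = np.tensordot(x, x, axes=([0, 2], [0, 2])) / (len(x) * n_s)
    filters = {
        cls: _xdawn_filters(protos[cls].mean, cov_signal, n_filters)
        for cls in _CLASS_ORDER
    }
    return SpatialFilters(filters=filters, n_filters=n_filters,
                          metadata={"n_train": len(train_idx)})


def oas_shrinkage(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Oracle-approximating shrinkage covariance of stacked row-variable data.

    ``x`` has shape ``(n_trials, D, n_samples)``; rows are variables.  Rows
    are mean-centred, the biased sample covariance ``S = Z Z' / n`` is
    shrunk toward ``mu I`` with ``mu = tr(S)/D`` using the closed-form OAS
    intensity, clipped to [0, 1].  Returns ``(covariances, rho)``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    n = x.shape[2]
    z = x - x.mean(axis=2, keepdims=True)
    s = (z @ z.transpose(0, 2, 1)) / n
    shrunk, rho = oas_from_sample(s, n)
    return (shrunk[0], rho[0]) if single else (shrunk, rho)


def oas_from_sample(s: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """OAS shrinkage applied to precomputed (stacked) sample covariances.

    ``s`` is ``(n_trials, D, D)`` biased sample covariances estimated from
    ``n`` samples each.  Same closed form as :func:`oas_shrinkage`.
    """
    d = s.shape[-1]
    tr = np.trace(s, axis1=-2, axis2=-1)
    tr2 = np.einsum("...de,...de->...", s, s)
    mu = tr / d
    if np.any(mu <= 0):
        raise ValueError("zero-variance trial: covariance target is singular")
    num = (1.0 - 2.0 / d) * tr2 + tr ** 2
    den = (n + 1.0 - 2.0 / d) * (tr2 - tr ** 2 / d)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 1.0)
    rho = np.clip(rho, 0.0, 1.0)
    shrunk = ((1.0 - rho)[..., None, None] * s
              + (rho * mu)[..., None, None] * np.eye(d))
    return shrunk, rho


def erp_covariances(trials: np.ndarray, proto_imagery: np.ndarray,
                    proto_no_imagery: np.ndarray, v_imagery: np.ndarray,
                    v_no_imagery: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized augmented-covariance construction (the fast path).

    ``trials`` is ``(n, C, S)``; prototypes ``(C, S)``; filters ``(f, C)``.
    Returns OAS-shrunk covariances ``(n, 4f, 4f)`` and shrinkage ``(n,)``.
    """
    fp = np.vstack([v_imagery @ proto_imagery, v_no_imagery @ proto_no_imagery])
    v_all = np.vstack([v_imagery, v_no_imagery])
    ft = v_all @ trials
    n = trials.shape[0]
    aug = np.concatenate([np.broadcast_to(fp, (n,) + fp.shape), ft], axis=1)
    return oas_shrinkage(aug)


def augment_and_covary(epochs: EpochSet, prototypes: dict[str, ClassPrototype],
                       filters: SpatialFilters,
                       idx: np.ndarray | None = None) -> SPDSet:
    """Build the per-trial augmented, filtered, OAS-shrunk covariance set.

    ``prototypes`` and ``filters`` must have been fitted on a training
    subset; ``idx`` selects which trials to transform (default: all).
    """
    idx = np.arange(epochs.n_trials) if idx is None else np.asarray(idx)
    covs, rho = erp_covariances(
        epochs.data[idx],
        prototypes[_CLASS_ORDER[0]].mean,
        prototypes[_CLASS_ORDER[1]].mean,
        filters.filters[_CLASS_ORDER[0]],
        filters.filters[_CLASS_ORDER[1]],
    )
    return SPDSet(matrices=covs, labels=epochs.labels[idx], shrinkage=rho)
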