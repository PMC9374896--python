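"""Riemannian algebra for symmetric positive-definite (SPD) matrices.

Sliding-window functional-connectivity matrices live on the manifold
Sym+_N of SPD matrices.  This module provides the geometric primitives
everything else is built on: matrix log/exp through the eigendecomposition,
the log-Euclidean (default) and affine-invariant geodesic distances, Fréchet
means, parallel transport between manifold base points, and the three-step
alignment that removes subject-to-subject offsets from trajectories of
connectivity matrices.

Conventions
-----------
* Matrices are plain ``numpy.ndarray``; a :class:`Trajectory` bundles a
  time-ordered stack of them with their window-center time indices.
* The log-Euclidean metric ``g(A, B) = ||log A - log B||_F`` is the default
  everywhere (closed-form means, flat log chart); the affine-invariant
  metric is available behind the ``metric`` flag.
* Near-singular inputs are ridge-lifted by ``1e-10 * trace/N * I`` before a
  matrix function is taken, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger("spdstates")

Metric = Literal["log_euclidean", "affine_invariant"]

#: relative symmetry tolerance for SPD validation
SYM_RTOL = 1e-10
#: ridge factor applied to near-singular matrices before matrix functions
RIDGE_FACTOR = 1e-10


class SPDValidationError(ValueError):
    """Raised when a matrix fails the SPD invariants (symmetry, positivity)."""


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def check_spd(S: np.ndarray, *, name: str = "matrix") -> np.ndarray:
    """Validate that ``S`` is symmetric positive-definite.

    Returns the exactly symmetrized matrix (average with its transpose) so
    downstream eigendecompositions see a bitwise-symmetric input.  Raises
    :class:`SPDValidationError` on asymmetry beyond ``SYM_RTOL`` (relative
    to the matrix norm) or a non-positive smallest eigenvalue.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise SPDValidationError(f"{name} must be square, got shape {S.shape}")
    scale = max(np.abs(S).max(), 1.0)
    if np.abs(S - S.T).max() > SYM_RTOL * scale * S.shape[0]:
        raise SPDValidationError(f"{name} is not symmetric")
    Ssym = 0.5 * (S + S.T)
    lo = scipy.linalg.eigvalsh(Ssym, subset_by_index=(0, 0))[0]
    if lo <= 0.0:
        raise SPDValidationError(
            f"{name} is not positive definite (min eigenvalue {lo:.3e})"
        )
    return Ssym


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + S.T)


def _safe_eigh(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with a ridge lift for near-singular inputs."""
    w, U = np.linalg.eigh(S)
    if w[0] <= 0.0:
        ridge = RIDGE_FACTOR * np.trace(S) / S.shape[0]
        logger.warning(
            "near-singular SPD input (min eig %.3e); ridge-lifting by %.3e",
            w[0], ridge,
        )
        w = w + ridge
    return w, U


# ---------------------------------------------------------------------------
# matrix functions
# ---------------------------------------------------------------------------

def spd_logm(S: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition.

    Maps Sym+_N to the (flat) space of symmetric matrices; inverse of
    :func:`spd_expm`.
    """
    S = check_spd(S, name="spd_logm input")
    w, U = _safe_eigh(S)
    return _symmetrize((U * np.log(w)) @ U.T)


def spd_expm(L: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; returns an SPD matrix."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise SPDValidationError(f"spd_expm input must be square, got {L.shape}")
    scale = max(np.abs(L).max(), 1.0)
    if np.abs(L - L.T).max() > SYM_RTOL * scale * L.shape[0]:
        raise SPDValidationError("spd_expm input is not symmetric")
    L = _symmetrize(L)
    w, U = np.linalg.eigh(L)
    return _symmetrize((U * np.exp(w)) @ U.T)


def _spd_power(S: np.ndarray, p: float) -> np.ndarray:
    w, U = _safe_eigh(_symmetrize(np.asarray(S, dtype=float)))
    return _symmetrize((U * w ** p) @ U.T)


def spd_sqrtm(S: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return _spd_power(S, 0.5)


def spd_invsqrtm(S: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return _spd_power(S, -0.5)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def geodesic_distance(
    A: np.ndarray,
    B: np.ndarray,
    metric: Metric = "log_euclidean",
) -> float:
    """Geodesic distance between two SPD matrices.

    ``log_euclidean``: ``||log A - log B||_F``.  ``affine_invariant``:
    ``||log(A^{-1/2} B A^{-1/2})||_F``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    if metric == "log_euclidean":
        return float(np.linalg.norm(spd_logm(A) - spd_logm(B), "fro"))
    if metric == "affine_invariant":
        isq = spd_invsqrtm(check_spd(A, name="geodesic_distance A"))
        M = _symmetrize(isq @ check_spd(B, name="geodesic_distance B") @ isq)
        w, _ = _safe_eigh(M)
        return float(np.linalg.norm(np.log(w)))
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_geodesic(
    logs: np.ndarray,
) -> np.ndarray:
    """Pairwise log-Euclidean distances from a (T, N, N) stack of log-matrices.

    Vectorized helper used by the mean-shift recurrence and grouping; the
    inputs are matrix logarithms, so the distance is a flat Frobenius norm.
    """
    flat = logs.reshape(logs.shape[0], -1)
    sq = np.sum(flat ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


# ---------------------------------------------------------------------------
# Fréchet mean
# ---------------------------------------------------------------------------

def frechet_mean(
    matrices: Sequence[np.ndarray],
    metric: Metric = "log_euclidean",
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Fréchet (Karcher) mean of a set of SPD matrices.

    The mean minimizes the sum of squared geodesic distances to the inputs.
    Under the log-Euclidean metric it has the closed form
    ``exp(mean(log S_i))``; under the affine-invariant metric it is found by
    Karcher iteration (step size 1, gradient = mean of the logs pulled back
    to the current iterate) to ``tol`` or ``max_iter`` sweeps.
    """
    mats = [np.asarray(S, dtype=float) for S in matrices]
    if len(mats) == 0:
        raise ValueError("frechet_mean of an empty set")
    dims = {S.shape for S in mats}
    if len(dims) != 1:
        raise ValueError(f"frechet_mean inputs have mixed shapes: {dims}")
    if metric == "log_euclidean":
        logs = np.stack([spd_logm(S) for S in mats])
        return spd_expm(logs.mean(axis=0))
    if metric == "affine_invariant":
        mean = spd_expm(np.stack([spd_logm(S) for S in mats]).mean(axis=0))
        for _ in range(max_iter):
            sq = spd_sqrtm(mean)
            isq = spd_invsqrtm(mean)
            tangent = np.zeros_like(mean)
            for S in mats:
                tangent += spd_logm(_symmetrize(isq @ S @ isq))
            tangent /= len(mats)
            mean = _symmetrize(sq @ spd_expm(tangent) @ sq)
            if np.linalg.norm(tangent, "fro") < tol:
                break
        else:
            logger.warning(
                "Karcher iteration did not converge within %d sweeps "
                "(last step norm %.3e); returning last iterate",
                max_iter, float(np.linalg.norm(tangent, "fro")),
            )
        return mean
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# parallel transport
# ---------------------------------------------------------------------------

def transport_operator(
    source_mean: np.ndarray, target_mean: np.ndarray
) -> np.ndarray:
    """Congruence operator ``E = (target · source^{-1})^{1/2}``.

    ``target · source^{-1}`` is similar to the SPD matrix
    ``source^{-1/2} target source^{-1/2}``, so the principal square root is
    computed through that symmetrized form:
    ``E = source^{1/2} (source^{-1/2} target source^{-1/2})^{1/2} source^{-1/2}``.
    Satisfies ``E @ E = target @ inv(source)``.
    """
    source = check_spd(source_mean, name="source_mean")
    target = check_spd(target_mean, name="target_mean")
    sq = spd_sqrtm(source)
    isq = spd_invsqrtm(source)
    middle = spd_sqrtm(_symmetrize(isq @ target @ isq))
    return sq @ middle @ isq


def parallel_transport(
    X: np.ndarray, source_mean: np.ndarray, target_mean: np.ndarray
) -> np.ndarray:
    """Transport ``X`` from the base point ``source_mean`` to ``target_mean``.

    Uses the congruence map ``E X E^T`` with ``E = (target·source^{-1})^{1/2}``
    — the standard domain-adaptation construction for covariance data.  The
    map preserves SPD-ness and, crucially, the affine-invariant geometry
    within a trajectory, so alignment removes only the between-subject
    offset.  ``source_mean == target_mean`` gives ``E = I``.
    """
    X = check_spd(X, name="parallel_transport X")
    E = transport_operator(source_mean, target_mean)
    return _symmetrize(E @ X @ E.T)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A time-ordered sequence of same-dimension SPD matrices.

    Parameters
    ----------
    matrices : (T, N, N) array
        One SPD matrix per sliding window.
    times : (T,) int array
        Window-center time indices, strictly increasing.
    subject_id : str
        Identifier of the scan/series the trajectory came from.
    """

    matrices: np.ndarray
    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.times = np.asarray(self.times, dtype=int)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"matrices must be (T, N, N), got {self.matrices.shape}"
            )
        if len(self.times) != len(self.matrices):
            raise ValueError("times length must match number of matrices")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]

    def logs(self) -> np.ndarray:
        """Stack of matrix logarithms, shape (T, N, N)."""
        return np.stack([spd_logm(S) for S in self.matrices])

    def validate(self) -> None:
        for i, S in enumerate(self.matrices):
            check_spd(S, name=f"{self.subject_id or 'trajectory'}[{i}]")


def align_trajectories(
    trajs: Sequence[Trajectory],
    metric: Metric = "log_euclidean",
    *,
    n_passes: int = 1,
) -> tuple[list[Trajectory], np.ndarray]:
    """Align trajectories to their population Fréchet mean by parallel transport.

    Three steps, per pass: (1) subject means ``X̄_m = mean(X_m)``,
    (2) population mean ``X̄ = mean({X̄_m})``, (3) transport every matrix via
    the congruence moving ``X̄_m`` to ``X̄``.  After one pass every subject
    mean coincides with the population mean, which is why one pass is the
    default.

    Returns the aligned trajectories and the population mean.
    """
    if len(trajs) == 0:
        raise ValueError("align_trajectories needs at least one trajectory")
    dims = {t.dim for t in trajs}
    if len(dims) != 1:
        raise ValueError(f"trajectories have mixed matrix dims: {dims}")
    current = list(trajs)
    pop_mean = None
    for _ in range(max(1, n_passes)):
        subject_means = [frechet_mean(t.matrices, metric) for t in current]
        pop_mean = frechet_mean(subject_means, metric)
        aligned = []
        for t, m in zip(current, subject_means):
            E = transport_operator(m, pop_mean)
            mats = np.stack([_symmetrize(E @ X @ E.T) for X in t.matrices])
            aligned.append(Trajectory(mats, t.times, t.subject_id))
        current = aligned
    return current, pop_mean
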