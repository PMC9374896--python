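"""Mean-shift recurrence on the SPD manifold and mode grouping.

Each window's learned representation is a small SPD matrix; windows that
belong to the same brain state should collapse onto a common mode.  The
recurrence alternates, for ``E`` layers:

1. the mean-shift vector ``Z_t`` — the Gaussian-kernel weighted average of
   all log-representations minus the current one, computed in the
   log-Euclidean chart where the manifold is flat;
2. the exponential-map update ``V_t <- exp(log V_t + Z_t)``.

Because consecutive exp/log pairs cancel in that chart, the whole
recurrence reduces to repeated kernel-weighted averaging of log-matrices
(:func:`ms_layer_logs`), which is what the training loop differentiates
through.  After the last layer the stratified points are grouped by
single-linkage under the geodesic distance, yielding one integer state
label per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .riemann import (
    Trajectory,
    frechet_mean,
    pairwise_geodesic,
    spd_expm,
    spd_logm,
)

#: initial kernel bandwidth of every mean-shift layer
DEFAULT_SIGMA = 0.5
#: default number of mean-shift layers E
DEFAULT_N_LAYERS = 5
#: grouping threshold as a fraction of the median pairwise geodesic distance
DEFAULT_TOL_FRACTION = 0.1


@dataclass
class MSRNNParams:
    """Per-layer kernel bandwidths ``sigma_e`` of the mean-shift recurrence."""

    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.sigmas.ndim != 1 or np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be a 1-D array of positive bandwidths")

    @classmethod
    def create(cls, n_layers: int = DEFAULT_N_LAYERS,
               sigma: float = DEFAULT_SIGMA) -> "MSRNNParams":
        return cls(sigmas=np.full(n_layers, sigma))

    @property
    def n_layers(self) -> int:
        return len(self.sigmas)


@dataclass
class StateLabeling:
    """Per-window state labels with the modes they index.

    ``labels[t]`` is an integer in ``[0, Q_detected)``; ``modes[q]`` is the
    Fréchet mean of the stratified representations assigned to state ``q``.
    """

    labels: np.ndarray
    modes: list[np.ndarray]
    Q_detected: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.Q_detected != len(self.modes):
            raise ValueError("Q_detected must equal the number of modes")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= self.Q_detected):
            raise ValueError("labels must index existing modes")

    def save(self, path, times: np.ndarray | None = None) -> None:
        """Two-column text: window-center time index, state label."""
        t = np.arange(len(self.labels)) if times is None else np.asarray(times)
        np.savetxt(path, np.column_stack([t, self.labels]), fmt="%d",
                   delimiter="\t", header="time\tstate", comments="")


# ---------------------------------------------------------------------------
# single-matrix operations (spec-level API)
# ---------------------------------------------------------------------------

def ms_vector(t: int, traj: Trajectory, sigma: float) -> np.ndarray:
    """Mean-shift vector for window ``t``: points from ``log V_t`` to the
    kernel-weighted average of all log-representations.

    ``Z_t = sum_s k(g_ts) log V_s / sum_s k(g_ts) - log V_t`` with the
    Gaussian kernel ``k(g) = exp(-g^2 / 2 sigma^2)`` on the geodesic
    distance.  Zero when all points coincide.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    logs = traj.logs()
    return _ms_vectors_from_logs(logs, sigma)[t]


def _ms_vectors_from_logs(logs: np.ndarray, sigma: float) -> np.ndarray:
    g = pairwise_geodesic(logs)
    K = np.exp(-(g ** 2) / (2.0 * sigma ** 2))
    A = K / K.sum(axis=1, keepdims=True)
    flat = logs.reshape(len(logs), -1)
    return (A @ flat).reshape(logs.shape) - logs


def ms_apply(V: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Exponential-map update ``exp(log V + Z)``; a zero shift is a fixed point."""
    if V.shape != Z.shape:
        raise ValueError(f"shape mismatch {V.shape} vs {Z.shape}")
    return spd_expm(spd_logm(V) + Z)


# ---------------------------------------------------------------------------
# the recurrence
# ---------------------------------------------------------------------------

def ms_layer_logs(logs: np.ndarray, sigma: float) -> np.ndarray:
    """One synchronous mean-shift layer in the log chart.

    Every point moves to the kernel-weighted average of all points
    (including itself); all shift vectors are computed before any point
    moves.
    """
    return logs + _ms_vectors_from_logs(logs, sigma)


def msrnn_forward(params: MSRNNParams, traj: Trajectory) -> Trajectory:
    """Run all ``E`` mean-shift layers; returns the stratified trajectory."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    logs = traj.logs()
    for sigma in params.sigmas:
        logs = ms_layer_logs(logs, sigma)
    mats = np.stack([spd_expm(L) for L in logs])
    return Trajectory(mats, traj.times, traj.subject_id)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def default_grouping_tol(g: np.ndarray) -> float:
    """Scale-free grouping threshold: ``0.1 x`` median pairwise distance."""
    off = g[np.triu_indices_from(g, k=1)]
    med = float(np.median(off)) if len(off) else 0.0
    return DEFAULT_TOL_FRACTION * med if med > 0 else 1e-12


def group_modes(stratified: Trajectory, tol: float | None = None) -> StateLabeling:
    """Group stratified representations into modes by single linkage.

    Two windows share a state when they are connected by a chain of
    geodesic steps each shorter than ``tol`` (single-linkage reachability).
    ``tol=None`` uses :func:`default_grouping_tol`.  Labels are renumbered
    in order of first appearance; each mode is the log-Euclidean Fréchet
    mean of its members.
    """
    logs = stratified.logs()
    T = len(logs)
    if T == 1:
        return StateLabeling(np.zeros(1, dtype=int),
                             [stratified.matrices[0]], 1)
    g = pairwise_geodesic(logs)
    if tol is None:
        tol = default_grouping_tol(g)
    if tol <= 0:
        raise ValueError("tol must be positive")
    Z = sch.linkage(squareform(g, checks=False), method="single")
    raw = sch.fcluster(Z, t=tol, criterion="distance")
    # renumber by first appearance so labels are deterministic in time order
    order: dict[int, int] = {}
    labels = np.empty(T, dtype=int)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    modes = [
        frechet_mean(stratified.matrices[labels == q])
        for q in range(len(order))
    ]
    return StateLabeling(labels, modes, len(order))
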