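"""Self-supervised training of the SPD network and mean-shift recurrence.

The objective is contrastive on pairs of windows: with geodesic distance
``g_tt'`` between stratified representations and similarity
``d_tt' = 1/(1 + g_tt')``, same-state pairs are pulled together by
``1 - d`` and different-state pairs are pushed below a margin by
``max(d - alpha, 0)``.  State labels come either from the mean-shift mode
grouping itself (self-supervised) or from a known task schedule.

Everything downstream of the network output lives in the log-Euclidean
chart, where the mean-shift layers are kernel-weighted averages of
log-matrices; the whole chain

    loss -> mean-shift layers -> matrix log -> ReEig -> BiMap

is differentiated analytically, and the BiMap weights are updated on the
Stiefel manifold (projection + QR retraction) while the kernel bandwidths
are trained through a softplus reparameterization that keeps them positive.
Gradients do not flow through the discrete grouping; labels are recomputed
every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .meanshift import (
    MSRNNParams,
    StateLabeling,
    default_grouping_tol,
    group_modes,
)
from .network import SPDNetModel, logm_backward, stiefel_step
from .riemann import Trajectory, pairwise_geodesic, spd_expm

#: above this many windows the pair sum is subsampled
PAIR_SUBSAMPLE_THRESHOLD = 400
#: number of ordered pairs drawn per epoch when subsampling
PAIR_SUBSAMPLE_SIZE = 50_000


@dataclass
class LossConfig:
    """Hyperparameters of the self-supervised objective.

    ``alpha`` is the margin on the similarity of negative pairs (in (0, 1]);
    ``label_source`` selects self-supervised mode grouping or a known task
    schedule; ``lr`` drives both the Stiefel steps and the bandwidth update.
    """

    alpha: float = 0.5
    label_source: Literal["ms_grouping", "known_schedule"] = "ms_grouping"
    lr: float = 0.01
    epochs: int = 20
    seed: int = 0
    grouping_tol: float | None = None
    grad_clip: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.lr <= 0 or self.epochs < 0:
            raise ValueError("lr must be positive and epochs non-negative")
        if self.grad_clip is not None and self.grad_clip <= 0:
            raise ValueError("grad_clip must be positive (or None)")


def pairwise_similarity(g: float | np.ndarray) -> float | np.ndarray:
    """Similarity ``d = 1 / (1 + g)`` of a geodesic distance; 1 at g = 0."""
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr < 0):
        raise ValueError("geodesic distance must be non-negative")
    out = 1.0 / (1.0 + g_arr)
    return float(out) if np.isscalar(g) or g_arr.ndim == 0 else out


def contrastive_loss(traj: Trajectory, labels: StateLabeling | np.ndarray,
                     alpha: float = 0.5) -> float:
    """Contrastive loss over all ordered pairs ``(t, t')``, ``t != t'``.

    Same label: ``1 - d_tt'``; different label: ``max(d_tt' - alpha, 0)``.
    """
    y = labels.labels if isinstance(labels, StateLabeling) else np.asarray(labels)
    if len(y) != len(traj):
        raise ValueError("labels length must match trajectory length")
    g = pairwise_geodesic(traj.logs())
    loss, _, _ = _pair_loss_and_grad(g, y, alpha, reduce="sum")
    return loss


# ---------------------------------------------------------------------------
# analytic pieces
# ---------------------------------------------------------------------------

def _pair_loss_and_grad(
    g: np.ndarray, y: np.ndarray, alpha: float, *,
    reduce: str = "sum",
    pair_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, int]:
    """Loss and its derivative w.r.t. each pairwise distance.

    Returns ``(loss, dloss/dg matrix, n_pairs)``; the default ``'sum'``
    matches the pair-sum definition of the objective, ``'mean'`` divides by
    the number of contributing ordered pairs.
    """
    T = len(y)
    d = 1.0 / (1.0 + g)
    same = (y[:, None] == y[None, :])
    off = ~np.eye(T, dtype=bool)
    if pair_mask is not None:
        off = off & pair_mask
    pos = same & off
    neg = (~same) & off
    viol = neg & (d > alpha)
    loss = float(np.sum(1.0 - d[pos]) + np.sum(d[viol] - alpha))
    # d(loss)/dg: positive pairs  d^2 ; violating negative pairs  -d^2
    dg = np.zeros_like(g)
    dg[pos] = d[pos] ** 2
    dg[viol] = -(d[viol] ** 2)
    n_pairs = int(off.sum())
    if reduce == "mean" and n_pairs > 0:
        loss /= n_pairs
        dg /= n_pairs
    return loss, dg, n_pairs


def _grad_logs_from_pair_grad(logs_flat: np.ndarray, g: np.ndarray,
                              dg: np.ndarray) -> np.ndarray:
    """Chain ``dloss/dg`` into gradients w.r.t. the flattened log-matrices.

    ``dg_tt'/dL_t = (L_t - L_t')/g_tt'`` (zero at coincident pairs, which is
    the correct subgradient since those pairs sit at the loss minimum).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(g > 0, dg / g, 0.0)
    coef = coef + coef.T  # ordered pairs (t,t') and (t',t)
    row = coef.sum(axis=1)
    return row[:, None] * logs_flat - coef @ logs_flat


def _ms_layer_forward_cached(logs_flat: np.ndarray, sigma: float):
    """One mean-shift layer on flattened logs, with backward cache."""
    sq = np.sum(logs_flat ** 2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * logs_flat @ logs_flat.T
    np.maximum(D, 0.0, out=D)
    W = np.exp(-D / (2.0 * sigma ** 2))
    r = W.sum(axis=1)
    A = W / r[:, None]
    out = A @ logs_flat
    return out, (logs_flat, D, W, r, A, out, sigma)


def _ms_layer_backward(cache, grad_out: np.ndarray) -> tuple[np.ndarray, float]:
    """Backward through one mean-shift layer.

    Returns the gradient w.r.t. the layer input and w.r.t. ``sigma``.
    """
    L, D, W, r, A, O, sigma = cache
    # direct dependence through the averaging weights' rows
    grad_L = A.T @ grad_out
    # dependence through the kernel weights w_ts
    #   dl/dw_ts = <grad_out_t, L_s - O_t> / r_t
    B = (grad_out @ L.T - np.sum(grad_out * O, axis=1)[:, None]) / r[:, None]
    C = B * W * (-1.0 / (2.0 * sigma ** 2))  # dl/dD_ts
    S = C + C.T
    grad_L += 2.0 * (S.sum(axis=1)[:, None] * L - S @ L)
    grad_sigma = float(np.sum(B * W * D) / sigma ** 3)
    return grad_L, grad_sigma


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    # inverse of log(1 + e^x); stable for y not tiny
    return y + np.log(-np.expm1(-y))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _forward_subject(model: SPDNetModel, sigmas: np.ndarray,
                     traj: Trajectory):
    """Network + mean-shift forward for one subject, keeping backward caches."""
    T = len(traj)
    P = model.out_dim
    caches = []
    V_eigs = []
    logs = np.empty((T, P, P))
    for t, X in enumerate(traj.matrices):
        cache: list = []
        V = model.forward_one(X, cache=cache)
        w, U = np.linalg.eigh(V)
        logs[t] = (U * np.log(w)) @ U.T
        caches.append(cache)
        V_eigs.append((w, U))

    flat = logs.reshape(T, -1)
    layer_caches = []
    for sigma in sigmas:
        flat, c = _ms_layer_forward_cached(flat, sigma)
        layer_caches.append(c)
    return flat, caches, V_eigs, layer_caches


def _backward_subject(
    model: SPDNetModel,
    sigmas: np.ndarray,
    fwd,
    y: np.ndarray,
    alpha: float,
    rng: np.random.Generator | None,
    grads_W: list[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Loss, weight-gradient accumulation and sigma gradients for one subject."""
    flat, caches, V_eigs, layer_caches = fwd
    T = flat.shape[0]
    P = model.out_dim
    strat_logs = flat.reshape(T, P, P)

    pair_mask = None
    if T > PAIR_SUBSAMPLE_THRESHOLD and rng is not None:
        pair_mask = np.zeros((T, T), dtype=bool)
        idx = rng.integers(0, T, size=(PAIR_SUBSAMPLE_SIZE, 2))
        pair_mask[idx[:, 0], idx[:, 1]] = True
        pair_mask |= pair_mask.T

    g = pairwise_geodesic(strat_logs)
    loss, dg, _ = _pair_loss_and_grad(g, y, alpha, pair_mask=pair_mask)
    grad_flat = _grad_logs_from_pair_grad(flat, g, dg)

    grad_sigmas = np.zeros_like(sigmas)
    for e in range(len(sigmas) - 1, -1, -1):
        grad_flat, gs = _ms_layer_backward(layer_caches[e], grad_flat)
        grad_sigmas[e] = gs

    for t in range(T):
        w, U = V_eigs[t]
        G = logm_backward(w, U, grad_flat[t].reshape(P, P))
        model.backward_one(caches[t], G, grads_W)
    return loss, grad_sigmas


def train(
    model: SPDNetModel,
    ms: MSRNNParams,
    data: Sequence[Trajectory],
    cfg: LossConfig,
    schedules: Sequence[np.ndarray] | None = None,
) -> tuple[SPDNetModel, MSRNNParams, list[float]]:
    """Jointly optimize the network weights and the mean-shift bandwidths.

    Per epoch and subject: forward through the network and the mean-shift
    recurrence, derive labels (mode grouping, or the provided ``schedules``
    when ``cfg.label_source == 'known_schedule'``), evaluate the contrastive
    loss on the stratified representations, and take one Riemannian step on
    the weights plus a gradient step on the (softplus-parameterized)
    bandwidths.  Returns the trained model, bandwidths, and the per-epoch
    mean loss history.  Deterministic for a fixed ``cfg.seed``.
    """
    if cfg.label_source == "known_schedule":
        if schedules is None or len(schedules) != len(data):
            raise ValueError("known_schedule requires one schedule per trajectory")
        for traj, y in zip(data, schedules):
            if len(y) != len(traj):
                raise ValueError("schedule length must match trajectory length")
    rng = np.random.default_rng(cfg.seed)
    rho = _softplus_inv(ms.sigmas.copy())
    history: list[float] = []
    for _ in range(cfg.epochs):
        sigmas = _softplus(rho)
        grads_W = model.zero_grads()
        grad_rho = np.zeros_like(rho)
        epoch_loss = 0.0
        for i, traj in enumerate(data):
            fwd = _forward_subject(model, sigmas, traj)
            if cfg.label_source == "known_schedule":
                y = np.asarray(schedules[i])
            else:
                # labels come from grouping the stratified output (stop-grad)
                P = model.out_dim
                strat = fwd[0].reshape(len(traj), P, P)
                y = _labels_from_logs(strat, cfg.grouping_tol)
            loss, gsig = _backward_subject(
                model, sigmas, fwd, y, cfg.alpha, rng, grads_W)
            grad_rho += gsig * _sigmoid(rho)
            epoch_loss += loss
        n = len(data)
        # clip gradient norms: the pair-sum objective scales like T^2, so
        # raw steps at the nominal learning rate would leave the region
        # where the eigendecompositions are well conditioned
        grads = [_clip_norm(gw / n, cfg.grad_clip) for gw in grads_W]
        model = stiefel_step(model, grads, cfg.lr)
        rho = rho - cfg.lr * _clip_norm(grad_rho / n, cfg.grad_clip)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite loss {epoch_loss} at epoch {len(history)}")
        history.append(epoch_loss / n)
    return model, MSRNNParams(_softplus(rho)), history


def _clip_norm(G: np.ndarray, clip: float | None) -> np.ndarray:
    if clip is None:
        return G
    norm = float(np.linalg.norm(G))
    return G * (clip / norm) if norm > clip else G


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _labels_from_logs(strat_logs: np.ndarray, tol: float | None) -> np.ndarray:
    mats = np.stack([spd_expm(L) for L in strat_logs])
    traj = Trajectory(mats, np.arange(len(mats)))
    return group_modes(traj, tol).labels
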