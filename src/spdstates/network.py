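"""Geometric feature-learning network on the SPD manifold.

The network is an alternating stack of two layer types that map SPD
matrices to smaller SPD matrices while staying on the manifold:

* **BiMap** — a bilinear positive map ``X -> W X W^T`` with row
  semi-orthogonal ``W`` (``W W^T = I``), the manifold analogue of a dense
  layer; it reduces the matrix dimension while preserving positive
  definiteness.
* **ReEig** — eigenvalue rectification ``U max(eps*I, Lambda) U^T``, the
  SPD analogue of ReLU: it floors the spectrum at ``eps`` and introduces
  the nonlinearity.

Training is Riemannian: Euclidean gradients of the BiMap weights are
projected onto the tangent space of the Stiefel manifold and the update is
retracted back by a QR-based row re-orthogonalization, so ``W W^T = I``
holds after every step.  Gradients through the eigendecomposition (ReEig,
and the matrix log used downstream) use the Daleckii-Krein / Loewner-matrix
formulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .riemann import Trajectory, _symmetrize

#: spectrum floor for ReEig layers
DEFAULT_EPSILON = 1e-4
#: minimum eigenvalue gap before duplicate eigenvalues are perturbed
_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

@dataclass
class BiMapLayer:
    """Bilinear map ``X -> W X W^T`` with row semi-orthogonal ``W``."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] > self.W.shape[1]:
            raise ValueError(f"W must be rows <= cols, got {self.W.shape}")

    @property
    def out_dim(self) -> int:
        return self.W.shape[0]

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    def orthogonality_defect(self) -> float:
        """``max |W W^T - I|`` — zero on the Stiefel manifold."""
        k = self.W.shape[0]
        return float(np.abs(self.W @ self.W.T - np.eye(k)).max())


@dataclass
class ReEigLayer:
    """Eigenvalue rectification with threshold ``epsilon``."""

    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def bimap_forward(layer: BiMapLayer, X: np.ndarray) -> np.ndarray:
    """Apply the bilinear positive map ``W X W^T``."""
    X = np.asarray(X, dtype=float)
    if X.shape != (layer.in_dim, layer.in_dim):
        raise ValueError(
            f"input dim {X.shape} does not match layer in_dim {layer.in_dim}"
        )
    return _symmetrize(layer.W @ X @ layer.W.T)


def reeig_forward(layer: ReEigLayer, X: np.ndarray) -> np.ndarray:
    """Rectify the spectrum: ``U max(eps*I, Lambda) U^T``.  Idempotent."""
    X = _symmetrize(np.asarray(X, dtype=float))
    w, U = np.linalg.eigh(X)
    return _symmetrize((U * np.maximum(w, layer.epsilon)) @ U.T)


def init_semiorthogonal(rows: int, cols: int, seed: int) -> BiMapLayer:
    """Random row semi-orthogonal ``W`` (rows x cols), deterministic per seed.

    Orthonormalizes a seeded Gaussian draw by QR; column signs are fixed by
    the sign of R's diagonal so the result is unique and reproducible.
    """
    if rows > cols:
        raise ValueError(f"rows ({rows}) must not exceed cols ({cols})")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((cols, rows))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))
    return BiMapLayer(W=Q.T)


def _retract_rows(W: np.ndarray) -> np.ndarray:
    """QR-based retraction: re-orthonormalize the rows of ``W``."""
    Q, R = np.linalg.qr(W.T)
    Q = Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))
    return Q.T


# ---------------------------------------------------------------------------
# eigen-gradients (Daleckii-Krein / Loewner)
# ---------------------------------------------------------------------------

def _loewner(w: np.ndarray, f, fprime) -> np.ndarray:
    """Loewner matrix ``K_ij = (f(w_i)-f(w_j))/(w_i-w_j)``, ``K_ii = f'(w_i)``.

    Duplicate eigenvalues are perturbed by ``1e-12`` before forming the
    divided differences, per the usual tie-breaking rule.
    """
    w = w.copy()
    for i in range(1, len(w)):
        if w[i] - w[i - 1] < _TIE_EPS:
            w[i] = w[i - 1] + _TIE_EPS
    fw = f(w)
    diff = w[:, None] - w[None, :]
    np.fill_diagonal(diff, 1.0)
    K = (fw[:, None] - fw[None, :]) / diff
    np.fill_diagonal(K, fprime(w))
    return K


def spectral_backward(w: np.ndarray, U: np.ndarray, grad_out: np.ndarray,
                      f, fprime) -> np.ndarray:
    """Gradient of ``X -> U f(Lambda) U^T`` at ``X = U diag(w) U^T``.

    ``grad_out`` is the (symmetric) upstream gradient with respect to the
    output; returns the gradient with respect to ``X``.
    """
    G = _symmetrize(grad_out)
    K = _loewner(w, f, fprime)
    return _symmetrize(U @ (K * (U.T @ G @ U)) @ U.T)


def reeig_backward(layer: ReEigLayer, w: np.ndarray, U: np.ndarray,
                   grad_out: np.ndarray) -> np.ndarray:
    eps = layer.epsilon
    return spectral_backward(
        w, U, grad_out,
        f=lambda v: np.maximum(v, eps),
        fprime=lambda v: (v > eps).astype(float),
    )


def logm_backward(w: np.ndarray, U: np.ndarray,
                  grad_out: np.ndarray) -> np.ndarray:
    return spectral_backward(w, U, grad_out, f=np.log, fprime=lambda v: 1.0 / v)


def bimap_backward(layer: BiMapLayer, X: np.ndarray,
                   grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``W X W^T`` w.r.t. ``X`` and ``W`` (symmetric ``X``)."""
    G = _symmetrize(grad_out)
    grad_X = _symmetrize(layer.W.T @ G @ layer.W)
    grad_W = 2.0 * G @ layer.W @ X
    return grad_X, grad_W


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class SPDNetModel:
    """Alternating BiMap/ReEig stack mapping Sym+_{N0} to Sym+_{NK}.

    ``dims`` is the strictly decreasing (or equal, for square layers)
    sequence of matrix dimensions ``[N0, ..., NK]``; one BiMap + ReEig pair
    per step.
    """

    bimaps: list[BiMapLayer]
    reeigs: list[ReEigLayer]

    def __post_init__(self) -> None:
        if len(self.bimaps) != len(self.reeigs):
            raise ValueError("need one ReEig per BiMap")
        for a, b in zip(self.bimaps, self.bimaps[1:]):
            if b.in_dim != a.out_dim:
                raise ValueError("layer dims do not chain")

    @classmethod
    def create(cls, dims: list[int], *, epsilon: float = DEFAULT_EPSILON,
               seed: int = 0) -> "SPDNetModel":
        if any(b > a for a, b in zip(dims, dims[1:])):
            raise ValueError(f"dims must be non-increasing, got {dims}")
        bimaps = [
            init_semiorthogonal(dims[k + 1], dims[k], seed=seed + k)
            for k in range(len(dims) - 1)
        ]
        reeigs = [ReEigLayer(epsilon) for _ in bimaps]
        return cls(bimaps=bimaps, reeigs=reeigs)

    @property
    def dims(self) -> list[int]:
        return [self.bimaps[0].in_dim] + [b.out_dim for b in self.bimaps]

    @property
    def out_dim(self) -> int:
        return self.bimaps[-1].out_dim if self.bimaps else 0

    # -- forward ------------------------------------------------------------

    def forward_one(self, X: np.ndarray, *, cache: list | None = None) -> np.ndarray:
        """Push one SPD matrix through the stack.

        When ``cache`` is a list, per-layer intermediates (inputs and
        eigendecompositions) are appended for the backward pass.
        """
        for bi, re in zip(self.bimaps, self.reeigs):
            Xb = bimap_forward(bi, X)
            w, U = np.linalg.eigh(Xb)
            Xr = _symmetrize((U * np.maximum(w, re.epsilon)) @ U.T)
            if cache is not None:
                cache.append((X, w, U))
            X = Xr
        return X

    def backward_one(self, cache: list, grad_out: np.ndarray,
                     grads_W: list[np.ndarray]) -> np.ndarray:
        """Backpropagate through the stack for one matrix.

        ``cache`` is the list filled by :meth:`forward_one`; ``grads_W``
        (one array per BiMap, same shapes as the weights) is accumulated
        in place.  Returns the gradient w.r.t. the input matrix.
        """
        G = grad_out
        for k in range(len(self.bimaps) - 1, -1, -1):
            X_in, w, U = cache[k]
            G = reeig_backward(self.reeigs[k], w, U, G)
            Xb_in = X_in  # input to the bimap at layer k
            G, gW = bimap_backward(self.bimaps[k], Xb_in, G)
            grads_W[k] += gW
        return G

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(b.W) for b in self.bimaps]

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint: JSON manifest + one tab-delimited weight file per layer."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "dims": self.dims,
            "epsilons": [r.epsilon for r in self.reeigs],
            "weights": [f"W{k}.tsv" for k in range(len(self.bimaps))],
        }
        (d / "model.json").write_text(json.dumps(manifest, indent=2))
        for k, b in enumerate(self.bimaps):
            np.savetxt(d / f"W{k}.tsv", b.W, delimiter="\t")

    @classmethod
    def load(cls, directory) -> "SPDNetModel":
        d = Path(directory)
        manifest = json.loads((d / "model.json").read_text())
        bimaps = [
            BiMapLayer(np.atleast_2d(np.loadtxt(d / name, delimiter="\t")))
            for name in manifest["weights"]
        ]
        reeigs = [ReEigLayer(e) for e in manifest["epsilons"]]
        return cls(bimaps=bimaps, reeigs=reeigs)


def spdnet_forward(model: SPDNetModel, traj: Trajectory) -> Trajectory:
    """Apply the network to every matrix of a trajectory independently."""
    if traj.dim != model.dims[0]:
        raise ValueError(
            f"trajectory dim {traj.dim} does not match model input {model.dims[0]}"
        )
    mats = np.stack([model.forward_one(X) for X in traj.matrices])
    return Trajectory(mats, traj.times, traj.subject_id)


def stiefel_step(model: SPDNetModel, euclidean_grads: list[np.ndarray],
                 lr: float) -> SPDNetModel:
    """One Riemannian gradient-descent step on every BiMap weight.

    The Euclidean gradient ``G`` is projected onto the Stiefel tangent space
    at ``W`` (``G - W G^T W`` for row semi-orthogonal ``W``), a step of size
    ``lr`` is taken, and the result is retracted by row re-orthogonalization.
    Returns a new model; ReEig layers are shared (stateless).
    """
    new_bimaps = []
    for layer, G in zip(model.bimaps, euclidean_grads):
        W = layer.W
        G_tan = G - W @ G.T @ W
        new_bimaps.append(BiMapLayer(_retract_rows(W - lr * G_tan)))
    return SPDNetModel(bimaps=new_bimaps, reeigs=model.reeigs)
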