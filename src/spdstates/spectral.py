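"""Spectral and shape signatures of learned brain-state representations.

Each brain state is summarized by the eigen-system of the Fréchet mean of
its low-dimensional SPD representations: the eigen-spectrum orders the
dominant geometric modes, the system energy (sum of squared eigenvalues,
i.e. the squared Frobenius norm) measures the overall magnitude of the
state, and per-mode perturbations of +/- one population standard deviation
delineate the variation each mode drives.  Perturbed low-dimensional
matrices are lifted back to region space by pseudo-inverting the network's
bilinear maps, giving eigenmode-specific connectivity circuits whose edges
can be attributed to labelled subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import SPDNetModel
from .riemann import _symmetrize, check_spd, frechet_mean

#: ridge added when lifting a rank-one component back to SPD
RANK_ONE_RIDGE = 1e-8
#: fraction of strongest |edges| kept when thresholding a circuit
DEFAULT_EDGE_FRACTION = 0.05


@dataclass
class EigenSpectrum:
    """Descending eigendecomposition of an SPD matrix.

    ``eigenvalues`` are sorted descending and strictly positive;
    ``eigenvectors`` holds the matching orthonormal columns, each with its
    first nonzero component made positive so the decomposition is unique.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be descending")
        if np.any(self.eigenvalues <= 0):
            raise ValueError("eigenvalues must be positive")

    def reconstruct(self) -> np.ndarray:
        U, lam = self.eigenvectors, self.eigenvalues
        return _symmetrize((U * lam) @ U.T)


def eigen_spectrum(S: np.ndarray) -> EigenSpectrum:
    """Descending eigendecomposition (equals the SVD for an SPD matrix)."""
    S = check_spd(S, name="eigen_spectrum input")
    w, U = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    for i in range(U.shape[1]):
        nz = np.flatnonzero(np.abs(U[:, i]) > 1e-12)
        if len(nz) and U[nz[0], i] < 0:
            U[:, i] = -U[:, i]
    return EigenSpectrum(eigenvalues=w, eigenvectors=U)


def system_energy(spec: EigenSpectrum) -> float:
    """Energy of the state: sum of squared eigenvalues (= ||S||_F^2)."""
    return float(np.sum(spec.eigenvalues ** 2))


def energy_resampling(
    reps: Sequence[np.ndarray],
    frac: float = 0.70,
    n_iter: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Subsampling distribution of a state's system energy.

    Per iteration: draw ``ceil(frac * n)`` representations without
    replacement, take their Fréchet mean, and record its energy.  With
    ``frac = 1`` every iteration uses the full set, so the distribution is
    degenerate.  Deterministic per seed.
    """
    reps = [np.asarray(R, dtype=float) for R in reps]
    if len(reps) < 2:
        raise ValueError("need at least 2 representations per state")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = int(np.ceil(frac * len(reps)))
    energies = np.empty(n_iter)
    for i in range(n_iter):
        # sorted so the mean is insensitive to draw order (frac=1 exact)
        idx = np.sort(rng.choice(len(reps), size=k, replace=False))
        mean = frechet_mean([reps[j] for j in idx])
        energies[i] = system_energy(eigen_spectrum(mean))
    return energies


def eigenvalue_population_std(per_subject_means: Sequence[np.ndarray]) -> np.ndarray:
    """Perturbation scale delta: per-index std of eigenvalues across subjects."""
    spectra = np.stack([
        eigen_spectrum(S).eigenvalues for S in per_subject_means
    ])
    return spectra.std(axis=0)


def perturb_eigenmode(
    spec: EigenSpectrum, i: int, delta: float, sign: int = +1
) -> np.ndarray:
    """Isolate mode ``i`` and perturb its eigenvalue by ``sign * delta``.

    All other modes are nulled; the rank-one component
    ``(lambda_i + sign*delta) u_i u_i^T`` is lifted to SPD by a small ridge.
    A perturbation that would drive the eigenvalue non-positive is floored
    at ``1e-8`` with a warning.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    lam = spec.eigenvalues[i] + sign * delta
    if lam <= 0:
        import logging
        logging.getLogger("spdstates").warning(
            "perturbation drives eigenvalue %d to %.3e; flooring at 1e-8",
            i, lam,
        )
        lam = 1e-8
    u = spec.eigenvectors[:, i]
    P = lam * np.outer(u, u)
    return _symmetrize(P) + RANK_ONE_RIDGE * np.eye(len(u))


def composite_bimap(model: SPDNetModel) -> np.ndarray:
    """Composite bilinear map ``W = W_K ... W_1`` (ReEig layers skipped)."""
    W = model.bimaps[0].W
    for layer in model.bimaps[1:]:
        W = layer.W @ W
    return W


def reconstruct_highdim(V: np.ndarray, model: SPDNetModel) -> np.ndarray:
    """Lift a low-dimensional representation back to region space.

    Inverts the bilinear (dimension-reducing) maps only:
    ``X_hat = W^+ V (W^+)^T`` with ``W^+`` the Moore-Penrose pseudoinverse
    of the composite map.  The result is symmetric PSD with rank at most
    the representation dimension, and re-projecting returns ``V`` exactly
    (``W X_hat W^T = V``) because the composed rows are orthonormal.
    """
    V = np.asarray(V, dtype=float)
    W = composite_bimap(model)
    if V.shape != (W.shape[0], W.shape[0]):
        raise ValueError(
            f"representation dim {V.shape} does not match model output "
            f"{W.shape[0]}")
    Wp = np.linalg.pinv(W)
    return _symmetrize(Wp @ V @ Wp.T)


# ---------------------------------------------------------------------------
# circuits and subnetwork attribution
# ---------------------------------------------------------------------------

def threshold_edges(circuit: np.ndarray, edge_frac: float) -> set[tuple[int, int]]:
    """Top ``edge_frac`` fraction of off-diagonal |entries| as an edge set.

    Edges are undirected pairs ``(i, j)`` with ``i < j``; at least one edge
    is always kept.
    """
    if not 0.0 < edge_frac <= 1.0:
        raise ValueError("edge_frac must be in (0, 1]")
    C = np.asarray(circuit, dtype=float)
    iu = np.triu_indices(C.shape[0], k=1)
    weights = np.abs(C[iu])
    if len(weights) == 0:
        raise ValueError("circuit has no off-diagonal entries")
    k = max(1, int(round(edge_frac * len(weights))))
    keep = np.argsort(weights)[::-1][:k]
    return {(int(iu[0][e]), int(iu[1][e])) for e in keep}


def common_circuit(c_minus: np.ndarray, c_plus: np.ndarray,
                   edge_frac: float = DEFAULT_EDGE_FRACTION) -> set[tuple[int, int]]:
    """Edges shared by the -delta and +delta perturbation circuits."""
    if np.shape(c_minus) != np.shape(c_plus):
        raise ValueError("circuits must share a shape")
    return threshold_edges(c_minus, edge_frac) & threshold_edges(c_plus, edge_frac)


class SubnetworkMap(dict):
    """Node index -> subnetwork name (DMN, CEN, VN, SMN, DAN, SN, BGN, UA...).

    A thin dict with text I/O; every node must be mapped exactly once.
    """

    @classmethod
    def from_file(cls, path) -> "SubnetworkMap":
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["node", "subnetwork"])
        m = cls()
        for _, row in df.iterrows():
            node = int(row["node"])
            if node in m:
                raise ValueError(f"node {node} mapped twice")
            m[node] = str(row["subnetwork"])
        return m

    def to_file(self, path) -> None:
        lines = [f"{n}\t{s}" for n, s in sorted(self.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def subnetwork_degree_share(
    circuit: np.ndarray,
    subnet_map: Mapping[int, str],
    edge_frac: float = DEFAULT_EDGE_FRACTION,
) -> dict[str, float]:
    """Percentage of connectivity degree carried by each subnetwork.

    Thresholds the circuit to its strongest ``edge_frac`` fraction of
    edges, counts incident edges per node, and reports each subnetwork's
    share of the total degree as a percentage (shares sum to 100).
    """
    edges = threshold_edges(circuit, edge_frac)
    if not edges:
        raise ValueError("empty edge set")
    n = np.shape(circuit)[0]
    degree = np.zeros(n)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    total = degree.sum()
    shares: dict[str, float] = {}
    for node, sub in subnet_map.items():
        shares[sub] = shares.get(sub, 0.0) + degree[node]
    return {s: 100.0 * v / total for s, v in shares.items()}


def state_spectra_table(
    state_reps: Mapping[object, Sequence[np.ndarray]],
) -> pd.DataFrame:
    """Per-state eigen-spectrum and energy of the Fréchet-mean representation.

    Rows: one per state; columns ``lambda_1..lambda_P`` descending plus
    ``energy``.  Means are geometric (Fréchet), not arithmetic.
    """
    rows = []
    for state, reps in state_reps.items():
        spec = eigen_spectrum(frechet_mean(reps))
        row = {"state": state}
        row.update({
            f"lambda_{i + 1}": v for i, v in enumerate(spec.eigenvalues)
        })
        row["energy"] = system_energy(spec)
        rows.append(row)
    return pd.DataFrame(rows)
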