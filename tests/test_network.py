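"""BiMap/ReEig layers: forwards, eigen-gradients, Stiefel optimization."""

import copy

import numpy as np
import pytest

from spdstates.network import (
    BiMapLayer,
    ReEigLayer,
    SPDNetModel,
    bimap_backward,
    bimap_forward,
    init_semiorthogonal,
    logm_backward,
    reeig_backward,
    reeig_forward,
    spdnet_forward,
    stiefel_step,
)
from spdstates.riemann import Trajectory, _symmetrize, check_spd, spd_logm
from .conftest import random_spd


def _fd_symmetric_grad(f, X, eps=1e-6):
    """Central finite differences of a scalar function of a symmetric matrix."""
    n = X.shape[0]
    G = np.zeros_like(X)
    for i in range(n):
        for j in range(n):
            Xp, Xm = X.copy(), X.copy()
            Xp[i, j] += eps / 2; Xp[j, i] += eps / 2
            Xm[i, j] -= eps / 2; Xm[j, i] -= eps / 2
            G[i, j] = (f(Xp) - f(Xm)) / (2 * eps)
    return _symmetrize(G)


class TestForward:
    def test_square_identity_bimap(self, spd_factory):
        X = spd_factory(3)
        assert np.allclose(bimap_forward(BiMapLayer(np.eye(3)), X), X)

    def test_row_selector_projects_diagonal(self):
        W = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        out = bimap_forward(BiMapLayer(W), np.diag([1.0, 2.0, 3.0]))
        assert np.allclose(out, np.diag([1.0, 2.0]))

    def test_bimap_matches_triple_product_and_stays_spd(self, rng):
        layer = init_semiorthogonal(2, 4, seed=7)
        X = random_spd(rng, 4)
        out = bimap_forward(layer, X)
        assert np.allclose(out, layer.W @ X @ layer.W.T)
        check_spd(out)

    def test_reeig_noop_above_threshold(self, spd_factory):
        X = spd_factory(4)  # eigenvalues well above 1e-4
        assert np.allclose(reeig_forward(ReEigLayer(1e-4), X), X, atol=1e-12)

    def test_reeig_rectifies_small_eigenvalues(self):
        out = reeig_forward(ReEigLayer(1e-4), np.diag([1.0, 1e-6]))
        assert np.allclose(np.sort(np.linalg.eigvalsh(out)), [1e-4, 1.0])

    def test_reeig_idempotent(self, rng):
        layer = ReEigLayer(0.3)
        for _ in range(50):
            X = random_spd(rng, 4, cond_scale=0.01)
            once = reeig_forward(layer, X)
            assert np.allclose(reeig_forward(layer, once), once, atol=1e-12)

    def test_trajectory_forward_preserves_length_and_spd(self, rng):
        model = SPDNetModel.create([6, 4, 3], seed=1)
        mats = np.stack([random_spd(rng, 6) for _ in range(5)])
        out = spdnet_forward(model, Trajectory(mats, np.arange(5)))
        assert len(out) == 5 and out.dim == 3
        out.validate()
        for M in out.matrices:
            assert np.linalg.eigvalsh(M)[0] >= model.reeigs[-1].epsilon * (1 - 1e-9)

    def test_square_orthogonal_model_preserves_spectrum(self, rng):
        model = SPDNetModel.create([4, 4], epsilon=1e-8, seed=3)
        X = random_spd(rng, 4)
        out = model.forward_one(X)
        assert np.allclose(np.linalg.eigvalsh(out), np.linalg.eigvalsh(X))


class TestInit:
    def test_square_init_is_orthogonal(self):
        layer = init_semiorthogonal(3, 3, seed=0)
        assert abs(abs(np.linalg.det(layer.W)) - 1.0) < 1e-10

    def test_rows_orthonormal(self):
        layer = init_semiorthogonal(2, 5, seed=4)
        assert layer.orthogonality_defect() < 1e-10

    def test_deterministic_per_seed(self):
        a = init_semiorthogonal(3, 6, seed=9)
        b = init_semiorthogonal(3, 6, seed=9)
        c = init_semiorthogonal(3, 6, seed=10)
        assert np.array_equal(a.W, b.W)
        assert not np.array_equal(a.W, c.W)

    def test_too_many_rows_raises(self):
        with pytest.raises(ValueError):
            init_semiorthogonal(5, 3, seed=0)


class TestGradients:
    """Analytic layer gradients vs central finite differences (< 1e-4)."""

    def test_bimap_gradients(self, rng):
        layer = init_semiorthogonal(2, 4, seed=11)
        X = random_spd(rng, 4)
        G = _symmetrize(rng.standard_normal((2, 2)))
        gX, gW = bimap_backward(layer, X, G)

        num_X = _fd_symmetric_grad(
            lambda M: np.sum(G * bimap_forward(layer, _symmetrize(M))), X)
        assert np.abs(gX - num_X).max() / np.abs(num_X).max() < 1e-6

        num_W = np.zeros_like(layer.W)
        eps = 1e-6
        for i in range(2):
            for j in range(4):
                Wp, Wm = layer.W.copy(), layer.W.copy()
                Wp[i, j] += eps; Wm[i, j] -= eps
                num_W[i, j] = (np.sum(G * (Wp @ X @ Wp.T))
                               - np.sum(G * (Wm @ X @ Wm.T))) / (2 * eps)
        assert np.abs(gW - num_W).max() / np.abs(num_W).max() < 1e-6

    def test_reeig_gradient_matches_fd(self, rng):
        """Eigenvalues straddle the threshold; eigenvalue gaps are wide."""
        layer = ReEigLayer(0.5)
        U = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        X = _symmetrize((U * np.array([0.1, 0.3, 1.2, 2.5])) @ U.T)
        G = _symmetrize(rng.standard_normal((4, 4)))
        w, V = np.linalg.eigh(X)
        gX = reeig_backward(layer, w, V, G)
        num = _fd_symmetric_grad(
            lambda M: np.sum(G * reeig_forward(layer, _symmetrize(M))), X)
        assert np.abs(gX - num).max() / np.abs(num).max() < 1e-4

    def test_logm_gradient_matches_fd(self, rng):
        X = random_spd(rng, 4)
        G = _symmetrize(rng.standard_normal((4, 4)))
        w, V = np.linalg.eigh(X)
        gX = logm_backward(w, V, G)
        num = _fd_symmetric_grad(
            lambda M: np.sum(G * spd_logm(_symmetrize(M))), X)
        assert np.abs(gX - num).max() / np.abs(num).max() < 1e-4

    def test_reeig_gradient_with_tied_eigenvalues_is_finite(self, rng):
        layer = ReEigLayer(0.5)
        X = np.eye(4) * 2.0  # fully degenerate spectrum
        w, V = np.linalg.eigh(X)
        G = _symmetrize(rng.standard_normal((4, 4)))
        assert np.all(np.isfinite(reeig_backward(layer, w, V, G)))


class TestStiefelStep:
    def test_zero_gradient_no_change(self):
        model = SPDNetModel.create([5, 3], seed=2)
        stepped = stiefel_step(model, model.zero_grads(), lr=0.1)
        assert np.allclose(stepped.bimaps[0].W, model.bimaps[0].W)

    def test_normal_gradient_keeps_manifold(self, rng):
        """A gradient of the form W S (S symmetric) is normal to the Stiefel
        manifold; after projection and retraction W W^T = I still holds."""
        model = SPDNetModel.create([4, 4], seed=5)
        S = _symmetrize(rng.standard_normal((4, 4)))
        G = model.bimaps[0].W @ S
        stepped = stiefel_step(model, [G], lr=0.05)
        assert stepped.bimaps[0].orthogonality_defect() < 1e-10

    def test_semiorthogonality_maintained_over_100_steps(self, rng):
        model = SPDNetModel.create([6, 4, 3], seed=8)
        for _ in range(100):
            grads = [rng.standard_normal(b.W.shape) for b in model.bimaps]
            model = stiefel_step(model, grads, lr=0.01)
        for b in model.bimaps:
            assert b.orthogonality_defect() < 1e-6


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = SPDNetModel.create([6, 4, 2], epsilon=3e-4, seed=1)
        model.save(tmp_path / "ckpt")
        back = SPDNetModel.load(tmp_path / "ckpt")
        assert back.dims == model.dims
        for a, b in zip(model.bimaps, back.bimaps):
            assert np.allclose(a.W, b.W)
        assert [r.epsilon for r in back.reeigs] == [3e-4] * 2
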