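"""SPD-manifold algebra: matrix functions, distances, means, transport."""

import numpy as np
import pytest

from spdstates.riemann import (
    SPDValidationError,
    Trajectory,
    align_trajectories,
    check_spd,
    frechet_mean,
    geodesic_distance,
    parallel_transport,
    spd_expm,
    spd_invsqrtm,
    spd_logm,
    spd_sqrtm,
    transport_operator,
)
from .conftest import random_spd


class TestMatrixFunctions:
    def test_log_of_identity_is_zero(self):
        assert np.allclose(spd_logm(np.eye(3)), 0.0)

    def test_log_of_diagonal(self):
        L = spd_logm(np.diag([np.e, np.e ** 2]))
        assert np.allclose(L, np.diag([1.0, 2.0]))

    def test_exp_of_zero_is_identity(self):
        assert np.allclose(spd_expm(np.zeros((3, 3))), np.eye(3))

    def test_exp_of_diagonal(self):
        assert np.allclose(spd_expm(np.diag([1.0, 2.0])),
                           np.diag([np.e, np.e ** 2]))

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_log_exp_round_trip(self, rng, n):
        for _ in range(10):
            S = random_spd(rng, n)
            back = spd_expm(spd_logm(S))
            assert np.linalg.norm(back - S) / np.linalg.norm(S) < 1e-8

    def test_logm_rejects_asymmetric(self):
        with pytest.raises(SPDValidationError):
            spd_logm(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_logm_rejects_indefinite(self):
        with pytest.raises(SPDValidationError):
            spd_logm(np.diag([1.0, -1.0]))

    def test_expm_rejects_asymmetric(self):
        with pytest.raises(SPDValidationError):
            spd_expm(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_sqrt_squares_back(self, spd_factory):
        S = spd_factory(5)
        R = spd_sqrtm(S)
        assert np.allclose(R @ R, S)
        assert np.allclose(spd_invsqrtm(S) @ R, np.eye(5), atol=1e-10)


class TestGeodesicDistance:
    def test_self_distance_zero(self, spd_factory):
        S = spd_factory(3)
        assert geodesic_distance(S, S) == 0.0

    def test_identity_to_scaled_identity(self):
        # ||log I - log(e I)||_F = ||I||_F = sqrt(2) in 2-D
        d = geodesic_distance(np.eye(2), np.e * np.eye(2))
        assert d == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_metric_axioms(self, rng):
        """Identity, symmetry, triangle inequality on random triples."""
        for _ in range(100):
            A, B, C = (random_spd(rng, 3) for _ in range(3))
            dab = geodesic_distance(A, B)
            assert dab >= 0
            assert dab == pytest.approx(geodesic_distance(B, A), rel=1e-10)
            assert dab <= (geodesic_distance(A, C)
                           + geodesic_distance(C, B) + 1e-10)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            geodesic_distance(np.eye(2), np.eye(3))

    def test_affine_invariant_matches_closed_form(self, spd_factory):
        A, B = spd_factory(4), spd_factory(4)
        isq = spd_invsqrtm(A)
        expected = np.linalg.norm(spd_logm(isq @ B @ isq.T), "fro")
        got = geodesic_distance(A, B, metric="affine_invariant")
        assert got == pytest.approx(expected, rel=1e-8)


class TestFrechetMean:
    def test_single_input_is_itself(self, spd_factory):
        S = spd_factory(3)
        assert np.allclose(frechet_mean([S]), S)

    def test_commuting_diagonal_geometric_mean(self):
        m = frechet_mean([np.diag([1.0, 1.0]), np.diag([np.e ** 2, np.e ** 2])])
        assert np.allclose(m, np.diag([np.e, np.e]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            frechet_mean([])

    def test_affine_invariant_two_point_midpoint(self, spd_factory):
        """The two-point Karcher mean is the closed-form geodesic midpoint
        A^{1/2} (A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}."""
        A, B = spd_factory(4), spd_factory(4)
        sq, isq = spd_sqrtm(A), spd_invsqrtm(A)
        midpoint = sq @ spd_sqrtm(isq @ B @ isq.T) @ sq
        got = frechet_mean([A, B], metric="affine_invariant")
        assert np.allclose(got, midpoint, rtol=1e-6, atol=1e-8)

    def test_log_euclidean_minimizes_along_geodesic(self, spd_factory):
        """The closed-form mean beats every point of a dense geodesic scan."""
        A, B = spd_factory(3), spd_factory(3)
        m = frechet_mean([A, B])
        la, lb = spd_logm(A), spd_logm(B)

        def cost(P):
            return geodesic_distance(P, A) ** 2 + geodesic_distance(P, B) ** 2

        best = cost(m)
        for t in np.linspace(0, 1, 101):
            P = spd_expm((1 - t) * la + t * lb)
            assert best <= cost(P) + 1e-10


class TestParallelTransport:
    def test_identity_when_means_coincide(self, spd_factory):
        S, M = spd_factory(3), spd_factory(3)
        assert np.allclose(parallel_transport(S, M, M), S, atol=1e-9)

    def test_source_mean_maps_to_target_mean(self, rng):
        for _ in range(10):
            src, tgt = random_spd(rng, 4), random_spd(rng, 4)
            moved = parallel_transport(src, src, tgt)
            assert np.allclose(moved, tgt, rtol=1e-8, atol=1e-8)

    def test_diagonal_case_by_hand(self):
        # E = (4I * I)^{1/2} = 2I, so diag(2,2) -> diag(8,8)
        out = parallel_transport(np.diag([2.0, 2.0]), np.eye(2),
                                 np.diag([4.0, 4.0]))
        assert np.allclose(out, np.diag([8.0, 8.0]))

    def test_operator_squares_to_ratio(self, spd_factory):
        src, tgt = spd_factory(4), spd_factory(4)
        E = transport_operator(src, tgt)
        assert np.allclose(E @ E, tgt @ np.linalg.inv(src), atol=1e-8)

    def test_congruence_preserves_affine_distance(self, rng):
        """Transport moves both matrices through the same congruence, so the
        affine-invariant distance between them is untouched."""
        for _ in range(20):
            A, B = random_spd(rng, 3), random_spd(rng, 3)
            src, tgt = random_spd(rng, 3), random_spd(rng, 3)
            d0 = geodesic_distance(A, B, metric="affine_invariant")
            d1 = geodesic_distance(
                parallel_transport(A, src, tgt),
                parallel_transport(B, src, tgt),
                metric="affine_invariant",
            )
            assert d1 == pytest.approx(d0, rel=1e-8, abs=1e-8)

    def test_rejects_non_pd(self):
        with pytest.raises(SPDValidationError):
            parallel_transport(np.eye(2), np.diag([1.0, -1.0]), np.eye(2))


class TestTrajectory:
    def test_times_must_increase(self):
        mats = np.stack([np.eye(2)] * 3)
        with pytest.raises(ValueError):
            Trajectory(mats, [0, 2, 1])

    def test_length_and_dim(self):
        t = Trajectory(np.stack([np.eye(3)] * 4), np.arange(4))
        assert len(t) == 4 and t.dim == 3


class TestAlignment:
    def test_constant_trajectories_align_to_population_mean(self, spd_factory):
        A, B = spd_factory(3), spd_factory(3)
        ta = Trajectory(np.stack([A] * 5), np.arange(5), "a")
        tb = Trajectory(np.stack([B] * 5), np.arange(5), "b")
        aligned, pop = align_trajectories([ta, tb])
        expected = frechet_mean([A, B])
        assert np.allclose(pop, expected)
        for t in aligned:
            for M in t.matrices:
                assert np.allclose(M, expected, rtol=1e-8, atol=1e-8)

    def test_post_alignment_subject_means_coincide(self, rng):
        """Under the affine-invariant metric the congruence is an isometry,
        so transported subject means land exactly on the population mean."""
        trajs = []
        for s in range(3):
            mats = np.stack([random_spd(rng, 3) for _ in range(6)])
            trajs.append(Trajectory(mats, np.arange(6), f"s{s}"))
        aligned, pop = align_trajectories(trajs, metric="affine_invariant")
        for t in aligned:
            m = frechet_mean(t.matrices, metric="affine_invariant")
            assert np.linalg.norm(m - pop) < 1e-6

    def test_single_centered_trajectory_unchanged(self, rng):
        mats = np.stack([random_spd(rng, 3) for _ in range(5)])
        traj = Trajectory(mats, np.arange(5))
        aligned, pop = align_trajectories([traj])
        # its own mean is the population mean -> E = I
        assert np.allclose(aligned[0].matrices, mats, atol=1e-8)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            align_trajectories([])
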