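"""Geometry: angle/skeleton conversions, angular metrics, flips, eigenworms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilpose import geometry as g

angle_arrays = st.lists(
    st.floats(-np.pi + 1e-9, np.pi), min_size=2, max_size=30
).map(lambda xs: np.array(xs))


class TestSkeletonConversions:
    def test_zero_angles_are_collinear_along_x(self):
        sk = g.angles_to_skeleton(np.zeros(3), ds=1.0)
        np.testing.assert_allclose(sk.points, [(0, 0), (1, 0), (2, 0), (3, 0)])

    def test_quarter_turn_tangents_move_along_y(self):
        sk = g.angles_to_skeleton(np.array([np.pi / 2, np.pi / 2]), ds=2.0)
        np.testing.assert_allclose(sk.points, [(0, 0), (0, 2), (0, 4)], atol=1e-12)

    def test_matches_cumulative_sum_oracle(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 10)
        ds, origin = 2.5, (3.0, -1.0)
        sk = g.angles_to_skeleton(theta, ds, origin)
        # independent oracle: explicit cumulative summation
        expected = [np.asarray(origin, float)]
        for th in theta:
            expected.append(expected[-1] + ds * np.array([np.cos(th), np.sin(th)]))
        np.testing.assert_allclose(sk.points, expected, atol=1e-12)
        assert sk.n_points == theta.size + 1

    def test_round_trip_identity(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 50)
        sk = g.angles_to_skeleton(theta, ds=1.0)
        np.testing.assert_allclose(g.skeleton_to_angles(sk), theta, atol=1e-9)

    def test_collinear_points_give_constant_angle(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(g.skeleton_to_angles(pts), np.pi / 4)

    def test_circle_arc_recovers_analytic_tangents(self):
        # points on a circle of radius r: tangent angle = point angle + pi/2
        r, n = 50.0, 30
        phis = np.linspace(0.0, np.pi / 2, n)
        pts = r * np.column_stack([np.cos(phis), np.sin(phis)])
        angles = g.skeleton_to_angles(pts)
        mid = (phis[:-1] + phis[1:]) / 2.0
        np.testing.assert_allclose(angles, mid + np.pi / 2, atol=1e-6)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            g.angles_to_skeleton(np.zeros(3), ds=0.0)
        with pytest.raises(ValueError):
            g.skeleton_to_angles(np.array([[0, 0], [0, 0], [1, 1]], float))


class TestAngularMetrics:
    def test_wrap_diff_known_values(self):
        assert g.wrap_angle_diff(1.3, 1.3) == 0.0
        assert abs(g.wrap_angle_diff(np.pi, -np.pi)) < 1e-12
        # 0.1 - 6.2 + 2 pi
        assert g.wrap_angle_diff(0.1, 6.2) == pytest.approx(0.1 - 6.2 + 2 * np.pi, abs=1e-9)

    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    @settings(max_examples=200, deadline=None)
    def test_wrap_diff_range_and_antisymmetry(self, a, b):
        d = g.wrap_angle_diff(a, b)
        assert -np.pi <= d <= np.pi
        if abs(abs(d) - np.pi) > 1e-12:
            assert g.wrap_angle_diff(b, a) == pytest.approx(-d, abs=1e-12)

    def test_rmse_matches_brute_force(self, rng):
        t1 = rng.uniform(-np.pi, np.pi, 100)
        t2 = rng.uniform(-np.pi, np.pi, 100)
        brute = np.sqrt(
            np.mean([g.wrap_angle_diff(a, b) ** 2 for a, b in zip(t1, t2)])
        )
        assert g.rmse_angle_distance(t1, t2) == pytest.approx(brute, abs=1e-12)
        assert g.rmse_angle_distance(t1, t1) == 0.0
        assert g.rmse_angle_distance(t1, t2) == g.rmse_angle_distance(t2, t1)

    def test_rmse_of_pi_offset_is_pi(self, rng):
        t = rng.uniform(-np.pi, np.pi, 40)
        assert g.rmse_angle_distance(t, t + np.pi) == pytest.approx(np.pi, abs=1e-9)

    def test_mean_abs_constant_offset(self, rng):
        t = rng.uniform(-1.0, 1.0, 60)
        c = 0.7
        assert g.mean_abs_angle_distance(t, t + c) == pytest.approx(c, abs=1e-9)
        assert g.mean_abs_angle_distance(t, t) == 0.0
        t2 = rng.uniform(-np.pi, np.pi, 60)
        brute = np.mean([abs(g.wrap_angle_diff(a, b)) for a, b in zip(t, t2)])
        assert g.mean_abs_angle_distance(t, t2) == pytest.approx(brute, abs=1e-12)

    def test_pseudometric_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(-np.pi, np.pi, (3, 20))
            dab = g.rmse_angle_distance(a, b)
            dbc = g.rmse_angle_distance(b, c)
            dac = g.rmse_angle_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            g.rmse_angle_distance(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            g.mean_abs_angle_distance(np.zeros(3), np.zeros(4))


class TestFlip:
    def test_involution(self, rng):
        t = rng.uniform(-np.pi, np.pi, 100)
        np.testing.assert_allclose(
            g.wrap_angle_diff(g.flip_centerline(g.flip_centerline(t)), t), 0.0, atol=1e-12
        )

    def test_zero_angles_flip_to_pi(self):
        np.testing.assert_allclose(g.flip_centerline(np.zeros(2)), [np.pi, np.pi])

    def test_flipped_skeleton_traverses_same_curve_reversed(self, rng):
        t = rng.uniform(-np.pi, np.pi, 25)
        fwd = g.angles_to_skeleton(t, ds=1.0).points
        bwd = g.angles_to_skeleton(g.flip_centerline(t), ds=1.0).points
        # same point set tail->head, up to rigid translation
        delta = bwd - fwd[::-1]
        np.testing.assert_allclose(delta - delta[0], 0.0, atol=1e-9)

    def test_flip_preserves_rmse_distance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 30)
        b = rng.uniform(-np.pi, np.pi, 30)
        assert g.rmse_angle_distance(
            g.flip_centerline(a), g.flip_centerline(b)
        ) == pytest.approx(g.rmse_angle_distance(a, b), abs=1e-9)


class TestEigenBasis:
    def test_identical_shapes_project_to_zero(self):
        shape = np.linspace(-1, 1, 20)
        shapes = np.tile(shape, (10, 1))
        shapes += 1e-9 * np.random.default_rng(0).standard_normal(shapes.shape)
        basis = g.compute_eigenbasis(shapes, n_modes=1)
        np.testing.assert_allclose(basis.mean_angles, shape, atol=1e-6)
        assert abs(g.project_modes(shape, basis)).max() < 1e-6

    def test_recovers_planted_two_dim_subspace(self, rng):
        n = 40
        v1 = np.sin(np.linspace(0, 2 * np.pi, n))
        v1 /= np.linalg.norm(v1)
        v2 = np.cos(np.linspace(0, 2 * np.pi, n))
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        coeffs = rng.normal(0, [3.0, 1.5], size=(500, 2))
        shapes = coeffs[:, :1] * v1 + coeffs[:, 1:] * v2
        basis = g.compute_eigenbasis(shapes, n_modes=2)
        # subspace-angle check: projecting planted vectors onto the span
        # must preserve their norm
        proj = basis.components.T @ (basis.components @ np.stack([v1, v2]).T)
        np.testing.assert_allclose(
            np.linalg.norm(proj, axis=0), 1.0, atol=1e-8
        )
        assert basis.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_projection_and_reconstruction(self, rng):
        shapes = rng.standard_normal((200, 30))
        basis = g.compute_eigenbasis(shapes, n_modes=5)
        # mean maps to zero coefficients; planted component recovers itself
        np.testing.assert_allclose(g.project_modes(basis.mean_angles, basis), 0.0, atol=1e-9)
        c = basis.mean_angles + 3.0 * basis.components[1]
        np.testing.assert_allclose(
            g.project_modes(c, basis), [0, 3, 0, 0, 0], atol=1e-9
        )
        # round-trip error equals the orthogonal-complement norm (oracle)
        x = rng.standard_normal(30)
        recon = g.reconstruct_from_modes(g.project_modes(x, basis), basis)
        centered = x - basis.mean_angles
        residual_oracle = centered - basis.components.T @ (basis.components @ centered)
        assert np.linalg.norm(x - recon) == pytest.approx(
            np.linalg.norm(residual_oracle), abs=1e-9
        )

    def test_rank_errors(self, rng):
        shapes = np.outer(rng.standard_normal(10), np.ones(5))
        with pytest.raises(ValueError):
            g.compute_eigenbasis(shapes, n_modes=3)


class TestUnwrapBody:
    def test_unwrap_restores_smooth_coil(self):
        smooth = np.linspace(0.0, 3.5 * np.pi, 100)  # deep coil, > one turn
        wrapped = g.wrap_angle(smooth)
        np.testing.assert_allclose(g.unwrap_body(wrapped), smooth, atol=1e-9)
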