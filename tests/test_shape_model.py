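"""Point-distribution model: landmarking, PCA, plausibility constraint."""

import numpy as np
import pytest
from scipy import integrate, optimize

from aaaseg._exceptions import (
    DegenerateContourError,
    DegenerateModelError,
    InvalidInputError,
)
from aaaseg.geometry import PlanarContour
from aaaseg.shape_model import (
    N_LANDMARKS,
    N_SLICES,
    LandmarkShape,
    apply_shape_constraint,
    build_shape_model,
    chi2_threshold,
    constrain,
    landmark_contour_stack,
    pca_modes,
    place_landmarks,
    project,
    reconstruct,
    resample_contour_stack,
    straighten,
    unstraighten,
)


def circle(radius=1.0, center=(0.0, 0.0), z=0.0, n=4096):
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    return PlanarContour(pts, z=z)


def random_shape(rng, base_radius=12.0):
    pts = np.empty((N_SLICES, N_LANDMARKS, 3))
    th = np.pi / 2 + 2 * np.pi * np.arange(N_LANDMARKS) / N_LANDMARKS
    for i in range(N_SLICES):
        r = base_radius + rng.normal(0, 1.0, N_LANDMARKS).clip(-3, 3)
        c = rng.normal(0, 5.0, 2)
        pts[i, :, 0] = c[0] + r * np.cos(th)
        pts[i, :, 1] = c[1] + r * np.sin(th)
        pts[i, :, 2] = 6.0 * i
    return LandmarkShape(pts)


# ---------------------------------------------------------------------------
# contour stack resampling


class TestResampleContourStack:
    def test_equal_endpoints_give_identical_contours(self):
        stack = [circle(10, z=0.0), circle(10, z=12.0)]
        out = resample_contour_stack(stack, 19)
        assert len(out) == 19
        for c in out:
            r = np.linalg.norm(c.points, axis=1)
            # accuracy limited by the polygonal chord error of the input
            np.testing.assert_allclose(r, 10.0, atol=1e-5)

    def test_linear_radius_interpolation(self):
        out = resample_contour_stack([circle(10, z=0.0), circle(20, z=12.0)], 19)
        mid = out[9]  # 10th contour sits at z = 6
        assert mid.z == pytest.approx(6.0)
        r = np.linalg.norm(mid.points, axis=1)
        np.testing.assert_allclose(r, 15.0, atol=1e-5)

    def test_evenly_spaced_input_passes_through(self):
        rng = np.random.default_rng(3)
        stack = []
        for i in range(19):
            pert = 1.0 + 0.05 * np.sin(3 * np.linspace(0, 2 * np.pi, 64, endpoint=False))
            th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            r = 10 * pert
            stack.append(
                PlanarContour(np.column_stack([r * np.cos(th), r * np.sin(th)]), z=2.0 * i)
            )
        out = resample_contour_stack(stack, 19)
        for a, b in zip(stack, out):
            np.testing.assert_allclose(a.points, b.points, atol=1e-6)
            assert a.z == pytest.approx(b.z)

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            resample_contour_stack([circle(10)], 19)
        with pytest.raises(InvalidInputError):
            resample_contour_stack([circle(10, z=0.0), circle(12, z=0.0)], 19)


# ---------------------------------------------------------------------------
# landmark placement


class TestPlaceLandmarks:
    def test_unit_circle_equiangular_from_anterior(self):
        lm = place_landmarks(circle(1.0), 20)
        np.testing.assert_allclose(np.linalg.norm(lm, axis=1), 1.0, atol=1e-6)
        angles = np.degrees(np.arctan2(lm[:, 1], lm[:, 0]))
        expected = 90 + 18 * np.arange(20)
        diff = (angles - expected + 180) % 360 - 180  # compare modulo 360
        np.testing.assert_allclose(diff, 0.0, atol=1e-4)

    def test_ellipse_points_lie_on_ellipse(self):
        th = 2 * np.pi * np.arange(4096) / 4096
        ell = PlanarContour(np.column_stack([2 * np.cos(th), np.sin(th)]))
        lm = place_landmarks(ell, 20)
        np.testing.assert_allclose((lm[:, 0] / 2) ** 2 + lm[:, 1] ** 2, 1.0, atol=1e-5)

    def test_single_landmark_is_anterior_point(self):
        lm = place_landmarks(circle(1.0), 1)
        np.testing.assert_allclose(lm[0], [0.0, 1.0], atol=1e-6)

    def test_non_star_shaped_raises(self):
        # a thin "C" shape whose centroid lies outside the polygon
        pts = np.array(
            [[1, 0], [2, 0], [2, 2], [-2, 2], [-2, -2], [2, -2], [2, -1],
             [-1, -1], [-1, 1], [1, 1]],
            dtype=float,
        )
        with pytest.raises(DegenerateContourError):
            place_landmarks(PlanarContour(pts), 20, origin=np.array([5.0, 0.0]))


# ---------------------------------------------------------------------------
# straightening


class TestStraighten:
    def test_removes_known_offset(self, rng):
        shape = random_shape(rng)
        shape.points[5, :, 0] += 3.0
        shape.points[5, :, 1] -= 4.0
        before = shape.points[5].mean(axis=0)
        s = straighten(shape)
        np.testing.assert_allclose(s.points.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(s.slice_centroids[5], before, atol=1e-12)

    def test_round_trip_identity(self, rng):
        for _ in range(5):
            shape = random_shape(rng)
            back = unstraighten(straighten(shape))
            np.testing.assert_allclose(back.points, shape.points, atol=1e-9)

    def test_double_straighten_rejected(self, rng):
        s = straighten(random_shape(rng))
        with pytest.raises(InvalidInputError):
            straighten(s)


# ---------------------------------------------------------------------------
# PCA / model building


class TestBuildShapeModel:
    def test_identical_shapes_degenerate(self, rng):
        s = straighten(random_shape(rng))
        copies = [LandmarkShape(s.points.copy(), True, s.slice_centroids.copy())
                  for _ in range(5)]
        with pytest.raises(DegenerateModelError):
            build_shape_model(copies)

    def test_single_direction_gives_one_mode(self, rng):
        base = straighten(random_shape(rng))
        delta = rng.normal(0, 1, base.points.shape)
        delta -= delta.mean(axis=1, keepdims=True)  # keep slices centred
        a = LandmarkShape(base.points + delta, True, base.slice_centroids)
        b = LandmarkShape(base.points - delta, True, base.slice_centroids)
        model = build_shape_model([a, b], variability_fraction=0.5)
        assert model.c == 1
        model2 = build_shape_model([a, b], variability_fraction=1.0)
        assert model2.c == 1  # only one nonzero eigenvalue exists

    def test_mode_count_matches_cumulative_sum_oracle(self, training_shapes, shape_model):
        X = np.stack([s.flatten() for s in training_shapes])
        _, _, w, total = pca_modes(X)
        cum = np.cumsum(w) / total
        c = shape_model.c
        assert cum[c - 1] >= 0.95 - 1e-12
        if c > 1:
            assert cum[c - 2] < 0.95

    def test_eigenvectors_orthonormal_and_sorted(self, shape_model):
        V = shape_model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(shape_model.c), atol=1e-8)
        assert np.all(np.diff(shape_model.eigenvalues) <= 1e-12)
        assert np.all(shape_model.eigenvalues > 0)

    def test_pca_matches_direct_covariance_oracle(self, rng):
        # dual (Gram) path vs brute-force covariance eigendecomposition
        for _ in range(10):
            n, pts = 6, 12
            X = rng.normal(0, 2.0, (n, pts * 3))
            mean, V, w, total = pca_modes(X)
            S = np.cov(X, rowvar=False, ddof=1)
            w_ref = np.sort(np.linalg.eigvalsh(S))[::-1][: w.size]
            np.testing.assert_allclose(w, w_ref, rtol=1e-8, atol=1e-10)
            assert total == pytest.approx(np.trace(S))
            # eigenvectors diagonalize S on the retained subspace
            np.testing.assert_allclose(V.T @ S @ V, np.diag(w), atol=1e-8)

    def test_errors(self, rng):
        s = straighten(random_shape(rng))
        with pytest.raises(InvalidInputError):
            build_shape_model([s])
        with pytest.raises(InvalidInputError):
            build_shape_model([s, s], variability_fraction=1.5)


class TestChi2Threshold:
    def test_two_dof_closed_form(self):
        assert chi2_threshold(2, 0.95) == pytest.approx(-2 * np.log(0.05), rel=1e-12)

    def test_one_dof_against_quadrature_oracle(self):
        from scipy.special import gamma

        def pdf(x):
            return x ** (-0.5) * np.exp(-x / 2) / (np.sqrt(2) * gamma(0.5))

        def cdf(x):
            return integrate.quad(pdf, 0, x)[0]

        ref = optimize.brentq(lambda x: cdf(x) - 0.5, 1e-9, 10)
        assert chi2_threshold(1, 0.50) == pytest.approx(ref, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            chi2_threshold(15, 1.5)
        with pytest.raises(InvalidInputError):
            chi2_threshold(0, 0.9)


# ---------------------------------------------------------------------------
# projection / constraint


class TestProjectConstrain:
    def test_mean_projects_to_zero(self, shape_model):
        mean = LandmarkShape.from_flat(
            shape_model.mean_shape, True, np.zeros((N_SLICES, 3))
        )
        p = project(mean, shape_model)
        np.testing.assert_allclose(p.b, 0.0, atol=1e-9)
        assert p.d_m == pytest.approx(0.0, abs=1e-12)

    def test_unit_mahalanobis_by_construction(self, shape_model):
        x = shape_model.mean_shape + np.sqrt(shape_model.eigenvalues[0]) * (
            shape_model.eigenvectors[:, 0]
        )
        shape = LandmarkShape.from_flat(x, True, np.zeros((N_SLICES, 3)))
        p = project(shape, shape_model)
        assert p.d_m == pytest.approx(1.0, rel=1e-9)
        assert p.b[0] == pytest.approx(
            np.sqrt(shape_model.eigenvalues[0]), rel=1e-9
        )

    def test_projection_matches_lstsq_oracle(self, shape_model, rng):
        x = shape_model.mean_shape + rng.normal(0, 1.0, shape_model.mean_shape.size)
        x = LandmarkShape.from_flat(x, True, np.zeros((N_SLICES, 3)))
        # projecting requires zero slice centroids; recentre per slice
        pts = x.points - x.points.mean(axis=1, keepdims=True)
        x = LandmarkShape(pts, True, np.zeros((N_SLICES, 3)))
        p = project(x, shape_model)
        b_ref = np.linalg.lstsq(
            shape_model.eigenvectors,
            x.flatten() - shape_model.mean_shape,
            rcond=None,
        )[0]
        np.testing.assert_allclose(p.b, b_ref, atol=1e-8)

    def test_reconstruct_inverts_project_in_span(self, shape_model, rng):
        b = rng.normal(0, 1, shape_model.c) * np.sqrt(shape_model.eigenvalues)
        x = shape_model.mean_shape + shape_model.eigenvectors @ b
        shape = LandmarkShape.from_flat(x, True, np.zeros((N_SLICES, 3)))
        p = project(shape, shape_model)
        np.testing.assert_allclose(reconstruct(p, shape_model), x, atol=1e-8)

    def test_constrain_within_bound_unchanged(self, shape_model):
        from aaaseg.shape_model import ShapeParams

        p = ShapeParams(b=np.zeros(shape_model.c), d_m=0.0)
        q = constrain(p, shape_model)
        assert q.alpha == 1.0 and q.d_m == 0.0

    def test_constrain_quadratic_scaling(self, shape_model):
        from aaaseg.shape_model import ShapeParams

        lam = shape_model.eigenvalues
        # b chosen so D_m = 4 * M_t exactly
        b = np.sqrt(lam * 4 * shape_model.m_t / shape_model.c)
        p = ShapeParams(b=b, d_m=float(np.sum(b**2 / lam)))
        assert p.d_m == pytest.approx(4 * shape_model.m_t, rel=1e-12)
        q = constrain(p, shape_model)
        assert q.alpha == pytest.approx(0.5, rel=1e-12)
        assert q.d_m == pytest.approx(shape_model.m_t, abs=1e-9)

    def test_constrain_idempotent_and_on_shell(self, shape_model, rng):
        from aaaseg.shape_model import ShapeParams

        for _ in range(20):
            b = rng.normal(0, 5, shape_model.c) * np.sqrt(shape_model.eigenvalues)
            p = ShapeParams(b=b, d_m=float(np.sum(b**2 / shape_model.eigenvalues)))
            q = constrain(p, shape_model)
            if p.d_m > shape_model.m_t:
                assert q.d_m == pytest.approx(shape_model.m_t, abs=1e-9)
            r = constrain(q, shape_model)
            np.testing.assert_allclose(r.b, q.b, atol=1e-12)

    def test_constraint_coverage_matches_chi2(self, rng):
        # for b ~ N(0, diag(lambda)), P(D_m <= M_t(c, t)) -> t
        c, t, n = 5, 0.90, 10_000
        lam = np.sort(rng.uniform(0.5, 50.0, c))[::-1]
        b = rng.normal(0, 1, (n, c)) * np.sqrt(lam)
        d_m = np.sum(b**2 / lam, axis=1)
        frac = float(np.mean(d_m <= chi2_threshold(c, t)))
        sigma = np.sqrt(t * (1 - t) / n)
        assert abs(frac - t) <= 3 * sigma


# ---------------------------------------------------------------------------
# full constraint round trip


class TestApplyShapeConstraint:
    def test_mean_shape_with_centroids_unchanged(self, shape_model, rng):
        mean = shape_model.mean_shape.reshape(N_SLICES, N_LANDMARKS, 3)
        centroids = rng.normal(0, 10, (N_SLICES, 3))
        centroids[:, 2] = 6.0 * np.arange(N_SLICES)
        stack = mean + centroids[:, None, :]
        out = apply_shape_constraint(stack, shape_model)
        np.testing.assert_allclose(out, stack, atol=1e-6)

    def test_implausible_stack_lands_on_shell(self, shape_model, rng):
        lam, V = shape_model.eigenvalues, shape_model.eigenvectors
        b = 10.0 * np.sqrt(lam)  # D_m = 100 c >> M_t
        x = shape_model.mean_shape + V @ b
        stack = x.reshape(N_SLICES, N_LANDMARKS, 3) + np.array([30.0, 40.0, 0.0])
        out = apply_shape_constraint(stack, shape_model)
        s = straighten(LandmarkShape(out))
        p = project(s, shape_model)
        assert p.d_m == pytest.approx(shape_model.m_t, rel=1e-6)

    def test_centroids_preserved_exactly(self, shape_model, rng):
        stack = random_shape(rng).points
        out = apply_shape_constraint(stack, shape_model)
        np.testing.assert_allclose(
            out.mean(axis=1), stack.mean(axis=1), rtol=0, atol=1e-9
        )

    def test_z_resampling_path_preserves_centroids(self, shape_model, rng):
        th = np.pi / 2 + 2 * np.pi * np.arange(N_LANDMARKS) / N_LANDMARKS
        k = 30
        stack = np.empty((k, N_LANDMARKS, 3))
        for i in range(k):
            r = 14 + rng.normal(0, 0.5, N_LANDMARKS)
            stack[i, :, 0] = 40 + r * np.cos(th)
            stack[i, :, 1] = 40 + r * np.sin(th)
            stack[i, :, 2] = 3.8 * i
        out = apply_shape_constraint(stack, shape_model)
        assert out.shape == (k, N_LANDMARKS, 3)
        np.testing.assert_allclose(
            out.mean(axis=1), stack.mean(axis=1), rtol=0, atol=1e-9
        )
        np.testing.assert_array_equal(out[:, :, 2], stack[:, :, 2])


class TestLandmarkShapeInvariants:
    def test_shape_bookkeeping(self, training_shapes):
        s = training_shapes[0]
        assert s.points.shape == (19, 20, 3)
        assert s.n_points == 380
        assert s.flatten().size == 1140

    def test_landmarked_phantom_slices_are_equiangular(self, phantom_spec):
        from aaaseg.phantom import sample_phantom_shape

        rng = np.random.default_rng(9)
        shapes = sample_phantom_shape(rng, phantom_spec)
        lm = landmark_contour_stack(shapes["outer"])
        s = straighten(lm)
        for i in range(N_SLICES):
            pts = s.points[i, :, :2] - s.points[i, :, :2].mean(axis=0)
            ang = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
            steps = np.diff(ang)
            # equal angles about the ray origin hold to raycasting accuracy
            np.testing.assert_allclose(steps, steps.mean(), atol=5e-2)
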