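import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from plaquemap._geometry import circle_points
from plaquemap.imaging_io import Contour, ContourStack, PlanarImage, VolumeImage
from plaquemap.registration import (
    BSplineRegistrationParams,
    BSplineTransform2D,
    SimilarityTransform2D,
    TransformChain,
    compose,
    compose_similarity,
    fit_similarity_from_landmarks,
    load_transform,
    register_contours_bspline,
    resample_volume,
    save_transform,
    stack_enface_photos,
)
from tests.conftest import circle_stack


class TestSimilarityTransform:
    def test_apply_then_invert_returns_input(self):
        t = SimilarityTransform2D(37.0, 1.3, (2.5, -1.0))
        pts = np.random.default_rng(0).uniform(-5, 5, (20, 2))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform2D(scale=0.0)

    def test_json_round_trip(self, tmp_path):
        t = SimilarityTransform2D(10.0, 0.9, (1.0, 2.0))
        save_transform(t, tmp_path / "t.json")
        back = load_transform(tmp_path / "t.json")
        assert back.rotation_deg == t.rotation_deg
        assert back.scale == t.scale


class TestFitSimilarity:
    def test_identity_when_moving_equals_fixed(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        fit = fit_similarity_from_landmarks(pts, pts)
        assert fit.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert fit.scale == pytest.approx(1.0, abs=1e-12)
        assert fit.translation_mm == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_exact_recovery_of_constructed_transform(self):
        rng = np.random.default_rng(3)
        moving = rng.uniform(-4, 4, (6, 2))
        truth = SimilarityTransform2D(30.0, 1.2, (3.0, -1.0))
        fit = fit_similarity_from_landmarks(truth.apply(moving), moving)
        assert fit.rotation_deg == pytest.approx(30.0, abs=1e-9)
        assert fit.scale == pytest.approx(1.2, abs=1e-9)
        assert fit.translation_mm == pytest.approx((3.0, -1.0), abs=1e-9)
        assert fit.rms_residual_mm_ < 1e-9

    def test_two_pairs_exact_zero_residual(self):
        moving = np.array([[0.0, 0.0], [1.0, 0.0]])
        fixed = np.array([[1.0, 1.0], [1.0, 3.0]])  # rot 90, scale 2, translate
        fit = fit_similarity_from_landmarks(fixed, moving)
        np.testing.assert_allclose(fit.apply(moving), fixed, atol=1e-12)
        assert fit.rms_residual_mm_ == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_coincident_points(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="coincident"):
            fit_similarity_from_landmarks(np.ones((3, 2)), pts)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError, match="index-matched"):
            fit_similarity_from_landmarks(np.zeros((3, 2)), np.zeros((2, 2)))

    @settings(max_examples=20, deadline=None)
    @given(
        rot=st.floats(-170, 170),
        scale=st.floats(0.5, 2.0),
        tx=st.floats(-5, 5),
        ty=st.floats(-5, 5),
    )
    def test_exact_on_noise_free_forward_data(self, rot, scale, tx, ty):
        moving = np.array([[0.0, 0.0], [3.0, 0.5], [1.0, 2.5], [-2.0, 1.0]])
        truth = SimilarityTransform2D(rot, scale, (tx, ty))
        fit = fit_similarity_from_landmarks(truth.apply(moving), moving)
        np.testing.assert_allclose(fit.apply(moving), truth.apply(moving), atol=1e-8)

    def test_matches_brute_force_optimizer_with_noise(self):
        rng = np.random.default_rng(5)
        moving = rng.uniform(-4, 4, (8, 2))
        truth = SimilarityTransform2D(20.0, 1.1, (1.0, 0.5))
        fixed = truth.apply(moving) + rng.normal(0, 0.05, (8, 2))

        def cost(p):
            t = SimilarityTransform2D(p[0], np.exp(p[1]), (p[2], p[3]))
            return np.sum((t.apply(moving) - fixed) ** 2)

        res = minimize(cost, [0.0, 0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        fit = fit_similarity_from_landmarks(fixed, moving)
        assert fit.rotation_deg == pytest.approx(res.x[0], abs=1e-5)
        assert fit.scale == pytest.approx(np.exp(res.x[1]), abs=1e-6)
        assert cost([fit.rotation_deg, np.log(fit.scale), *fit.translation_mm]) <= res.fun + 1e-10


def make_photo(landmarks, z=0.0, size=8):
    return PlanarImage(np.zeros((size, size), dtype=np.uint8), 0.1, z, landmarks)


class TestStackEnfacePhotos:
    def test_aligned_photos_give_identities(self):
        marks = {"a": (0.1, 0.1), "b": (0.5, 0.2), "c": (0.3, 0.6)}
        photos = [make_photo(marks, z=float(k)) for k in range(3)]
        _, transforms = stack_enface_photos(photos)
        for t in transforms:
            assert t.is_identity(tol=1e-9)

    def test_rotation_about_landmark_recovered(self):
        base = np.array([[0.2, 0.2], [0.6, 0.2], [0.4, 0.6]])
        rot = SimilarityTransform2D(10.0, 1.0, (0.0, 0.0))
        pivot = base[0]
        rotated = rot.apply(base - pivot) + pivot
        photos = [
            make_photo({k: tuple(p) for k, p in zip("abc", base)}, z=0.0),
            make_photo({k: tuple(p) for k, p in zip("abc", rotated)}, z=1.0),
        ]
        _, transforms = stack_enface_photos(photos)
        assert transforms[1].rotation_deg == pytest.approx(-10.0, abs=1e-6)
        assert transforms[1].scale == pytest.approx(1.0, abs=1e-12)

    def test_chained_rotations_accumulate(self):
        base = np.array([[0.2, 0.2], [0.6, 0.2], [0.4, 0.6]])
        r5 = SimilarityTransform2D(5.0, 1.0, (0.0, 0.0))
        p1 = r5.apply(base)
        p2 = r5.apply(p1)
        photos = [
            make_photo({k: tuple(p) for k, p in zip("abc", pts)}, z=float(i))
            for i, pts in enumerate([base, p1, p2])
        ]
        _, transforms = stack_enface_photos(photos)
        assert transforms[2].rotation_deg == pytest.approx(-10.0, abs=1e-6)

    def test_missing_shared_landmarks_names_pair(self):
        photos = [
            make_photo({"a": (0.1, 0.1), "b": (0.2, 0.3)}, z=0.0),
            make_photo({"x": (0.1, 0.1), "b": (0.2, 0.3)}, z=1.0),
        ]
        with pytest.raises(ValueError, match="0 and 1"):
            stack_enface_photos(photos)


class TestBSplineTransform:
    def test_zero_coefficients_identity(self):
        t = BSplineTransform2D.for_domain(0, 10, 0, 10, 5.0)
        pts = np.random.default_rng(0).uniform(0, 10, (50, 2))
        np.testing.assert_allclose(t.apply(pts), pts)

    def test_invert_points_round_trip(self):
        rng = np.random.default_rng(1)
        t = BSplineTransform2D.for_domain(-10, 10, -10, 10, 5.0)
        t.coefficients += rng.uniform(-0.8, 0.8, t.coefficients.shape)
        pts = rng.uniform(-5, 5, (40, 2))
        back = t.invert_points(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-8)

    def test_displacement_smooth_partition_of_unity(self):
        # constant coefficients displace every supported point by that constant
        t = BSplineTransform2D.for_domain(0, 10, 0, 10, 2.0)
        t.coefficients[...] = (0.3, -0.2)
        pts = np.random.default_rng(2).uniform(1, 9, (30, 2))
        np.testing.assert_allclose(t.displacement(pts), np.tile([0.3, -0.2], (30, 1)), atol=1e-12)


class TestRegisterContoursBSpline:
    def test_moving_equals_fixed_yields_near_zero_field(self, lumen_stack):
        t = register_contours_bspline(lumen_stack, lumen_stack)
        assert t.max_abs_coefficient() < 0.05

    def test_recovers_known_warp(self):
        fixed = circle_stack(radius=3.0, n_slices=3, center=(8.0, 8.0))
        truth = BSplineTransform2D((-4.0, -4.0), (8.0, 8.0), np.zeros((4, 4, 2)))
        truth.coefficients[1:3, 1:3] = [[[1.0, 0.4], [-0.6, 0.8]], [[0.5, -1.0], [0.9, 0.2]]]
        moving = fixed.map_points(truth.invert_points)
        fit = register_contours_bspline(fixed, moving, BSplineRegistrationParams(seed=1))
        # mean post-registration contour distance
        dists = []
        for c in moving:
            warped = fit.apply(c.points)
            ref = fixed.get(c.slice_index, c.structure).points
            from shapely.geometry import Point
            from plaquemap._geometry import contour_linestring

            ring = contour_linestring(ref)
            dists.extend(ring.distance(Point(p)) for p in warped)
        assert np.mean(dists) < 0.2

    def test_metric_monotone_on_accepted_iterations(self):
        fixed = circle_stack(radius=5.0, n_slices=1, center=(8.0, 8.0), n=180)
        moving = circle_stack(radius=5.0, n_slices=1, center=(8.5, 8.0), n=180)
        fit = register_contours_bspline(
            fixed, moving, BSplineRegistrationParams(iterations=120, seed=0)
        )
        metrics = [m for _, m in fit.metric_trace_]
        assert all(b < a for a, b in zip(metrics, metrics[1:]))
        assert fit.final_metric_ < fit.initial_metric_

    def test_non_overlapping_boxes_advise_rigid(self):
        fixed = circle_stack(radius=2.0, n_slices=1, center=(0.0, 0.0))
        moving = circle_stack(radius=2.0, n_slices=1, center=(50.0, 0.0))
        with pytest.raises(ValueError, match="rigid"):
            register_contours_bspline(fixed, moving)

    def test_no_matching_structures(self):
        fixed = circle_stack(structure="lumen", n_slices=1)
        moving = circle_stack(structure="media", n_slices=1)
        with pytest.raises(ValueError, match="matching"):
            register_contours_bspline(fixed, moving)


class TestCompose:
    def test_two_identities(self):
        chain = TransformChain(
            [
                (SimilarityTransform2D(), "a", "b"),
                (SimilarityTransform2D(), "b", "c"),
            ]
        )
        pts = np.random.default_rng(0).uniform(-3, 3, (10, 2))
        np.testing.assert_allclose(compose(chain).apply(pts), pts)

    def test_similarity_then_inverse_is_identity(self):
        t = SimilarityTransform2D(0.0, 2.0, (1.0, 1.0))
        chain = TransformChain([(t, "a", "b"), (t.inverse(), "b", "a")])
        pts = np.random.default_rng(1).uniform(-3, 3, (25, 2))
        np.testing.assert_allclose(chain.apply(pts), pts, atol=1e-9)

    def test_equals_sequential_application(self):
        rng = np.random.default_rng(2)
        sim = SimilarityTransform2D(15.0, 1.1, (0.5, -0.5))
        bsp = BSplineTransform2D.for_domain(-20, 20, -20, 20, 5.0)
        bsp.coefficients += rng.uniform(-0.5, 0.5, bsp.coefficients.shape)
        chain = TransformChain([(sim, "a", "b"), (bsp, "b", "c")])
        pts = rng.uniform(-8, 8, (100, 2))
        np.testing.assert_allclose(chain.apply(pts), bsp.apply(sim.apply(pts)), atol=1e-12)

    def test_association(self):
        rng = np.random.default_rng(3)
        ts = [SimilarityTransform2D(r, s, (tx, ty)) for r, s, tx, ty in rng.uniform(0.5, 1.5, (3, 4))]
        c_all = TransformChain([(ts[0], "a", "b"), (ts[1], "b", "c"), (ts[2], "c", "d")])
        left = compose_similarity(ts[1], ts[0])
        c_grouped = TransformChain([(left, "a", "c"), (ts[2], "c", "d")])
        pts = rng.uniform(-3, 3, (30, 2))
        np.testing.assert_allclose(c_all.apply(pts), c_grouped.apply(pts), atol=1e-10)

    def test_domain_label_mismatch_shows_link(self):
        with pytest.raises(ValueError, match="'b' != next source 'x'"):
            TransformChain(
                [
                    (SimilarityTransform2D(), "a", "b"),
                    (SimilarityTransform2D(), "x", "c"),
                ]
            )


class TestResampleVolume:
    def test_identity_same_grid(self):
        vol = VolumeImage(np.random.default_rng(0).random((6, 5, 4)), (1, 1, 1))
        out = resample_volume(vol, None, vol)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-12)

    def test_one_voxel_translation_shifts_with_zero_fill(self):
        vol = VolumeImage(np.random.default_rng(1).random((6, 6, 3)), (1, 1, 1))
        shift = SimilarityTransform2D(0.0, 1.0, (1.0, 0.0))  # maps target into source
        out = resample_volume(vol, shift, vol)
        np.testing.assert_allclose(out.voxels[:-1], vol.voxels[1:], atol=1e-12)
        np.testing.assert_allclose(out.voxels[-1], 0.0)

    def test_constant_volume_stays_constant(self):
        vol = VolumeImage(np.full((8, 8, 4), 3.3), (0.5, 0.5, 1.0))
        t = SimilarityTransform2D(10.0, 1.0, (0.2, -0.1))
        target = VolumeImage(np.zeros((4, 4, 2)), (0.5, 0.5, 1.0), (1.0, 1.0, 0.0))
        out = resample_volume(vol, t, target)
        np.testing.assert_allclose(out.voxels, 3.3, atol=1e-12)
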