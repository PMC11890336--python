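"""Transform estimation, point-list variants and TRE."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ushisto import (
    Landmark,
    Transform2D,
    enumerate_point_list_variants,
    estimate_transform,
    register_slice_pair,
    target_registration_error,
)
from ushisto.registration import fiducial_centroid, pair_landmarks


def _lm_pair(label, role, us_xy, wsi_xy):
    return (
        Landmark(label, role, tuple(us_xy), "US"),
        Landmark(label, role, tuple(wsi_xy), "WSI"),
    )


def _make_pairs(n_circ=6, roles=("fiducial_left", "fiducial_middle", "fiducial_right"), rng=None):
    rng = rng or np.random.default_rng(0)
    circ = [
        _lm_pair(f"circ-{i}", "circumferential", rng.uniform(0, 30, 2), rng.uniform(0, 30, 2))
        for i in range(n_circ)
    ]
    fid = {r: _lm_pair(r, r, rng.uniform(0, 30, 2), rng.uniform(0, 30, 2)) for r in roles}
    return circ, fid


class TestEstimateTransform:
    def test_identity_on_equal_point_sets(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [7.0, 5.0]])
        for model in ("rigid", "similarity", "affine"):
            t = estimate_transform(pts, pts, model=model)
            assert np.allclose(t.matrix, np.eye(3), atol=1e-12)

    def test_recovers_constructed_similarity(self):
        rng = np.random.default_rng(7)
        src = rng.uniform(-10, 10, (8, 2))
        truth = Transform2D.from_similarity(0.9, 30.0, (3.0, 1.0))
        dst = truth.apply(src)
        t = estimate_transform(src, dst, model="similarity")
        assert abs(t.scale - 0.9) < 1e-9
        assert abs(t.rotation_deg - 30.0) < 1e-9
        assert np.allclose(t.translation_mm, (3.0, 1.0), atol=1e-9)
        assert np.allclose(t.matrix, truth.matrix, atol=1e-9)

    @pytest.mark.parametrize("model", ["rigid", "similarity", "affine"])
    def test_residual_matches_numerical_optimizer(self, model):
        """Closed-form least squares ties a generic optimizer on 20 noisy instances."""
        rng = np.random.default_rng(42)
        n_params = {"rigid": 3, "similarity": 4, "affine": 6}[model]

        def unpack(p):
            if model == "affine":
                m = np.eye(3)
                m[:2, :2] = p[:4].reshape(2, 2)
                m[:2, 2] = p[4:]
                return m
            s = p[3] if model == "similarity" else 1.0
            c, si = np.cos(p[0]), np.sin(p[0])
            return np.array([[s * c, -s * si, p[1]], [s * si, s * c, p[2]], [0, 0, 1]])

        for _ in range(20):
            src = rng.uniform(-10, 10, (7, 2))
            dst = (
                Transform2D.from_similarity(rng.uniform(0.7, 1.3), rng.uniform(-60, 60),
                                            rng.uniform(-5, 5, 2)).apply(src)
                + rng.normal(0, 0.5, (7, 2))
            )

            def cost(p):
                m = unpack(p)
                res = src @ m[:2, :2].T + m[:2, 2] - dst
                return (res**2).sum()

            t = estimate_transform(src, dst, model=model)
            x0 = np.zeros(n_params)
            if model == "similarity":
                x0[3] = 1.0
            elif model == "affine":
                x0[:4] = np.eye(2).ravel()
            best = min(
                (minimize(cost, x0 + rng.normal(0, 0.1, n_params), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
                 for _ in range(3)),
                key=lambda r: r.fun,
            )
            res_closed = cost(np.zeros(1)) if False else ((t.apply(src) - dst) ** 2).sum()
            assert res_closed <= best.fun + 1e-6

    def test_matches_skimage_similarity_estimate(self):
        """Independent library oracle for the closed-form similarity fit."""
        from skimage.transform import SimilarityTransform

        rng = np.random.default_rng(3)
        src = rng.uniform(0, 20, (10, 2))
        dst = rng.uniform(0, 20, (10, 2))
        ours = estimate_transform(src, dst, model="similarity")
        ref = SimilarityTransform.from_estimate(src, dst)
        assert np.allclose(ours.matrix, ref.params, atol=1e-9)

    def test_reflection_raises_for_similarity(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [5.0, 5.0]])
        dst = src * np.array([1.0, -1.0])  # mirrored
        with pytest.raises(ValueError, match="reflection"):
            estimate_transform(src, dst, model="similarity")
        # affine happily absorbs the flip
        t = estimate_transform(src, dst, model="affine")
        assert np.allclose(t.apply(src), dst, atol=1e-9)

    def test_collinear_points_raise_for_affine(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(np.linalg.LinAlgError):
            estimate_transform(src, src + 1.0, model="affine")

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            estimate_transform(np.zeros((2, 2)), np.zeros((2, 2)))


class TestTRE:
    def test_three_four_five_triangle(self):
        tre = target_registration_error(
            Transform2D.identity(), np.array([[1.0, 2.0]]), np.array([[4.0, 6.0]])
        )
        assert tre == pytest.approx(5.0, abs=1e-12)

    def test_zero_when_markers_coincide_after_transform(self):
        t = Transform2D.from_similarity(2.0, 45.0, (1.0, -2.0))
        us = np.array([[3.0, 4.0], [-1.0, 2.0]])
        assert target_registration_error(t, us, t.apply(us)) == 0.0

    def test_multi_marker_tre_is_arithmetic_mean(self):
        us = np.array([[0.0, 0.0], [10.0, 0.0]])
        wsi = np.array([[1.0, 0.0], [13.0, 0.0]])  # individual errors 1 and 3
        tre = target_registration_error(Transform2D.identity(), us, wsi)
        assert tre == pytest.approx(2.0, abs=1e-12)

    def test_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(5)
        us, wsi = rng.uniform(0, 10, (3, 2)), rng.uniform(0, 10, (3, 2))
        t = Transform2D.from_similarity(1.1, 12.0, (0.5, 0.5))
        base = target_registration_error(t, us, wsi)
        motion = Transform2D.from_similarity(1.0, 77.0, (4.0, -9.0))
        # moving both modalities' validation points by the same rigid motion,
        # with the transform conjugated accordingly, leaves the TRE unchanged
        t2 = motion.compose(t).compose(motion.inverse())
        moved = target_registration_error(t2, motion.apply(us), motion.apply(wsi))
        assert moved == pytest.approx(base, abs=1e-9)

    def test_empty_validation_list_raises(self):
        with pytest.raises(ValueError):
            target_registration_error(
                Transform2D.identity(), np.empty((0, 2)), np.empty((0, 2))
            )


class TestVariants:
    def test_three_fiducials_give_four_protocol_variants(self):
        circ, fid = _make_pairs(n_circ=6)
        variants = enumerate_point_list_variants(circ, fid)
        assert [v.variant_id for v in variants] == [1, 2, 3, 4]
        v1 = variants[0]
        assert len(v1.training_points) == 6
        assert len(v1.validation_fiducials) == 3
        # variant 3 trains on left+right, validates the middle
        v3 = variants[2]
        train_roles = {p[0].role for p in v3.training_points} - {"circumferential"}
        assert train_roles == {"fiducial_left", "fiducial_right"}
        assert v3.validation_fiducials[0][0].role == "fiducial_middle"

    def test_validation_never_in_training(self):
        circ, fid = _make_pairs(n_circ=6)
        for v in enumerate_point_list_variants(circ, fid):
            train = {id(lm) for p in v.training_points for lm in p}
            val = {id(lm) for p in v.validation_fiducials for lm in p}
            assert not train & val

    def test_single_fiducial_gives_only_variant_one(self):
        circ, fid = _make_pairs(n_circ=5, roles=("fiducial_middle",))
        variants = enumerate_point_list_variants(circ, fid)
        assert len(variants) == 1
        assert variants[0].validation_fiducials[0][0].role == "fiducial_middle"

    def test_two_fiducials_adapt(self):
        circ, fid = _make_pairs(n_circ=5, roles=("fiducial_left", "fiducial_right"))
        variants = enumerate_point_list_variants(circ, fid)
        assert len(variants) == 3  # variant 1 + two leave-one-out splits
        for v in variants[1:]:
            assert len(v.validation_fiducials) == 1

    def test_no_fiducials_raise(self):
        circ, _ = _make_pairs(n_circ=5)
        with pytest.raises(ValueError, match="validation marker"):
            enumerate_point_list_variants(circ, {})

    def test_too_few_circumferential_raise(self):
        circ, fid = _make_pairs(n_circ=2)
        with pytest.raises(ValueError, match="circumferential"):
            enumerate_point_list_variants(circ, fid)


class TestRegisterSlicePair:
    def test_noise_free_phantom_exact(self, noise_free_pair):
        pair, truth = noise_free_pair
        result = register_slice_pair(pair)
        assert all(t < 1e-9 for t in result.per_variant_tre_mm.values())
        assert result.best_variant == 1  # tie broken toward the lowest id
        assert np.allclose(result.best_transform.matrix, truth.true_transform.matrix, atol=1e-9)

    def test_recovers_similarity_under_shrinkage(self, shrinkage_pair):
        pair, truth = shrinkage_pair
        result = register_slice_pair(pair)
        assert result.best_tre_mm < 1e-9
        assert np.allclose(result.best_transform.matrix, truth.true_transform.matrix, atol=1e-9)
        assert result.best_transform.scale == pytest.approx(0.9, abs=1e-9)

    def test_duplicate_fiducial_role_raises(self):
        us = [Landmark("fiducial_left", "fiducial_left", (0.0, 0.0), "US")]
        wsi = [
            Landmark("fiducial_left", "fiducial_left", (0.0, 0.0), "WSI"),
            Landmark("fiducial_left", "fiducial_left", (1.0, 0.0), "WSI"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            pair_landmarks(us, wsi)


def test_fiducial_centroid_of_segmented_marker():
    mask = np.zeros((20, 20), bool)
    mask[4:7, 10:13] = True  # rows 4..6, cols 10..12 -> center (5, 11)
    x, y = fiducial_centroid(mask, (0.5, 0.5))
    assert x == pytest.approx((11 + 0.5) * 0.5)
    assert y == pytest.approx((5 + 0.5) * 0.5)
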