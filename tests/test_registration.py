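"""PCA references, coarse control-point affine, Mattes MI, 1+1-ES
refinement and the exhaustive optimizer-parameter search."""

import warnings

import numpy as np
import pytest

from multimsi.cube import PixelMatrix, partition_pixels, to_pixel_matrix
from multimsi.metrics import entropy
from multimsi.registration import (
    DegenerateGeometryError,
    OptimizerParams,
    coarse_align,
    default_parameter_grid,
    exhaustive_search,
    mattes_mi,
    one_plus_one_register,
    pca_reference_images,
    register_modalities,
)
from multimsi.transform import AffineTransform2D, warp_image


def full_grid_matrix(data_2d_stack: np.ndarray) -> PixelMatrix:
    """(h, w, k) array -> PixelMatrix over all pixels."""
    h, w, k = data_2d_stack.shape
    rows, cols = np.indices((h, w))
    return PixelMatrix(
        data=data_2d_stack.reshape(h * w, k),
        coordinates=np.stack([rows.ravel(), cols.ravel()], axis=1),
        variables=np.arange(k, dtype=float),
        block_map=[("lipid_neg", 0, k)],
        grid_shape=(h, w),
    )


class TestPcaReferenceImages:
    def test_rank_one_pattern_recovered(self, rng):
        pattern = rng.random((12, 12))
        spectrum = rng.random(8) + 0.5
        stack = pattern[:, :, None] * spectrum
        imgs = pca_reference_images(full_grid_matrix(stack), 1)
        r = np.corrcoef(imgs[0].ravel(), pattern.ravel())[0, 1]
        assert abs(r) > 0.999999

    def test_two_orthogonal_patterns(self, rng):
        h = w = 16
        p1 = np.zeros((h, w))
        p1[:8] = 1.0
        p2 = np.zeros((h, w))
        p2[:, :8] = 1.0
        p1 -= p1.mean()
        p2 -= p2.mean()
        s1 = np.array([3.0, 0, 0, 0, 0])
        s2 = np.array([0, 2.0, 0, 0, 0])
        stack = p1[:, :, None] * s1 + p2[:, :, None] * s2 + 1e-4 * rng.random((h, w, 5))
        imgs = pca_reference_images(full_grid_matrix(stack), 2)
        r1 = abs(np.corrcoef(imgs[0].ravel(), p1.ravel())[0, 1])
        r2 = abs(np.corrcoef(imgs[1].ravel(), p2.ravel())[0, 1])
        assert r1 > 0.99 and r2 > 0.99

    def test_white_noise_explained_variance(self):
        # for n >> p iid noise each component explains ~1/p of variance
        ratios = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal((2000, 10))
            xc = x - x.mean(axis=0)
            _, s, _ = np.linalg.svd(xc, full_matrices=False)
            ratios.append(s[0] ** 2 / np.sum(s**2))
        assert abs(float(np.mean(ratios)) - 0.1) < 0.03

    def test_truncation_warning(self, rng):
        stack = rng.random((4, 4, 2))
        with pytest.warns(UserWarning, match="truncating"):
            imgs = pca_reference_images(full_grid_matrix(stack), 10)
        assert len(imgs) == 2


class TestCoarseAlign:
    def test_pure_translation(self):
        moving = np.array([[0.0, 0], [10, 0], [0, 10]])
        fixed = moving + [5.0, -2.0]
        T = coarse_align(fixed, moving)
        assert np.allclose(T.matrix[:2, :2], np.eye(2), atol=1e-12)
        assert np.allclose(T.matrix[:2, 2], [5.0, -2.0], atol=1e-12)

    def test_known_affine_recovered(self, rng):
        gen = AffineTransform2D.from_params(rotation=np.deg2rad(7), scale=(1.03, 1.03), translation=(4, -1))
        moving = rng.uniform(0, 50, (5, 2))
        fixed = gen.apply_points(moving)
        T = coarse_align(fixed, moving)
        assert np.allclose(T.matrix, gen.matrix, atol=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        moving = rng.uniform(0, 50, (5, 2))
        gen = AffineTransform2D.from_params(rotation=0.1, translation=(3, 2))
        fixed = gen.apply_points(moving)
        fixed[0] += [2.0, -1.0]  # perturb one pair
        T = coarse_align(fixed, moving)
        # normal-equation oracle
        design = np.column_stack([moving, np.ones(5)])
        coeffs = np.linalg.solve(design.T @ design, design.T @ fixed)
        assert np.allclose(T.matrix[:2].T, coeffs, atol=1e-9)
        residuals = np.linalg.norm(T.apply_points(moving) - fixed, axis=1)
        assert np.argmax(residuals) == 0

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(DegenerateGeometryError):
            coarse_align(pts, pts)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            coarse_align(np.zeros((2, 2)), np.zeros((2, 2)))


class TestMattesMi:
    def test_self_mi_equals_entropy_dense(self, rng):
        # 16 well-separated levels survive both 60-bin and 256-level binning
        a = (rng.integers(0, 16, (32, 32)) * 16).astype(float)
        assert mattes_mi(a, a) == pytest.approx(entropy(a), abs=1e-10)

    def test_independent_noise_near_zero(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.random((256, 256))
            b = r.random((256, 256))
            vals.append(mattes_mi(a, b))
        assert float(np.mean(vals)) < 0.05

    def test_shuffle_reduces_mi(self, rng):
        a = np.cumsum(rng.random((32, 32)), axis=0)
        shuffled = rng.permutation(a.ravel()).reshape(a.shape)
        assert mattes_mi(a, shuffled) < mattes_mi(a, a)

    def test_constant_image_warns_zero(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            assert mattes_mi(np.ones((8, 8)), rng.random((8, 8))) == 0.0

    def test_sampled_evaluation_seeded(self, rng):
        a, b = rng.random((64, 64)), rng.random((64, 64))
        v1 = mattes_mi(a, b, n_samples=500, seed=3, use_all_pixels=False)
        v2 = mattes_mi(a, b, n_samples=500, seed=3, use_all_pixels=False)
        v3 = mattes_mi(a, b, n_samples=500, seed=4, use_all_pixels=False)
        assert v1 == v2
        assert v1 != v3


def structured_phantom(seed: int = 0, n: int = 64) -> np.ndarray:
    r = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(r.random((n, n)), 3)
    img[20:30, 12:20] += 1.0
    img[40:52, 40:50] += 1.5
    return gaussian_filter(img, 1)


class TestOnePlusOne:
    def test_already_aligned_stays_near_identity(self):
        fixed = structured_phantom()
        res = one_plus_one_register(fixed, fixed, params=OptimizerParams(seed=0))
        # MI trace of accepted parents is non-decreasing
        assert all(b >= a - 1e-12 for a, b in zip(res.metric_trace, res.metric_trace[1:]))
        corner_shift = np.linalg.norm(res.transform.apply_points([[0.0, 0.0]]) - [[0.0, 0.0]])
        assert corner_shift < 1.0

    def test_recovers_planted_shift_with_defaults(self):
        fixed = structured_phantom()
        T_true = AffineTransform2D.from_params(translation=(4, 3))
        moving = warp_image(fixed, T_true.inverse(), interpolation="linear")
        res = one_plus_one_register(fixed, moving, params=OptimizerParams(seed=0))
        pts = np.array([[10.0, 10.0], [50.0, 20.0], [30.0, 50.0]])
        err = np.linalg.norm(
            res.transform.apply_points(T_true.inverse().apply_points(pts)) - pts, axis=1
        ).mean()
        assert err < 0.5

    def test_reproducible_bit_exact(self):
        fixed = structured_phantom()
        moving = warp_image(fixed, AffineTransform2D.from_params(translation=(-3, 2)), interpolation="linear")
        r1 = one_plus_one_register(fixed, moving, params=OptimizerParams(seed=7))
        r2 = one_plus_one_register(fixed, moving, params=OptimizerParams(seed=7))
        assert np.array_equal(r1.transform.matrix, r2.transform.matrix)
        assert r1.metric_trace == r2.metric_trace

    def test_rotation_plus_translation_with_coarse_init(self):
        fixed = structured_phantom(n=96)
        T_true = AffineTransform2D.from_params(
            rotation=np.deg2rad(6), translation=(10, -5), center=(47.5, 47.5)
        )
        moving = warp_image(fixed, T_true, interpolation="linear")
        # T_true maps fixed->moving, so registration target is its inverse
        pts = np.array([[20.0, 20.0], [70.0, 25.0], [30.0, 70.0], [60.0, 60.0], [45.0, 40.0]])
        init = coarse_align(pts, T_true.apply_points(pts))
        errs = []
        for seed in range(10):
            res = one_plus_one_register(fixed, moving, init, OptimizerParams(seed=seed))
            errs.append(
                np.linalg.norm(
                    res.transform.apply_points(T_true.apply_points(pts)) - pts, axis=1
                ).mean()
            )
        assert float(np.mean(errs)) < 1.0

    def test_metric_trace_bounded_by_iterations(self):
        fixed = structured_phantom()
        params = OptimizerParams(max_iterations=17, seed=0)
        res = one_plus_one_register(fixed, fixed, params=params)
        assert len(res.metric_trace) <= 17 + 1

    def test_result_never_worse_than_init(self):
        fixed = structured_phantom()
        moving = warp_image(fixed, AffineTransform2D.from_params(translation=(5, -4)), interpolation="linear")
        init = AffineTransform2D.identity()
        init_mi = mattes_mi(fixed, warp_image(moving, init, fixed.shape, "linear"))
        res = one_plus_one_register(fixed, moving, init, OptimizerParams(seed=1))
        assert res.metric_trace[-1] >= init_mi - 1e-12


class TestExhaustiveSearch:
    def test_grid_of_one_equals_single_run(self):
        fixed = structured_phantom()
        moving = warp_image(fixed, AffineTransform2D.from_params(translation=(3, 1)), interpolation="linear")
        params = OptimizerParams(seed=5)
        grid = [params]
        best_params, result = exhaustive_search(fixed, moving, grid=grid, seed=5)
        single = one_plus_one_register(fixed, moving, params=params)
        assert np.array_equal(result.transform.matrix, single.transform.matrix)

    def test_best_params_maximize_ssim(self):
        fixed = structured_phantom()
        moving = warp_image(fixed, AffineTransform2D.from_params(translation=(4, -2)), interpolation="linear")
        grid = default_parameter_grid(n_growth=2, radius_values=(0.5, 2.0))
        best_params, result = exhaustive_search(fixed, moving, grid=grid, seed=0)
        ssims = []
        for p in grid:
            p_seeded = OptimizerParams(
                growth_factor=p.growth_factor,
                epsilon=p.epsilon,
                initial_radius=p.initial_radius,
                seed=0,
            )
            ssims.append(one_plus_one_register(fixed, moving, None, p_seeded).final_metrics["ssim"])
        assert result.final_metrics["ssim"] == pytest.approx(max(ssims), abs=1e-12)

    def test_degenerate_grid_falls_back_to_init(self, rng):
        fixed = structured_phantom()
        moving = rng.random(fixed.shape)  # unrelated noise: nothing improves
        grid = [OptimizerParams(max_iterations=1, initial_radius=1e-4, epsilon=1e-5)]
        with warnings.catch_warnings(record=True) as captured:
            warnings.simplefilter("always")
            _, result = exhaustive_search(fixed, moving, grid=grid, seed=0)
        # either the single run kept init (notes set) or fallback warned
        assert result.notes == "fallback to initial transform" or np.allclose(
            result.transform.matrix, np.eye(3), atol=1e-2
        )

    def test_empty_grid_rejected(self):
        fixed = structured_phantom()
        with pytest.raises(ValueError, match="empty"):
            exhaustive_search(fixed, fixed, grid=[])


class TestRegisterModalities:
    def test_same_cube_twice_near_identity(self, noisy_phantom):
        cubes, _, _ = noisy_phantom
        T, result = register_modalities(cubes[0], cubes[0], config={"seed": 0})
        assert result.final_metrics["ssim"] > 0.99
        center_err = np.linalg.norm(T.apply_points([[24.0, 24.0]]) - [[24.0, 24.0]])
        assert center_err < 1.0

    def test_nonaffine_warp_flagged_not_crashed(self, noisy_phantom):
        cubes, _, _ = noisy_phantom
        cube = cubes[0]
        # strong non-affine distortion: swirl the values
        from skimage.transform import swirl

        warped = cube.copy()
        for k in range(cube.n_variables):
            warped.values[:, :, k] = swirl(
                cube.values[:, :, k], strength=4, radius=40, preserve_range=True
            )
        T, result = register_modalities(cube, warped, config={"seed": 0})
        assert result.final_metrics["ssim"] < 0.95  # poor fit is reported, no crash
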