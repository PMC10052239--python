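"""OPLS, VIP selection, hyperspectral downsampling and PLS image fusion."""

import numpy as np
import pytest

from multimsi.cube import PixelMatrix, SpectralImageCube, partition_pixels, to_pixel_matrix
from multimsi.fusion import (
    block_average,
    downsample_hyperspectral,
    fit_opls,
    fuse,
    fusion_report,
    select_variables,
    vip,
)
from multimsi.transform import AffineTransform2D


def matrix_from(data: np.ndarray, grid=None) -> PixelMatrix:
    n, k = data.shape
    h = grid[0] if grid else int(np.ceil(np.sqrt(n)))
    w = grid[1] if grid else h
    rows, cols = np.divmod(np.arange(n), w)
    return PixelMatrix(
        data=data,
        coordinates=np.stack([rows, cols], axis=1),
        variables=np.arange(k, dtype=float) + 400,
        block_map=[("lipid_neg", 0, k)],
        grid_shape=(h, w),
    )


def planted_xy(seed=0, n=400, k=200, informative=5, noise=0.05):
    """X with `informative` columns carrying Y-covariance, rest noise."""
    r = np.random.default_rng(seed)
    t = r.standard_normal(n)
    x = r.standard_normal((n, k))
    x[:, :informative] = t[:, None] * r.uniform(1, 2, informative) + noise * r.standard_normal((n, informative))
    y = t[:, None] * np.array([2.0, -1.0]) + noise * r.standard_normal((n, 2))
    return x, y


class TestFitOpls:
    def test_exact_linear_recovery(self, rng):
        n = 200
        x = rng.standard_normal((n, 10))
        y = x[:, :3] @ np.array([[1.0], [2.0], [-1.0]])
        model = fit_opls(x, y, n_predictive=3, n_orthogonal=0)
        y_hat = model.predict(x)
        r2 = 1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.999
        w = np.abs(model.pred_weights[0])
        assert w[:3].min() > w[3:].max()

    def test_independent_y_no_heldout_r2(self):
        r = np.random.default_rng(0)
        x = r.standard_normal((400, 20))
        y = r.standard_normal((400, 2))
        model = fit_opls(x[:300], y[:300], n_predictive=2, n_orthogonal=1)
        y_hat = model.predict(x[300:])
        ss_res = np.sum((y[300:] - y_hat) ** 2)
        ss_tot = np.sum((y[300:] - y[:300].mean(axis=0)) ** 2)
        assert 1 - ss_res / ss_tot < 0.05

    def test_orthogonal_component_does_not_rotate_predictive_weights(self):
        r = np.random.default_rng(1)
        n = 500
        t_y = r.standard_normal(n)
        t_o = r.standard_normal(n)
        t_o -= t_o @ t_y / (t_y @ t_y) * t_y  # exactly orthogonal score
        w_y = np.zeros(12)
        w_y[:4] = [1.0, 0.5, -0.5, 1.0]
        p_o = np.zeros(12)
        p_o[6:10] = [1.0, -1.0, 0.5, 0.5]
        x0 = np.outer(t_y, w_y) + 0.01 * r.standard_normal((n, 12))
        x1 = x0 + np.outer(t_o, p_o)
        y = t_y[:, None]
        m0 = fit_opls(x0, y, n_predictive=1, n_orthogonal=0, scale=False)
        m1 = fit_opls(x1, y, n_predictive=1, n_orthogonal=1, scale=False)
        cos = abs(m0.pred_weights[0] @ m1.pred_weights[0])
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_reconstruction_invariant(self, rng):
        x, y = planted_xy(seed=2, n=150, k=30)
        model = fit_opls(x, y, n_predictive=2, n_orthogonal=2)
        xw = (x - model.x_mean) / model.x_scale
        assert np.abs(model.reconstruct_x() - xw).max() < 1e-8

    def test_rank_truncation_warns(self, rng):
        x = rng.standard_normal((10, 4))
        y = rng.standard_normal((10, 1))
        with pytest.warns(UserWarning, match="truncat"):
            fit_opls(x, y, n_predictive=8, n_orthogonal=0)


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        # single predictive component with perfectly symmetric variables
        r = np.random.default_rng(3)
        t = r.standard_normal(300)
        x = np.tile(t[:, None], (1, 6)) + 1e-9 * r.standard_normal((300, 6))
        y = t[:, None]
        model = fit_opls(x, y, n_predictive=1, n_orthogonal=0)
        result = vip(model)
        assert np.allclose(result.vip, 1.0, atol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_of_squares_identity(self, seed):
        x, y = planted_xy(seed=seed, n=200, k=50)
        model = fit_opls(x, y, n_predictive=2, n_orthogonal=1)
        result = vip(model)
        assert np.sum(result.vip**2) == pytest.approx(model.k_p, abs=1e-8)

    def test_planted_informative_variables_dominate(self):
        x, y = planted_xy(seed=0)
        model = fit_opls(x, y, n_predictive=2, n_orthogonal=1)
        result = vip(model)
        top5 = np.argsort(result.vip)[-5:]
        assert set(top5) == {0, 1, 2, 3, 4}
        assert result.vip[:5].min() > 1.0

    def test_selection_sensitivity_and_fpr(self):
        sens, fprs = [], []
        for seed in range(10):
            x, y = planted_xy(seed=seed)
            model = fit_opls(x, y, n_predictive=2, n_orthogonal=1)
            selected = vip(model).selected
            sens.append(selected[:5].mean())
            fprs.append(selected[5:].mean())
        assert float(np.mean(sens)) == 1.0
        assert float(np.mean(fprs)) < 0.05

    def test_no_predictive_components_rejected(self, rng):
        x, y = planted_xy(seed=1, n=100, k=20)
        model = fit_opls(x, y, n_predictive=1, n_orthogonal=0)
        model.pred_weights = model.pred_weights[:0]
        with pytest.raises(ValueError):
            vip(model)


class TestSelectVariables:
    def test_threshold_zero_keeps_all(self):
        x, y = planted_xy(seed=0, n=100, k=20)
        xm = matrix_from(x)
        model = fit_opls(x, y, n_predictive=1, n_orthogonal=0)
        result = vip(model, threshold=0.0)
        assert select_variables(xm, result).n_columns == 20

    def test_threshold_above_max_errors(self):
        x, y = planted_xy(seed=0, n=100, k=20)
        xm = matrix_from(x)
        result = vip(fit_opls(x, y, 1, 0), threshold=1e6)
        with pytest.raises(ValueError, match="threshold"):
            select_variables(xm, result)

    def test_planted_five_survive_at_one(self):
        x, y = planted_xy(seed=0)
        xm = matrix_from(x)
        result = vip(fit_opls(x, y, 2, 1), threshold=1.0)
        kept = select_variables(xm, result)
        assert set(kept.variables) == set(xm.variables[:5])


class TestDownsampleHyperspectral:
    def _hyper(self, values):
        return SpectralImageCube(
            values=values,
            variables=np.arange(values.shape[2], dtype=float) + 500,
            modality_tag="hyperspectral",
            pixel_size=2.5,
        )

    def test_constant_cube(self):
        cube = self._hyper(np.full((8, 8, 3), 2.0))
        y = downsample_hyperspectral(cube, (4, 4))
        assert np.allclose(y.data, 2.0)
        assert y.n_rows == 16

    def test_checkerboard_two_x(self):
        values = np.zeros((4, 4, 1))
        values[::2, ::2, 0] = 1.0
        values[1::2, 1::2, 0] = 1.0
        cube = self._hyper(values)
        y = downsample_hyperspectral(cube, (2, 2))
        # block-mean oracle: each MSI pixel is the mean of its 4 children
        assert np.allclose(y.data, 0.5)

    def test_identity_equal_grids_is_copy(self, rng):
        values = rng.random((5, 5, 2))
        cube = self._hyper(values)
        y = downsample_hyperspectral(cube, (5, 5), T=AffineTransform2D.identity())
        assert np.allclose(y.data.reshape(5, 5, 2), values)

    def test_grid_mismatch_rejected(self, rng):
        cube = self._hyper(rng.random((9, 9, 2)))
        with pytest.raises(Exception, match="multiple"):
            downsample_hyperspectral(cube, (4, 4))


def perfect_link_setup(seed=0, grid=12, factor=4, n_ions=3):
    """Microscopy channels that are exact high-res versions of the ions."""
    r = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    hi = gaussian_filter(r.random((grid * factor, grid * factor, n_ions)), 3, axes=(0, 1))
    hyper = SpectralImageCube(
        values=hi, variables=np.arange(n_ions, dtype=float) + 500, modality_tag="hyperspectral"
    )
    lo = block_average(hi, factor)
    x = matrix_from(lo.reshape(grid * grid, n_ions), grid=(grid, grid))
    return x, hyper, hi


class TestFuse:
    def test_perfect_link_scores_100(self):
        x, hyper, _ = perfect_link_setup()
        model = fuse(x, hyper, config={"pls_components": 3})
        for ion in model.ions:
            assert ion.reconstruction_score == pytest.approx(100.0, abs=0.1)
            assert float(np.median(ion.ci_image)) < 1e-3

    def test_self_consistency_of_reconstruction_score(self):
        x, hyper, _ = perfect_link_setup(seed=1)
        # add noise so the score is well below 100
        noisy = matrix_from(
            x.data + 0.3 * np.random.default_rng(5).standard_normal(x.data.shape),
            grid=x.grid_shape,
        )
        model = fuse(noisy, hyper, config={"pls_components": 3})
        for j, ion in enumerate(model.ions):
            lo = block_average(ion.predicted_highres, model.upscale)
            yv = noisy.data[:, j]
            pred = lo[noisy.coordinates[:, 0], noisy.coordinates[:, 1]]
            score = 100 * (1 - np.sum((yv - pred) ** 2) / np.sum((yv - yv.mean()) ** 2))
            assert ion.reconstruction_score == pytest.approx(score, abs=1e-8)

    def test_independent_ion_flagged(self):
        x, hyper, _ = perfect_link_setup(seed=2)
        r = np.random.default_rng(9)
        independent = matrix_from(r.standard_normal(x.data.shape), grid=x.grid_shape)
        model = fuse(independent, hyper, config={"pls_components": 3})
        for ion in model.ions:
            assert ion.reconstruction_score < 25
            assert ion.flagged

    def test_zero_variance_ion_skipped(self):
        x, hyper, _ = perfect_link_setup(seed=3)
        data = x.data.copy()
        data[:, 1] = 4.2
        constant = matrix_from(data, grid=x.grid_shape)
        with pytest.warns(UserWarning, match="zero variance"):
            model = fuse(constant, hyper, config={"pls_components": 2})
        assert len(model.ions) == x.n_columns - 1

    def test_monotone_noise_degradation(self):
        x, hyper, _ = perfect_link_setup(seed=4)
        medians = []
        r = np.random.default_rng(11)
        base_noise = r.standard_normal(hyper.values.shape)
        for sigma in (0.0, 0.05, 0.1, 0.2, 0.4):
            noisy_hyper = SpectralImageCube(
                values=np.clip(hyper.values + sigma * base_noise, 0, None),
                variables=hyper.variables,
                modality_tag="hyperspectral",
            )
            model = fuse(x, noisy_hyper, config={"pls_components": 3})
            medians.append(float(np.median([i.reconstruction_score for i in model.ions])))
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_highres_feature_localization_dice(self, small_phantom):
        cubes, hyper, truth = small_phantom
        part = partition_pixels(cubes[0])
        x = to_pixel_matrix(cubes[0], part)
        # pick a core-pattern variable of block 0: visible in microscopy
        idx = int(np.flatnonzero(truth.assignments[0] == "core")[0])
        x_sel = x.column_slice(np.array([idx]))
        model = fuse(x_sel, hyper, config={"pls_components": 8})
        pred = model.ions[0].predicted_highres
        truth_hi = truth.ion_truth_image(0, idx, highres=True)
        thr_p = pred.mean() + 2 * pred.std()
        thr_t = truth_hi.mean() + 2 * truth_hi.std()
        a = pred > thr_p
        b = truth_hi > thr_t
        dice = 2 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
        assert dice > 0.8

    def test_ci_wider_at_high_leverage_pixels(self):
        x, hyper, hi = perfect_link_setup(seed=6)
        noisy = matrix_from(
            x.data + 0.2 * np.random.default_rng(7).standard_normal(x.data.shape),
            grid=x.grid_shape,
        )
        model = fuse(noisy, hyper, config={"pls_components": 3})
        ion = model.ions[0]
        feats = hi.reshape(-1, hi.shape[2])
        dist = np.linalg.norm(feats - feats.mean(axis=0), axis=1)
        r = np.corrcoef(dist, ion.ci_image.ravel())[0, 1]
        assert r > 0.5  # wider CI where features are far from training mean


class TestFusionReport:
    def test_report_files_and_rows(self, tmp_path):
        x, hyper, _ = perfect_link_setup(seed=8, n_ions=2)
        model = fuse(x, hyper, config={"pls_components": 2})
        table = fusion_report(model, tmp_path)
        assert len(table) == 2
        files = {p.name for p in tmp_path.iterdir()}
        assert "reconstruction_scores.csv" in files
        for ion in model.ions:
            tag = f"mz_{ion.variable:.4f}"
            for kind in ("measured", "predicted", "residual", "ci95"):
                assert f"{tag}_{kind}.tiff" in files

    def test_perfect_link_ci_near_zero_everywhere(self, tmp_path):
        x, hyper, _ = perfect_link_setup(seed=9, n_ions=2)
        model = fuse(x, hyper, config={"pls_components": 2})
        for ion in model.ions:
            assert float(np.quantile(ion.ci_image, 0.99)) < 1e-2
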