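"""Intensity-based multimodal registration.

Pipeline: PCA score images as low-noise references, optional coarse
control-point affine, then automated refinement by a 1+1-evolutionary
optimizer maximizing Mattes mutual information, with an exhaustive
search over optimizer parameters selecting the best-SSIM result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from multimsi.cube import PixelMatrix, SpectralImageCube, partition_pixels, to_pixel_matrix
from multimsi.metrics import metric_suite
from multimsi.transform import AffineTransform2D, apply_transform, warp_image


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class OptimizerParams:
    """Settings of the 1+1-evolutionary optimizer.

    The search radius is expressed in scaled parameter units where one
    unit corresponds to roughly one pixel of border displacement.
    """

    max_iterations: int = 100
    growth_factor: float = 1.05
    epsilon: float = 1.5e-3
    initial_radius: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must be > 1")
        if not self.epsilon < self.initial_radius:
            raise ValueError("epsilon must be smaller than initial_radius")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    metric_trace: list[float]
    final_metrics: dict[str, float]
    params_used: OptimizerParams
    converged: bool = True
    notes: str = ""


def pca_reference_images(matrix: PixelMatrix, n_components: int = 3) -> list[np.ndarray]:
    """PCA score images of a pixel matrix, restored to the image grid.

    Used as registration references: lower noise and higher contrast than
    single ion images. Components are ordered by explained variance with
    a deterministic sign (largest-magnitude loading positive); black
    pixels are 0.
    """
    x = matrix.data - matrix.data.mean(axis=0, keepdims=True)
    rank = min(x.shape)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    images = []
    for k in range(n_components):
        loading = vt[k]
        sign = 1.0 if loading[np.argmax(np.abs(loading))] >= 0 else -1.0
        scores = sign * u[:, k] * s[k]
        img = np.zeros(matrix.grid_shape)
        img[matrix.coordinates[:, 0], matrix.coordinates[:, 1]] = scores
        images.append(img)
    return images


def coarse_align(
    fixed_points: np.ndarray, moving_points: np.ndarray
) -> AffineTransform2D:
    """Least-squares affine from >= 3 control-point pairs.

    Minimizes sum ||T(moving_i) - fixed_i||^2; at least five well-spread
    points are recommended in practice.
    """
    fixed_points = np.asarray(fixed_points, dtype=float).reshape(-1, 2)
    moving_points = np.asarray(moving_points, dtype=float).reshape(-1, 2)
    if fixed_points.shape != moving_points.shape:
        raise ValueError("point lists must have equal length")
    n = fixed_points.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 point pairs, got {n}")
    design = np.column_stack([moving_points, np.ones(n)])
    if np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max())) < 3:
        raise DegenerateGeometryError("control points are collinear")
    coeffs, *_ = np.linalg.lstsq(design, fixed_points, rcond=None)
    matrix = np.eye(3)
    matrix[:2, :] = coeffs.T
    return AffineTransform2D(matrix)


def mattes_mi(
    fixed: np.ndarray,
    moving: np.ndarray,
    n_samples: int = 500,
    n_bins: int = 60,
    seed: int = 0,
    use_all_pixels: bool = True,
) -> float:
    """Mattes-style mutual information in bits from a binned joint
    intensity histogram (box binning, ``n_bins`` per axis).

    With ``use_all_pixels`` (the default) the joint histogram is dense;
    otherwise ``n_samples`` random pixels are drawn with ``seed``.
    Higher values mean better alignment.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    a = fixed.ravel()
    b = moving.ravel()
    if not use_all_pixels and n_samples < a.size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(a.size, size=n_samples, replace=False)
        a, b = a[idx], b[idx]
    if a.max() == a.min() or b.max() == b.min():
        warnings.warn("constant image: mutual information is 0", stacklevel=2)
        return 0.0
    hist, _, _ = np.histogram2d(a, b, bins=n_bins)
    p_ab = hist / hist.sum()
    p_a = p_ab.sum(axis=1)
    p_b = p_ab.sum(axis=0)

    def h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    return h(p_a) + h(p_b) - h(p_ab.ravel())


# 1+1-ES search space: (tx, ty, rotation, log-scale-x, log-scale-y, shear),
# scaled so one radius unit displaces the image border by about one pixel.
_N_PARAMS = 6


def _param_scales(shape: tuple[int, int]) -> np.ndarray:
    radius_px = 0.5 * float(np.hypot(*shape))
    return np.array([1.0, 1.0, 1 / radius_px, 1 / radius_px, 1 / radius_px, 1 / radius_px])


def _params_to_transform(
    p: np.ndarray, shape: tuple[int, int], init: AffineTransform2D
) -> AffineTransform2D:
    """Perturbation (applied in the fixed frame, about the image center)
    composed with the initial transform."""
    center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    pert = AffineTransform2D.from_params(
        translation=(p[0], p[1]),
        rotation=p[2],
        scale=(float(np.exp(p[3])), float(np.exp(p[4]))),
        shear=p[5],
        center=center,
    )
    return pert.compose(init)


def one_plus_one_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: AffineTransform2D | None = None,
    params: OptimizerParams | None = None,
    n_bins: int = 60,
) -> RegistrationResult:
    """Refine an affine registration with a 1+1-evolutionary optimizer.

    Each iteration perturbs the current parent's transform parameters by
    an isotropic random step of the current search radius; the child
    replaces the parent iff its Mattes MI improves. The radius grows by
    ``growth_factor`` on success and shrinks by its inverse on failure,
    providing a mechanism to step out of non-optimal minima. Terminates
    at ``max_iterations`` or when the radius falls below ``epsilon``.
    The returned transform never has worse MI than ``init``.
    """
    if init is None:
        init = AffineTransform2D.identity()
    if params is None:
        params = OptimizerParams()
    rng = np.random.default_rng(params.seed)
    shape = fixed.shape
    scales = _param_scales(shape)

    def objective(p: np.ndarray) -> float:
        warped = warp_image(moving, _params_to_transform(p, shape, init), shape, "linear")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mattes_mi(fixed, warped, n_bins=n_bins, use_all_pixels=True)

    parent = np.zeros(_N_PARAMS)
    parent_mi = objective(parent)
    if not np.isfinite(parent_mi):
        raise FloatingPointError("non-finite registration metric at initialization")
    radius = params.initial_radius
    trace = [parent_mi]
    converged = False
    for _ in range(params.max_iterations):
        if radius < params.epsilon:
            converged = True
            break
        child = parent + rng.standard_normal(_N_PARAMS) * radius * scales
        child_mi = objective(child)
        if not np.isfinite(child_mi):
            raise FloatingPointError(
                f"non-finite registration metric; trace so far: {trace}"
            )
        if child_mi > parent_mi:
            parent, parent_mi = child, child_mi
            radius *= params.growth_factor
        else:
            radius /= params.growth_factor
        trace.append(parent_mi)

    transform = _params_to_transform(parent, shape, init)
    resampled = warp_image(moving, transform, shape, "bicubic")
    final = metric_suite(fixed, resampled)
    return RegistrationResult(
        transform=transform,
        metric_trace=trace,
        final_metrics=final,
        params_used=params,
        converged=converged,
    )


def default_parameter_grid(
    n_growth: int = 3, radius_values: tuple[float, ...] | None = None
) -> list[OptimizerParams]:
    """Optimizer-parameter grid for the exhaustive search.

    Growth factors span [1.005, 1.1] (sub-sampled from the 0.0005-step
    ladder); epsilon and initial radius take multiplicative decade steps
    across their published limits, 1.5e-7..1.5e-3 and 6.25e-4..6.25e-2.
    Radii are in scaled units where one unit is about one pixel of border
    displacement, so the grid is augmented with pixel-scale radii that
    make refinement from a coarse alignment effective at phantom scale.
    """
    growths = np.linspace(1.005, 1.1, n_growth)
    if radius_values is None:
        radius_values = (6.25e-2, 1.0, 4.0)
    grid = []
    for g in growths:
        for r in radius_values:
            grid.append(
                OptimizerParams(
                    growth_factor=round(float(g), 6),
                    epsilon=1.5e-7,
                    initial_radius=float(r),
                )
            )
    return grid


def exhaustive_search(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: AffineTransform2D | None = None,
    grid: list[OptimizerParams] | None = None,
    seed: int = 0,
) -> tuple[OptimizerParams, RegistrationResult]:
    """Run the 1+1 optimizer per grid point; keep the parameter set whose
    registered result maximizes SSIM against the fixed image.

    Ties break by higher MI, then by grid order. If no run improves on
    the initial alignment, an init-equivalent result is returned with a
    warning.
    """
    if init is None:
        init = AffineTransform2D.identity()
    if grid is None:
        grid = default_parameter_grid()
    if not grid:
        raise ValueError("parameter grid is empty")

    init_resampled = warp_image(moving, init, fixed.shape, "bicubic")
    init_metrics = metric_suite(fixed, init_resampled)

    best: tuple[float, float, int] | None = None
    best_params: OptimizerParams | None = None
    best_result: RegistrationResult | None = None
    for i, base in enumerate(grid):
        params = OptimizerParams(
            max_iterations=base.max_iterations,
            growth_factor=base.growth_factor,
            epsilon=base.epsilon,
            initial_radius=base.initial_radius,
            seed=seed,
        )
        result = one_plus_one_register(fixed, moving, init, params)
        key = (result.final_metrics["ssim"], result.final_metrics["mutual_information"], -i)
        if best is None or key > best:
            best = key
            best_params, best_result = params, result

    assert best_result is not None and best_params is not None
    if best_result.final_metrics["ssim"] < init_metrics["ssim"]:
        warnings.warn(
            "no optimizer run improved on the initial alignment; returning init",
            stacklevel=2,
        )
        best_result = RegistrationResult(
            transform=init,
            metric_trace=[],
            final_metrics=init_metrics,
            params_used=best_params,
            converged=False,
            notes="fallback to initial transform",
        )
    return best_params, best_result


def overlay_image(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Magenta/green RGB overlay of two images for visual inspection."""

    def norm(a: np.ndarray) -> np.ndarray:
        lo, hi = a.min(), a.max()
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    f, m = norm(fixed), norm(moving)
    return np.stack([f, m, f], axis=-1)


def register_modalities(
    fixed_cube: SpectralImageCube,
    moving_cube: SpectralImageCube,
    control_points: tuple[np.ndarray, np.ndarray] | None = None,
    config: dict | None = None,
) -> tuple[AffineTransform2D, RegistrationResult]:
    """Full registration chain between two preprocessed cubes.

    PCA reference images (default PC1, ``reference_component`` selects
    another), coarse control-point affine when points are supplied, then
    ``refine_rounds`` passes of the exhaustive optimizer search (each
    seeded differently, chained through the best transform so far), and
    final bicubic resampling metrics. References are lightly Gaussian
    smoothed (``reference_smooth``, pixels) before entering the MI
    objective, which sharpens its optimum on noisy data.
    """
    config = dict(config or {})
    component = int(config.get("reference_component", 0))
    seed = int(config.get("seed", 0))
    grid = config.get("search_grid")
    interpolation = config.get("interpolation", "bicubic")
    smooth = float(config.get("reference_smooth", 1.0))
    rounds = int(config.get("refine_rounds", 2))

    refs = []
    for cube in (fixed_cube, moving_cube):
        matrix = to_pixel_matrix(cube, partition_pixels(cube))
        ref = pca_reference_images(matrix, n_components=component + 1)[component]
        if smooth > 0:
            from scipy.ndimage import gaussian_filter

            ref = gaussian_filter(ref, smooth)
        refs.append(ref)
    fixed_ref, moving_ref = refs

    if control_points is not None:
        init = coarse_align(*control_points)
    else:
        init = AffineTransform2D.identity()

    best_params, result = exhaustive_search(fixed_ref, moving_ref, init, grid, seed)
    for r in range(1, max(rounds, 1)):
        best_params, result = exhaustive_search(
            fixed_ref, moving_ref, result.transform, grid, seed + 1000 * r
        )
    result.transform.frame_from = moving_cube.modality_tag
    result.transform.frame_to = fixed_cube.modality_tag

    resampled_ref = warp_image(
        moving_ref, result.transform, fixed_ref.shape, interpolation
    )
    result.final_metrics = metric_suite(fixed_ref, resampled_ref)
    if "overlay_path" in config:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(config["overlay_path"], np.clip(overlay_image(fixed_ref, resampled_ref), 0, 1))
    return result.transform, result


def resample_to_fixed(
    moving_cube: SpectralImageCube,
    fixed_cube: SpectralImageCube,
    T: AffineTransform2D,
    interpolation: str = "bicubic",
) -> SpectralImageCube:
    """Resample a moving cube onto the fixed cube's grid."""
    return apply_transform(
        moving_cube, T, interpolation, output_shape=(fixed_cube.height, fixed_cube.width)
    )
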