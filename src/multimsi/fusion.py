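"""MSI-microscopy fusion: OPLS linking MSI blocks to hyperspectral
channels, VIP-based variable selection, and PLS-driven prediction of ion
distributions at microscopy resolution with per-ion quality imagery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from multimsi.cube import (
    DimensionError,
    PixelMatrix,
    PixelPartition,
    SpectralImageCube,
    restore_score_image,
)
from multimsi.transform import AffineTransform2D, apply_transform


@dataclass
class OPLSModel:
    """Orthogonal projections to latent structures, multivariate Y.

    Y-orthogonal variation is filtered from X before the predictive
    components are extracted, so predictive + orthogonal + residual
    reconstruct X exactly.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    # orthogonal part
    ortho_weights: np.ndarray  # (n_ortho, K)
    ortho_scores: np.ndarray  # (n, n_ortho)
    ortho_loadings: np.ndarray  # (n_ortho, K)
    # predictive part
    pred_weights: np.ndarray  # (A_p, K), unit norm per component
    pred_scores: np.ndarray  # (n, A_p)
    pred_loadings: np.ndarray  # (A_p, K)
    y_loadings: np.ndarray  # (A_p, M)
    ss_comp: np.ndarray  # explained Y sum of squares per predictive component
    x_residual: np.ndarray

    @property
    def n_predictive(self) -> int:
        return self.pred_weights.shape[0]

    @property
    def k_p(self) -> int:
        """Total number of predictive X-variables."""
        return self.pred_weights.shape[1]

    @property
    def ss_cum(self) -> float:
        return float(self.ss_comp.sum())

    def reconstruct_x(self) -> np.ndarray:
        """Predictive + orthogonal + residual, in preprocessed units."""
        return (
            self.pred_scores @ self.pred_loadings
            + self.ortho_scores @ self.ortho_loadings
            + self.x_residual
        )

    def _filter_orthogonal(self, x: np.ndarray) -> np.ndarray:
        xf = x.copy()
        for j in range(self.ortho_weights.shape[0]):
            t_o = xf @ self.ortho_weights[j]
            xf -= np.outer(t_o, self.ortho_loadings[j])
        return xf

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Predict Y for new X rows (original units in, original units out)."""
        x = (np.asarray(x_new, dtype=float) - self.x_mean) / self.x_scale
        xf = self._filter_orthogonal(x)
        w = self.pred_weights.T  # (K, A)
        p = self.pred_loadings  # (A, K)
        b = w @ np.linalg.solve(p @ w, self.y_loadings)
        return (xf @ b) * self.y_scale + self.y_mean


@dataclass
class VIPResult:
    vip: np.ndarray
    threshold: float = 1.0

    @property
    def selected(self) -> np.ndarray:
        return self.vip > self.threshold


def _dominant_xy_weight(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit X-weight maximizing covariance with Y (first left singular
    vector of XᵀY)."""
    cov = x.T @ y
    if cov.shape[1] == 1:
        w = cov[:, 0]
    else:
        u, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u[:, 0]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X and Y share no covariance; cannot extract component")
    w = w / norm
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def fit_opls(
    x: PixelMatrix | np.ndarray,
    y: PixelMatrix | np.ndarray,
    n_predictive: int = 2,
    n_orthogonal: int = 1,
    scale: bool = True,
) -> OPLSModel:
    """Fit an OPLS model regressing X blocks onto Y channels.

    With ``scale=True`` X and Y are mean-centered and scaled to unit
    variance internally (the predictive-modeling convention). Requested
    components beyond the available rank are truncated with a warning.
    """
    xd = np.asarray(x.data if isinstance(x, PixelMatrix) else x, dtype=float)
    yd = np.asarray(y.data if isinstance(y, PixelMatrix) else y, dtype=float)
    if yd.ndim == 1:
        yd = yd[:, None]
    if xd.shape[0] != yd.shape[0]:
        raise DimensionError("X and Y must have the same rows")
    x_mean = xd.mean(axis=0)
    y_mean = yd.mean(axis=0)
    if scale:
        x_scale = np.where(xd.std(axis=0, ddof=1) == 0, 1.0, xd.std(axis=0, ddof=1))
        y_scale = np.where(yd.std(axis=0, ddof=1) == 0, 1.0, yd.std(axis=0, ddof=1))
    else:
        x_scale = np.ones(xd.shape[1])
        y_scale = np.ones(yd.shape[1])
    xw = (xd - x_mean) / x_scale
    yw = (yd - y_mean) / y_scale

    k = xd.shape[1]
    ortho_w, ortho_t, ortho_p = [], [], []
    for _ in range(n_orthogonal):
        w = _dominant_xy_weight(xw, yw)
        t = xw @ w
        p = xw.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            warnings.warn("no Y-orthogonal variation left; truncating", stacklevel=2)
            break
        w_o = w_o / norm
        t_o = xw @ w_o
        p_o = xw.T @ t_o / (t_o @ t_o)
        xw = xw - np.outer(t_o, p_o)
        ortho_w.append(w_o)
        ortho_t.append(t_o)
        ortho_p.append(p_o)

    max_pred = min(xw.shape[0] - 1, k)
    if n_predictive > max_pred:
        warnings.warn(
            f"n_predictive={n_predictive} exceeds rank; truncating to {max_pred}",
            stacklevel=2,
        )
        n_predictive = max_pred
    pred_w, pred_t, pred_p, y_load, ss = [], [], [], [], []
    for _ in range(n_predictive):
        try:
            w = _dominant_xy_weight(xw, yw)
        except ValueError:
            warnings.warn("X-Y covariance exhausted; truncating", stacklevel=2)
            break
        t = xw @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p = xw.T @ t / tt
        c = yw.T @ t / tt
        ss.append(tt * float(c @ c))  # explained SS of Y by this component
        xw = xw - np.outer(t, p)
        yw = yw - np.outer(t, c)
        pred_w.append(w)
        pred_t.append(t)
        pred_p.append(p)
        y_load.append(c)

    n = xd.shape[0]
    return OPLSModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        ortho_weights=np.array(ortho_w).reshape(len(ortho_w), k),
        ortho_scores=(
            np.column_stack(ortho_t) if ortho_t else np.zeros((n, 0))
        ),
        ortho_loadings=np.array(ortho_p).reshape(len(ortho_p), k),
        pred_weights=np.array(pred_w).reshape(len(pred_w), k),
        pred_scores=np.column_stack(pred_t) if pred_t else np.zeros((n, 0)),
        pred_loadings=np.array(pred_p).reshape(len(pred_p), k),
        y_loadings=np.array(y_load).reshape(len(y_load), yd.shape[1]),
        ss_comp=np.asarray(ss, dtype=float),
        x_residual=xw,
    )


def vip(model: OPLSModel, threshold: float = 1.0) -> VIPResult:
    """Per-variable importance in projection of the predictive components.

    VIP_k = sqrt( K_p * Σ_a w_ak² · SS_comp,a / SS_cum ) with unit-norm
    weights per component, so Σ VIP² = K_p — the average VIP is 1.
    Variables with VIP above ``threshold`` (default 1) are selected.
    """
    if model.n_predictive < 1:
        raise ValueError("model has no predictive components")
    ss_cum = model.ss_cum
    if ss_cum <= 0:
        raise ValueError("zero cumulative explained sum of squares")
    w2 = model.pred_weights**2  # (A, K); rows unit norm
    scores = np.sqrt(model.k_p * (model.ss_comp @ w2) / ss_cum)
    return VIPResult(vip=scores, threshold=threshold)


def select_variables(x: PixelMatrix, vips: VIPResult) -> PixelMatrix:
    """Restrict X to the VIP-selected columns, preserving the block map."""
    if vips.vip.size != x.n_columns:
        raise DimensionError("VIP length must equal X column count")
    selected = vips.selected
    if not selected.any():
        raise ValueError(
            f"no variable exceeds VIP threshold {vips.threshold}; lower the threshold"
        )
    return x.column_slice(selected)


def block_average(image: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping factor x factor blocks of a 2D/3D image."""
    h, w = image.shape[:2]
    if h % factor or w % factor:
        raise DimensionError(
            f"grid {image.shape[:2]} not divisible by factor {factor}"
        )
    shape = (h // factor, factor, w // factor, factor) + image.shape[2:]
    return image.reshape(shape).mean(axis=(1, 3))


def downsample_hyperspectral(
    cube: SpectralImageCube,
    target_grid: tuple[int, int],
    T: AffineTransform2D | None = None,
    partition: PixelPartition | None = None,
) -> PixelMatrix:
    """Block-average microscopy channels into each MSI pixel footprint.

    ``T`` (from registration) is applied at microscopy resolution first;
    the warped grid must be an integer multiple of ``target_grid``. With
    a ``partition``, rows follow its data-pixel order so the result can
    serve directly as a Y matrix next to an MSI pixel matrix.
    """
    if T is not None and not np.array_equal(T.matrix, np.eye(3)):
        cube = apply_transform(cube, T, "bicubic")
    th, tw = target_grid
    if cube.height % th or cube.width % tw or cube.height // th != cube.width // tw:
        raise DimensionError(
            f"microscopy grid {(cube.height, cube.width)} is not an integer "
            f"multiple of target grid {target_grid} after transform"
        )
    factor = cube.height // th
    lowres = block_average(cube.values, factor)
    if partition is None:
        rows, cols = np.indices((th, tw))
        coords = np.stack([rows.ravel(), cols.ravel()], axis=1)
    else:
        if partition.shape != target_grid:
            raise DimensionError("partition grid does not match target grid")
        coords = partition.data_pixel_index
    return PixelMatrix(
        data=lowres[coords[:, 0], coords[:, 1], :],
        coordinates=coords,
        variables=cube.variables,
        block_map=[(cube.modality_tag, 0, cube.n_variables)],
        grid_shape=target_grid,
    )


@dataclass
class IonFusion:
    """Fusion products for a single selected ion."""

    variable: float
    reconstruction_score: float
    predicted_highres: np.ndarray
    measured_image: np.ndarray  # original, non-interpolated ion image
    residual_image: np.ndarray  # absolute residual at MSI resolution
    ci_image: np.ndarray  # 95% CI half-width at microscopy resolution
    coefficients: np.ndarray
    flagged: bool = False  # poor reconstruction


@dataclass
class FusionModel:
    ions: list[IonFusion]
    upscale: int
    grid_shape: tuple[int, int]
    config: dict = field(default_factory=dict)

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [i.variable for i in self.ions],
                "reconstruction_score": [i.reconstruction_score for i in self.ions],
                "flagged": [i.flagged for i in self.ions],
            }
        )


def _texture_features(values: np.ndarray, radius: int = 1) -> np.ndarray:
    """Local mean and variance per channel (uniform window)."""
    from scipy.ndimage import uniform_filter

    size = 2 * radius + 1
    feats = []
    for k in range(values.shape[2]):
        chan = values[:, :, k]
        mean = uniform_filter(chan, size=size)
        sq = uniform_filter(chan**2, size=size)
        feats.extend([mean, np.maximum(sq - mean**2, 0.0)])
    return np.stack(feats, axis=-1)


def fuse(
    x_selected: PixelMatrix,
    microscopy: SpectralImageCube,
    T: AffineTransform2D | None = None,
    config: dict | None = None,
) -> FusionModel:
    """Per-ion PLS fusion predicting MSI ion distributions at microscopy
    resolution.

    For each selected ion a PLS regression is trained from microscopy
    features block-averaged to MSI pixels; applying the same (linear)
    regression to the full-resolution features yields the high-resolution
    prediction, whose block average reproduces the MSI-resolution
    prediction exactly and defines the reconstruction score
    100·(1 − SS_res/SS_tot). 95% confidence half-widths come from
    prediction-variance propagation in the PLS latent space.
    """
    config = dict(config or {})
    n_components = int(config.get("pls_components", 0))
    use_texture = bool(config.get("texture_features", False))
    flag_below = float(config.get("flag_below", 25.0))

    if T is not None and not np.array_equal(T.matrix, np.eye(3)):
        microscopy = apply_transform(microscopy, T, "bicubic")
    grid = x_selected.grid_shape
    if microscopy.height % grid[0] or microscopy.width % grid[1]:
        raise DimensionError("microscopy is not registered onto an integer multiple of the MSI grid")
    factor = microscopy.height // grid[0]

    hi_feats = microscopy.values
    if use_texture:
        hi_feats = np.concatenate([hi_feats, _texture_features(hi_feats)], axis=-1)
    lo_feats = block_average(hi_feats, factor)
    coords = x_selected.coordinates
    f_train = lo_feats[coords[:, 0], coords[:, 1], :]
    n_feats = f_train.shape[1]
    if n_components <= 0:
        n_components = min(10, n_feats, x_selected.n_rows - 1)
    hi_flat = hi_feats.reshape(-1, n_feats)

    partition = PixelPartition(
        shape=grid,
        data_pixel_index=coords,
        black_pixel_index=_complement_coords(grid, coords),
    )

    ions: list[IonFusion] = []
    for j in range(x_selected.n_columns):
        yv = x_selected.data[:, j]
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        if ss_tot == 0:
            warnings.warn(
                f"ion {x_selected.variables[j]} has zero variance; skipped",
                stacklevel=2,
            )
            continue
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(f_train, yv)
        pred_lo_rows = pls.predict(f_train).ravel()
        ss_res = float(np.sum((yv - pred_lo_rows) ** 2))
        score = 100.0 * (1.0 - ss_res / ss_tot)

        pred_hi = pls.predict(hi_flat).ravel().reshape(microscopy.height, microscopy.width)
        residual = restore_score_image(
            np.abs(yv - pred_lo_rows), partition, background=0.0
        )
        ci = _prediction_ci_halfwidth(pls, f_train, yv, pred_lo_rows, hi_flat).reshape(
            microscopy.height, microscopy.width
        )
        ions.append(
            IonFusion(
                variable=float(x_selected.variables[j]),
                reconstruction_score=score,
                predicted_highres=pred_hi,
                measured_image=restore_score_image(yv, partition, background=0.0),
                residual_image=residual,
                ci_image=ci,
                coefficients=pls.coef_.ravel().copy(),
                flagged=score < flag_below,
            )
        )
    return FusionModel(ions=ions, upscale=factor, grid_shape=grid, config=config)


def _complement_coords(grid: tuple[int, int], coords: np.ndarray) -> np.ndarray:
    mask = np.ones(grid, dtype=bool)
    mask[coords[:, 0], coords[:, 1]] = False
    rows, cols = np.nonzero(mask)
    return np.stack([rows, cols], axis=1)


def _prediction_ci_halfwidth(
    pls: PLSRegression,
    f_train: np.ndarray,
    y: np.ndarray,
    y_fit: np.ndarray,
    f_new: np.ndarray,
) -> np.ndarray:
    """95% half-width of the predicted mean via latent-space leverage.

    The PLS prediction is linear in the latent scores t = (f - mean)·R,
    so the standard error of the predicted mean at a new point follows
    the usual regression propagation s·sqrt(t (TᵀT)⁻¹ tᵀ)."""
    t_train = pls.transform(f_train)
    n, a = t_train.shape
    dof = max(n - a - 1, 1)
    s2 = float(np.sum((y - y_fit) ** 2)) / dof
    gram_inv = np.linalg.pinv(t_train.T @ t_train)
    t_new = pls.transform(f_new)
    leverage = np.einsum("ij,jk,ik->i", t_new, gram_inv, t_new)
    tq = stats.t.ppf(0.975, dof)
    return tq * np.sqrt(s2 * np.maximum(leverage, 0.0))


def fusion_report(model: FusionModel, out_dir: str | Path) -> pd.DataFrame:
    """Write per-ion measured/predicted/residual/CI images (TIFF) and a
    CSV summary of reconstruction scores; returns the summary table."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ion in model.ions:
        tag = f"mz_{ion.variable:.4f}"
        tifffile.imwrite(out_dir / f"{tag}_measured.tiff", ion.measured_image.astype(np.float32))
        tifffile.imwrite(out_dir / f"{tag}_predicted.tiff", ion.predicted_highres.astype(np.float32))
        tifffile.imwrite(out_dir / f"{tag}_residual.tiff", ion.residual_image.astype(np.float32))
        tifffile.imwrite(out_dir / f"{tag}_ci95.tiff", ion.ci_image.astype(np.float32))
    table = model.score_table()
    table.to_csv(out_dir / "reconstruction_scores.csv", index=False)
    return table
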