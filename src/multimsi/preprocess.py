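"""Spectral preprocessing: baseline correction, RMS normalization, peak
region extraction, ROI subsetting."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import minimum_filter1d

from multimsi.cube import SpectralImageCube, partition_pixels


class ParameterError(ValueError):
    pass


class EmptyResultError(ValueError):
    pass


def baseline_correct(cube: SpectralImageCube, window: int = 101) -> SpectralImageCube:
    """Subtract a per-spectrum rolling-minimum baseline.

    The baseline at each variable is the minimum intensity within a
    centered window of ``window`` variables, so output intensities are
    always >= 0 and isolated peaks keep their height.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > cube.n_variables:
        raise ParameterError(
            f"window {window} exceeds variable count {cube.n_variables}"
        )
    baseline = minimum_filter1d(cube.values, size=window, axis=2, mode="nearest")
    return replace(cube, values=cube.values - baseline)


def rms_normalize(cube: SpectralImageCube) -> SpectralImageCube:
    """Divide each data-pixel spectrum by its own root-mean-square intensity.

    Black (all-zero) pixels are untouched; every data-pixel spectrum has
    RMS exactly 1 afterwards.
    """
    rms = np.sqrt(np.mean(cube.values**2, axis=2, keepdims=True))
    if not np.any(rms > 0):
        raise ParameterError("cube has no data pixels to normalize")
    scale = np.where(rms > 0, rms, 1.0)
    return replace(cube, values=cube.values / scale)


def peak_regions(
    mean_spectrum: np.ndarray, noise_factor: float = 3.0
) -> tuple[np.ndarray, float]:
    """Boolean mask of variables inside peak regions of a mean spectrum.

    A peak region is a contiguous run of variables whose mean intensity
    exceeds median + ``noise_factor`` x MAD of the mean spectrum (the
    median offset makes the rule robust to residual baseline). A factor
    of 0 thresholds at zero and keeps every column. Returns
    (mask, threshold).
    """
    mean_spectrum = np.asarray(mean_spectrum, dtype=float)
    if noise_factor == 0:
        return np.ones(mean_spectrum.size, dtype=bool), 0.0
    med = np.median(mean_spectrum)
    mad = np.median(np.abs(mean_spectrum - med))
    threshold = med + noise_factor * mad
    return mean_spectrum >= threshold, float(threshold)


def peak_extract(cube: SpectralImageCube, noise_factor: float = 3.0) -> SpectralImageCube:
    """Keep only variable columns lying inside peak regions of the dataset
    mean spectrum; noise between peaks is dropped.

    All data points over a peak are retained — no centroiding or binning,
    so overlapping peaks stay as separate column runs.
    """
    if noise_factor < 0:
        raise ParameterError("noise_factor must be nonnegative")
    partition = partition_pixels(cube)
    if partition.n_data == 0:
        raise ParameterError("no data pixels; mean spectrum undefined")
    idx = partition.data_pixel_index
    mean_spectrum = cube.values[idx[:, 0], idx[:, 1], :].mean(axis=0)
    mask, threshold = peak_regions(mean_spectrum, noise_factor)
    if not mask.any():
        raise EmptyResultError(
            f"no variable exceeds the peak threshold {threshold:.4g}"
        )
    return replace(
        cube, values=cube.values[:, :, mask], variables=cube.variables[mask]
    )


def roi_subset(cube: SpectralImageCube, mask: np.ndarray) -> SpectralImageCube:
    """Crop a cube to the bounding box of a binary ROI mask.

    Outside-mask pixels inside the box are zeroed (become black). The
    crop offset is accumulated into ``origin`` so absolute coordinates
    remain recoverable.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cube.height, cube.width):
        raise ParameterError(
            f"mask shape {mask.shape} does not match grid {(cube.height, cube.width)}"
        )
    if not mask.any():
        raise ParameterError("empty ROI mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    values = cube.values[r0:r1, c0:c1, :] * mask[r0:r1, c0:c1, None]
    return replace(
        cube,
        values=values,
        origin=(cube.origin[0] + int(r0), cube.origin[1] + int(c0)),
    )
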