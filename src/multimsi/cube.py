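"""Core imaging containers: spectral cubes, pixel partitions, pixel matrices.

Grid convention used throughout the package: row-major, 0-based indices,
pixel centers; a pixel is addressed as (row, col). Intensity arrays are
stored as ``values[row, col, variable]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MODALITY_TAGS = ("lipid_neg", "lipid_pos", "peptide", "hyperspectral")


class DimensionError(ValueError):
    """Grid / shape mismatch between imaging objects."""


@dataclass
class SpectralImageCube:
    """Pixel grid with a per-pixel spectral vector.

    Parameters
    ----------
    values : ndarray, shape (height, width, n_variables)
        Nonnegative intensities (negatives only appear after centering).
    variables : ndarray, shape (n_variables,)
        Strictly increasing channel identifiers (m/z for MSI, nm for
        hyperspectral bands).
    pixel_size : float
        Isotropic pixel edge length in micrometers.
    modality_tag : str
        One of ``lipid_neg``, ``lipid_pos``, ``peptide``, ``hyperspectral``.
    origin : tuple of int
        Absolute (row, col) of this cube's (0, 0) pixel; retained by
        :func:`~multimsi.preprocess.roi_subset` so cropped cubes keep
        their original coordinates.
    """

    values: np.ndarray
    variables: np.ndarray
    pixel_size: float = 10.0
    modality_tag: str = "lipid_neg"
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.variables = np.asarray(self.variables, dtype=np.float64)
        if self.values.ndim != 3:
            raise DimensionError(
                f"values must be (height, width, n_variables), got shape {self.values.shape}"
            )
        if self.values.shape[2] != self.variables.size:
            raise DimensionError(
                f"{self.values.shape[2]} intensity channels vs {self.variables.size} variables"
            )
        if self.modality_tag not in MODALITY_TAGS:
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if self.variables.size > 1 and not np.all(np.diff(self.variables) > 0):
            raise ValueError("variable identifiers must be strictly increasing")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return self.variables.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "SpectralImageCube":
        return replace(self, values=self.values.copy(), variables=self.variables.copy())

    def total_ion_image(self) -> np.ndarray:
        """Per-pixel sum over variables (the TIC image)."""
        return self.values.sum(axis=2)


@dataclass
class PixelPartition:
    """Split of a grid into data pixels (TIC > 0) and black pixels (TIC == 0)."""

    shape: tuple[int, int]
    data_pixel_index: np.ndarray  # (n_data, 2) int rows of (row, col)
    black_pixel_index: np.ndarray  # (n_black, 2)

    def __post_init__(self) -> None:
        self.data_pixel_index = np.asarray(self.data_pixel_index, dtype=np.intp).reshape(-1, 2)
        self.black_pixel_index = np.asarray(self.black_pixel_index, dtype=np.intp).reshape(-1, 2)
        n = self.data_pixel_index.shape[0] + self.black_pixel_index.shape[0]
        if n != self.shape[0] * self.shape[1]:
            raise DimensionError("partition does not cover the grid")

    @property
    def n_data(self) -> int:
        return self.data_pixel_index.shape[0]

    def data_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[self.data_pixel_index[:, 0], self.data_pixel_index[:, 1]] = True
        return mask


@dataclass
class PixelMatrix:
    """Data-pixel rows x spectral-variable columns, with provenance.

    ``block_map`` assigns each column range to its source modality so
    concatenated multimodal matrices stay separable.
    """

    data: np.ndarray  # (n_data_pixels, n_columns)
    coordinates: np.ndarray  # (n_data_pixels, 2) of (row, col)
    variables: np.ndarray
    block_map: list[tuple[str, int, int]] = field(default_factory=list)  # (tag, start, stop)
    grid_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.intp).reshape(-1, 2)
        self.variables = np.asarray(self.variables, dtype=np.float64)
        if self.data.shape[0] != self.coordinates.shape[0]:
            raise DimensionError("row count must equal number of data-pixel coordinates")
        if self.data.shape[1] != self.variables.size:
            raise DimensionError("column count must equal number of variables")
        stops = 0
        for _tag, start, stop in self.block_map:
            if start != stops or stop <= start:
                raise ValueError("block_map ranges must be contiguous and non-overlapping")
            stops = stop
        if self.block_map and stops != self.data.shape[1]:
            raise ValueError("block_map must cover all columns")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def block(self, tag: str) -> np.ndarray:
        for t, start, stop in self.block_map:
            if t == tag:
                return self.data[:, start:stop]
        raise KeyError(tag)

    def column_slice(self, columns: np.ndarray) -> "PixelMatrix":
        """Restrict to a boolean/integer column selection, keeping block_map."""
        columns = np.asarray(columns)
        if columns.dtype == bool:
            idx = np.flatnonzero(columns)
        else:
            idx = columns.astype(np.intp)
        new_map: list[tuple[str, int, int]] = []
        pos = 0
        for tag, start, stop in self.block_map:
            kept = int(np.count_nonzero((idx >= start) & (idx < stop)))
            if kept:
                new_map.append((tag, pos, pos + kept))
                pos += kept
        return PixelMatrix(
            data=self.data[:, idx],
            coordinates=self.coordinates,
            variables=self.variables[idx],
            block_map=new_map,
            grid_shape=self.grid_shape,
        )


def partition_pixels(cube: SpectralImageCube) -> PixelPartition:
    """Classify pixels: black iff the summed spectrum is exactly zero."""
    tic = cube.total_ion_image()
    rows, cols = np.indices(tic.shape)
    black = tic == 0
    coords = np.stack([rows.ravel(), cols.ravel()], axis=1)
    flat_black = black.ravel()
    return PixelPartition(
        shape=tic.shape,
        data_pixel_index=coords[~flat_black],
        black_pixel_index=coords[flat_black],
    )


def to_pixel_matrix(cube: SpectralImageCube, partition: PixelPartition) -> PixelMatrix:
    """Flatten data pixels into a rows-by-variables matrix (coordinates kept)."""
    if partition.shape != (cube.height, cube.width):
        raise DimensionError(
            f"partition grid {partition.shape} does not match cube grid {(cube.height, cube.width)}"
        )
    idx = partition.data_pixel_index
    return PixelMatrix(
        data=cube.values[idx[:, 0], idx[:, 1], :],
        coordinates=idx,
        variables=cube.variables,
        block_map=[(cube.modality_tag, 0, cube.n_variables)],
        grid_shape=(cube.height, cube.width),
    )


def concat_pixel_matrices(matrices: list[PixelMatrix]) -> PixelMatrix:
    """Column-concatenate matrices sharing one pixel index."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_rows != first.n_rows or not np.array_equal(m.coordinates, first.coordinates):
            raise DimensionError("all matrices must share identical pixel coordinates")
    block_map: list[tuple[str, int, int]] = []
    pos = 0
    for m in matrices:
        for tag, start, stop in m.block_map:
            block_map.append((tag, pos + start, pos + stop))
        pos += m.n_columns
    return PixelMatrix(
        data=np.concatenate([m.data for m in matrices], axis=1),
        coordinates=first.coordinates,
        variables=np.concatenate([m.variables for m in matrices]),
        block_map=block_map,
        grid_shape=first.grid_shape,
    )


def restore_score_image(
    scores: np.ndarray,
    partition: PixelPartition,
    grid: tuple[int, int] | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Put a per-data-pixel score vector back on the image grid.

    Exact inverse of :func:`to_pixel_matrix` row ordering; black pixels
    get ``background``. No interpolation is applied.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    shape = grid if grid is not None else partition.shape
    if scores.size != partition.n_data:
        raise DimensionError(
            f"{scores.size} scores for {partition.n_data} data pixels"
        )
    img = np.full(shape, background, dtype=np.float64)
    idx = partition.data_pixel_index
    img[idx[:, 0], idx[:, 1]] = scores
    return img
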