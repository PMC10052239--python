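"""2D affine transforms between pixel coordinate frames and cube resampling.

Point convention: (x, y) = (column, row), matching the homogeneous-matrix
convention of scikit-image, so ``T @ [x, y, 1]`` maps a point in the
``frame_from`` grid to the ``frame_to`` grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import transform as sktransform

from multimsi.cube import SpectralImageCube

INTERP_ORDERS = {"nearest": 0, "linear": 1, "bicubic": 3}


@dataclass
class AffineTransform2D:
    """3x3 homogeneous affine map between two modality frames."""

    matrix: np.ndarray
    frame_from: str = "moving"
    frame_to: str = "fixed"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        if not np.allclose(self.matrix[2], [0.0, 0.0, 1.0]):
            raise ValueError("last row of a homogeneous affine must be [0, 0, 1]")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("affine transform is not invertible")

    @classmethod
    def identity(cls, frame_from: str = "moving", frame_to: str = "fixed") -> "AffineTransform2D":
        return cls(np.eye(3), frame_from, frame_to)

    @classmethod
    def from_params(
        cls,
        translation: tuple[float, float] = (0.0, 0.0),
        rotation: float = 0.0,
        scale: tuple[float, float] = (1.0, 1.0),
        shear: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
        frame_from: str = "moving",
        frame_to: str = "fixed",
    ) -> "AffineTransform2D":
        """Build rotation/scale/shear about ``center`` plus a translation."""
        t = sktransform.AffineTransform(
            scale=scale, rotation=rotation, shear=shear
        ).params
        cx, cy = center
        to_origin = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        back = np.array([[1, 0, cx + translation[0]], [0, 1, cy + translation[1]], [0, 0, 1.0]])
        return cls(back @ t @ to_origin, frame_from, frame_to)

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(
            np.linalg.inv(self.matrix), self.frame_to, self.frame_from
        )

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the map applying ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.matrix @ other.matrix, other.frame_from, self.frame_to
        )

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        return out[:, :2]

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "frame_from": self.frame_from,
            "frame_to": self.frame_to,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(np.asarray(d["matrix"]), d["frame_from"], d["frame_to"])


def warp_image(
    image: np.ndarray,
    T: AffineTransform2D,
    output_shape: tuple[int, int] | None = None,
    interpolation: str = "bicubic",
) -> np.ndarray:
    """Resample a single 2D image from the moving frame into the fixed frame."""
    if interpolation not in INTERP_ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(INTERP_ORDERS)}")
    if output_shape is None:
        output_shape = image.shape
    if np.array_equal(T.matrix, np.eye(3)) and output_shape == image.shape:
        return image.copy()
    tform = sktransform.AffineTransform(matrix=np.linalg.inv(T.matrix))
    return sktransform.warp(
        image.astype(np.float64),
        tform,
        output_shape=output_shape,
        order=INTERP_ORDERS[interpolation],
        mode="constant",
        cval=0.0,
        clip=True,
        preserve_range=True,
    )


def apply_transform(
    cube: SpectralImageCube,
    T: AffineTransform2D,
    interpolation: str = "bicubic",
    output_shape: tuple[int, int] | None = None,
) -> SpectralImageCube:
    """Geometrically resample every variable channel of a cube identically.

    ``T`` maps the moving (cube) frame to the fixed frame; out-of-domain
    pixels are 0 (black). Default interpolation is bicubic.
    """
    if output_shape is None:
        output_shape = (cube.height, cube.width)
    if np.array_equal(T.matrix, np.eye(3)) and output_shape == (cube.height, cube.width):
        return cube.copy()
    out = np.empty(output_shape + (cube.n_variables,))
    for k in range(cube.n_variables):
        out[:, :, k] = warp_image(cube.values[:, :, k], T, output_shape, interpolation)
    return replace(cube, values=out)
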