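"""Image similarity metrics: MSE, Jaccard, entropy, joint entropy, mutual
information (all histogram metrics on 8-bit quantized views, in bits) and
structural similarity.

All metrics are deterministic — no sampling anywhere — and therefore
bit-identical across runs.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from multimsi.cube import DimensionError


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"image shapes differ: {a.shape} vs {b.shape}")


def quantize_uint8(
    a: np.ndarray, b: np.ndarray | None = None, joint: bool = True
) -> tuple[np.ndarray, ...]:
    """Linear min-max rescale to [0, 255] then floor to integer IDs.

    With ``joint=True`` (default) the min/max are pooled over both images
    so the intensity->ID mapping is identical for the pair; per-image
    scaling is available for the alternate reading.
    """
    imgs = [np.asarray(a, dtype=float)] + ([] if b is None else [np.asarray(b, dtype=float)])
    out = []
    if joint and b is not None:
        lo = min(img.min() for img in imgs)
        hi = max(img.max() for img in imgs)
    for img in imgs:
        if not joint or b is None:
            lo, hi = img.min(), img.max()
        if hi == lo:
            out.append(np.zeros(img.shape, dtype=np.uint8))
        else:
            q = np.floor((img - lo) / (hi - lo) * 256.0)
            out.append(np.clip(q, 0, 255).astype(np.uint8))
    return tuple(out)


def mse(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Mean square error (1/(m*n)) * sum((I - K)^2)."""
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    _check_shapes(fixed, moving)
    return float(np.mean((fixed - moving) ** 2))


def jaccard(
    a: np.ndarray, b: np.ndarray, mode: str = "multiclass", joint_scale: bool = True
) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| on 8-bit quantized images.

    ``multiclass`` (default): per intensity label present in either image,
    intersection/union of the label's pixel sets, averaged over labels —
    the per-label set convention. ``binary``: threshold > 0 foreground.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    _check_shapes(a_arr, b_arr)
    qa, qb = quantize_uint8(a_arr, b_arr, joint=joint_scale)
    if mode == "binary":
        fa, fb = qa > 0, qb > 0
        union = np.count_nonzero(fa | fb)
        if union == 0:
            return 1.0
        return float(np.count_nonzero(fa & fb) / union)
    if mode != "multiclass":
        raise ValueError("mode must be 'multiclass' or 'binary'")
    labels = np.union1d(np.unique(qa), np.unique(qb))
    scores = []
    for lab in labels:
        ma, mb = qa == lab, qb == lab
        union = np.count_nonzero(ma | mb)
        scores.append(np.count_nonzero(ma & mb) / union)
    return float(np.mean(scores))


def histogram_distribution(a: np.ndarray) -> np.ndarray:
    """Probability distribution p_X(x) over the 256 quantized intensity IDs."""
    (qa,) = quantize_uint8(a)
    counts = np.bincount(qa.ravel(), minlength=256)
    return counts / counts.sum()


def _entropy_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]  # lim p->0 of -p log p is 0
    return float(-np.sum(p * np.log2(p)))


def entropy(a: np.ndarray) -> float:
    """Shannon entropy H(A) in bits over the 256-level histogram."""
    return _entropy_from_probs(histogram_distribution(np.asarray(a, dtype=float)))


def joint_entropy(a: np.ndarray, b: np.ndarray, joint_scale: bool = True) -> float:
    """Joint entropy H(A, B) in bits over the 256x256 joint histogram."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    _check_shapes(a_arr, b_arr)
    qa, qb = quantize_uint8(a_arr, b_arr, joint=joint_scale)
    joint_ids = qa.ravel().astype(np.int64) * 256 + qb.ravel()
    counts = np.bincount(joint_ids, minlength=256 * 256)
    return _entropy_from_probs(counts / counts.sum())


def mutual_information(a: np.ndarray, b: np.ndarray, joint_scale: bool = True) -> float:
    """MI(A, B) = H(A) + H(B) - H(A, B), in bits; symmetric, >= 0."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    _check_shapes(a_arr, b_arr)
    qa, qb = quantize_uint8(a_arr, b_arr, joint=joint_scale)
    h_a = _entropy_from_probs(np.bincount(qa.ravel(), minlength=256) / qa.size)
    h_b = _entropy_from_probs(np.bincount(qb.ravel(), minlength=256) / qb.size)
    return h_a + h_b - joint_entropy_quantized(qa, qb)


def joint_entropy_quantized(qa: np.ndarray, qb: np.ndarray) -> float:
    joint_ids = qa.ravel().astype(np.int64) * 256 + qb.ravel()
    counts = np.bincount(joint_ids, minlength=256 * 256)
    return _entropy_from_probs(counts / counts.sum())


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity (Gaussian 11x11 window, sigma 1.5,
    K1=0.01, K2=0.03) after rescaling both images to a common range."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    _check_shapes(a_arr, b_arr)
    lo = min(a_arr.min(), b_arr.min())
    hi = max(a_arr.max(), b_arr.max())
    if hi == lo:
        return 1.0
    a_s = (a_arr - lo) / (hi - lo)
    b_s = (b_arr - lo) / (hi - lo)
    return float(
        structural_similarity(
            a_s,
            b_s,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def metric_suite(fixed: np.ndarray, moving: np.ndarray) -> dict[str, float]:
    """All evaluation metrics for one registered image pair."""
    return {
        "mse": mse(fixed, moving),
        "ssim": ssim(fixed, moving),
        "jaccard": jaccard(fixed, moving),
        "mutual_information": mutual_information(fixed, moving),
        "h_a": entropy(fixed),
        "h_b": entropy(moving),
        "h_ab": joint_entropy(fixed, moving),
    }
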