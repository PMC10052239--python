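"""Multiblock chemometrics: multimodal matrix assembly, centering/scaling,
PCA, and an OnPLS-style decomposition into globally joint, locally joint
and unique variation with score-image reconstruction.

The joint-part extraction is a documented sequential-deflation scheme:
globally joint components are consensus directions maximizing shared
covariance across all blocks, locally joint components do the same on
deflated data for explicit block subsets, and unique components are the
dominant remaining principal directions of each block constrained to be
orthogonal to every block's joint score space. Each block therefore
satisfies the exact additive reconstruction

    X_b = global part + local parts + unique part + residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from multimsi.cube import (
    DimensionError,
    PixelMatrix,
    PixelPartition,
    SpectralImageCube,
    restore_score_image,
    to_pixel_matrix,
)

__all__ = [
    "MultimodalDataset",
    "OnPLSModel",
    "assemble_multimodal",
    "center_scale",
    "cross_validate_components",
    "fit_onpls",
    "fit_pca",
    "restore_score_image",
]


@dataclass
class MultimodalDataset:
    """Registered blocks sharing one pixel index, plus the common partition."""

    blocks: list[PixelMatrix]
    common_mask: PixelPartition
    centered: bool = False
    preprocessing: list[dict] = field(default_factory=list)  # per block

    def __post_init__(self) -> None:
        first = self.blocks[0]
        for b in self.blocks[1:]:
            if b.n_rows != first.n_rows or not np.array_equal(
                b.coordinates, first.coordinates
            ):
                raise DimensionError("all blocks must share identical pixel coordinates")
        for b in self.blocks:
            if not np.all(np.isfinite(b.data)):
                raise ValueError("blocks must not contain missing values")

    @property
    def n_rows(self) -> int:
        return self.blocks[0].n_rows

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([b.data for b in self.blocks], axis=1)


def assemble_multimodal(cubes: list[SpectralImageCube]) -> MultimodalDataset:
    """Crop registered cubes to their common spatial area and align rows.

    A pixel is black if black in ANY block, which guarantees the matrix
    has no missing values; all blocks then share identical row order and
    coordinates.
    """
    if not cubes:
        raise ValueError("no cubes supplied")
    shape = (cubes[0].height, cubes[0].width)
    for c in cubes[1:]:
        if (c.height, c.width) != shape:
            raise DimensionError("cubes must be resampled to one common grid first")
    common = np.ones(shape, dtype=bool)
    for c in cubes:
        common &= c.total_ion_image() > 0
    if not common.any():
        raise ValueError("empty intersection of data masks")
    rows, cols = np.indices(shape)
    coords = np.stack([rows.ravel(), cols.ravel()], axis=1)
    flat = common.ravel()
    partition = PixelPartition(
        shape=shape, data_pixel_index=coords[flat], black_pixel_index=coords[~flat]
    )
    return MultimodalDataset(
        blocks=[to_pixel_matrix(c, partition) for c in cubes], common_mask=partition
    )


def center_scale(dataset: MultimodalDataset, mode: str = "mean_center") -> MultimodalDataset:
    """Per-column mean centering, optionally with unit-variance scaling.

    Zero-variance columns under ``unit_variance`` are flagged and left
    centered only. Parameters are stored for the inverse transform.
    """
    if mode not in ("mean_center", "unit_variance"):
        raise ValueError("mode must be 'mean_center' or 'unit_variance'")
    if dataset.n_rows < 2:
        raise ValueError("need at least 2 rows")
    new_blocks = []
    records = []
    for b in dataset.blocks:
        mean = b.data.mean(axis=0)
        data = b.data - mean
        scale = np.ones(b.n_columns)
        constant = np.zeros(b.n_columns, dtype=bool)
        if mode == "unit_variance":
            sd = data.std(axis=0, ddof=1)
            constant = sd == 0
            if constant.any():
                warnings.warn(
                    f"{constant.sum()} zero-variance column(s) left centered only",
                    stacklevel=2,
                )
            scale = np.where(constant, 1.0, sd)
            data = data / scale
        records.append({"mean": mean, "scale": scale, "constant": constant, "mode": mode})
        new_blocks.append(
            PixelMatrix(
                data=data,
                coordinates=b.coordinates,
                variables=b.variables,
                block_map=b.block_map,
                grid_shape=b.grid_shape,
            )
        )
    return MultimodalDataset(
        blocks=new_blocks,
        common_mask=dataset.common_mask,
        centered=True,
        preprocessing=records,
    )


def inverse_center_scale(dataset: MultimodalDataset) -> MultimodalDataset:
    """Undo :func:`center_scale` using the stored per-block parameters."""
    if not dataset.preprocessing:
        raise ValueError("dataset carries no preprocessing record")
    blocks = []
    for b, rec in zip(dataset.blocks, dataset.preprocessing):
        data = b.data * rec["scale"] + rec["mean"]
        blocks.append(
            PixelMatrix(
                data=data,
                coordinates=b.coordinates,
                variables=b.variables,
                block_map=b.block_map,
                grid_shape=b.grid_shape,
            )
        )
    return MultimodalDataset(blocks=blocks, common_mask=dataset.common_mask)


def _svd_sign_fix(u: np.ndarray, s: np.ndarray, vt: np.ndarray):
    """Deterministic sign: largest-magnitude loading entry positive."""
    for k in range(vt.shape[0]):
        if vt[k, np.argmax(np.abs(vt[k]))] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    return u, s, vt


def fit_pca(
    data: np.ndarray | MultimodalDataset, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA of a centered matrix (or concatenated dataset).

    Returns (scores, loadings, explained_variance); loadings are rows,
    explained variance is non-increasing, signs deterministic.
    """
    if isinstance(data, MultimodalDataset):
        x = data.concatenated()
    else:
        x = np.asarray(data, dtype=float)
    if n_components > min(x.shape):
        warnings.warn(
            f"n_components={n_components} exceeds {min(x.shape)}; truncating",
            stacklevel=2,
        )
        n_components = min(x.shape)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = _svd_sign_fix(u, s, vt)
    k = n_components
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    explained = s[:k] ** 2 / max(x.shape[0] - 1, 1)
    return scores, loadings, explained


@dataclass
class OnPLSModel:
    """Sequential-deflation multiblock decomposition.

    Per block ``b``: globally joint scores/loadings shared across all
    blocks, locally joint parts per declared block subset, unique parts,
    and the residual; the four parts add back to the (centered) block
    exactly.
    """

    n_blocks: int
    global_scores: list[np.ndarray]  # per block, (n, n_global)
    global_loadings: list[np.ndarray]  # per block, (n_global, p_b)
    local_scores: dict[tuple[int, ...], dict[int, np.ndarray]]
    local_loadings: dict[tuple[int, ...], dict[int, np.ndarray]]
    unique_scores: list[np.ndarray]
    unique_loadings: list[np.ndarray]
    residuals: list[np.ndarray]
    component_counts: dict
    partition: PixelPartition | None = None

    def block_part(self, b: int, part: str) -> np.ndarray:
        """Reconstructed data of one variation part for block b."""
        if part == "global":
            return self.global_scores[b] @ self.global_loadings[b]
        if part == "local":
            total = np.zeros_like(self.residuals[b])
            for subset, per_block in self.local_scores.items():
                if b in per_block:
                    total += per_block[b] @ self.local_loadings[subset][b]
            return total
        if part == "unique":
            return self.unique_scores[b] @ self.unique_loadings[b]
        if part == "residual":
            return self.residuals[b]
        raise ValueError(part)

    def reconstruct_block(self, b: int) -> np.ndarray:
        return (
            self.block_part(b, "global")
            + self.block_part(b, "local")
            + self.block_part(b, "unique")
            + self.residuals[b]
        )

    def variance_fractions(self, b: int, block_data: np.ndarray) -> dict[str, float]:
        total = float(np.sum(block_data**2))
        if total == 0:
            return {p: 0.0 for p in ("global", "local", "unique", "residual")}
        return {
            p: float(np.sum(self.block_part(b, p) ** 2)) / total
            for p in ("global", "local", "unique", "residual")
        }

    def score_image(
        self, b: int, part: str, component: int, background: float = np.nan
    ) -> np.ndarray:
        if self.partition is None:
            raise ValueError("model has no pixel partition attached")
        if part == "global":
            vec = self.global_scores[b][:, component]
        elif part == "unique":
            vec = self.unique_scores[b][:, component]
        else:
            raise ValueError("score_image supports 'global' and 'unique' parts")
        return restore_score_image(vec, self.partition, background=background)

    def local_score_image(
        self, subset: tuple[int, ...], b: int, component: int, background: float = np.nan
    ) -> np.ndarray:
        vec = self.local_scores[subset][b][:, component]
        return restore_score_image(vec, self.partition, background=background)


def _consensus_component(blocks: list[np.ndarray], tol: float = 1e-12, max_iter: int = 1000):
    """One consensus direction maximizing shared covariance across blocks.

    Alternating update: block weights w_b ∝ X_bᵀ t, block scores
    t_b = X_b w_b, consensus t ∝ Σ t_b (consensus-PCA iteration).
    Returns per-block (score, loading) pairs for rank-1 deflation.
    """
    n_blocks = len(blocks)
    if n_blocks == 1:
        u, s, vt = np.linalg.svd(blocks[0], full_matrices=False)
        u, s, vt = _svd_sign_fix(u, s, vt)
        t_b = u[:, 0] * s[0]
        p_b = blocks[0].T @ t_b / (t_b @ t_b)
        return [(t_b, p_b)]

    def block_score(x, target):
        w = x.T @ target
        nw = np.linalg.norm(w)
        if nw > 0:
            w /= nw
        return x @ w

    def sharedness(ts):
        # sum of pairwise score covariances, the quantity being maximized
        total = np.sum(ts, axis=0)
        return float(sum((total - t) @ t for t in ts))

    def iterate(t_init):
        ts = list(t_init)
        prev = np.concatenate(ts)
        nrm = np.linalg.norm(prev)
        prev = prev / nrm if nrm else prev
        for _ in range(max_iter):
            # each block's weight is driven by the OTHER blocks' scores, so
            # the criterion rewards cross-block sharedness, not
            # within-block variance
            total = np.sum(ts, axis=0)
            ts = [block_score(x, total - t_b) for x, t_b in zip(blocks, ts)]
            cur = np.concatenate(ts)
            norm = np.linalg.norm(cur)
            if norm == 0:
                break
            cur = cur / norm
            if np.linalg.norm(cur - np.sign(cur @ prev) * prev) < tol:
                break
            prev = cur
        return ts

    concat = np.concatenate(blocks, axis=1)
    if n_blocks == 2:
        # exact optimum of cov(t_0, t_1): leading SVD pair of X_0ᵀ X_1
        u2, _, vt2 = np.linalg.svd(blocks[0].T @ blocks[1], full_matrices=False)
        t_blocks = [blocks[0] @ u2[:, 0], blocks[1] @ vt2[0]]
    else:
        # several deterministic starts; keep the best converged solution
        u, _, _ = np.linalg.svd(concat, full_matrices=False)
        inits = [[block_score(x, u[:, k]) for x in blocks] for k in range(min(3, u.shape[1]))]
        for i in range(n_blocks):
            for j in range(i + 1, n_blocks):
                ui, _, vtj = np.linalg.svd(blocks[i].T @ blocks[j], full_matrices=False)
                seed_t = blocks[i] @ ui[:, 0] + blocks[j] @ vtj[0]
                inits.append([block_score(x, seed_t) for x in blocks])
        best = None
        t_blocks = None
        for t_init in inits:
            ts = iterate(t_init)
            crit = sharedness(ts)
            if best is None or crit > best:
                best, t_blocks = crit, ts
    # deterministic sign: largest-magnitude concatenated weight positive
    consensus = np.sum(t_blocks, axis=0)
    w_cat = concat.T @ consensus
    if w_cat.size and w_cat[np.argmax(np.abs(w_cat))] < 0:
        t_blocks = [-t for t in t_blocks]
        consensus = -consensus
    out = []
    for x, t_seed in zip(blocks, t_blocks):
        others = consensus - t_seed
        w = x.T @ others
        nw = np.linalg.norm(w)
        if nw > 0:
            w /= nw
        t_b = x @ w
        denom = t_b @ t_b
        p_b = x.T @ t_b / denom if denom > 0 else np.zeros(x.shape[1])
        out.append((t_b, p_b))
    return out


def fit_onpls(
    dataset: MultimodalDataset,
    n_global: int,
    n_local: dict[tuple[int, ...], int] | None = None,
    n_unique: dict[int, int] | None = None,
) -> OnPLSModel:
    """Decompose centered blocks into globally joint, locally joint and
    unique variation by sequential deflation.

    1. ``n_global`` consensus components over all blocks, deflated from
       every block.
    2. For each declared subset, consensus components over only those
       blocks on the deflated data.
    3. Per block, dominant remaining principal directions projected onto
       the orthogonal complement of every block's joint score space.
    """
    if dataset.n_blocks < 2:
        raise ValueError("OnPLS needs at least 2 blocks")
    if not dataset.centered:
        warnings.warn("dataset not marked centered; fitting on raw values", stacklevel=2)
    n_local = {tuple(sorted(k)): v for k, v in (n_local or {}).items()}
    n_unique = dict(n_unique or {})
    for subset in n_local:
        if len(subset) < 2 or len(subset) >= dataset.n_blocks:
            raise ValueError(
                f"local subset {subset} must name >= 2 and < all blocks"
            )

    X = [b.data.copy() for b in dataset.blocks]
    n = dataset.n_rows
    g_scores = [np.zeros((n, 0)) for _ in X]
    g_loads = [np.zeros((0, x.shape[1])) for x in X]
    for _ in range(n_global):
        comps = _consensus_component(X)
        for b, (t_b, p_b) in enumerate(comps):
            X[b] -= np.outer(t_b, p_b)
            g_scores[b] = np.column_stack([g_scores[b], t_b])
            g_loads[b] = np.vstack([g_loads[b], p_b])

    l_scores: dict[tuple[int, ...], dict[int, np.ndarray]] = {}
    l_loads: dict[tuple[int, ...], dict[int, np.ndarray]] = {}
    for subset, count in n_local.items():
        l_scores[subset] = {b: np.zeros((n, 0)) for b in subset}
        l_loads[subset] = {b: np.zeros((0, X[b].shape[1])) for b in subset}
        for _ in range(count):
            comps = _consensus_component([X[b] for b in subset])
            for b, (t_b, p_b) in zip(subset, comps):
                X[b] -= np.outer(t_b, p_b)
                l_scores[subset][b] = np.column_stack([l_scores[subset][b], t_b])
                l_loads[subset][b] = np.vstack([l_loads[subset][b], p_b])

    # unique scores of block b must be orthogonal to the joint score
    # spaces of all OTHER blocks (own-block orthogonality comes from the
    # rank-1 deflations themselves)
    def other_joint_basis(b: int) -> np.ndarray:
        cols = [g_scores[c] for c in range(len(X)) if c != b]
        cols += [
            per_block[c]
            for per_block in l_scores.values()
            for c in per_block
            if c != b
        ]
        cols = [c for c in cols if c.shape[1]]
        if not cols:
            return np.zeros((n, 0))
        q, r = np.linalg.qr(np.concatenate(cols, axis=1))
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        return q[:, keep]

    u_scores = [np.zeros((n, 0)) for _ in X]
    u_loads = [np.zeros((0, x.shape[1])) for x in X]
    for b, count in n_unique.items():
        q = other_joint_basis(b)
        for _ in range(count):
            e_proj = X[b] - q @ (q.T @ X[b]) if q.shape[1] else X[b]
            uu, ss, vv = np.linalg.svd(e_proj, full_matrices=False)
            uu, ss, vv = _svd_sign_fix(uu, ss, vv)
            if ss[0] <= 1e-12 * max(1.0, np.abs(X[b]).max()):
                warnings.warn(
                    f"block {b}: residual rank exhausted, truncating unique part",
                    stacklevel=2,
                )
                break
            t_u = uu[:, 0] * ss[0]
            p_u = X[b].T @ t_u / (t_u @ t_u)
            X[b] -= np.outer(t_u, p_u)
            u_scores[b] = np.column_stack([u_scores[b], t_u])
            u_loads[b] = np.vstack([u_loads[b], p_u])

    return OnPLSModel(
        n_blocks=dataset.n_blocks,
        global_scores=g_scores,
        global_loadings=g_loads,
        local_scores=l_scores,
        local_loadings=l_loads,
        unique_scores=u_scores,
        unique_loadings=u_loads,
        residuals=X,
        component_counts={
            "global": n_global,
            "local": n_local,
            "unique": n_unique,
        },
        partition=dataset.common_mask,
    )


def cross_validate_components(
    data: np.ndarray | MultimodalDataset,
    candidate_counts: list[int] | None = None,
    n_folds: int = 7,
    improvement: float = 0.01,
) -> tuple[int, dict[int, float]]:
    """Advise a PCA component count by 7-fold venetian-blind cross-validation.

    Rows are split into interleaved folds by row order; for each
    candidate count the out-of-fold reconstruction Q² is computed, and
    the recommended count is where Q² stops improving by more than
    ``improvement`` absolute. Returns (recommended, {count: Q²}).
    """
    if isinstance(data, MultimodalDataset):
        x = data.concatenated()
    else:
        x = np.asarray(data, dtype=float)
    if x.shape[0] < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} rows")
    if candidate_counts is None:
        candidate_counts = list(range(1, min(11, min(x.shape) + 1)))
    ss_total = float(np.sum(x**2))
    q2: dict[int, float] = {0: 0.0}
    folds = [np.arange(f, x.shape[0], n_folds) for f in range(n_folds)]
    for k in sorted(candidate_counts):
        press = 0.0
        for test_idx in folds:
            train = np.delete(x, test_idx, axis=0)
            _, loadings, _ = fit_pca(train, k)
            test = x[test_idx]
            recon = test @ loadings.T @ loadings
            press += float(np.sum((test - recon) ** 2))
        q2[k] = 1.0 - press / ss_total
    recommended = 0
    prev = 0.0
    for k in sorted(c for c in q2 if c > 0):
        if q2[k] - prev > improvement:
            recommended = k
            prev = q2[k]
        else:
            break
    return recommended, q2
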