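"""Synthetic trimodal phantoms with known spatial-chemical structure.

Generates three MSI blocks plus a finer-resolution hyperspectral cube on
an elliptical tissue region, with plaque-like focal features (cored and
diffuse morphotypes), planted globally joint / locally joint / unique
spatial patterns, known per-modality misalignments, and a full ground
truth record so every downstream stage can be scored without external
data.
"""

from __future__ import annotations

import json
import uuid as uuid_mod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from multimsi.cube import SpectralImageCube
from multimsi.fusion import block_average
from multimsi.imaging_io import write_imzml, write_tiff_cube
from multimsi.transform import AffineTransform2D, apply_transform

MSI_TAGS = ("lipid_neg", "lipid_pos", "peptide")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Block widths default to the 673/553/20 split of the three MSI
    modalities; features are 50-100 um across on a 10 um grid with
    30-40 um cores for the cored morphotype, and the hyperspectral cube
    sits on an ``upscale`` x finer grid with 32 emission channels.
    """

    grid: tuple[int, int] = (64, 64)
    upscale: int = 4
    pixel_size: float = 10.0
    n_features: int = 8
    feature_diameter: tuple[float, float] = (50.0, 100.0)  # micrometers
    core_diameter: tuple[float, float] = (30.0, 40.0)
    block_widths: tuple[int, ...] = (673, 553, 20)
    global_fraction: float = 0.1
    local_plan: dict = field(
        default_factory=lambda: {(0, 1): "core", (1, 2): "periphery"}
    )
    local_fraction: float = 0.1
    unique_fraction: float = 0.1
    effect_size: float = 3.0
    base_level: float = 1.0
    anatomy_strength: float = 0.3  # shared smooth tissue texture, all modalities
    noise_sigma: float = 0.15
    floor_sigma: float = 0.02
    n_hyper_channels: int = 32
    misalignments: list[AffineTransform2D] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upscale < 1:
            raise ValueError("upscale must be >= 1")
        if any(w < 1 for w in self.block_widths):
            raise ValueError("block widths must be >= 1")
        if self.feature_diameter[0] <= 0:
            raise ValueError("feature diameters must be positive")


@dataclass
class PhantomTruth:
    """Everything needed to score recovery experiments downstream."""

    spec: PhantomSpec
    features: list[dict]  # center (MSI px, row/col), diameter_um, morphotype
    maps: dict[str, np.ndarray]  # pattern name -> MSI-resolution map
    maps_highres: dict[str, np.ndarray]
    tissue_mask: np.ndarray  # MSI resolution
    tissue_mask_highres: np.ndarray
    transforms: list[AffineTransform2D]  # planted misalignment per MSI block
    assignments: list[np.ndarray]  # per block: pattern name per variable
    loadings: list[np.ndarray]  # per block: effect loading per variable
    endmembers: np.ndarray  # (3, n_channels) core / periphery / mixed spectra
    anatomy: np.ndarray | None = None  # shared background texture, MSI res
    anatomy_highres: np.ndarray | None = None
    tissue_fraction: np.ndarray | None = None  # partial-volume coverage, MSI res

    def landmarks(self) -> np.ndarray:
        """Feature centers as (x, y) points in the reference MSI frame."""
        return np.array([[f["center"][1], f["center"][0]] for f in self.features])

    def pattern_of(self, block: int) -> dict[str, np.ndarray]:
        """Boolean variable masks per planted pattern for one block."""
        names = np.unique(self.assignments[block])
        return {n: self.assignments[block] == n for n in names}

    def ion_truth_image(self, block: int, var_index: int, highres: bool = True) -> np.ndarray:
        """Noise-free ion image for one variable (high or MSI resolution)."""
        pattern = self.assignments[block][var_index]
        maps = self.maps_highres if highres else self.maps
        tissue = self.tissue_mask_highres if highres else self.tissue_mask
        spec = self.spec
        anatomy = self.anatomy_highres if highres else self.anatomy
        if anatomy is None:
            anatomy = np.ones(tissue.shape)
        coverage = tissue.astype(float)
        if not highres and self.tissue_fraction is not None:
            coverage = self.tissue_fraction * tissue
        img = spec.base_level * anatomy * coverage
        if pattern != "background":
            img = img + spec.effect_size * self.loadings[block][var_index] * maps[pattern]
        return img * tissue


def _radial_feature(shape, center, radius_px, soft=1.2):
    rr, cc = np.indices(shape)
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip(1.0 - (d / radius_px) ** 2, 0.0, 1.0) ** soft


def _smooth_blob_map(rng, shape, tissue, sigma, n_blobs=4):
    img = np.zeros(shape)
    coords = np.argwhere(tissue)
    for _ in range(n_blobs):
        r, c = coords[rng.integers(len(coords))]
        img += _radial_feature(shape, (r, c), sigma * (1.0 + rng.random()))
    img = gaussian_filter(img, sigma=1.0) * tissue
    m = img.max()
    return img / m if m > 0 else img


def _place_features(rng, spec: PhantomSpec, tissue_hi: np.ndarray) -> list[dict]:
    shape = tissue_hi.shape
    um_to_hipx = spec.upscale / spec.pixel_size
    features: list[dict] = []
    attempts = 0
    while len(features) < spec.n_features and attempts < 4000:
        attempts += 1
        d_um = rng.uniform(*spec.feature_diameter)
        r_px = 0.5 * d_um * um_to_hipx
        row = rng.uniform(r_px, shape[0] - r_px)
        col = rng.uniform(r_px, shape[1] - r_px)
        if not tissue_hi[int(row), int(col)]:
            continue
        if any(
            np.hypot(row - f["center_hi"][0], col - f["center_hi"][1])
            < r_px + 0.5 * f["diameter_um"] * um_to_hipx + 2
            for f in features
        ):
            continue
        morphotype = "cored" if len(features) % 2 == 0 else "diffuse"
        features.append(
            {
                "center_hi": (row, col),
                "center": (row / spec.upscale, col / spec.upscale),
                "diameter_um": d_um,
                "core_diameter_um": rng.uniform(*spec.core_diameter),
                "morphotype": morphotype,
            }
        )
    if len(features) < spec.n_features:
        raise ValueError(
            f"could not place {spec.n_features} non-overlapping features on the grid"
        )
    return features


def _build_maps(spec: PhantomSpec, features: list[dict], tissue_hi: np.ndarray):
    """High-resolution planted pattern maps with near-disjoint supports.

    Features alternate between the 'global' pool (whole-plaque map) and
    the 'cored' pool whose cores and peripheries feed the two local
    maps, keeping pairwise spatial correlations low by construction.
    """
    shape = tissue_hi.shape
    um_to_hipx = spec.upscale / spec.pixel_size
    global_map = np.zeros(shape)
    core_map = np.zeros(shape)
    periphery_map = np.zeros(shape)
    for i, f in enumerate(features):
        r_out = 0.5 * f["diameter_um"] * um_to_hipx
        whole = _radial_feature(shape, f["center_hi"], r_out)
        if i % 2 == 0:
            global_map += whole
        else:
            r_core = 0.5 * f["core_diameter_um"] * um_to_hipx
            core = _radial_feature(shape, f["center_hi"], r_core)
            core_map += core
            periphery_map += np.clip(whole - _radial_feature(shape, f["center_hi"], r_core * 1.4), 0, None)
    maps = {}
    for name, m in (
        ("global", global_map),
        ("core", core_map),
        ("periphery", periphery_map),
    ):
        m = m * tissue_hi
        peak = m.max()
        maps[name] = m / peak if peak > 0 else m
    return maps


def _decorrelate_maps(maps: dict[str, np.ndarray], tissue: np.ndarray) -> None:
    """Near-orthogonalize planted maps in place.

    Sequential Gram-Schmidt over tissue pixels with a clip back to
    nonnegative intensities, then unit spatial variance so equal effect
    sizes plant equal variance regardless of feature footprint.
    """
    order = [n for n in ("global", "core", "periphery") if n in maps]
    order += sorted(n for n in maps if n.startswith("unique"))
    for i, name in enumerate(order):
        m = maps[name]
        for prev in order[:i]:
            p = maps[prev][tissue]
            c = m[tissue]
            pc = p - p.mean()
            denom = pc @ pc
            if denom > 0:
                m = m - ((c - c.mean()) @ pc / denom) * maps[prev]
        m = np.clip(m, 0.0, None) * tissue
        sd = m[tissue].std()
        maps[name] = m / sd if sd > 0 else m


def _pattern_correlations(maps: dict[str, np.ndarray]) -> float:
    names = sorted(maps)
    worst = 0.0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = maps[a].ravel(), maps[b].ravel()
            if va.std() == 0 or vb.std() == 0:
                continue
            worst = max(worst, abs(float(np.corrcoef(va, vb)[0, 1])))
    return worst


def make_phantom(
    spec: PhantomSpec,
) -> tuple[list[SpectralImageCube], SpectralImageCube, PhantomTruth]:
    """Generate the trimodal MSI cubes, hyperspectral cube and ground truth.

    Feature placement is re-drawn (new sub-seed) until all planted
    spatial maps are pairwise nearly uncorrelated (|r| < 0.2). All
    randomness derives from ``spec.seed``.
    """
    h, w = spec.grid
    hi_shape = (h * spec.upscale, w * spec.upscale)

    rr, cc = np.indices(hi_shape)
    cy, cx = (hi_shape[0] - 1) / 2, (hi_shape[1] - 1) / 2
    tissue_hi = (
        ((rr - cy) / (0.45 * hi_shape[0])) ** 2 + ((cc - cx) / (0.45 * hi_shape[1])) ** 2
    ) <= 1.0
    tissue_frac = block_average(tissue_hi.astype(float), spec.upscale)
    tissue_lo = tissue_frac >= 0.5
    # partial-volume coverage of retained pixels, so MSI edge intensities
    # agree with block-averaged microscopy
    tissue_pv = tissue_frac * tissue_lo

    for redraw in range(100):
        rng = np.random.default_rng(spec.seed * 1000 + redraw)
        features = _place_features(rng, spec, tissue_hi)
        maps_hi = _build_maps(spec, features, tissue_hi)
        if spec.n_features > 0:
            maps_hi["unique_0"] = _smooth_blob_map(rng, hi_shape, tissue_hi, 3.0 * spec.upscale)
            maps_hi["unique_1"] = _smooth_blob_map(rng, hi_shape, tissue_hi, 3.0 * spec.upscale)
            maps_hi["unique_2"] = _smooth_blob_map(rng, hi_shape, tissue_hi, 3.0 * spec.upscale)
            _decorrelate_maps(maps_hi, tissue_hi)
            lowres_check = {
                k: block_average(v, spec.upscale) for k, v in maps_hi.items()
            }
            if max(_pattern_correlations(maps_hi), _pattern_correlations(lowres_check)) < 0.15:
                break
        else:
            maps_hi = {k: np.zeros(hi_shape) for k in ("global", "core", "periphery")}
            maps_hi.update(
                {f"unique_{b}": np.zeros(hi_shape) for b in range(len(spec.block_widths))}
            )
            break
    else:
        raise RuntimeError("failed to draw near-orthogonal planted patterns")

    maps_lo = {k: block_average(v, spec.upscale) for k, v in maps_hi.items()}

    # smooth anatomical texture shared by every modality: real sections show
    # tissue morphology in all channels, and it gives the registration
    # references their mutual structure
    if spec.anatomy_strength > 0:
        field = gaussian_filter(
            rng.standard_normal(hi_shape), sigma=4.0 * spec.upscale
        )
        field = (field - field[tissue_hi].mean()) / (field[tissue_hi].std() or 1.0)
        anatomy_hi = np.clip(1.0 + spec.anatomy_strength * field, 0.2, None)
    else:
        anatomy_hi = np.ones(hi_shape)
    anatomy_lo = block_average(anatomy_hi, spec.upscale)

    # per-block variable assignment and loadings
    assignments, loadings = [], []
    for b, width in enumerate(spec.block_widths):
        patt = np.full(width, "background", dtype=object)
        order = rng.permutation(width)
        pos = 0

        def take(n):
            nonlocal pos
            sel = order[pos : pos + n]
            pos += n
            return sel

        n_g = max(1, int(round(spec.global_fraction * width)))
        patt[take(n_g)] = "global"
        for subset, name in spec.local_plan.items():
            if b in subset:
                n_l = max(1, int(round(spec.local_fraction * width)))
                patt[take(n_l)] = name
        n_u = max(1, int(round(spec.unique_fraction * width)))
        patt[take(n_u)] = f"unique_{b}"
        assignments.append(patt.astype(str))
        loadings.append(rng.uniform(0.5, 1.5, size=width))

    misalignments = spec.misalignments or [
        AffineTransform2D.identity(t, "reference") for t in MSI_TAGS[: len(spec.block_widths)]
    ]

    cubes: list[SpectralImageCube] = []
    for b, width in enumerate(spec.block_widths):
        values = np.empty((h, w, width))
        for j in range(width):
            img = spec.base_level * anatomy_lo * tissue_pv
            if assignments[b][j] != "background":
                img = img + spec.effect_size * loadings[b][j] * maps_lo[assignments[b][j]] * tissue_lo
            noise = np.exp(spec.noise_sigma * rng.standard_normal((h, w)))
            floor = np.abs(rng.standard_normal((h, w))) * spec.floor_sigma
            values[:, :, j] = (img * noise + floor) * tissue_lo
        # m/z axes loosely spanning lipid/peptide ranges per modality
        start = (400.0, 450.0, 800.0)[b % 3]
        mz = start + np.arange(width) * 0.7
        cube = SpectralImageCube(
            values=values,
            variables=mz,
            pixel_size=spec.pixel_size,
            modality_tag=MSI_TAGS[b % 3],
        )
        T = misalignments[b]
        if not np.array_equal(T.matrix, np.eye(3)):
            cube = apply_transform(cube, T, "bicubic")
        cubes.append(cube)

    # hyperspectral lambda stack: two smooth emission endmembers mixed by
    # the high-resolution core / periphery maps over a dim tissue background
    chan = np.arange(spec.n_hyper_channels)
    em_core = np.exp(-0.5 * ((chan - 0.3 * spec.n_hyper_channels) / 3.5) ** 2)
    em_peri = np.exp(-0.5 * ((chan - 0.7 * spec.n_hyper_channels) / 3.5) ** 2)
    # mixed-polymorph plaques emit an intermediate curve, spectrally
    # independent of the two pure endmembers
    em_mid = np.exp(-0.5 * ((chan - 0.5 * spec.n_hyper_channels) / 3.5) ** 2)
    base_spec = 0.1 * np.ones(spec.n_hyper_channels)
    hyper = (
        maps_hi["core"][:, :, None] * em_core
        + maps_hi["periphery"][:, :, None] * em_peri
        + maps_hi["global"][:, :, None] * em_mid
        + (anatomy_hi * tissue_hi)[:, :, None] * base_spec
    )
    hyper = hyper * np.exp(0.5 * spec.noise_sigma * rng.standard_normal(hyper.shape))
    hyper *= tissue_hi[:, :, None]
    wavelengths = 500.0 + 10.0 * chan  # nm band centers
    hyper_cube = SpectralImageCube(
        values=hyper,
        variables=wavelengths,
        pixel_size=spec.pixel_size / spec.upscale,
        modality_tag="hyperspectral",
    )

    truth = PhantomTruth(
        spec=spec,
        features=features,
        maps=maps_lo,
        maps_highres=maps_hi,
        tissue_mask=tissue_lo,
        tissue_mask_highres=tissue_hi,
        transforms=misalignments,
        assignments=assignments,
        loadings=loadings,
        endmembers=np.stack([em_core, em_peri, em_mid]),
        anatomy=anatomy_lo,
        anatomy_highres=anatomy_hi,
        tissue_fraction=tissue_frac,
    )
    return cubes, hyper_cube, truth


def write_fixture_suite(out_dir: str | Path, spec: PhantomSpec | None = None) -> dict:
    """Emit a small on-disk fixture set: per-block imzML, the lambda-stack
    TIFF and a truth JSON; regenerates byte-identically from the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = PhantomSpec(grid=(64, 64), block_widths=(40, 30, 10), n_features=6)
    cubes, hyper, truth = make_phantom(spec)
    paths = {}
    rng = np.random.default_rng(spec.seed)
    for cube in cubes:
        path = out_dir / f"{cube.modality_tag}.imzML"
        write_imzml(
            cube, path, mode="processed", file_uuid=uuid_mod.UUID(bytes=rng.bytes(16))
        )
        paths[cube.modality_tag] = str(path)
    hyper_path = out_dir / "lambda_stack.tiff"
    write_tiff_cube(hyper, hyper_path)
    paths["hyperspectral"] = str(hyper_path)

    truth_json = {
        "seed": spec.seed,
        "grid": list(spec.grid),
        "upscale": spec.upscale,
        "block_widths": list(spec.block_widths),
        "features": [
            {
                "center": list(map(float, f["center"])),
                "diameter_um": float(f["diameter_um"]),
                "core_diameter_um": float(f["core_diameter_um"]),
                "morphotype": f["morphotype"],
            }
            for f in truth.features
        ],
        "transforms": [t.to_dict() for t in truth.transforms],
        "assignments": [a.tolist() for a in truth.assignments],
        "loadings": [lo.tolist() for lo in truth.loadings],
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    paths["truth"] = str(truth_path)
    return paths
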