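"""Imaging file I/O: imzML 1.1 read/write, multi-channel TIFF, CSV export.

The imzML support is a self-contained implementation of the open
imzML 1.1 exchange format (XML descriptor + ``.ibd`` binary file),
covering both *continuous* mode (one shared m/z axis) and *processed*
mode (per-spectrum axes). Only 64-bit float, uncompressed, external
binary arrays are emitted; the reader accepts 32/64-bit floats and
integers.
"""

from __future__ import annotations

import hashlib
import os
import uuid as uuid_mod
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from multimsi.cube import DimensionError, SpectralImageCube, partition_pixels

MZML_NS = "http://psi.hupo.org/ms/mzml"

_DTYPES = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000519": np.dtype("<i4"),  # 32-bit integer
    "MS:1000522": np.dtype("<i8"),  # 64-bit integer
}


class ImzmlFormatError(ValueError):
    """Raised for malformed imzML/ibd pairs (including checksum mismatch)."""


def _cv(parent: ET.Element, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(
        parent,
        "cvParam",
        cvRef=accession.split(":")[0],
        accession=accession,
        name=name,
        value=value,
    )


def write_imzml(
    cube: SpectralImageCube,
    path: str | Path,
    mode: str = "processed",
    file_uuid: uuid_mod.UUID | None = None,
) -> None:
    """Write a cube as an imzML/ibd pair.

    ``path`` names the ``.imzML`` file; the ``.ibd`` is placed next to it.
    Black (all-zero) pixels are skipped, matching how instruments omit
    off-sample coordinates; ``read_imzml`` reinstates them as zeros.
    Passing ``file_uuid`` makes the output byte-deterministic.
    """
    if mode not in ("continuous", "processed"):
        raise ValueError("mode must be 'continuous' or 'processed'")
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if file_uuid is None:
        file_uuid = uuid_mod.uuid4()

    mz = np.ascontiguousarray(cube.variables, dtype="<f8")
    partition = partition_pixels(cube)
    spectra: list[dict] = []

    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        if mode == "continuous":
            mz_offset = ibd.tell()
            ibd.write(mz.tobytes())
        for row, col in partition.data_pixel_index:
            intens = np.ascontiguousarray(cube.values[row, col, :], dtype="<f8")
            if mode == "processed":
                mz_offset = ibd.tell()
                ibd.write(mz.tobytes())
            int_offset = ibd.tell()
            ibd.write(intens.tobytes())
            spectra.append(
                {
                    "x": int(col) + 1,  # imzML coordinates are 1-based
                    "y": int(row) + 1,
                    "mz_offset": mz_offset,
                    "mz_length": mz.size,
                    "int_offset": int_offset,
                    "int_length": intens.size,
                }
            )
    sha1 = hashlib.sha1(ibd_path.read_bytes()).hexdigest()

    root = ET.Element("mzML", xmlns=MZML_NS, version="1.1")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    if mode == "continuous":
        _cv(fcontent, "IMS:1000030", "continuous")
    else:
        _cv(fcontent, "IMS:1000031", "processed")
    _cv(fcontent, "IMS:1000080", "universally unique identifier", "{%s}" % file_uuid)
    _cv(fcontent, "IMS:1000091", "ibd SHA-1", sha1)

    groups = ET.SubElement(root, "referenceableParamGroupList", count="2")
    for gid, acc, name in (
        ("mzArray", "MS:1000514", "m/z array"),
        ("intensityArray", "MS:1000515", "intensity array"),
    ):
        g = ET.SubElement(groups, "referenceableParamGroup", id=gid)
        _cv(g, "MS:1000523", "64-bit float")
        _cv(g, "MS:1000576", "no compression")
        _cv(g, acc, name)
        _cv(g, "IMS:1000101", "external data", "true")

    scan_list = ET.SubElement(root, "scanSettingsList", count="1")
    scan = ET.SubElement(scan_list, "scanSettings", id="scanSettings0")
    _cv(scan, "IMS:1000042", "max count of pixels x", str(cube.width))
    _cv(scan, "IMS:1000043", "max count of pixels y", str(cube.height))
    _cv(scan, "IMS:1000046", "pixel size x", str(cube.pixel_size))
    _cv(scan, "IMS:1000047", "pixel size y", str(cube.pixel_size))

    run = ET.SubElement(root, "run", id=cube.modality_tag)
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, sp in enumerate(spectra):
        spec = ET.SubElement(
            slist, "spectrum", index=str(i), id=f"spectrum={i}", defaultArrayLength="0"
        )
        sl = ET.SubElement(spec, "scanList", count="1")
        sc = ET.SubElement(sl, "scan")
        _cv(sc, "IMS:1000050", "position x", str(sp["x"]))
        _cv(sc, "IMS:1000051", "position y", str(sp["y"]))
        bal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for ref, off_key, len_key in (
            ("mzArray", "mz_offset", "mz_length"),
            ("intensityArray", "int_offset", "int_length"),
        ):
            bda = ET.SubElement(bal, "binaryDataArray", encodedLength="0")
            ET.SubElement(bda, "referenceableParamGroupRef", ref=ref)
            _cv(bda, "IMS:1000102", "external offset", str(sp[off_key]))
            _cv(bda, "IMS:1000103", "external array length", str(sp[len_key]))
            _cv(bda, "IMS:1000104", "external encoded length", str(sp[len_key] * 8))
            ET.SubElement(bda, "binary")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _iter_cv(elem: ET.Element):
    for cv in elem.iter(f"{{{MZML_NS}}}cvParam"):
        yield cv.get("accession"), cv.get("value", ""), cv.get("name", "")


def read_imzml(
    path: str | Path,
    modality_tag: str = "lipid_neg",
    validate_checksum: bool = True,
) -> SpectralImageCube:
    """Read an imzML/ibd pair into a :class:`SpectralImageCube`.

    The pixel grid is inferred from the coordinate extents; coordinates
    absent from the file become all-zero (black) pixels. Non-rectangular
    acquisitions are padded, never rejected. An unsorted m/z axis is
    re-sorted ascending with intensities permuted consistently.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise ImzmlFormatError(f"missing ibd file: {ibd_path}")
    tree = ET.parse(path)
    root = tree.getroot()

    pixel_size = 10.0
    declared_sha1 = None
    max_x = max_y = 0
    for acc, value, _name in _iter_cv(root):
        if acc == "IMS:1000046" and value:
            pixel_size = float(value)
        elif acc == "IMS:1000091":
            declared_sha1 = value.lower()
        elif acc == "IMS:1000042" and value:
            max_x = int(value)
        elif acc == "IMS:1000043" and value:
            max_y = int(value)
    if validate_checksum and declared_sha1:
        actual = hashlib.sha1(ibd_path.read_bytes()).hexdigest()
        if actual != declared_sha1:
            raise ImzmlFormatError(
                f"ibd SHA-1 mismatch: declared {declared_sha1}, actual {actual}"
            )

    ibd = np.fromfile(ibd_path, dtype=np.uint8)

    def read_array(offset: int, length: int, dtype: np.dtype) -> np.ndarray:
        end = offset + length * dtype.itemsize
        if end > ibd.size:
            raise ImzmlFormatError("binary array extends past end of ibd file")
        return ibd[offset:end].view(dtype).astype(np.float64)

    records = []  # (x0, y0, mz, intensities)
    for spec in root.iter(f"{{{MZML_NS}}}spectrum"):
        x = y = None
        for acc, value, _ in _iter_cv(spec):
            if acc == "IMS:1000050":
                x = int(value)
            elif acc == "IMS:1000051":
                y = int(value)
        if x is None or y is None:
            raise ImzmlFormatError("spectrum without position x/y")
        arrays = {}
        for bda in spec.iter(f"{{{MZML_NS}}}binaryDataArray"):
            ref_el = bda.find(f"{{{MZML_NS}}}referenceableParamGroupRef")
            ref = ref_el.get("ref") if ref_el is not None else None
            offset = length = None
            dtype = np.dtype("<f8")
            for acc, value, _ in _iter_cv(bda):
                if acc == "IMS:1000102":
                    offset = int(value)
                elif acc == "IMS:1000103":
                    length = int(value)
                elif acc in _DTYPES:
                    dtype = _DTYPES[acc]
                elif acc in ("MS:1000514", "MS:1000515"):
                    ref = "mzArray" if acc == "MS:1000514" else "intensityArray"
            if ref is None or offset is None or length is None:
                raise ImzmlFormatError("binaryDataArray missing offset/length/reference")
            arrays[ref] = read_array(offset, length, dtype)
        if "mzArray" not in arrays or "intensityArray" not in arrays:
            raise ImzmlFormatError("spectrum missing m/z or intensity array")
        records.append((x - 1, y - 1, arrays["mzArray"], arrays["intensityArray"]))

    if not records:
        raise ImzmlFormatError("no spectra in file")

    axis = np.unique(np.concatenate([r[2] for r in records]))
    height = max(max(r[1] for r in records) + 1, max_y)
    width = max(max(r[0] for r in records) + 1, max_x)
    values = np.zeros((height, width, axis.size))
    for x0, y0, mz, intens in records:
        cols = np.searchsorted(axis, mz)
        values[y0, x0, cols] = intens
    return SpectralImageCube(
        values=values,
        variables=axis,
        pixel_size=pixel_size,
        modality_tag=modality_tag,
    )


def read_tiff_cube(
    path: str | Path,
    pixel_size: float = 2.5,
    wavelengths: np.ndarray | None = None,
    modality_tag: str = "hyperspectral",
) -> SpectralImageCube:
    """Read a multi-channel TIFF lambda stack as an (x, y, lambda) cube.

    Accepts channel-first ``(c, h, w)`` or channel-last ``(h, w, c)``
    stacks; planar single-channel images get a singleton channel axis.
    """
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3 and arr.shape[0] < min(arr.shape[1], arr.shape[2]):
        arr = np.moveaxis(arr, 0, -1)
    elif arr.ndim != 3:
        raise DimensionError(f"unsupported TIFF shape {arr.shape}")
    n_chan = arr.shape[2]
    if wavelengths is None:
        wavelengths = np.arange(n_chan, dtype=float)
    return SpectralImageCube(
        values=arr.astype(np.float64),
        variables=np.asarray(wavelengths, dtype=float),
        pixel_size=pixel_size,
        modality_tag=modality_tag,
    )


def write_tiff_cube(cube: SpectralImageCube, path: str | Path) -> None:
    """Write a cube as a channel-first multi-page float32 TIFF."""
    tifffile.imwrite(
        os.fspath(path),
        np.moveaxis(cube.values, -1, 0).astype(np.float32),
        photometric="minisblack",
    )


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary mask from single-channel TIFF or a CSV row,col index list."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(os.fspath(path)) > 0
    idx = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    if shape is None:
        shape = (idx[:, 0].max() + 1, idx[:, 1].max() + 1)
    mask = np.zeros(shape, dtype=bool)
    mask[idx[:, 0], idx[:, 1]] = True
    return mask


def export_matrix_csv(matrix, path: str | Path) -> None:
    """Dump a PixelMatrix to CSV with a row,col + variable-identifier header."""
    header = "row,col," + ",".join(f"{v:.6f}" for v in matrix.variables)
    out = np.concatenate([matrix.coordinates.astype(float), matrix.data], axis=1)
    np.savetxt(path, out, delimiter=",", header=header, comments="")
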