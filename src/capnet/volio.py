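"""Volume I/O and binary-segmentation postprocessing.

All volumes are 3D arrays in (z, y, x) axis order with a per-axis voxel
spacing in nanometres. Physical quantities are kept in nm internally and
only converted to um/mm in reports.

Postprocessing mirrors the standard cleanup applied to semantic
segmentations of vascular lumina before topological analysis: filling of
fully enclosed holes, selection of the largest connected component, and
extraction of cubic analysis subregions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "VoxelVolume",
    "read_stack",
    "write_stack",
    "resample_isotropic",
    "fill_holes",
    "largest_component",
    "extract_subregion",
    "subregion_volume_mm3",
]

NM_PER_MM = 1.0e6


@dataclass
class VoxelVolume:
    """A 3D scalar or binary grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Grayscale values or {0, 1} labels. Slice index z increases with
        physical z.
    spacing_nm : tuple of float
        Voxel edge length per axis in (z, y, x) order, nanometres.
    origin_vx : tuple of int
        Offset of this (sub)volume within its parent volume, voxels.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float]
    origin_vx: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_nm}")
        self.origin_vx = tuple(int(o) for o in self.origin_vx)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def require_binary(self) -> np.ndarray:
        if not self.is_binary:
            raise ValueError("volume is not binary (values outside {0, 1})")
        return self.data.astype(bool)

    def volume_mm3(self) -> float:
        """Physical volume of the full grid in mm^3."""
        extent = [n * s for n, s in zip(self.shape, self.spacing_nm)]
        return float(np.prod(extent)) / NM_PER_MM**3

    def copy_with(self, data: np.ndarray, **kw) -> "VoxelVolume":
        return VoxelVolume(
            data,
            kw.pop("spacing_nm", self.spacing_nm),
            kw.pop("origin_vx", self.origin_vx),
        )


def subregion_volume_mm3(size_vx, spacing_nm) -> float:
    """Physical volume of a subregion of `size_vx` voxels at `spacing_nm`.

    A 1000^3 voxel cube at 150 nm isotropic spacing is (150 um)^3 =
    3.375e-3 mm^3.
    """
    extent = [float(n) * float(s) for n, s in zip(size_vx, spacing_nm)]
    return float(np.prod(extent)) / NM_PER_MM**3


# ---------------------------------------------------------------------------
# I/O: multipage TIFF and MetaImage (.mhd / .mha)
# ---------------------------------------------------------------------------

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _sidecar_path(path: str) -> str:
    return path + ".spacing.json"


def write_stack(volume: VoxelVolume, path: str) -> None:
    """Write a volume as multipage TIFF (+ JSON spacing sidecar) or MetaImage.

    The format is chosen by extension: ``.tif``/``.tiff`` or
    ``.mhd``/``.mha``. Binary volumes are stored as uint8 so the
    write -> read round trip is bit-identical.
    """
    ext = os.path.splitext(path)[1].lower()
    data = volume.data
    if volume.is_binary:
        data = data.astype(np.uint8)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"spacing_nm": list(volume.spacing_nm)}, fh)
    elif ext in (".mhd", ".mha"):
        _write_metaimage(data, volume.spacing_nm, path)
    else:
        raise ValueError(f"unsupported volume format: {path!r}")


def read_stack(path: str, spacing_nm=None) -> VoxelVolume:
    """Read a multipage TIFF or MetaImage volume.

    Spacing is taken from the file's metadata (MetaImage `ElementSpacing`,
    or the TIFF's JSON sidecar); `spacing_nm` overrides / supplies it when
    metadata is absent.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected 2D pages in {path!r}, got array ndim={data.ndim}")
        if spacing_nm is None:
            sidecar = _sidecar_path(path)
            if not os.path.exists(sidecar):
                raise ValueError(f"no spacing metadata for {path!r} and no spacing_nm given")
            with open(sidecar) as fh:
                spacing_nm = json.load(fh)["spacing_nm"]
        return VoxelVolume(data, tuple(spacing_nm))
    if ext in (".mhd", ".mha"):
        data, file_spacing = _read_metaimage(path)
        return VoxelVolume(data, tuple(spacing_nm) if spacing_nm is not None else file_spacing)
    raise ValueError(f"unsupported volume format: {path!r}")


def _write_metaimage(data: np.ndarray, spacing_nm, path: str) -> None:
    # MetaImage headers list dimensions in (x, y, z) order; spacing values
    # are stored in nm to match the rest of the package.
    dtype = np.dtype(data.dtype)
    if dtype not in _MET_NAMES:
        raise ValueError(f"unsupported dtype for MetaImage: {dtype}")
    nz, ny, nx = data.shape
    sz, sy, sx = spacing_nm
    local = path.lower().endswith(".mha")
    raw_name = "LOCAL" if local else os.path.basename(path)[:-4] + ".raw"
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sx:g} {sy:g} {sz:g}\n"
        f"ElementType = {_MET_NAMES[dtype]}\n"
        f"ElementDataFile = {raw_name}\n"
    )
    raw = np.ascontiguousarray(data).tobytes()
    if local:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(raw)
    else:
        with open(path, "w") as fh:
            fh.write(header)
        with open(os.path.join(os.path.dirname(path) or ".", raw_name), "wb") as fh:
            fh.write(raw)


def _read_metaimage(path: str):
    fields: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            key, _, value = line.decode("ascii", errors="replace").partition("=")
            key, value = key.strip(), value.strip()
            fields[key] = value
            if key == "ElementDataFile":
                break
        if "ElementDataFile" not in fields:
            raise ValueError(f"malformed MetaImage header in {path!r}")
        if fields.get("ElementDataFile") == "LOCAL":
            raw = fh.read()
        else:
            raw_path = os.path.join(os.path.dirname(path) or ".", fields["ElementDataFile"])
            with open(raw_path, "rb") as rfh:
                raw = rfh.read()
    if fields.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise ValueError("big-endian MetaImage data is not supported")
    dtype = _MET_TYPES.get(fields.get("ElementType", ""))
    if dtype is None:
        raise ValueError(f"unsupported ElementType {fields.get('ElementType')!r}")
    nx, ny, nz = (int(v) for v in fields["DimSize"].split())
    sx, sy, sz = (float(v) for v in fields.get("ElementSpacing", "1 1 1").split())
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz).reshape(nz, ny, nx).copy()
    return data, (sz, sy, sx)


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------


def resample_isotropic(
    volume: VoxelVolume,
    target_nm: float,
    mode: str = "linear",
    threshold: bool = False,
) -> VoxelVolume:
    """Resample to an isotropic voxel size of `target_nm`.

    Output shape per axis is floor(extent_nm / target_nm). `mode` selects
    linear interpolation (grayscale) or nearest neighbour (labels);
    applying linear interpolation to a binary volume is rejected unless
    `threshold=True`, in which case the interpolated values are
    re-binarised at 0.5.
    """
    target_nm = float(target_nm)
    if target_nm <= 0:
        raise ValueError("target_nm must be > 0")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    binary = volume.is_binary
    if mode == "linear" and binary and not threshold:
        raise ValueError(
            "linear interpolation of a binary volume creates non-{0,1} values; "
            "use mode='nearest' or pass threshold=True"
        )
    shape_out = tuple(
        max(1, int(np.floor(n * s / target_nm)))
        for n, s in zip(volume.shape, volume.spacing_nm)
    )
    # Input sample i sits at physical position i * spacing; the output grid
    # keeps that origin so equal spacing is an exact identity.
    axes = [
        np.arange(n_out) * (target_nm / s)
        for n_out, s in zip(shape_out, volume.spacing_nm)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    order = 1 if mode == "linear" else 0
    data = volume.data.astype(np.float64) if mode == "linear" else volume.data
    out = ndi.map_coordinates(data, grid, order=order, mode="nearest")
    if mode == "linear" and binary:
        out = (out >= 0.5).astype(volume.data.dtype)
    elif mode == "linear":
        out = out.astype(np.result_type(volume.data.dtype, np.float32))
    return VoxelVolume(out, (target_nm,) * 3, volume.origin_vx)


def fill_holes(volume: VoxelVolume, mode: str = "full_3d") -> VoxelVolume:
    """Fill background cavities fully enclosed by the foreground label.

    Background components not connected to the border are set to
    foreground. The background phase uses face connectivity (6 in 3D,
    4 in 2D), complementary to the 26/8 foreground connectivity used
    elsewhere, avoiding the digital-topology paradox of using the same
    connectivity for both phases. `mode='per_slice_2d'` fills each z
    slice independently (a z-through tunnel is enclosed in every 2D
    slice but not in 3D).
    """
    fg = volume.require_binary()
    if mode == "full_3d":
        filled = ndi.binary_fill_holes(fg)  # default structure = 6-connectivity
    elif mode == "per_slice_2d":
        filled = np.empty_like(fg)
        for z in range(fg.shape[0]):
            filled[z] = ndi.binary_fill_holes(fg[z])  # 4-connectivity background
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return volume.copy_with(filled.astype(volume.data.dtype))


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def largest_component(volume: VoxelVolume, connectivity: int = 26) -> VoxelVolume:
    """Keep only the largest foreground component.

    Ties are broken deterministically by keeping the component containing
    the foreground voxel with the smallest (z, y, x) index.
    """
    fg = volume.require_binary()
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}")
    structure = ndi.generate_binary_structure(3, _CONN_RANK[connectivity])
    labels, n = ndi.label(fg, structure=structure)
    if n == 0:
        raise ValueError("volume has no foreground voxels")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first_index = {
            int(lab): int(np.flatnonzero(flat == lab)[0]) for lab in candidates
        }
        keep = min(first_index, key=first_index.get)
    return volume.copy_with((labels == keep).astype(volume.data.dtype))


def extract_subregion(volume: VoxelVolume, origin_vx, size_vx) -> VoxelVolume:
    """Extract a rectangular subregion; its origin within the parent is recorded."""
    origin_vx = tuple(int(o) for o in origin_vx)
    size_vx = tuple(int(s) for s in size_vx)
    if any(s <= 0 for s in size_vx):
        raise ValueError(f"subregion size must be positive, got {size_vx}")
    if any(o < 0 or o + s > n for o, s, n in zip(origin_vx, size_vx, volume.shape)):
        raise ValueError(
            f"subregion origin={origin_vx} size={size_vx} exceeds volume shape {volume.shape}"
        )
    sl = tuple(slice(o, o + s) for o, s in zip(origin_vx, size_vx))
    new_origin = tuple(p + o for p, o in zip(volume.origin_vx, origin_vx))
    return VoxelVolume(volume.data[sl].copy(), volume.spacing_nm, new_origin)
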