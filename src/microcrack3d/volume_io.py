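"""Reading, writing and merging of grey-level micro-CT volumes.

Conventions
-----------
Volumes are stored in ``(z, y, x)`` axis order with slice index 0 at the
bottom of the scan.  Indexing is 0-based and a voxel's physical centre is
``(index + 0.5) * voxel_size_um``.  Voxels are isotropic by contract: one
voxel size applies to all three axes.

Three on-disk layouts are supported:

* a multi-page TIFF (one page per slice) plus a small JSON sidecar holding
  the voxel size and value kind,
* a directory of single-page TIFF slices (sorted by filename) plus the same
  sidecar (``meta.json`` inside the directory),
* an MHD-style text header (``ElementSpacing`` etc.) next to a ``.raw`` file.

Boolean masks are stored as 8-bit ``{0, 255}``; label maps as 16-bit when
they fit, 32-bit otherwise.  Round trips are lossless for every stored dtype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GreyVolume",
    "VolumeMeta",
    "MetadataError",
    "VolumeFormatError",
    "UnitError",
    "CapacityError",
    "read_volume",
    "write_volume",
    "merge_scans",
]


class VolumeFormatError(ValueError):
    """The on-disk data is malformed (e.g. inconsistent slice shapes)."""


class MetadataError(VolumeFormatError):
    """Required physical metadata is missing or contradictory."""


class UnitError(ValueError):
    """Physical units of two volumes are incompatible."""


class CapacityError(ValueError):
    """A value range does not fit the requested storage dtype."""


@dataclass
class GreyVolume:
    """A 3D scalar attenuation field with isotropic physical voxel size.

    Parameters
    ----------
    data
        3D array in ``(z, y, x)`` order.
    voxel_size_um
        Edge length of the cubic voxel in micrometres; strictly positive.
    origin_um
        Physical position of the corner of voxel ``(0, 0, 0)``; default zeros.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume must be 3D, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError(f"empty grid {self.data.shape}")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise MetadataError(f"voxel size must be > 0, got {self.voxel_size_um}")
        self.voxel_size_um = float(self.voxel_size_um)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> np.ndarray:
        """Physical extent (z, y, x) of the grid in micrometres."""
        return np.asarray(self.data.shape) * self.voxel_size_um


@dataclass
class VolumeMeta:
    """Sidecar metadata describing a stored volume."""

    dtype: str
    shape: tuple[int, int, int]
    voxel_size_um: float
    kind: str = "grey"  # grey | mask | labels
    value_scale: str = "attenuation (arbitrary units)"

    def validate_against(self, data: np.ndarray) -> None:
        if tuple(self.shape) != data.shape:
            raise MetadataError(
                f"metadata dimensions {tuple(self.shape)} do not match "
                f"stored grid {data.shape}"
            )


_MHD_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_USHORT": np.uint16,
    "MET_UINT": np.uint32,
    "MET_SHORT": np.int16,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(v): k for k, v in _MHD_TYPES.items()}


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "meta.json"
    return path.with_suffix(".json")


def _storage_array(data: np.ndarray, kind: str) -> np.ndarray:
    """Map an in-memory array to its on-disk representation."""
    if kind == "mask":
        return (data.astype(bool).astype(np.uint8)) * 255
    if kind == "labels":
        maxlab = int(data.max()) if data.size else 0
        if maxlab < 2**16:
            return data.astype(np.uint16)
        if maxlab < 2**32:
            return data.astype(np.uint32)
        raise CapacityError(f"label count {maxlab} exceeds 32-bit capacity")
    return data


def _infer_kind(data: np.ndarray) -> str:
    if data.dtype == bool:
        return "mask"
    if np.issubdtype(data.dtype, np.integer) and data.dtype not in (
        np.dtype(np.uint8),
        np.dtype(np.uint16),
    ):
        # Signed/wide integer grids are treated as label maps.
        if np.issubdtype(data.dtype, np.signedinteger) or data.dtype == np.uint32:
            return "labels"
    return "grey"


def write_volume(
    vol: GreyVolume | np.ndarray,
    path: str | Path,
    voxel_size_um: float | None = None,
    kind: str | None = None,
) -> Path:
    """Write a grey volume, boolean mask or label map to disk.

    ``path`` ending in ``.mhd`` selects the MHD/raw layout; otherwise a
    multi-page TIFF plus JSON sidecar is written.  Returns the sidecar
    (or header) path.
    """
    path = Path(path)
    if isinstance(vol, GreyVolume):
        data = vol.data
        voxel_size_um = vol.voxel_size_um
    else:
        data = np.asarray(vol)
        if voxel_size_um is None:
            raise MetadataError("voxel_size_um is required when writing a bare array")
    if data.ndim != 3:
        raise VolumeFormatError("only 3D volumes can be written")
    if kind is None:
        kind = _infer_kind(data)
    stored = _storage_array(data, kind)

    meta = VolumeMeta(
        dtype=str(stored.dtype),
        shape=tuple(int(s) for s in data.shape),  # type: ignore[arg-type]
        voxel_size_um=float(voxel_size_um),
        kind=kind,
    )

    if path.suffix.lower() == ".mhd":
        if stored.dtype not in _MHD_NAMES:
            stored = stored.astype(np.float32)
        raw = path.with_suffix(".raw")
        stored.tofile(raw)
        sp = meta.voxel_size_um
        header = "\n".join(
            [
                "ObjectType = Image",
                "NDims = 3",
                "BinaryData = True",
                "BinaryDataByteOrderMSB = False",
                # DimSize is x y z per MHD convention; array is (z, y, x).
                f"DimSize = {stored.shape[2]} {stored.shape[1]} {stored.shape[0]}",
                f"ElementSpacing = {sp} {sp} {sp}",
                f"ElementType = {_MHD_NAMES[stored.dtype]}",
                f"Kind = {kind}",
                f"ElementDataFile = {raw.name}",
                "",
            ]
        )
        path.write_text(header)
        return path

    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stored, photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "dtype": meta.dtype,
                "shape": list(meta.shape),
                "voxel_size_um": meta.voxel_size_um,
                "kind": meta.kind,
                "value_scale": meta.value_scale,
            },
            indent=2,
        )
    )
    return sidecar


def _read_mhd(path: Path) -> GreyVolume:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        nx, ny, nz = (int(t) for t in fields["DimSize"].split())
        spacing = [float(t) for t in fields["ElementSpacing"].split()]
        dtype = _MHD_TYPES[fields["ElementType"]]
        datafile = fields["ElementDataFile"]
    except KeyError as exc:
        raise MetadataError(f"MHD header {path} missing key {exc}") from exc
    if len(set(spacing)) != 1:
        raise MetadataError(f"anisotropic ElementSpacing {spacing} not supported")
    raw = path.parent / datafile
    data = np.fromfile(raw, dtype=dtype)
    if data.size != nx * ny * nz:
        raise VolumeFormatError(
            f"raw file {raw} holds {data.size} values, header promises {nx*ny*nz}"
        )
    data = data.reshape(nz, ny, nx)
    kind = fields.get("Kind", "grey")
    if kind == "mask":
        data = data > 0
    return GreyVolume(data, spacing[0])


def _read_tiff_stack_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not files:
        raise VolumeFormatError(f"no TIFF slices found in {path}")
    slices = []
    shape0 = None
    for i, f in enumerate(files):
        sl = tifffile.imread(f)
        if sl.ndim != 2:
            raise VolumeFormatError(f"slice {i} ({f.name}) is not a 2D image")
        if shape0 is None:
            shape0 = sl.shape
        elif sl.shape != shape0:
            raise VolumeFormatError(
                f"slice {i} ({f.name}) has shape {sl.shape}, expected {shape0}"
            )
        slices.append(sl)
    return np.stack(slices, axis=0)


def read_volume(
    path: str | Path,
    voxel_size_um: float | None = None,
) -> GreyVolume:
    """Read a volume written by :func:`write_volume` (or compatible data).

    ``voxel_size_um`` overrides/supplies the voxel size when no sidecar is
    present; if both exist and disagree, a :class:`MetadataError` is raised.
    """
    path = Path(path)
    if path.suffix.lower() == ".mhd":
        vol = _read_mhd(path)
        if voxel_size_um is not None and not np.isclose(
            voxel_size_um, vol.voxel_size_um
        ):
            raise MetadataError(
                f"caller voxel size {voxel_size_um} contradicts header "
                f"{vol.voxel_size_um}"
            )
        return vol

    if path.is_dir():
        data = _read_tiff_stack_dir(path)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeFormatError(f"{path} is not a slice stack")

    sidecar = _sidecar_path(path)
    kind = "grey"
    if sidecar.exists():
        meta_raw = json.loads(sidecar.read_text())
        meta = VolumeMeta(
            dtype=meta_raw.get("dtype", str(data.dtype)),
            shape=tuple(meta_raw["shape"]),
            voxel_size_um=float(meta_raw["voxel_size_um"]),
            kind=meta_raw.get("kind", "grey"),
        )
        meta.validate_against(data)
        if voxel_size_um is not None and not np.isclose(
            voxel_size_um, meta.voxel_size_um
        ):
            raise MetadataError(
                f"caller voxel size {voxel_size_um} contradicts sidecar "
                f"{meta.voxel_size_um}"
            )
        voxel_size_um = meta.voxel_size_um
        kind = meta.kind
    elif voxel_size_um is None:
        raise MetadataError(f"no sidecar next to {path} and no voxel size given")

    if kind == "mask":
        data = data > 0
    return GreyVolume(data, voxel_size_um)


def merge_scans(
    lower: GreyVolume,
    upper: GreyVolume,
    overlap_slices: int,
    mode: str = "ramp",
) -> GreyVolume:
    """Merge two vertically adjacent scans sharing ``overlap_slices`` slices.

    The lower scan's top ``overlap_slices`` slices image the same physical
    region as the upper scan's bottom ones.  In that region voxels are
    blended with a linear ramp from lower to upper scan (``mode="ramp"``),
    or taken from the lower scan (``mode="take-lower"``).  The merged
    z-extent is ``z_lower + z_upper - overlap_slices``.
    """
    if not np.isclose(lower.voxel_size_um, upper.voxel_size_um):
        raise UnitError(
            f"voxel sizes differ: {lower.voxel_size_um} vs {upper.voxel_size_um}"
        )
    if lower.data.shape[1:] != upper.data.shape[1:]:
        raise VolumeFormatError(
            f"xy dimensions differ: {lower.data.shape[1:]} vs {upper.data.shape[1:]}"
        )
    zl, zu = lower.data.shape[0], upper.data.shape[0]
    if not (0 < overlap_slices <= min(zl, zu)):
        raise ValueError(
            f"overlap_slices must be in (0, {min(zl, zu)}], got {overlap_slices}"
        )
    if mode not in ("ramp", "take-lower"):
        raise ValueError(f"unknown merge mode {mode!r}")

    nz = zl + zu - overlap_slices
    out = np.empty((nz,) + lower.data.shape[1:], dtype=lower.data.dtype)
    out[: zl - overlap_slices] = lower.data[: zl - overlap_slices]
    out[zl:] = upper.data[overlap_slices:]

    lo = lower.data[zl - overlap_slices :]
    up = upper.data[:overlap_slices]
    if mode == "take-lower":
        out[zl - overlap_slices : zl] = lo
    else:
        # Weight for the upper scan rises linearly through the overlap.  The
        # "lo + w*(up - lo)" form guarantees exact reconstruction when both
        # scans hold identical data in the overlap.
        w = (np.arange(1, overlap_slices + 1) / (overlap_slices + 1.0))[:, None, None]
        blended = lo + w * (up.astype(np.float64) - lo)
        if np.issubdtype(out.dtype, np.integer):
            blended = np.rint(blended)
        out[zl - overlap_slices : zl] = blended.astype(out.dtype)
    return GreyVolume(out, lower.voxel_size_um, lower.origin_um)
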