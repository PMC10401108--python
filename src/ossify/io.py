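"""Image-stack, label-volume and table I/O.

Every volumetric file is plain (multipage) TIFF; tables are CSV with a
leading ``# units:`` comment line; results and configurations are JSON.
Units are fixed package-wide: lengths in µm, volumes in µm³ (mm³ only for
micro-CT-scale bone volumes), times in seconds or minutes as labelled.

Axis convention: arrays are indexed ``(z, y, x)`` with z the milling /
slice direction.  Physical position of voxel index ``i`` is
``i * voxel_size`` (voxel-corner convention); centroids are reported as
the mean voxel index times the voxel size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DENSITY = "density"
STRUCTURE = "structure"

_UNITS_LINE = "# units: lengths um, volumes um^3, times s unless labelled"


class StackIOError(ValueError):
    """Raised for malformed stacks or tables."""


@dataclass
class ImageStack:
    """A 3D scalar intensity volume with isotropic physical voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity grid, slice-major.
    voxel_size : float
        Edge length of one voxel in µm (isotropic).
    channel : str
        ``"density"`` (BSE-like, electron-density contrast) or
        ``"structure"`` (Inlens/SE-like, surface-potential contrast).
    bit_depth : int
        Nominal bit depth of the acquisition (8 for uint8 data).
    """

    voxels: np.ndarray
    voxel_size: float
    channel: str = DENSITY
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise StackIOError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise StackIOError("every axis must have at least one voxel")
        if not self.voxel_size > 0:
            raise StackIOError("voxel_size must be positive (µm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size) ** 3


@dataclass
class LabelVolume:
    """Integer-labelled segmentation aligned to an :class:`ImageStack`.

    ``labels`` is a non-negative integer grid; 0 is background and
    positive labels are contiguous ids 1..K within the class.
    """

    labels: np.ndarray
    class_name: str
    voxel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise StackIOError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise StackIOError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise StackIOError("labels must be non-negative")
        if not self.voxel_size > 0:
            raise StackIOError("voxel_size must be positive (µm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


def _is_grayscale(arr: np.ndarray) -> bool:
    return arr.ndim == 2


def read_stack(path, voxel_size: float | None = None, channel: str = DENSITY) -> ImageStack:
    """Read a grayscale multipage TIFF, or a directory of per-slice TIFFs.

    Slices in a directory are ordered lexicographically by file name
    (``s1, s10, s2`` — document your zero padding).  ``voxel_size`` given
    as an argument wins over any value stored in the TIFF metadata; one
    of the two must be available.
    """
    path = Path(path)
    meta_voxel_size = None
    if path.is_dir():
        slice_paths = sorted(p for p in path.iterdir()
                             if p.suffix.lower() in (".tif", ".tiff"))
        if not slice_paths:
            raise StackIOError(f"no TIFF slices found in directory {path}")
        planes = []
        shape = None
        for p in slice_paths:
            arr = tifffile.imread(p)
            if not _is_grayscale(arr):
                raise StackIOError(f"slice {p.name} is not grayscale (shape {arr.shape})")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise StackIOError(
                    f"slice {p.name} has shape {arr.shape}, expected {shape}")
            planes.append(arr)
        voxels = np.stack(planes, axis=0)
    else:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if getattr(page, "samplesperpixel", 1) != 1:
                raise StackIOError(f"{path.name} is not grayscale "
                                   f"({page.samplesperpixel} samples per pixel)")
            voxels = tif.asarray()
            desc = page.description or ""
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxels.ndim != 3:
            raise StackIOError(
                f"{path.name}: expected grayscale slices, got array of shape {voxels.shape}")
        try:
            meta = json.loads(desc)
            meta_voxel_size = float(meta["voxel_size_um"])
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            meta_voxel_size = None
    vs = voxel_size if voxel_size is not None else meta_voxel_size
    if vs is None:
        raise StackIOError("voxel_size not given and not stored in the TIFF metadata")
    bit_depth = voxels.dtype.itemsize * 8
    return ImageStack(voxels=voxels, voxel_size=float(vs), channel=channel,
                      bit_depth=int(bit_depth))


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multipage TIFF; voxel size goes into the
    ImageDescription tag as JSON so round trips are self-describing."""
    path = Path(path)
    meta = json.dumps({"voxel_size_um": stack.voxel_size, "channel": stack.channel,
                       "units": "um"})
    tifffile.imwrite(path, stack.voxels, description=meta,
                     photometric="minisblack")


def read_labels(path, voxel_size: float | None = None, class_name: str = "") -> LabelVolume:
    """Read a label TIFF written by :func:`write_labels`."""
    stack = read_stack(path, voxel_size=voxel_size, channel=class_name or "labels")
    labels = stack.voxels
    if not np.issubdtype(labels.dtype, np.integer):
        raise StackIOError("label TIFF must hold integer data")
    return LabelVolume(labels=labels, class_name=class_name, voxel_size=stack.voxel_size)


def write_labels(vol: LabelVolume, path) -> None:
    meta = json.dumps({"voxel_size_um": vol.voxel_size, "class_name": vol.class_name,
                       "units": "um"})
    tifffile.imwrite(Path(path), vol.labels, description=meta,
                     photometric="minisblack")


# -- tabular I/O -------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    """Flatten a list of dataclass records into a DataFrame.

    3-vector fields (centroids) are expanded into ``_z/_y/_x`` columns.
    """
    rows = []
    for rec in records:
        row = {}
        for f in fields(rec):
            val = getattr(rec, f.name)
            if isinstance(val, (tuple, list, np.ndarray)) and len(val) == 3:
                for axis, v in zip("zyx", val):
                    row[f"{f.name}_{axis}"] = float(v)
            else:
                row[f.name] = val
        rows.append(row)
    return pd.DataFrame(rows)


def _expected_columns(record_type) -> list[str]:
    cols = []
    for f in fields(record_type):
        if f.type in ("tuple[float, float, float]",) or f.name == "centroid":
            cols.extend(f"{f.name}_{axis}" for axis in "zyx")
        else:
            cols.append(f.name)
    return cols


def write_table(records, path, record_type=None) -> None:
    """Write records to CSV with a units comment line and full float precision.

    An empty record list still produces a header-only file when
    ``record_type`` is given (so the schema survives).
    """
    path = Path(path)
    if len(records) == 0:
        if record_type is None:
            raise StackIOError("record_type required to write an empty table")
        frame = pd.DataFrame(columns=_expected_columns(record_type))
    else:
        frame = records_to_frame(records)
    with open(path, "w") as fh:
        fh.write(_UNITS_LINE + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_table(path, record_type) -> list:
    """Read a CSV written by :func:`write_table` back into dataclass records.

    Raises :class:`StackIOError` listing any missing required columns.
    """
    frame = pd.read_csv(Path(path), comment="#")
    expected = _expected_columns(record_type)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise StackIOError(
            f"table {Path(path).name} is missing required columns: {', '.join(missing)}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in fields(record_type):
            if f"{f.name}_z" in expected:
                kwargs[f.name] = (float(row[f"{f.name}_z"]), float(row[f"{f.name}_y"]),
                                  float(row[f"{f.name}_x"]))
            else:
                val = row[f.name]
                # restore dataclass field types from CSV strings/numpy scalars
                if f.type in ("int", int):
                    val = int(val)
                elif f.type in ("float", float):
                    val = float(val)
                elif f.type in ("bool", bool):
                    val = bool(val) if isinstance(val, (bool, np.bool_)) \
                        else str(val).strip().lower() in ("true", "1")
                kwargs[f.name] = val
        records.append(record_type(**kwargs))
    return records


def write_json(obj, path) -> None:
    """Serialize a dataclass (or dict) result to JSON with a units field."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = dataclasses.asdict(obj)
    else:
        payload = dict(obj)
    payload.setdefault("units", "um, um^3, s, min as labelled")
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)!r}")
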