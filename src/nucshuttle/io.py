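"""Raster containers and TIFF/OME-TIFF input/output.

The package's universal raster type is :class:`VolumeStack`: one multi-channel
3D image with an explicit per-axis voxel size in micrometres, stored in the
canonical axis order ``(channel, z, y, x)``.  Time-lapse data is an ordered
sequence of identically shaped stacks (:class:`TimeLapse`) with timestamps in
seconds from the first frame, i.e. axis order ``(t, channel, z, y, x)`` on
disk.

Coordinates are 0-based voxel indices; the physical position of voxel ``i``
along an axis is ``i * voxel_size`` (voxel centres), and all crop ranges are
half-open.  Grey values are stored as unsigned 16-bit on disk when the data is
integer-valued, and processed as floating point in memory.
"""

from __future__ import annotations

import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "VolumeStack",
    "TimeLapse",
    "read_stack",
    "write_stack",
    "read_timelapse",
    "write_timelapse",
]


@dataclass
class VolumeStack:
    """A multi-channel 3D fluorescence image with physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)`` holding non-negative,
        finite grey values.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel_names
        One label per channel, e.g. ``("nuclear", "cytoplasm", "reporter")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must have axes (channel, z, y, x); got {self.data.ndim} axes"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be three strictly positive values, got {self.voxel_size}")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grey values must be finite")
        if self.data.min() < 0:
            raise ValueError("grey values must be non-negative")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical span (z, y, x) in µm covered by the voxel grid."""
        return tuple(n * v for n, v in zip(self.shape_zyx, self.voxel_size))

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {list(self.channel_names)}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """The 3D ``(z, y, x)`` array for one named channel (a view)."""
        return self.data[self.channel_index(name)]

    def with_data(self, data: np.ndarray) -> "VolumeStack":
        return VolumeStack(data, self.voxel_size, self.channel_names)

    def astype_float(self) -> "VolumeStack":
        if np.issubdtype(self.data.dtype, np.floating):
            return self
        return self.with_data(self.data.astype(np.float64))


@dataclass
class TimeLapse:
    """An ordered sequence of identical-geometry stacks with timestamps.

    ``timestamps`` are seconds from the first frame; strictly increasing,
    first entry 0.
    """

    frames: list[VolumeStack]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("time lapse needs at least one frame")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if self.timestamps[0] != 0:
            raise ValueError("first timestamp must be 0")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        ref = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=1):
            if f.data.shape != ref.data.shape:
                raise ValueError(f"frame {i} shape differs from frame 0")
            if f.voxel_size != ref.voxel_size:
                raise ValueError(f"frame {i} voxel size differs from frame 0")
            if f.channel_names != ref.channel_names:
                raise ValueError(f"frame {i} channel names differ from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.frames[0].voxel_size

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.frames[0].channel_names


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def _storage_dtype(data: np.ndarray) -> np.ndarray:
    """uint16 on disk for integer-valued data in range, float32 otherwise."""
    if np.issubdtype(data.dtype, np.integer):
        if data.min() >= 0 and data.max() <= np.iinfo(np.uint16).max:
            return data.astype(np.uint16)
        return data.astype(np.float32)
    if np.all(data == np.round(data)) and data.size and data.max() <= np.iinfo(np.uint16).max:
        return data.astype(np.uint16)
    return data.astype(np.float32)


def write_stack(stack: VolumeStack, path: str | Path) -> None:
    """Write a :class:`VolumeStack` as OME-TIFF with voxel size and channel names.

    Integer grey values round-trip losslessly (stored as uint16); float data is
    stored as float32.
    """
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    arr = _storage_dtype(stack.data)
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeZ": dz,
        "PhysicalSizeY": dy,
        "PhysicalSizeX": dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    tifffile.imwrite(path, arr, ome=True, metadata=metadata)


def _parse_ome(xml: str) -> tuple[tuple[float, float, float] | None, list[str] | None]:
    """Extract (dz, dy, dx) in µm and channel names from OME-XML (namespace-agnostic)."""
    root = _ET.fromstring(xml)

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    voxel = None
    names: list[str] = []
    for el in root.iter():
        if local(el.tag) == "Pixels":
            a = el.attrib
            if all(k in a for k in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX")):
                voxel = (
                    float(a["PhysicalSizeZ"]),
                    float(a["PhysicalSizeY"]),
                    float(a["PhysicalSizeX"]),
                )
            for ch in el:
                if local(ch.tag) == "Channel" and "Name" in ch.attrib:
                    names.append(ch.attrib["Name"])
            break
    return voxel, (names or None)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _to_czyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/reshape a tifffile series into (C, Z, Y, X)."""
    axes = axes.upper()
    # tifffile reports bare multi-channel TIFFs as samples (S): treat as C
    if "C" not in axes and "S" in axes:
        axes = axes.replace("S", "C")
    # plain multi-page TIFFs come back with unlabelled (Q/I) axes: interpret
    # trailing unknown as Z, a leading second unknown as C
    for unknown in "QI":
        if unknown in axes and "Z" not in axes:
            i = axes.rfind(unknown)
            axes = axes[:i] + "Z" + axes[i + 1 :]
        if unknown in axes and "C" not in axes:
            i = axes.rfind(unknown)
            axes = axes[:i] + "C" + axes[i + 1 :]
    # squeeze singleton axes tifffile may report (S, Q, T of length 1)
    keep = [i for i, ax in enumerate(axes) if ax in "CZYX"]
    extra = [i for i in range(arr.ndim) if i not in keep]
    for i in sorted(extra, reverse=True):
        if arr.shape[i] != 1:
            raise ValueError(f"unsupported non-singleton axis {axes[i]!r} in TIFF")
        arr = np.squeeze(arr, axis=i)
    axes = "".join(ax for ax in axes if ax in "CZYX")
    order = [axes.index(ax) for ax in "CZYX" if ax in axes]
    arr = np.transpose(arr, order)
    axes = "".join(ax for ax in "CZYX" if ax in axes)
    if "C" not in axes:
        arr = arr[None]
    if "Z" not in axes:
        arr = arr[:, None] if arr.ndim == 3 else arr.reshape(arr.shape[0], 1, *arr.shape[1:])
    return arr


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
) -> VolumeStack:
    """Read a TIFF/OME-TIFF as a :class:`VolumeStack`.

    Voxel size is taken from embedded OME metadata (or a ``<file>.yaml``
    sidecar) unless ``voxel_size_override`` is given; a file with no voxel
    size and no override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        voxel, names = (None, None)
        if tf.ome_metadata:
            voxel, names = _parse_ome(tf.ome_metadata)
    arr = _to_czyx(np.asarray(arr), axes)

    side = _read_sidecar(path)
    if voxel is None and "voxel_size" in side:
        voxel = tuple(float(v) for v in side["voxel_size"])
    if names is None and "channel_names" in side:
        names = [str(n) for n in side["channel_names"]]

    if voxel_size_override is not None:
        voxel = tuple(float(v) for v in voxel_size_override)
    if voxel is None:
        raise ValueError(f"voxel size unknown for {path}: no metadata and no override")
    if any(v <= 0 for v in voxel):
        raise ValueError(f"non-positive voxel size {voxel}")
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    return VolumeStack(arr, voxel, tuple(names))


def write_timelapse(tl: TimeLapse, path: str | Path) -> None:
    """Write a :class:`TimeLapse` as a 5D (TCZYX) OME-TIFF.

    Frame timestamps (seconds) go into a ``<file>.yaml`` sidecar, since OME's
    uniform TimeIncrement cannot represent irregular sampling.
    """
    path = Path(path)
    ref = tl.frames[0]
    dz, dy, dx = ref.voxel_size
    arr = _storage_dtype(np.stack([f.data for f in tl.frames]))
    metadata = {
        "axes": "TCZYX",
        "PhysicalSizeZ": dz,
        "PhysicalSizeY": dy,
        "PhysicalSizeX": dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(ref.channel_names)},
    }
    tifffile.imwrite(path, arr, ome=True, metadata=metadata)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({"timestamps_s": [float(t) for t in tl.timestamps]}, fh)


def read_timelapse(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
) -> TimeLapse:
    """Read a 5D (TCZYX) OME-TIFF written by :func:`write_timelapse`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = np.asarray(series.asarray())
        axes = series.axes.upper()
        voxel, names = (None, None)
        if tf.ome_metadata:
            voxel, names = _parse_ome(tf.ome_metadata)
    if "T" not in axes:
        raise ValueError(f"{path} has no time axis (axes={axes})")
    t_idx = axes.index("T")
    arr = np.moveaxis(arr, t_idx, 0)
    rest_axes = axes[:t_idx] + axes[t_idx + 1 :]

    side = _read_sidecar(path)
    if voxel_size_override is not None:
        voxel = tuple(float(v) for v in voxel_size_override)
    if voxel is None and "voxel_size" in side:
        voxel = tuple(float(v) for v in side["voxel_size"])
    if voxel is None:
        raise ValueError(f"voxel size unknown for {path}")
    if names is None:
        names = [f"ch{i}" for i in range(_to_czyx(arr[0], rest_axes).shape[0])]

    frames = [
        VolumeStack(_to_czyx(arr[t], rest_axes), voxel, tuple(names))
        for t in range(arr.shape[0])
    ]
    if "timestamps_s" in side:
        timestamps = np.asarray(side["timestamps_s"], dtype=float)
    else:
        timestamps = np.arange(len(frames), dtype=float)
    return TimeLapse(frames, timestamps)
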