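"""Path-based axonal intensity profiling.

The axon path (a 3D polyline starting at the axon hillock) is an input —
from phantom ground truth, an SWC file or a 3-column CSV in µm — never traced
here: the measurement, not the tracing, is the deliverable.  The path is
resampled into fixed-length arc segments; per segment the mean grey value is
taken over the voxels the line passes through (sampling radius 0, the
default) or over all voxels within a tube radius.  The whole-path mean is the
length-weighted mean of the segment means.

A reporter is declared "detected" along the axon when the whole-path mean
exceeds the background estimate by a configurable multiple of the background
sampling SD (default 2); this criterion is this package's operational
definition of detection above background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import TimeLapse, VolumeStack
from .preprocess import BackgroundEstimate

__all__ = [
    "AxonPath",
    "AxonProfile",
    "read_path",
    "sample_path",
    "axon_baseline_test",
    "axon_timecourse",
    "detect_spike",
]


@dataclass
class AxonPath:
    """Ordered 3D polyline in µm (z, y, x), starting at the axon hillock."""

    polyline: np.ndarray
    step: float = 1.0  # segment length in µm

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 3 or len(self.polyline) < 2:
            raise ValueError("polyline must be an (N>=2, 3) array of µm points")
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive polyline points must be distinct")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum()
        )

    def resample(self, spacing: float) -> np.ndarray:
        """Points along the path at the given arc-length spacing (µm)."""
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.arange(0.0, cum[-1] + spacing / 2, spacing)
        s = np.clip(s, 0.0, cum[-1])
        out = np.empty((len(s), 3))
        for ax in range(3):
            out[:, ax] = np.interp(s, cum, self.polyline[:, ax])
        return out


@dataclass
class AxonProfile:
    """Per-segment intensity samples along the axon path.

    ``arc_positions`` are segment-centre arc lengths from the hillock;
    ``segment_means`` maps channel name to one mean grey value per segment;
    ``whole_path_mean`` is the length-weighted mean of the segment means.
    """

    arc_positions: np.ndarray
    segment_lengths: np.ndarray
    segment_means: dict[str, np.ndarray]
    whole_path_mean: dict[str, float]
    background: BackgroundEstimate | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc_positions) <= 0):
            raise ValueError("arc positions must be strictly increasing")


def read_path(path: str | Path, step: float = 1.0) -> AxonPath:
    """Load an axon path from SWC or a 3-column CSV (z, y, x in µm).

    SWC rows are ``id type x y z radius parent``; the traced order is kept and
    coordinates are converted to the package's (z, y, x) convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".swc":
        pts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split()
                x, y, z = float(f[2]), float(f[3]), float(f[4])
                pts.append((z, y, x))
        return AxonPath(np.asarray(pts), step=step)
    arr = pd.read_csv(path, comment="#").to_numpy(dtype=float)[:, :3]
    return AxonPath(arr, step=step)


def _segment_voxels(
    stack: VolumeStack,
    pts: np.ndarray,
    radius: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique voxel indices on (or within ``radius`` of) densely sampled points."""
    vs = np.asarray(stack.voxel_size)
    shape = np.asarray(stack.shape_zyx)
    if radius <= 0:
        idx = np.round(pts / vs).astype(int)
    else:
        lo = np.maximum(np.floor((pts.min(axis=0) - radius) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((pts.max(axis=0) + radius) / vs).astype(int) + 1, shape)
        grids = [np.arange(lo[ax], hi[ax]) * vs[ax] for ax in range(3)]
        Z, Y, X = np.meshgrid(*grids, indexing="ij")
        centers = np.stack([Z, Y, X], axis=-1).reshape(-1, 3)
        tree = cKDTree(pts)
        d, _ = tree.query(centers, k=1, distance_upper_bound=radius + 1e-9)
        sel = np.isfinite(d)
        idx = np.round(centers[sel] / vs).astype(int)
    if len(idx) == 0:
        raise ValueError("segment samples no voxels")
    bad = np.any((idx < 0) | (idx >= shape), axis=1)
    if np.any(bad):
        s = pts[min(int(np.flatnonzero(bad)[0]), len(pts) - 1)]
        raise ValueError(f"path exits the volume near (z,y,x)=({s[0]:.2f},{s[1]:.2f},{s[2]:.2f}) µm")
    idx = np.unique(idx, axis=0)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def sample_path(
    stack: VolumeStack,
    path: AxonPath,
    channels: Sequence[str] | None = None,
    radius: float = 0.0,
    background: BackgroundEstimate | None = None,
) -> AxonProfile:
    """Per-segment and whole-path mean grey values along the axon path.

    The path is cut into arcs of ``path.step`` µm; for each arc the mean grey
    value is taken over the voxels the line passes through (``radius=0``) or
    within ``radius`` µm of it.
    """
    if channels is None:
        channels = list(stack.channel_names)
    dense_spacing = min(stack.voxel_size) / 4.0
    pts = path.resample(dense_spacing)
    arc = np.arange(len(pts)) * dense_spacing
    n_seg = max(int(np.ceil(path.length / path.step - 1e-9)), 1)

    seg_means: dict[str, list[float]] = {ch: [] for ch in channels}
    seg_centers = []
    seg_lengths = []
    for i in range(n_seg):
        s0, s1 = i * path.step, min((i + 1) * path.step, path.length)
        sel = (arc >= s0 - 1e-9) & (arc <= s1 + 1e-9)
        zz, yy, xx = _segment_voxels(stack, pts[sel], radius)
        for ch in channels:
            seg_means[ch].append(float(stack.channel(ch)[zz, yy, xx].mean()))
        seg_centers.append((s0 + s1) / 2)
        seg_lengths.append(s1 - s0)

    lengths = np.asarray(seg_lengths)
    means = {ch: np.asarray(v) for ch, v in seg_means.items()}
    whole = {
        ch: float(np.average(means[ch], weights=lengths)) for ch in channels
    }
    return AxonProfile(
        arc_positions=np.asarray(seg_centers),
        segment_lengths=lengths,
        segment_means=means,
        whole_path_mean=whole,
        background=background,
    )


def axon_baseline_test(
    profile: AxonProfile,
    background: BackgroundEstimate,
    channel: str,
    criterion_sd: float = 2.0,
) -> dict:
    """Is the whole-path mean detectably above background?

    Returns ``{"above_background": bool, "effect": mean − background}``;
    detection requires the mean to exceed background by more than
    ``criterion_sd`` × the background sampling SD (strict inequality, so a
    mean exactly at background is not detected).
    """
    mean = profile.whole_path_mean[channel]
    bg = background.mean[channel]
    sd = background.sd[channel]
    return {
        "above_background": bool(mean > bg + criterion_sd * sd),
        "effect": float(mean - bg),
    }


def axon_timecourse(
    tl: TimeLapse,
    path: AxonPath,
    channel: str,
    radius: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whole-path mean per frame plus the (time × segment) intensity matrix."""
    means = []
    matrix = []
    for i, frame in enumerate(tl.frames):
        try:
            prof = sample_path(frame, path, channels=[channel], radius=radius)
        except ValueError as exc:
            raise ValueError(f"frame {i} (t={tl.timestamps[i]:g} s): {exc}") from exc
        means.append(prof.whole_path_mean[channel])
        matrix.append(prof.segment_means[channel])
    return np.asarray(tl.timestamps), np.asarray(means), np.asarray(matrix)


def detect_spike(
    series: np.ndarray,
    timestamps: np.ndarray | None = None,
    min_fold: float = 3.0,
    window: int = 2,
) -> float | None:
    """Earliest time the trailing windowed mean exceeds ``min_fold`` × baseline.

    The baseline is the mean of the first ``window`` frames.  Returns the
    timestamp (or the frame index when ``timestamps`` is None); ``None`` if
    the series never crosses the threshold.  A non-positive baseline (e.g. a
    background-subtracted empty axon) is floored at a tiny positive value, so
    a flat zero series still yields ``None``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 3:
        raise ValueError("series must be 1D with at least 3 frames")
    if window < 1 or window > len(series):
        raise ValueError("window must be in [1, len(series)]")
    if timestamps is None:
        timestamps = np.arange(len(series), dtype=float)
    baseline = float(series[:window].mean())
    threshold = min_fold * max(baseline, np.finfo(float).tiny)
    kernel = np.ones(window) / window
    rolled = np.convolve(series, kernel, mode="valid")  # rolled[i] = mean of [i, i+window)
    for i, v in enumerate(rolled):
        end = i + window - 1  # trailing-window position
        if end < window:  # skip the baseline window itself
            continue
        if v > threshold:
            return float(timestamps[end])
    return None
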