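"""Background estimation, smoothing and Richardson–Lucy deconvolution.

Background is estimated the way the axon analysis defines it: short line
segments placed in regions of the image without a positively expressing cell,
the mean grey value taken per line and averaged across lines.  The mean filter
acts in 2D within each z-plane by default (it is a per-image display filter in
origin), switchable to 3D.  Deconvolution is off by default in the measurement
pipeline: it is provided for visualisation-style workflows, and measurements
must be reproducible without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import VolumeStack

__all__ = [
    "BackgroundEstimate",
    "estimate_background_lines",
    "auto_background_lines",
    "mean_filter",
    "gaussian_psf",
    "richardson_lucy",
]


@dataclass
class BackgroundEstimate:
    """Per-channel background grey levels and how they were sampled.

    ``mean``/``sd`` map channel name to the mean and SD of the sampled voxel
    grey values; ``line_means`` holds the per-line means that were averaged;
    ``lines`` records the sampled segments (pairs of (z, y, x) µm points).
    """

    mean: dict[str, float]
    sd: dict[str, float]
    line_means: dict[str, list[float]] = field(default_factory=dict)
    lines: list[np.ndarray] = field(default_factory=list)
    n_voxels: int = 0

    def __post_init__(self) -> None:
        for ch, m in self.mean.items():
            if m < 0:
                raise ValueError(f"background mean for {ch!r} is negative")


def _line_voxels(
    stack: VolumeStack, p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique voxel indices intersected by the segment p0→p1 (µm)."""
    vs = np.asarray(stack.voxel_size)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValueError("background line has zero length")
    n = max(int(np.ceil(length / (vs.min() / 4.0))), 2)
    t = np.linspace(0.0, 1.0, n)
    pts = p0 + t[:, None] * (p1 - p0)
    idx = np.round(pts / vs).astype(int)
    shape = np.asarray(stack.shape_zyx)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError(f"line from {p0} to {p1} µm leaves the stack")
    idx = np.unique(idx, axis=0)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def estimate_background_lines(
    stack: VolumeStack,
    channel: str | Sequence[str] | None = None,
    lines: Sequence[np.ndarray] | None = None,
    n_lines: int = 2,
    line_length_um: float = 8.0,
    seed: int = 0,
) -> BackgroundEstimate:
    """Estimate background from line samples in cell-free regions.

    ``lines`` is a sequence of ``(2, 3)`` arrays (segment endpoints, µm,
    (z, y, x)); if omitted, ``n_lines`` lines of ``line_length_um`` are
    auto-placed in the darkest regions of the stack (seeded).  The estimate
    per channel is the mean of per-line mean grey values.
    """
    if channel is None:
        channels = list(stack.channel_names)
    elif isinstance(channel, str):
        channels = [channel]
    else:
        channels = list(channel)
    if lines is None:
        lines = auto_background_lines(stack, n_lines, line_length_um, seed)
    lines = [np.asarray(l, dtype=float) for l in lines]
    if len(lines) < 1:
        raise ValueError("at least one background line required")

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    line_means: dict[str, list[float]] = {}
    n_vox = 0
    for ch in channels:
        data = stack.channel(ch)
        per_line = []
        values = []
        for line in lines:
            zz, yy, xx = _line_voxels(stack, line[0], line[1])
            v = data[zz, yy, xx]
            per_line.append(float(v.mean()))
            values.append(v)
        values = np.concatenate(values)
        n_vox = len(values)
        mean[ch] = float(np.mean(per_line))
        sd[ch] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        line_means[ch] = per_line
    return BackgroundEstimate(mean, sd, line_means, lines, n_vox)


def auto_background_lines(
    stack: VolumeStack,
    n_lines: int = 2,
    line_length_um: float = 8.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Place x-parallel line segments in low-intensity (off-cell) regions.

    Candidate positions are drawn seeded; the ``n_lines`` candidates with the
    lowest summed intensity across channels win.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    vs = np.asarray(stack.voxel_size)
    shape = np.asarray(stack.shape_zyx)
    extent = (shape - 1) * vs
    if extent[2] <= line_length_um:
        raise ValueError("stack too small in x for the requested line length")
    total = stack.data.sum(axis=0)
    candidates = []
    for _ in range(max(40, 10 * n_lines)):
        z = rng.uniform(0, extent[0])
        y = rng.uniform(0, extent[1])
        x0 = rng.uniform(0, extent[2] - line_length_um)
        p0 = np.array([z, y, x0])
        p1 = np.array([z, y, x0 + line_length_um])
        zz, yy, xx = _line_voxels(stack, p0, p1)
        candidates.append((float(total[zz, yy, xx].mean()), p0, p1))
    candidates.sort(key=lambda c: c[0])
    return [np.stack([p0, p1]) for _, p0, p1 in candidates[:n_lines]]


def mean_filter(stack: VolumeStack, radius: int, mode: str = "2d") -> VolumeStack:
    """Box mean filter of the given voxel radius; radius 0 is the identity.

    ``mode="2d"`` (default) averages the square neighbourhood within each
    z-plane; ``mode="3d"`` averages the full cube.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return stack
    k = 2 * int(radius) + 1
    size = (1, 1, k, k) if mode == "2d" else (1, k, k, k)
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    data = ndimage.uniform_filter(stack.data.astype(np.float64), size=size, mode="reflect")
    return stack.with_data(data)


def gaussian_psf(
    sigma_um: Sequence[float],
    voxel_size: Sequence[float],
    truncate: float = 3.0,
) -> np.ndarray:
    """A unit-sum anisotropic Gaussian PSF kernel sampled on the voxel grid."""
    sig_vox = np.asarray(sigma_um) / np.asarray(voxel_size)
    half = np.maximum(np.ceil(truncate * sig_vox).astype(int), 1)
    grids = [np.arange(-h, h + 1) for h in half]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    k = np.exp(
        -0.5 * ((zz / sig_vox[0]) ** 2 + (yy / sig_vox[1]) ** 2 + (xx / sig_vox[2]) ** 2)
    )
    return k / k.sum()


def richardson_lucy(
    stack: VolumeStack,
    psf: np.ndarray,
    iterations: int,
    channel: str | None = None,
) -> VolumeStack:
    """Richardson–Lucy deconvolution with reflective boundary handling.

    The standard multiplicative update under a Poisson noise model:
    ``est <- est * (K* ⊗ (data / (K ⊗ est)))`` with the PSF ``K`` and its
    adjoint (mirrored kernel) ``K*``.  Output is non-negative; a delta PSF
    reproduces the input exactly for any iteration count.  Reflective padding
    avoids edge ringing without introducing flux from outside the image.
    """
    psf = np.asarray(psf, dtype=np.float64)
    if psf.ndim != 3:
        raise ValueError("psf must be a 3D kernel")
    if np.any(psf < 0):
        raise ValueError("psf must be non-negative")
    total = psf.sum()
    if total <= 0:
        raise ValueError("psf must have positive total")
    if any(p > s for p, s in zip(psf.shape, stack.shape_zyx)):
        raise ValueError("psf larger than the stack")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    psf = psf / total
    psf_mirror = psf[::-1, ::-1, ::-1]

    channels = [channel] if channel is not None else list(stack.channel_names)
    out = stack.data.astype(np.float64).copy()
    eps = np.finfo(np.float64).tiny
    for ch in channels:
        i = stack.channel_index(ch)
        data = out[i]
        est = np.full_like(data, max(data.mean(), eps))
        for _ in range(int(iterations)):
            blurred = ndimage.convolve(est, psf, mode="mirror")
            ratio = data / np.maximum(blurred, eps)
            est = est * ndimage.convolve(ratio, psf_mirror, mode="mirror")
        out[i] = np.clip(est, 0.0, None)
    return stack.with_data(out)
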