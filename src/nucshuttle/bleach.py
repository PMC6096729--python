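"""Radial attenuation of fluorescence around the UV target column.

The focused UV beam forms a narrow column parallel to the optical (z) axis;
bleaching attenuates with in-plane distance from the column.  Voxels of a
pre/post image pair are binned by their 2D radial distance to the column
centre and the per-bin attenuation is ``1 − mean(post)/mean(pre)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VolumeStack

__all__ = ["AttenuationProfile", "radial_attenuation", "attenuation_at"]


@dataclass
class AttenuationProfile:
    """Binned radial attenuation: 1 − post/pre per radius bin."""

    radii: np.ndarray  # bin centres, µm
    attenuation: np.ndarray  # fraction per bin; NaN where pre mean was 0
    counts: np.ndarray  # voxels per bin

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be increasing")
        if not (len(self.radii) == len(self.attenuation) == len(self.counts)):
            raise ValueError("radii, attenuation and counts must align")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.attenuation)


def radial_attenuation(
    pre: VolumeStack,
    post: VolumeStack,
    channel: str,
    column_center: tuple[float, float],
    bin_width: float = 2.0,
    max_radius: float | None = None,
    annulus_mask: np.ndarray | None = None,
) -> AttenuationProfile:
    """Radial attenuation profile around a z-parallel column at ``(y, x)`` µm.

    ``pre`` and ``post`` must share shape and voxel size (registration is
    assumed; no motion correction).  Bins with zero pre-bleach intensity are
    flagged as NaN and excluded from readouts.  ``annulus_mask`` optionally
    restricts the sampled voxels (e.g. to a uniform-expression region).
    """
    if pre.data.shape != post.data.shape or pre.voxel_size != post.voxel_size:
        raise ValueError("pre and post stacks must share shape and voxel size")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cy, cx = column_center
    nz, ny, nx = pre.shape_zyx
    dz, dy, dx = pre.voxel_size
    yy = (np.arange(ny) * dy - cy) ** 2
    xx = (np.arange(nx) * dx - cx) ** 2
    r2d = np.sqrt(yy[:, None] + xx[None, :])
    r = np.broadcast_to(r2d[None, :, :], (nz, ny, nx)).ravel()
    a = pre.channel(channel).ravel().astype(np.float64)
    b = post.channel(channel).ravel().astype(np.float64)
    if annulus_mask is not None:
        sel = np.asarray(annulus_mask, dtype=bool).ravel()
        r, a, b = r[sel], a[sel], b[sel]
    if max_radius is None:
        max_radius = float(r.max())
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    which = np.digitize(r, edges) - 1
    nbins = len(edges) - 1
    valid = (which >= 0) & (which < nbins)
    which, a, b = which[valid], a[valid], b[valid]

    counts = np.bincount(which, minlength=nbins)
    pre_sum = np.bincount(which, weights=a, minlength=nbins)
    post_sum = np.bincount(which, weights=b, minlength=nbins)
    att = np.full(nbins, np.nan)
    ok = (counts > 0) & (pre_sum > 0)
    att[ok] = 1.0 - post_sum[ok] / pre_sum[ok]
    centres = (edges[:-1] + edges[1:]) / 2
    return AttenuationProfile(radii=centres, attenuation=att, counts=counts)


def attenuation_at(profile: AttenuationProfile, radius: float) -> float:
    """Attenuation at a radius by linear interpolation between bin centres."""
    ok = profile.valid
    radii = profile.radii[ok]
    att = profile.attenuation[ok]
    if len(radii) == 0:
        raise ValueError("profile has no valid bins")
    if not radii[0] <= radius <= radii[-1]:
        raise ValueError(
            f"radius {radius} µm outside profile range [{radii[0]}, {radii[-1]}] µm"
        )
    return float(np.interp(radius, radii, att))
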