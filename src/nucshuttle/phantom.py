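"""Synthetic single-neuron phantoms with full ground truth.

This module generates the test bed for every measurement in the package: a
geometric scene (soma and nucleus ellipsoids, an axon tube, nuclear granules),
per-compartment fluorophore emission densities, a confocal-like forward model
(partial-volume rasterization, Gaussian PSF blur, Poisson photon noise,
Gaussian read noise), a stereotyped degeneration time course (soma swelling to
a sphere, nuclear-to-cytoplasmic reporter redistribution, pyknosis or
karyorrhexis, fragment release, axonal influx with a late spike, dissolution),
and a radially attenuating UV bleach column.

Scene coordinates are physical micrometres in ``(z, y, x)`` order; voxel ``i``
of the rendered grid is centred at ``origin + i * voxel_size``.  Every
stochastic operation is reproducible given its seed.

The PSF is a parametric anisotropic Gaussian — a standard confocal
approximation; :func:`render` accepts any externally supplied kernel through
``OpticsParams.psf_sigma`` being replaced by a custom kernel in
:func:`nucshuttle.preprocess.richardson_lucy`-style workflows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import TimeLapse, VolumeStack

__all__ = [
    "Ellipsoid",
    "Granule",
    "PhantomScene",
    "OpticsParams",
    "AxonalInflux",
    "FragmentRelease",
    "DegenerationParams",
    "ramp_curve",
    "build_scene",
    "default_axon",
    "grid_for_scene",
    "render",
    "simulate_degeneration",
    "apply_uv_bleach",
    "sample_granule_volumes",
]

REPORTER = "reporter"
NUCLEAR = "nuclear"
CYTOPLASM = "cytoplasm"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes in µm, (z, y, x) order."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError(f"semi-axes must be positive, got {self.semiaxes}")

    @property
    def volume(self) -> float:
        az, ay, ax = self.semiaxes
        return 4.0 / 3.0 * math.pi * az * ay * ax

    def scaled_coords(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        a = np.asarray(self.semiaxes)
        return (pts - c) / a

    def contains(self, pts: np.ndarray) -> np.ndarray:
        s = self.scaled_coords(np.atleast_2d(pts))
        return (s**2).sum(axis=-1) <= 1.0

    def surface_points(self, n: int = 256) -> np.ndarray:
        """Deterministic quasi-uniform surface sample (Fibonacci sphere)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        unit = np.stack(
            [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)],
            axis=1,
        )
        return np.asarray(self.center) + unit * np.asarray(self.semiaxes)

    def bbox(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        a = np.asarray(self.semiaxes) + margin
        return c - a, c + a


def sphere(center: Sequence[float], radius: float) -> Ellipsoid:
    return Ellipsoid(tuple(center), (radius, radius, radius))


@dataclass(frozen=True)
class Granule:
    """A spherical nuclear reporter accumulation.

    ``multiplier`` scales the nuclear reporter density inside the granule
    (e.g. 3.0 means three-fold concentrated relative to diffuse nucleoplasm).
    """

    center: tuple[float, float, float]
    radius: float
    multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("granule radius must be positive")
        if self.multiplier < 1:
            raise ValueError("granule multiplier must be >= 1")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    def as_ellipsoid(self) -> Ellipsoid:
        return sphere(self.center, self.radius)


def _sphere_inside_ellipsoid(center: Sequence[float], radius: float, ell: Ellipsoid) -> bool:
    # conservative sufficient criterion: scaled centre norm + r / min semi-axis <= 1
    s = np.linalg.norm(np.asarray(ell.scaled_coords(np.asarray(center, dtype=float))))
    return s + radius / min(ell.semiaxes) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class PhantomScene:
    """Geometric ground truth for one synthetic neuron.

    ``concentrations`` maps channel name -> compartment -> emission density
    (expected grey value per voxel before optics); compartments are
    ``"nucleus"``, ``"cytoplasm"`` and ``"axon"``.  Granule multipliers apply
    to the reporter channel's nuclear density.
    """

    soma: Ellipsoid
    nucleus: Ellipsoid
    concentrations: dict[str, dict[str, float]]
    axon: np.ndarray | None = None  # (N, 3) polyline, µm, starting at the hillock
    axon_radius: float = 0.4
    granules: list[Granule] = field(default_factory=list)
    nuclear_fraction_truth: float = float("nan")

    def __post_init__(self) -> None:
        if not np.all(self.soma.contains(self.nucleus.surface_points())):
            raise ValueError("nucleus must lie entirely inside the soma")
        for g in self.granules:
            if not _sphere_inside_ellipsoid(g.center, g.radius, self.nucleus):
                raise ValueError(f"granule at {g.center} not inside the nucleus")
        if self.axon is not None:
            self.axon = np.asarray(self.axon, dtype=float)
            if self.axon.ndim != 2 or self.axon.shape[1] != 3 or len(self.axon) < 2:
                raise ValueError("axon must be an (N>=2, 3) polyline in µm")
        for ch, comp in self.concentrations.items():
            for k, v in comp.items():
                if k not in ("nucleus", "cytoplasm", "axon"):
                    raise ValueError(f"unknown compartment {k!r} in channel {ch!r}")
                if v < 0:
                    raise ValueError("emission densities must be non-negative")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    @property
    def cytoplasm_volume(self) -> float:
        return self.soma.volume - self.nucleus.volume

    def reporter_masses(self, channel: str = REPORTER) -> tuple[float, float]:
        """Analytic (nuclear, cytoplasmic) reporter emission integrals."""
        conc = self.concentrations[channel]
        cn = conc.get("nucleus", 0.0)
        cc = conc.get("cytoplasm", 0.0)
        extra = sum((g.multiplier - 1.0) * g.volume for g in self.granules)
        return cn * (self.nucleus.volume + extra), cc * self.cytoplasm_volume

    def nuclear_fraction(self, channel: str = REPORTER) -> float:
        """Fraction of reporter emission inside the nucleus (analytic)."""
        mn, mc = self.reporter_masses(channel)
        if mn + mc == 0:
            raise ValueError("scene has no reporter emission")
        return mn / (mn + mc)

    def nuclear_fraction_numeric(
        self,
        channel: str = REPORTER,
        voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2),
        supersample: int = 4,
    ) -> float:
        """Recompute the nuclear fraction by brute-force grid integration.

        Independent of the analytic formula: integrates the emission density
        over a supersampled grid covering the soma.
        """
        lo, hi = self.soma.bbox(margin=0.5)
        vs = np.asarray(voxel_size)
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs[i])) for i in range(3))
        origin = tuple(lo)
        nuc = _ellipsoid_occupancy(self.nucleus, shape, voxel_size, origin, supersample)
        som = _ellipsoid_occupancy(self.soma, shape, voxel_size, origin, supersample)
        conc = self.concentrations[channel]
        cn = conc.get("nucleus", 0.0)
        cc = conc.get("cytoplasm", 0.0)
        nuc_mass = cn * nuc.sum()
        for g in self.granules:
            occ = _ellipsoid_occupancy(g.as_ellipsoid(), shape, voxel_size, origin, supersample)
            nuc_mass += (g.multiplier - 1.0) * cn * occ.sum()
        cyt_mass = cc * np.clip(som - nuc, 0.0, None).sum()
        return float(nuc_mass / (nuc_mass + cyt_mass))


@dataclass(frozen=True)
class OpticsParams:
    """Forward-model optics.

    ``psf_sigma`` is the anisotropic Gaussian PSF standard deviation
    ``(σz, σy, σx)`` in µm; the defaults approximate a 63×/1.2 NA water
    immersion confocal (lateral FWHM ≈ 0.24 µm, axial ≈ 0.7 µm).
    ``photon_scale`` is the expected photon count per unit grey value
    (``None`` disables shot noise); ``read_noise_sd`` and
    ``background_level`` are in grey values.  There is no absolute intensity
    calibration in this model; the default scales are assumptions.
    """

    psf_sigma: tuple[float, float, float] = (0.3, 0.1, 0.1)
    photon_scale: float | None = 0.5
    read_noise_sd: float = 2.0
    background_level: float = 20.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("PSF sigmas must be positive")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive (or None)")
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise and background must be non-negative")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def default_axon(
    soma: Ellipsoid,
    length: float = 30.0,
    bend: float = 2.0,
) -> np.ndarray:
    """A gently bending axon polyline leaving the soma along +x from the hillock."""
    cz, cy, cx = soma.center
    x0 = cx + soma.semiaxes[2] * 0.95
    return np.array(
        [
            [cz, cy, x0],
            [cz, cy, x0 + length / 3],
            [cz, cy + bend, x0 + 2 * length / 3],
            [cz, cy + bend, x0 + length],
        ]
    )


def build_scene(
    *,
    target_nuclear_fraction: float = 0.782,
    soma_center: Sequence[float] = (7.0, 7.0, 7.0),
    soma_semiaxes: Sequence[float] = (4.0, 4.5, 4.5),
    nucleus_center: Sequence[float] | None = None,
    nucleus_semiaxes: Sequence[float] = (3.0, 3.5, 3.5),
    axon: np.ndarray | None = None,
    axon_radius: float = 0.4,
    granule_radii: Sequence[float] = (),
    granule_multiplier: float = 3.0,
    granule_min_separation: float = 0.0,
    cytoplasm_reporter_density: float = 60.0,
    nuclear_marker_density: float = 150.0,
    cytoplasm_marker_density: float = 80.0,
    channels: Sequence[str] = (NUCLEAR, CYTOPLASM, REPORTER),
    seed: int = 0,
) -> PhantomScene:
    """Build a scene whose true nuclear reporter fraction equals the target.

    The cytoplasmic reporter density is the free parameter of reference; the
    nuclear density is solved so that direct integration of reporter emission
    over the nucleus (including granule excess) divided by the whole-soma
    integral equals ``target_nuclear_fraction`` exactly (well within 1e-6).
    Granules are placed inside the nucleus by seeded rejection sampling,
    largest first, without overlap.
    """
    f = float(target_nuclear_fraction)
    if not 0.0 < f < 1.0:
        raise ValueError("target_nuclear_fraction must be in (0, 1)")
    soma = Ellipsoid(tuple(soma_center), tuple(soma_semiaxes))
    nucleus = Ellipsoid(
        tuple(nucleus_center) if nucleus_center is not None else tuple(soma_center),
        tuple(nucleus_semiaxes),
    )
    if not np.all(soma.contains(nucleus.surface_points())):
        raise ValueError("infeasible geometry: nucleus not inside soma")

    rng = np.random.default_rng(seed)
    granules = _place_granules(
        nucleus, granule_radii, granule_multiplier, rng,
        min_separation=granule_min_separation,
    )

    v_cyt = soma.volume - nucleus.volume
    if v_cyt <= 0:
        raise ValueError("infeasible geometry: no cytoplasmic volume")
    v_nuc_eff = nucleus.volume + sum((g.multiplier - 1.0) * g.volume for g in granules)
    cc = float(cytoplasm_reporter_density)
    cn = f / (1.0 - f) * cc * v_cyt / v_nuc_eff
    if cn < 0:
        raise ValueError("target fraction unreachable with non-negative concentrations")

    conc_all = {
        NUCLEAR: {"nucleus": float(nuclear_marker_density)},
        CYTOPLASM: {
            # small cytosolic proteins equilibrate through nuclear pores, so the
            # cytoplasmic marker fills the whole soma and the axon
            "nucleus": float(cytoplasm_marker_density),
            "cytoplasm": float(cytoplasm_marker_density),
            "axon": float(cytoplasm_marker_density),
        },
        REPORTER: {"nucleus": cn, "cytoplasm": cc, "axon": 0.0},
    }
    concentrations = {ch: conc_all[ch] for ch in channels}

    scene = PhantomScene(
        soma=soma,
        nucleus=nucleus,
        concentrations=concentrations,
        axon=axon,
        axon_radius=axon_radius,
        granules=granules,
        nuclear_fraction_truth=f,
    )
    assert abs(scene.nuclear_fraction() - f) < 1e-9
    return scene


def _place_granules(
    nucleus: Ellipsoid,
    radii: Sequence[float],
    multiplier: float,
    rng: np.random.Generator,
    max_tries: int = 500,
    min_separation: float = 0.0,
) -> list[Granule]:
    placed: list[Granule] = []
    for r in sorted(radii, reverse=True):
        a_min = min(nucleus.semiaxes)
        if r >= a_min:
            raise ValueError(f"granule radius {r} µm does not fit in the nucleus")
        for _ in range(max_tries):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rad = (1.0 - r / a_min) * rng.random() ** (1.0 / 3.0)
            center = np.asarray(nucleus.center) + u * rad * np.asarray(nucleus.semiaxes)
            if not _sphere_inside_ellipsoid(center, r, nucleus):
                continue
            if all(
                np.linalg.norm(center - np.asarray(g.center))
                >= r + g.radius + min_separation
                for g in placed
            ):
                placed.append(Granule(tuple(center), r, multiplier))
                break
        else:
            raise RuntimeError(
                f"could not place granule of radius {r} µm without overlap"
            )
    return placed


def sample_granule_volumes(
    n: int,
    rng: np.random.Generator,
    frac_in_range: float = 0.83,
    in_range: tuple[float, float] = (0.023, 0.048),
    out_range: tuple[float, float] = (0.048, 5.7),
) -> np.ndarray:
    """Granule volumes (µm³) emulating the observed nuclear accumulation sizes.

    A fraction ``frac_in_range`` is uniform over ``in_range``; the remainder is
    log-uniform over ``out_range`` (sizes above ~0.05 µm³ are increasingly
    rare, hence the log scale).
    """
    k = int(round(frac_in_range * n))
    v_in = rng.uniform(in_range[0], in_range[1], size=k)
    v_out = np.exp(rng.uniform(np.log(out_range[0]), np.log(out_range[1]), size=n - k))
    v = np.concatenate([v_in, v_out])
    rng.shuffle(v)
    return v


def radius_from_volume(volume: float | np.ndarray) -> float | np.ndarray:
    return (3.0 * np.asarray(volume) / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _sub_axis(n: int, vs: float, origin: float, ss: int, i0: int, i1: int) -> np.ndarray:
    """Supersampled physical coordinates for voxels [i0, i1) on one axis."""
    idx = np.arange(i0 * ss, i1 * ss)
    return origin + ((idx // ss) + ((idx % ss) + 0.5) / ss - 0.5) * vs


def _clip_bbox(
    lo: np.ndarray,
    hi: np.ndarray,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    origin: Sequence[float],
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None:
    out = []
    for ax in range(3):
        i0 = int(np.floor((lo[ax] - origin[ax]) / voxel_size[ax] - 0.5))
        i1 = int(np.ceil((hi[ax] - origin[ax]) / voxel_size[ax] + 0.5)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, shape[ax])
        if i1 <= i0:
            return None
        out.append((i0, i1))
    return tuple(out)


def _ellipsoid_occupancy(
    ell: Ellipsoid,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    origin: Sequence[float],
    supersample: int,
) -> np.ndarray:
    """Partial-volume occupancy (0..1 per voxel) of an ellipsoid."""
    occ = np.zeros(tuple(shape), dtype=np.float64)
    lo, hi = ell.bbox()
    box = _clip_bbox(lo, hi, shape, voxel_size, origin)
    if box is None:
        return occ
    (z0, z1), (y0, y1), (x0, x1) = box
    ss = int(supersample)
    axes = [
        _sub_axis(shape[ax], voxel_size[ax], origin[ax], ss, b0, b1)
        for ax, (b0, b1) in enumerate(box)
    ]
    c = ell.center
    a = ell.semiaxes
    tz = ((axes[0] - c[0]) / a[0]) ** 2
    ty = ((axes[1] - c[1]) / a[1]) ** 2
    tx = ((axes[2] - c[2]) / a[2]) ** 2
    inside = tz[:, None, None] + ty[None, :, None] + tx[None, None, :] <= 1.0
    sub = inside.reshape(z1 - z0, ss, y1 - y0, ss, x1 - x0, ss)
    occ[z0:z1, y0:y1, x0:x1] = sub.mean(axis=(1, 3, 5))
    return occ


def _polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _tube_occupancy(
    poly: np.ndarray,
    radius: float,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    origin: Sequence[float],
    supersample: int,
) -> np.ndarray:
    """Partial-volume occupancy of a capsule tube around a polyline."""
    occ = np.zeros(tuple(shape), dtype=np.float64)
    lo = poly.min(axis=0) - radius
    hi = poly.max(axis=0) + radius
    box = _clip_bbox(lo, hi, shape, voxel_size, origin)
    if box is None:
        return occ
    (z0, z1), (y0, y1), (x0, x1) = box
    ss = int(supersample)
    axes = [
        _sub_axis(shape[ax], voxel_size[ax], origin[ax], ss, b0, b1)
        for ax, (b0, b1) in enumerate(box)
    ]
    Z, Y, X = np.meshgrid(*axes, indexing="ij", sparse=False)
    pts = np.stack([Z, Y, X], axis=-1).reshape(-1, 3)
    d2 = np.full(len(pts), np.inf)
    for p0, p1 in zip(poly[:-1], poly[1:]):
        v = p1 - p0
        L2 = float(v @ v)
        if L2 == 0:
            continue
        t = np.clip((pts - p0) @ v / L2, 0.0, 1.0)
        diff = pts - (p0 + t[:, None] * v)
        d2 = np.minimum(d2, np.einsum("ij,ij->i", diff, diff))
    inside = (d2 <= radius**2).reshape(
        (z1 - z0) * ss, (y1 - y0) * ss, (x1 - x0) * ss
    )
    sub = inside.reshape(z1 - z0, ss, y1 - y0, ss, x1 - x0, ss)
    occ[z0:z1, y0:y1, x0:x1] = sub.mean(axis=(1, 3, 5))
    return occ


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class _FrameGeom:
    """Internal per-frame geometry with per-compartment densities."""

    soma: Ellipsoid
    nuclear_bodies: list[Ellipsoid]
    granules: list[Granule]
    axon: np.ndarray | None
    axon_radius: float
    densities: dict[str, dict[str, float]]  # channel -> compartment -> density
    fragments: list[tuple[Ellipsoid, dict[str, float]]] = field(default_factory=list)


def _render_geom(
    geom: _FrameGeom,
    optics: OpticsParams,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    origin: Sequence[float],
    supersample: int,
    rng: np.random.Generator | None,
) -> VolumeStack:
    soma_occ = _ellipsoid_occupancy(geom.soma, shape, voxel_size, origin, supersample)
    nuc_occ = np.zeros_like(soma_occ)
    for body in geom.nuclear_bodies:
        nuc_occ += _ellipsoid_occupancy(body, shape, voxel_size, origin, supersample)
    nuc_occ = np.minimum(nuc_occ, soma_occ)
    cyt_occ = np.clip(soma_occ - nuc_occ, 0.0, None)
    axon_occ = None
    if geom.axon is not None:
        tube = _tube_occupancy(
            geom.axon, geom.axon_radius, shape, voxel_size, origin, supersample
        )
        axon_occ = np.clip(tube - soma_occ, 0.0, None)
    gran_occ = [
        _ellipsoid_occupancy(g.as_ellipsoid(), shape, voxel_size, origin, supersample)
        for g in geom.granules
    ]
    frag_occ = [
        _ellipsoid_occupancy(e, shape, voxel_size, origin, supersample)
        for e, _ in geom.fragments
    ]

    sigma_vox = tuple(s / v for s, v in zip(optics.psf_sigma, voxel_size))
    channels = []
    for ch, dens in geom.densities.items():
        cn = dens.get("nucleus", 0.0)
        cc = dens.get("cytoplasm", 0.0)
        ca = dens.get("axon", 0.0)
        img = cn * nuc_occ + cc * cyt_occ
        if axon_occ is not None and ca:
            img += ca * axon_occ
        if ch == REPORTER:
            for g, occ in zip(geom.granules, gran_occ):
                img += (g.multiplier - 1.0) * cn * occ
        for (e, fdens), occ in zip(geom.fragments, frag_occ):
            img += fdens.get(ch, 0.0) * occ
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="constant", cval=0.0)
        img += optics.background_level
        if rng is not None:
            if optics.photon_scale is not None:
                img = rng.poisson(np.clip(img, 0, None) * optics.photon_scale) / optics.photon_scale
            if optics.read_noise_sd > 0:
                img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        channels.append(np.clip(img, 0.0, None))
    return VolumeStack(np.stack(channels), tuple(voxel_size), tuple(geom.densities))


def _scene_geom(scene: PhantomScene) -> _FrameGeom:
    return _FrameGeom(
        soma=scene.soma,
        nuclear_bodies=[scene.nucleus],
        granules=list(scene.granules),
        axon=scene.axon,
        axon_radius=scene.axon_radius,
        densities={ch: dict(d) for ch, d in scene.concentrations.items()},
    )


def grid_for_scene(
    scene: PhantomScene,
    voxel_size: tuple[float, float, float],
    margin_um: float = 1.5,
    include_axon: bool = True,
) -> tuple[int, int, int]:
    """Grid shape (origin at 0) covering the scene in the positive octant."""
    lo, hi = scene.soma.bbox()
    if include_axon and scene.axon is not None:
        hi = np.maximum(hi, scene.axon.max(axis=0) + scene.axon_radius)
        lo = np.minimum(lo, scene.axon.min(axis=0) - scene.axon_radius)
    if np.any(lo < margin_um / 2 - 1e-9):
        warnings.warn("scene extends close to the grid origin; consider shifting it")
    return tuple(
        int(np.ceil((hi[i] + margin_um) / voxel_size[i])) for i in range(3)
    )


def _check_in_grid(
    geom: _FrameGeom,
    shape: Sequence[int],
    voxel_size: Sequence[float],
    origin: Sequence[float],
    policy: str,
) -> None:
    if policy == "ignore":
        return
    lo, hi = geom.soma.bbox()
    if geom.axon is not None:
        hi = np.maximum(hi, geom.axon.max(axis=0) + geom.axon_radius)
        lo = np.minimum(lo, geom.axon.min(axis=0) - geom.axon_radius)
    grid_lo = np.asarray(origin) - np.asarray(voxel_size) / 2
    grid_hi = np.asarray(origin) + (np.asarray(shape) - 0.5) * np.asarray(voxel_size)
    if np.any(lo < grid_lo - 1e-9) or np.any(hi > grid_hi + 1e-9):
        msg = f"scene bbox [{lo}, {hi}] extends beyond grid [{grid_lo}, {grid_hi}]"
        if policy == "error":
            raise ValueError(msg)
        warnings.warn(msg)


def render(
    scene: PhantomScene,
    optics: OpticsParams,
    shape: Sequence[int],
    voxel_size: tuple[float, float, float],
    seed: int | None = 0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    supersample: int = 3,
    out_of_grid: str = "warn",
) -> VolumeStack:
    """Render a scene through the confocal forward model.

    Rasterizes each compartment with ``supersample``³ subvoxel partial-volume
    sampling, convolves each channel with the Gaussian PSF (zero padding),
    adds the background level, then Poisson photon noise and Gaussian read
    noise.  ``seed=None`` renders noiselessly; otherwise the output is
    deterministic given the seed.
    """
    geom = _scene_geom(scene)
    _check_in_grid(geom, shape, voxel_size, origin, out_of_grid)
    rng = np.random.default_rng(seed) if seed is not None else None
    return _render_geom(geom, optics, shape, voxel_size, origin, supersample, rng)


# ---------------------------------------------------------------------------
# degeneration time course
# ---------------------------------------------------------------------------

def ramp_curve(t0: float, t1: float, final: float = 1.0) -> Callable[[float], float]:
    """Monotone piecewise-linear curve: 0 before t0, ``final`` after t1."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if not 0.0 <= final <= 1.0:
        raise ValueError("final must be in [0, 1]")

    def curve(t: float) -> float:
        return final * float(np.clip((t - t0) / (t1 - t0), 0.0, 1.0))

    return curve


@dataclass(frozen=True)
class AxonalInflux:
    """Reporter influx along the axon: slow rise then a sharp late spike.

    Densities are reporter emission densities (grey per µm³); the density ramps
    linearly from ``onset_s`` to ``ramp_density`` just before the spike, jumps
    to ``peak_density`` at ``spike_s`` over ``spike_width_s``, and relaxes back
    to the ramp level after the spike.
    """

    onset_s: float
    spike_s: float
    ramp_density: float = 15.0
    peak_density: float = 120.0
    spike_width_s: float = 1200.0

    def density(self, t: float) -> float:
        if t < self.onset_s:
            return 0.0
        pre = self.spike_s - self.spike_width_s
        if t <= pre:
            span = max(pre - self.onset_s, 1e-9)
            return self.ramp_density * (t - self.onset_s) / span
        if t <= self.spike_s:
            w = (t - pre) / self.spike_width_s
            return self.ramp_density + (self.peak_density - self.ramp_density) * w
        post = self.spike_s + self.spike_width_s
        if t <= post:
            w = (t - self.spike_s) / self.spike_width_s
            return self.peak_density + (self.ramp_density - self.peak_density) * w
        return self.ramp_density


@dataclass(frozen=True)
class FragmentRelease:
    """One reporter-containing (or not) fragment leaving the soma membrane."""

    time_s: float
    radius_um: float
    contains_reporter: bool = True


@dataclass
class DegenerationParams:
    """Parameters of the stereotyped degeneration sequence.

    ``t_expand_end`` — seconds to maximal swelling (observed range 22 min to
    5 h 26 min); ``swell_factor`` — final spherical radius over initial mean
    radius; ``redistribution_curve`` — monotone map from time to the fraction
    of initially nuclear reporter moved to the cytoplasm; ``nuclear_fate`` —
    "pyknosis" (condensation at constant reporter mass) or "karyorrhexis"
    (fragmentation into ``n_karyorrhexis_fragments`` mass-conserving bodies);
    ``dissolution_time`` — seconds at which the cytoplasmic signal disperses
    (must follow full expansion).
    """

    t_expand_end: float = 3600.0
    swell_factor: float = 1.5
    redistribution_curve: Callable[[float], float] | None = None
    nuclear_fate: str = "pyknosis"
    n_karyorrhexis_fragments: int = 3
    fate_onset: float | None = None  # default: t_expand_end
    axonal_influx: AxonalInflux | None = None
    fragment_release: list[FragmentRelease] = field(default_factory=list)
    fragment_speed_um_s: float = 0.003
    fragment_density_factor: float = 2.0
    dissolution_time: float = 7200.0
    engulfment_time: float | None = None

    def __post_init__(self) -> None:
        if self.nuclear_fate not in ("pyknosis", "karyorrhexis"):
            raise ValueError("nuclear_fate must be 'pyknosis' or 'karyorrhexis'")
        if self.dissolution_time <= self.t_expand_end:
            raise ValueError("dissolution_time must exceed t_expand_end")
        if self.redistribution_curve is None:
            self.redistribution_curve = ramp_curve(
                0.1 * self.t_expand_end, self.t_expand_end, 0.85
            )
        if self.n_karyorrhexis_fragments < 2:
            raise ValueError("karyorrhexis needs at least 2 fragments")


def simulate_degeneration(
    scene: PhantomScene,
    deg: DegenerationParams,
    optics: OpticsParams,
    timestamps: Sequence[float],
    seed: int = 0,
    shape: Sequence[int] | None = None,
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    supersample: int = 3,
    noise: bool = True,
) -> tuple[TimeLapse, pd.DataFrame]:
    """Simulate a degeneration time lapse with per-frame ground truth.

    Returns the rendered :class:`~nucshuttle.io.TimeLapse` and a ground-truth
    table with one row per timepoint: soma mean radius, nuclear reporter
    fraction, axonal reporter density, cumulative fragments emitted, number of
    nuclear bodies and total reporter mass (for conservation checks).

    Reporter mass bookkeeping: redistribution moves mass from the nuclear to
    the cytoplasmic pool; axonal influx and released fragments draw their mass
    from the cytoplasmic pool, so total reporter mass is conserved until
    dissolution (and until a fragment exits the field of view).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if timestamps[0] < 0:
        raise ValueError("timestamps must be non-negative")
    horizon = deg.dissolution_time * 4
    if timestamps[-1] > horizon:
        raise ValueError(f"timestamps beyond simulated horizon ({horizon} s)")

    if shape is None:
        shape = grid_for_scene(scene, voxel_size)

    rng_master = np.random.default_rng(seed)
    frame_seeds = rng_master.integers(0, 2**31 - 1, size=len(timestamps))

    # geometry at rest
    a0 = np.asarray(scene.soma.semiaxes)
    r_final = deg.swell_factor * float(a0.mean())
    n0 = np.asarray(scene.nucleus.semiaxes)
    mn0, mc0 = scene.reporter_masses()
    conc = scene.concentrations
    fate_onset = deg.fate_onset if deg.fate_onset is not None else deg.t_expand_end

    # karyorrhexis fragment layout (fixed across frames, seeded); the first
    # three drift directions are orthonormal so fragments actually separate
    nk = deg.n_karyorrhexis_fragments
    q_mat, _ = np.linalg.qr(rng_master.standard_normal((3, 3)))
    extra = rng_master.standard_normal((max(nk - 3, 0), 3))
    if len(extra):
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
    kfrag_dirs = np.vstack([q_mat, extra])[:nk]
    shares = rng_master.dirichlet(np.full(nk, 8.0))

    # released-fragment trajectories (fixed directions, seeded)
    frag_dirs = rng_master.standard_normal((len(deg.fragment_release), 3))
    if len(deg.fragment_release):
        frag_dirs /= np.linalg.norm(frag_dirs, axis=1, keepdims=True)

    axon_volume = 0.0
    if scene.axon is not None:
        axon_volume = float(
            _polyline_arclengths(scene.axon)[-1] * math.pi * scene.axon_radius**2
        )

    frames: list[VolumeStack] = []
    rows = []
    frag_masses: list[float] = [0.0] * len(deg.fragment_release)

    for k, t in enumerate(timestamps):
        w = float(np.clip(t / deg.t_expand_end, 0.0, 1.0))
        soma_t = Ellipsoid(scene.soma.center, tuple(a0 + (r_final - a0) * w))
        q = float(
            np.clip(
                (t - fate_onset) / max(deg.dissolution_time - fate_onset, 1e-9),
                0.0,
                1.0,
            )
        )
        rho = float(np.clip(deg.redistribution_curve(t), 0.0, 1.0))
        mn_t = mn0 * (1.0 - rho)

        # nuclear bodies for this frame
        if deg.nuclear_fate == "pyknosis" or q == 0.0:
            shrink = 1.0 - 0.5 * q if deg.nuclear_fate == "pyknosis" else 1.0
            bodies = [Ellipsoid(scene.nucleus.center, tuple(n0 * shrink))]
        else:
            bodies = []
            for i in range(deg.n_karyorrhexis_fragments):
                s = float(shares[i]) ** (1.0 / 3.0)
                # fragments are condensed (half-scale) and drift apart with q
                drift = kfrag_dirs[i] * q * 0.8 * n0
                c = np.asarray(scene.nucleus.center) + drift
                bodies.append(Ellipsoid(tuple(c), tuple(n0 * s * 0.5)))
        v_nuc_t = sum(b.volume for b in bodies)
        v_cyt_t = max(soma_t.volume - v_nuc_t, 1e-9)

        # axonal influx density and mass
        d_axon = 0.0
        if deg.axonal_influx is not None and scene.axon is not None:
            d_axon = deg.axonal_influx.density(t)
        m_axon = d_axon * axon_volume

        # fragments released so far; mass fixed at release
        fragments: list[tuple[Ellipsoid, dict[str, float]]] = []
        mc_t = mc0 + mn0 * rho
        emitted = 0
        for i, fr in enumerate(deg.fragment_release):
            if t < fr.time_s:
                continue
            emitted += 1
            if frag_masses[i] == 0.0 and fr.contains_reporter:
                cc_now = (mc_t - m_axon) / v_cyt_t
                frag_masses[i] = min(
                    deg.fragment_density_factor * cc_now * (4 / 3 * math.pi * fr.radius_um**3),
                    0.2 * mc_t,
                )
            # travels outward from the membrane along its fixed direction
            surf = _ellipsoid_surface_point(soma_t, frag_dirs[i])
            pos = surf + frag_dirs[i] * deg.fragment_speed_um_s * (t - fr.time_s)
            frag = sphere(tuple(pos), fr.radius_um)
            fdens = {
                REPORTER: frag_masses[i] / frag.volume if fr.contains_reporter else 0.0,
                CYTOPLASM: deg.fragment_density_factor
                * conc.get(CYTOPLASM, {}).get("cytoplasm", 0.0),
            }
            fragments.append((frag, fdens))

        mc_t = max(mc_t - m_axon - sum(frag_masses[:]), 0.0)

        dissolved = t >= deg.dissolution_time
        engulfed = deg.engulfment_time is not None and t >= deg.engulfment_time
        if dissolved:
            mc_t = 0.0
            d_axon = 0.0
            m_axon = 0.0

        densities: dict[str, dict[str, float]] = {}
        for ch in scene.channel_names:
            base = conc[ch]
            if engulfed:
                densities[ch] = {"nucleus": 0.0, "cytoplasm": 0.0, "axon": 0.0}
            elif ch == REPORTER:
                densities[ch] = {
                    "nucleus": mn_t / v_nuc_t,
                    "cytoplasm": mc_t / v_cyt_t,
                    "axon": d_axon,
                }
            else:
                densities[ch] = {
                    "nucleus": 0.0 if dissolved and "cytoplasm" in base else base.get("nucleus", 0.0),
                    "cytoplasm": 0.0 if dissolved else base.get("cytoplasm", 0.0),
                    "axon": 0.0 if dissolved else base.get("axon", 0.0),
                }

        geom = _FrameGeom(
            soma=soma_t,
            nuclear_bodies=[] if engulfed else bodies,
            granules=[],  # granule excess mass is folded into the nuclear pool
            axon=scene.axon,
            axon_radius=scene.axon_radius,
            densities=densities,
            fragments=[] if engulfed else fragments,
        )
        _check_in_grid(geom, shape, voxel_size, origin, "warn" if k == 0 else "ignore")
        rng = np.random.default_rng(frame_seeds[k]) if noise else None
        frames.append(
            _render_geom(geom, optics, shape, voxel_size, origin, supersample, rng)
        )
        rows.append(
            {
                "time_s": t,
                "soma_mean_radius_um": float(np.mean(soma_t.semiaxes)),
                "nuclear_fraction": mn_t / (mn_t + mc_t) if (mn_t + mc_t) > 0 else np.nan,
                "axon_mean_density": d_axon,
                "fragments_emitted": emitted,
                "nuclear_bodies": len(bodies),
                "reporter_total_mass": mn_t + mc_t + m_axon + sum(frag_masses),
            }
        )

    ts = timestamps - timestamps[0]
    tl = TimeLapse(frames, ts)
    return tl, pd.DataFrame(rows)


def _ellipsoid_surface_point(ell: Ellipsoid, direction: np.ndarray) -> np.ndarray:
    """Intersection of a ray from the centre with the ellipsoid surface."""
    u = direction / np.linalg.norm(direction)
    a = np.asarray(ell.semiaxes)
    scale = 1.0 / np.sqrt(np.sum((u / a) ** 2))
    return np.asarray(ell.center) + u * scale


# ---------------------------------------------------------------------------
# UV bleach column
# ---------------------------------------------------------------------------

def bleach_survival(
    r: np.ndarray | float,
    half_attenuation_radius: float,
    floor: float = 0.05,
) -> np.ndarray | float:
    """Radial survival fraction around the UV column: 1 − A·exp(−(r/ρ)²).

    ``A = 1 − floor`` anchors the on-axis survival at ``floor``; ρ is solved so
    that attenuation (1 − survival) is exactly 50% at
    ``half_attenuation_radius`` and tends to 0 far from the column.
    """
    if half_attenuation_radius <= 0:
        raise ValueError("half_attenuation_radius must be positive")
    if not 0.0 <= floor < 0.5:
        raise ValueError(
            "floor must be in [0, 0.5): on-axis survival above 50% cannot "
            "attenuate by half at any radius"
        )
    amp = 1.0 - floor
    rho = half_attenuation_radius / math.sqrt(math.log(2.0 * amp))
    return 1.0 - amp * np.exp(-((np.asarray(r) / rho) ** 2))


def apply_uv_bleach(
    stack: VolumeStack,
    column_center: tuple[float, float],
    half_attenuation_radius: float,
    floor: float = 0.05,
) -> VolumeStack:
    """Bleach all channels around a z-parallel UV column at ``(y, x)`` µm.

    Attenuation (1 − post/pre) is monotone non-increasing with in-plane
    distance from the column axis, 50% at ``half_attenuation_radius`` and
    ``1 − floor`` on the axis.
    """
    cy, cx = column_center
    _, ny, nx = stack.shape_zyx
    dz, dy, dx = stack.voxel_size
    if not (0.0 <= cy <= (ny - 1) * dy and 0.0 <= cx <= (nx - 1) * dx):
        raise ValueError(f"column centre ({cy}, {cx}) µm outside the field of view")
    yy = (np.arange(ny) * dy - cy) ** 2
    xx = (np.arange(nx) * dx - cx) ** 2
    r = np.sqrt(yy[:, None] + xx[None, :])
    surv = bleach_survival(r, half_attenuation_radius, floor)
    data = stack.data.astype(np.float64) * surv[None, None, :, :]
    return stack.with_data(data)
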