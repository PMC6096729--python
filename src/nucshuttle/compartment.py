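"""Nucleo-cytoplasmic partition of a reporter over the 3D soma.

The core measurement: voxels of the soma are split into a nuclear set (above
threshold in both the reporter-bearing soma and the nuclear-marker channel)
and a cytoplasmic set (the remainder), the reporter grey value is summed over
each set, and the nuclear fraction is the nuclear sum over the soma total.
Grey value is treated as proportional to fluorophore concentration throughout.

Thresholding defaults to Otsu per channel; voxels equal to the threshold are
included.  The soma mask is the largest connected component of the
cytoplasmic (or membrane-filled) channel, hole-filled so the nucleus interior
belongs to the soma even when the soma marker is dim there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import TimeLapse, VolumeStack
from .preprocess import BackgroundEstimate

__all__ = [
    "CompartmentMasks",
    "PartitionResult",
    "segment_channel",
    "compute_masks",
    "partition",
    "partition_timecourse",
    "timecourse_table",
]


@dataclass
class CompartmentMasks:
    """Disjoint soma = nucleus ∪ cytoplasm boolean rasters."""

    soma_mask: np.ndarray
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.soma_mask, self.nuclear_mask, self.cytoplasm_mask):
            if m.dtype != bool or m.shape != self.soma_mask.shape:
                raise ValueError("masks must be boolean rasters of equal shape")
        if np.any(self.nuclear_mask & ~self.soma_mask):
            raise ValueError("nuclear mask must be a subset of the soma mask")
        if np.any(self.cytoplasm_mask != (self.soma_mask & ~self.nuclear_mask)):
            raise ValueError("cytoplasm mask must equal soma minus nucleus")


@dataclass
class PartitionResult:
    """Summed-grey-value decomposition of the reporter over the soma."""

    nuclear_sum: float
    cytoplasmic_sum: float
    nuclear_fraction: float
    voxels_nuclear: int
    voxels_cytoplasm: int
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError("nuclear fraction must lie in [0, 1]")


def _drop_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove 26-connected components smaller than ``min_voxels``."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (counts >= min_voxels)[labels] & mask


def _resolve_threshold(data: np.ndarray, method: str | float) -> float:
    if isinstance(method, str):
        if method == "otsu":
            # float histogram: integer input would snap the threshold to the
            # top of the lower class, conflicting with the >= tie rule
            return float(threshold_otsu(data.astype(np.float64)))
        if method.startswith("fixed:"):
            return float(method.split(":", 1)[1])
        raise ValueError(f"unknown threshold method {method!r}")
    return float(method)


def segment_channel(
    stack: VolumeStack,
    channel: str,
    method: str | float = "otsu",
    min_object_voxels: int = 1,
    largest_component: bool = False,
    fill_holes: bool = False,
) -> np.ndarray:
    """Boolean mask of above-threshold voxels in one channel.

    Voxels equal to the threshold are included.  Objects smaller than
    ``min_object_voxels`` (26-connectivity) are removed; optionally only the
    largest connected component is kept and its holes filled.
    """
    data = stack.channel(channel)
    thr = _resolve_threshold(data, method)
    mask = data >= thr
    if min_object_voxels > 1 and mask.any():
        mask = _drop_small(mask, min_object_voxels)
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    return mask


def compute_masks(
    stack: VolumeStack,
    nuclear_channel: str = "nuclear",
    soma_channel: str = "cytoplasm",
    method: str | float = "otsu",
    min_object_voxels: int = 8,
    crop: tuple[slice, slice, slice] | None = None,
) -> CompartmentMasks:
    """Build soma/nucleus/cytoplasm masks from the two marker channels.

    The soma is the largest connected component of the soma channel
    (hole-filled); the nucleus is the nuclear-marker mask intersected with it
    — operationalising "voxels containing both reporter and nuclear marker".
    ``crop`` restricts the analysis to a soma bounding region (half-open voxel
    slices), excluding e.g. the axon.
    """
    soma_data = stack.channel(soma_channel)
    nuc_data = stack.channel(nuclear_channel)
    thr_soma = _resolve_threshold(soma_data, method)
    thr_nuc = _resolve_threshold(nuc_data, method)
    soma = segment_channel(
        stack, soma_channel, thr_soma, min_object_voxels,
        largest_component=True, fill_holes=True,
    )
    nuclear = (nuc_data >= thr_nuc)
    if min_object_voxels > 1 and nuclear.any():
        nuclear = _drop_small(nuclear, min_object_voxels)
    if crop is not None:
        keep = np.zeros_like(soma)
        keep[crop] = True
        soma &= keep
    nuclear &= soma
    if not soma.any():
        raise ValueError("empty soma mask: no voxels above threshold")
    return CompartmentMasks(
        soma_mask=soma,
        nuclear_mask=nuclear,
        cytoplasm_mask=soma & ~nuclear,
        thresholds={soma_channel: thr_soma, nuclear_channel: thr_nuc},
    )


def partition(
    stack: VolumeStack,
    reporter: str,
    masks: CompartmentMasks,
    background: BackgroundEstimate | None = None,
) -> PartitionResult:
    """Summed reporter grey value over the nuclear and cytoplasmic voxel sets.

    With ``background`` given, the per-channel background mean is subtracted
    voxel-wise and floored at zero before summing (off by default).  On
    integer input without background subtraction the two sums add up to the
    soma total exactly.
    """
    if not masks.soma_mask.any():
        raise ValueError("soma mask is empty")
    data = stack.channel(reporter)
    if background is not None:
        data = np.clip(data.astype(np.float64) - background.mean[reporter], 0.0, None)
    if np.issubdtype(data.dtype, np.integer):
        nuc = int(data[masks.nuclear_mask].sum(dtype=np.int64))
        cyt = int(data[masks.cytoplasm_mask].sum(dtype=np.int64))
    else:
        nuc = float(data[masks.nuclear_mask].sum())
        cyt = float(data[masks.cytoplasm_mask].sum())
    total = nuc + cyt
    if total == 0:
        raise ValueError("nuclear and cytoplasmic sums are both zero; fraction undefined")
    return PartitionResult(
        nuclear_sum=nuc,
        cytoplasmic_sum=cyt,
        nuclear_fraction=nuc / total,
        voxels_nuclear=int(masks.nuclear_mask.sum()),
        voxels_cytoplasm=int(masks.cytoplasm_mask.sum()),
        thresholds=dict(masks.thresholds),
    )


def partition_timecourse(
    tl: TimeLapse,
    reporter: str = "reporter",
    nuclear_channel: str = "nuclear",
    soma_channel: str = "cytoplasm",
    method: str | float = "otsu",
    min_object_voxels: int = 8,
    background: BackgroundEstimate | None = None,
) -> list[PartitionResult]:
    """One partition per frame, with masks recomputed per frame.

    Per-frame mask recomputation is required because the geometry changes
    during swelling and nuclear condensation/fragmentation.  Errors are
    re-raised with the offending frame index.
    """
    results = []
    for i, frame in enumerate(tl.frames):
        try:
            masks = compute_masks(
                frame, nuclear_channel, soma_channel, method, min_object_voxels
            )
            results.append(partition(frame, reporter, masks, background))
        except ValueError as exc:
            raise ValueError(f"frame {i} (t={tl.timestamps[i]:g} s): {exc}") from exc
    return results


def timecourse_table(tl: TimeLapse, results: Sequence[PartitionResult]) -> pd.DataFrame:
    """Tabulate a partition time course against the frame timestamps."""
    return pd.DataFrame(
        {
            "time_s": tl.timestamps[: len(results)],
            "nuclear_sum": [r.nuclear_sum for r in results],
            "cytoplasmic_sum": [r.cytoplasmic_sum for r in results],
            "nuclear_fraction": [r.nuclear_fraction for r in results],
            "voxels_nuc": [r.voxels_nuclear for r in results],
            "voxels_cyt": [r.voxels_cytoplasm for r in results],
        }
    )
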