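"""Nucleus and chromosome-territory segmentation on 3-channel stacks.

The workflow mirrors per-channel thresholding of confocal 3D-FISH stacks:
the blue (DNA counterstain) channel yields a single filled nucleus mask and
its geometric centre; each paint channel yields up to ``max_objects``
territory objects (two homologs per chromosome in a diploid nucleus), each
with an unweighted centroid in physical µm.

All centroids use the voxel-centre convention: voxel ``(i, j, k)`` sits at
``((i + 0.5) dz, (j + 0.5) dy, (k + 0.5) dx)``, so distances are Euclidean
in µm and anisotropy is handled by the scaling, not by the geometry code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .synthetic import Scene

__all__ = [
    "NucleusMask",
    "TerritoryObject",
    "SegmentationError",
    "DegenerateThresholdError",
    "threshold_channel",
    "extract_nucleus",
    "extract_territories",
    "voxel_centroid",
]

_STRUCT3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class SegmentationError(RuntimeError):
    """Thresholding produced no usable object."""


class DegenerateThresholdError(SegmentationError):
    """Automatic thresholding is undefined (constant-intensity channel)."""


@dataclass
class NucleusMask:
    """Single connected, hole-filled nucleus with its geometric centre."""

    mask: np.ndarray            # boolean (z, y, x)
    center: np.ndarray          # µm (z, y, x)
    volume: float               # µm^3
    voxel_size: tuple[float, float, float]
    truncated: bool = False     # mask touches the frame edge


@dataclass
class TerritoryObject:
    channel: str
    center: np.ndarray          # µm (z, y, x)
    volume: float               # µm^3
    voxel_count: int


def voxel_centroid(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Unweighted centroid of a voxel set in physical µm.

    Equals the mean of the voxel-centre coordinates, which for a binary mask
    is the mask's geometric centre.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise SegmentationError("cannot take the centroid of an empty mask")
    return (idx.mean(axis=0) + 0.5) * np.asarray(voxel_size, dtype=float)


def threshold_channel(scene: Scene, channel: str, method: str = "otsu",
                      value: float | None = None) -> np.ndarray:
    """Threshold one channel to a boolean grid.

    ``method`` is one of ``"otsu"`` (default), ``"fixed"`` (absolute
    threshold ``value``) or ``"fraction_of_max"`` (``value`` times the
    channel maximum).  Voxels strictly above the threshold are foreground.
    """
    img = scene.channel(channel)
    if method == "otsu":
        if img.min() == img.max():
            raise DegenerateThresholdError(
                f"channel {channel!r} has constant intensity; Otsu is undefined"
            )
        t = threshold_otsu(img)
    elif method == "fixed":
        if value is None:
            raise ValueError("method 'fixed' requires a threshold value")
        t = value
    elif method == "fraction_of_max":
        if value is None or not 0 <= value <= 1:
            raise ValueError("method 'fraction_of_max' requires value in [0, 1]")
        t = value * float(img.max())
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > t


def extract_nucleus(scene: Scene, method: str = "otsu",
                    value: float | None = None) -> NucleusMask:
    """Segment the nucleus from the blue channel.

    Largest 26-connected component after thresholding, 3D hole-filled; the
    centre is the unweighted centroid of the mask in µm.  A mask touching
    the frame border is returned with ``truncated=True`` and a warning.
    """
    fg = threshold_channel(scene, "blue", method=method, value=value)
    labels, n = ndimage.label(fg, structure=_STRUCT3D)
    if n == 0:
        raise SegmentationError("empty nucleus mask after thresholding")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(mask)

    truncated = bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if truncated:
        warnings.warn("nucleus mask touches the frame edge (truncated nucleus)",
                      stacklevel=2)

    vsize = scene.voxel_size
    voxel_vol = float(np.prod(vsize))
    return NucleusMask(
        mask=mask,
        center=voxel_centroid(mask, vsize),
        volume=float(mask.sum()) * voxel_vol,
        voxel_size=tuple(vsize),
        truncated=truncated,
    )


def extract_territories(scene: Scene, channel: str, max_objects: int = 2,
                        min_volume: float = 0.5,
                        nucleus_mask: NucleusMask | np.ndarray | None = None,
                        clip_to_nucleus: bool = True,
                        method: str = "otsu",
                        value: float | None = None) -> list[TerritoryObject]:
    """Extract chromosome-territory objects from a paint channel.

    Connected components above ``min_volume`` (µm^3), optionally clipped to
    the nucleus mask, sorted by volume descending and truncated to
    ``max_objects`` (two homologs by default).  Returns an empty list when
    nothing survives — the caller decides whether that is an error.
    """
    if channel not in ("green", "red"):
        raise ValueError(f"{channel!r} is not a territory channel")
    nmask = None
    if nucleus_mask is not None:
        nmask = nucleus_mask.mask if isinstance(nucleus_mask, NucleusMask) else nucleus_mask

    img = scene.channel(channel)
    if method == "otsu":
        # restrict the histogram to the nucleus: territories occupy a tiny
        # fraction of the frame, where global Otsu degenerates into
        # splitting the background mode
        vals = img[nmask] if nmask is not None else img
        if vals.size == 0 or vals.min() == vals.max():
            return []
        fg = img > threshold_otsu(vals)
        if nmask is not None and (fg & nmask).sum() > 0.25 * nmask.sum():
            # paint signal occupies a small minority of the nucleus; a
            # threshold keeping more than this is splitting noise, not signal
            return []
    else:
        try:
            fg = threshold_channel(scene, channel, method=method, value=value)
        except DegenerateThresholdError:
            return []

    if nmask is not None and clip_to_nucleus:
        fg = fg & nmask

    labels, n = ndimage.label(fg, structure=_STRUCT3D)
    if n == 0:
        return []
    vsize = scene.voxel_size
    voxel_vol = float(np.prod(vsize))
    counts = np.bincount(labels.ravel())
    objects = []
    for lab in range(1, n + 1):
        vol = counts[lab] * voxel_vol
        if vol < min_volume:
            continue
        objects.append(
            TerritoryObject(
                channel=channel,
                center=voxel_centroid(labels == lab, vsize),
                volume=vol,
                voxel_count=int(counts[lab]),
            )
        )
    objects.sort(key=lambda o: o.volume, reverse=True)
    return objects[:max_objects]
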