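"""Intact/detached segmentation and per-channel quantification.

The phenotype of interest is epithelial (chiefly podocyte) detachment:
in high glucose or cytokine stress, small marker-positive cells shed
from the main organoid body and scatter around it.  The pipeline
quantifies this by

1. estimating a scalar background per channel across an acquisition set
   (mean over images of each image's minimum pixel intensity),
2. collapsing confocal z-stacks to a single plane (max projection by
   default),
3. thresholding at ``background + threshold_offset`` — one global value
   per experiment — and removing sub-``min_object_px`` specks,
4. partitioning the surviving connected components into *intact* (area
   at or above ``main_body_min_px``, i.e. main organoid bodies) and
   *detached* (everything smaller: shed single cells and small
   clusters), and
5. reporting areas, the intact/detached ratio, and background-subtracted
   mean intensities, optionally normalized to the control condition.

Areas are in pixels throughout; no physical calibration is applied.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import (
    ChannelQuant,
    ImageSet,
    MultiChannelImage,
    SegmentationParams,
    SegmentationResult,
)

__all__ = [
    "estimate_background",
    "z_project",
    "above_background_mask",
    "segment_components",
    "classify_intact_detached",
    "quantify_channel",
    "quantify_image",
    "live_dead_ratio",
]


def _structure(connectivity: int) -> np.ndarray:
    # 4-connectivity = edge neighbours only; 8 adds diagonals.
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def estimate_background(
    image_set: ImageSet | Sequence[MultiChannelImage],
    channel: str,
    projection: str = "max",
) -> float:
    """Scalar background for ``channel``: mean over images of per-image minima.

    Each image contributes the minimum pixel intensity of its (projected)
    channel plane; the background is the arithmetic mean of those minima
    across the whole acquisition set.
    """
    images = image_set.images if isinstance(image_set, ImageSet) else image_set
    if len(images) == 0:
        raise ValueError("cannot estimate background from an empty image set")
    minima = []
    for i, img in enumerate(images):
        if channel not in img.channels:
            raise KeyError(f"image {i} lacks channel {channel!r}")
        plane = img.channels[channel]
        if plane.ndim == 3:
            plane = z_project(plane, method=projection)
        minima.append(float(plane.min()))
    return float(np.mean(minima))


def z_project(stack: np.ndarray, method: str = "max") -> np.ndarray:
    """Collapse a ``(Z, H, W)`` stack to one plane (default per-pixel max)."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a (Z, H, W) stack with at least one slice")
    if method == "max":
        return arr.max(axis=0)
    if method == "mean":
        return arr.mean(axis=0)
    if method == "sum":
        return arr.sum(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def above_background_mask(
    grid: np.ndarray, background: float, params: SegmentationParams
) -> np.ndarray:
    """Pixels strictly above ``background + threshold_offset``, de-specked.

    Connected components (under ``params.connectivity``) smaller than
    ``params.min_object_px`` are removed as noise.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    mask = np.asarray(grid) > background + params.threshold_offset
    if params.min_object_px > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=_structure(params.connectivity))
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        keep = areas >= params.min_object_px
        keep[0] = False
        mask = keep[labels]
    return mask


def segment_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected components of a boolean mask.

    Labels run 1..K in deterministic raster order: the component whose
    first pixel comes earliest in row-major order gets label 1.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=_structure(connectivity))
    return labels


def classify_intact_detached(
    label_map: np.ndarray, params: SegmentationParams
) -> tuple[list[int], list[int]]:
    """Split labeled components into intact (main bodies) and detached.

    Components with area >= ``main_body_min_px`` are intact; all other
    components are detached.  If no component reaches the body
    threshold, the largest component is deemed intact — an organoid is
    assumed present in every analyzed field.
    """
    n = int(label_map.max())
    if n == 0:
        raise ValueError("no above-background signal")
    areas = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    intact = [i + 1 for i in range(n) if areas[i] >= params.main_body_min_px]
    if not intact:
        intact = [int(np.argmax(areas)) + 1]  # argmax → lowest label on ties
    intact_set = set(intact)
    detached = [i + 1 for i in range(n) if i + 1 not in intact_set]
    return intact, detached


def quantify_channel(
    image: MultiChannelImage,
    channel: str,
    background: float,
    params: SegmentationParams,
    control_mean: float | None = None,
) -> ChannelQuant:
    """Full quantification of one marker channel of one image.

    Returns areas (px) of the intact and detached partitions, the
    intact/detached ratio with a floored denominator (flagged when the
    floor engaged), the number of detached objects, and the mean
    background-subtracted intensity over the union mask (negative
    differences clipped to zero).  When ``control_mean`` is given, the
    intensity normalized to the control condition is included.
    """
    grid = image.channels[channel]
    if grid.ndim == 3:
        grid = z_project(grid, method=params.z_projection)
    mask = above_background_mask(grid, background, params)
    labels = segment_components(mask, params.connectivity)
    intact, detached = classify_intact_detached(labels, params)

    areas = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    intact_area = int(areas[intact].sum())
    detached_area = int(areas[detached].sum()) if detached else 0

    floored = detached_area < params.ratio_epsilon_px
    ratio = intact_area / max(detached_area, params.ratio_epsilon_px)

    union = labels > 0
    diff = np.clip(np.asarray(grid, dtype=float) - background, 0.0, None)
    mean_intensity = float(diff[union].mean())

    normalized = None
    if control_mean is not None:
        if control_mean <= 0:
            raise ValueError("control-condition mean intensity must be positive")
        normalized = mean_intensity / control_mean

    return ChannelQuant(
        channel=channel,
        intact_labels=intact,
        detached_labels=detached,
        label_map=labels,
        intact_area_px=intact_area,
        detached_area_px=detached_area,
        intact_detached_ratio=float(ratio),
        ratio_floored=bool(floored),
        n_detached=len(detached),
        mean_intensity=mean_intensity,
        normalized_intensity=normalized,
    )


def quantify_image(
    image: MultiChannelImage,
    backgrounds: dict[str, float],
    params: SegmentationParams,
    channels: Sequence[str] | None = None,
    control_means: dict[str, float] | None = None,
) -> SegmentationResult:
    """Quantify several channels of one image; see :func:`quantify_channel`."""
    chans = list(channels) if channels is not None else sorted(backgrounds)
    result = SegmentationResult()
    for ch in chans:
        ctrl = control_means.get(ch) if control_means else None
        result.per_channel[ch] = quantify_channel(
            image, ch, backgrounds[ch], params, control_mean=ctrl
        )
    return result


def live_dead_ratio(
    green: np.ndarray,
    red: np.ndarray,
    green_background: float,
    red_background: float,
    params: SegmentationParams,
) -> tuple[float, bool]:
    """Above-background area of the live (green) channel over the dead (red).

    A zero red area floors the denominator at ``ratio_epsilon_px`` and
    sets the flag.
    """
    green = np.asarray(green)
    red = np.asarray(red)
    if green.shape != red.shape:
        raise ValueError("green and red grids must share dimensions")
    green_area = int(above_background_mask(green, green_background, params).sum())
    red_area = int(above_background_mask(red, red_background, params).sum())
    floored = red_area < params.ratio_epsilon_px
    return green_area / max(red_area, params.ratio_epsilon_px), floored
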