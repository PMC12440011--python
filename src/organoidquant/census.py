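"""Whole-well organoid census by three-marker coincidence.

An organoid is a structure showing simultaneous signal from all
required nephron markers (by default ECAD, PODXL and LTL).  This is
operationalized as: a connected component of the union of the
above-background marker masks counts as an organoid iff its area
reaches ``min_organoid_px`` *and* it contains above-background pixels
of every required marker.  Counts per day are normalized to day 0 as
percent remaining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .segmentation import above_background_mask, segment_components
from .types import MultiChannelImage, SegmentationParams, NEPHRON_MARKERS

__all__ = ["CensusParams", "OrganoidRegion", "detect_organoids", "count_organoids", "percent_remaining"]


@dataclass
class CensusParams:
    required_markers: tuple[str, ...] = NEPHRON_MARKERS
    min_organoid_px: int = 100
    connectivity: int = 8

    def __post_init__(self) -> None:
        if len(self.required_markers) < 2:
            raise ValueError("census requires at least two coincident markers")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_organoid_px < 1:
            raise ValueError("min_organoid_px must be >= 1")


@dataclass
class OrganoidRegion:
    centroid: tuple[float, float]
    area_px: int
    markers_present: dict[str, bool] = field(default_factory=dict)

    @property
    def is_organoid(self) -> bool:
        return all(self.markers_present.values())


def detect_organoids(
    image: MultiChannelImage,
    backgrounds: Mapping[str, float],
    params: CensusParams,
    seg_params: SegmentationParams,
) -> list[OrganoidRegion]:
    """Candidate regions of the marker-union mask, with marker coincidence.

    Returns every connected component of the union of above-background
    marker masks whose area reaches ``min_organoid_px``, recording for
    each whether it contains signal from every required marker.  Use
    :func:`count_organoids` (or ``region.is_organoid``) for the census
    count proper.
    """
    marker_masks = {}
    for marker in params.required_markers:
        if marker not in image.channels:
            raise KeyError(f"required marker channel {marker!r} missing from image")
        if marker not in backgrounds:
            raise KeyError(f"no background estimate for marker {marker!r}")
        grid = image.channels[marker]
        marker_masks[marker] = above_background_mask(grid, backgrounds[marker], seg_params)

    union = np.zeros(image.shape, dtype=bool)
    for m in marker_masks.values():
        union |= m
    labels = segment_components(union, params.connectivity)
    n = int(labels.max())
    if n == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    regions = []
    centroids = ndimage.center_of_mass(union, labels, range(1, n + 1))
    for lab in range(1, n + 1):
        if areas[lab] < params.min_organoid_px:
            continue
        comp = labels == lab
        present = {
            marker: bool(np.logical_and(comp, mask).any())
            for marker, mask in marker_masks.items()
        }
        regions.append(
            OrganoidRegion(
                centroid=tuple(map(float, centroids[lab - 1])),
                area_px=int(areas[lab]),
                markers_present=present,
            )
        )
    return regions


def count_organoids(
    image: MultiChannelImage,
    backgrounds: Mapping[str, float],
    params: CensusParams,
    seg_params: SegmentationParams,
) -> int:
    return sum(r.is_organoid for r in detect_organoids(image, backgrounds, params, seg_params))


def percent_remaining(counts: Mapping[float, int]) -> dict[float, float]:
    """Per-day counts normalized to day 0 (percent).

    Day 0 must be present with a positive count.
    """
    if 0 not in counts and 0.0 not in counts:
        raise ValueError("day 0 count is required for normalization")
    day0 = counts.get(0, counts.get(0.0))
    if day0 <= 0:
        raise ValueError("day 0 count must be positive")
    return {float(day): 100.0 * c / day0 for day, c in counts.items()}
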