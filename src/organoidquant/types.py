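"""Core containers shared across the quantification modules.

The central object is :class:`MultiChannelImage`: a dictionary of 2-D
(or z-stacked 3-D) fluorescence intensity grids keyed by channel label
(``PODXL``, ``ECAD``, ``LTL``, ``nuclei``, ...), optionally carrying a
pixel size.  Images acquired under identical settings are grouped into
an :class:`ImageSet`, the unit over which the scalar background is
estimated and against whose control condition intensities are
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The three nephron-segment markers whose coincidence defines an organoid.
NEPHRON_MARKERS = ("ECAD", "LTL", "PODXL")


@dataclass
class MultiChannelImage:
    """Per-channel intensity grids sharing one field of view.

    Parameters
    ----------
    channels
        Mapping of channel label to a non-negative ``(H, W)`` plane or
        ``(Z, H, W)`` z-stack.  All channels must share the same spatial
        ``(H, W)`` dimensions.
    pixel_size
        Optional physical pixel size (arbitrary units); carried as
        metadata only — all quantification is in pixel units.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiChannelImage requires at least one channel")
        shapes = set()
        for name, grid in self.channels.items():
            arr = np.asarray(grid)
            if arr.ndim not in (2, 3):
                raise ValueError(
                    f"channel {name!r} must be 2-D or a z-stack, got ndim={arr.ndim}"
                )
            if arr.size and arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            shapes.add(arr.shape[-2:])
            self.channels[name] = arr
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on spatial dimensions: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial ``(H, W)`` shape shared by all channels."""
        return next(iter(self.channels.values())).shape[-2:]

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.channels)

    def is_stack(self, channel: str) -> bool:
        return self.channels[channel].ndim == 3


@dataclass
class ImageSet:
    """Images sharing acquisition settings, with per-image condition labels.

    ``control_condition`` must be one of the conditions whenever
    intensity normalization against the control is requested.
    """

    images: Sequence[MultiChannelImage]
    conditions: Sequence[str]
    control_condition: str | None = None

    def __post_init__(self) -> None:
        if len(self.images) == 0:
            raise ValueError("ImageSet must contain at least one image")
        if len(self.images) != len(self.conditions):
            raise ValueError("one condition label per image is required")
        if (
            self.control_condition is not None
            and self.control_condition not in set(self.conditions)
        ):
            raise ValueError(
                f"control condition {self.control_condition!r} absent from image set"
            )


@dataclass
class SegmentationParams:
    """Tunable knobs of the intact/detached segmentation.

    threshold_offset
        Intensity offset added to the estimated background to form the
        global threshold; a single value is used across a whole
        experiment.
    connectivity
        Pixel connectivity for component labeling, 4 or 8.
    min_object_px
        Components smaller than this are treated as noise and removed.
    main_body_min_px
        Minimum component area qualifying as a main organoid body
        (*intact*); everything else surviving the noise floor is
        *detached*.
    ratio_epsilon_px
        Floor for the detached-area denominator so intact/detached
        ratios of fully intact organoids stay finite (flagged).
    """

    threshold_offset: float = 50.0
    connectivity: int = 8
    min_object_px: int = 4
    main_body_min_px: int = 100
    ratio_epsilon_px: float = 1.0
    z_projection: str = "max"

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.main_body_min_px <= self.min_object_px:
            raise ValueError("main_body_min_px must exceed min_object_px")
        if self.ratio_epsilon_px <= 0:
            raise ValueError("ratio_epsilon_px must be positive")
        if self.z_projection not in ("max", "mean", "sum"):
            raise ValueError("z_projection must be one of max/mean/sum")


@dataclass
class ChannelQuant:
    """Quantities extracted from one marker channel of one image."""

    channel: str
    intact_labels: list[int]
    detached_labels: list[int]
    label_map: np.ndarray
    intact_area_px: int
    detached_area_px: int
    intact_detached_ratio: float
    ratio_floored: bool
    n_detached: int
    mean_intensity: float
    normalized_intensity: float | None = None

    @property
    def intact_mask(self) -> np.ndarray:
        return np.isin(self.label_map, self.intact_labels)

    @property
    def detached_mask(self) -> np.ndarray:
        return np.isin(self.label_map, self.detached_labels)

    @property
    def intact_fraction(self) -> float:
        total = self.intact_area_px + self.detached_area_px
        return self.intact_area_px / total if total else float("nan")


@dataclass
class SegmentationResult:
    """Per-channel quantification of one image."""

    per_channel: dict[str, ChannelQuant] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> ChannelQuant:
        return self.per_channel[channel]


@dataclass
class GroundTruth:
    """Generator-emitted truth accompanying every synthetic artifact.

    Only the fields relevant to the generator that produced it are
    populated; the rest stay ``None``.
    """

    intact_masks: dict[str, np.ndarray] | None = None
    detached_masks: dict[str, np.ndarray] | None = None
    intact_fraction: dict[str, float] | None = None
    n_organoids: int | None = None
    detached_counts: dict[str, int] | None = None
    organoid_centroids: list[tuple[float, float]] | None = None
    counts_by_day: dict[float, int] | None = None
    n_overlap: int | None = None
    n_concordant: int | None = None
    concordant_fraction: float | None = None
    kept_cells: np.ndarray | None = None

    def validate_masks(self) -> None:
        """Check the mask consistency contract (disjoint intact/detached)."""
        if self.intact_masks is None or self.detached_masks is None:
            return
        for ch, intact in self.intact_masks.items():
            detached = self.detached_masks[ch]
            if np.logical_and(intact, detached).any():
                raise AssertionError(f"intact/detached truth masks overlap in {ch}")


@dataclass
class OrganoidRecord:
    """Identity and measurements of a single organoid observation."""

    organoid_id: str
    condition: str
    day: float
    channel_quants: Mapping[str, ChannelQuant] | None = None
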