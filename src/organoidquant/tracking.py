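"""Time-lapse tracking of individual organoids from recorded t0 positions.

Organoid positions recorded at time zero are matched to detections at
each later timepoint by greedy nearest-neighbour assignment: candidate
(t0, detection) pairs are visited in ascending distance order, ties
broken by t0 order then detection label, and pairs beyond
``max_displacement_px`` leave an explicit gap.  Organoids are sparse
and near-sessile, so the greedy assignment is adequate and fully
deterministic.

Per-track metrics (body area, detached area, detached object count and
their day-over-day deltas) quantify detachment growth and body
shrinkage over the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import ChannelQuant, MultiChannelImage, SegmentationParams

__all__ = ["Track", "match_tracks", "track_metrics", "analyze_series"]


@dataclass
class Track:
    """Per-timepoint trajectory of one tracked organoid."""

    organoid_id: str
    times: list[float]
    body_area_px: list[int]
    detached_area_px: list[int]
    detached_count: list[int]
    body_area_delta: list[int] = field(default_factory=list)
    detached_count_delta: list[int] = field(default_factory=list)
    gaps: list[float] = field(default_factory=list)  # timepoints without a match


def match_tracks(
    t0_positions: Mapping[str, tuple[float, float]] | Sequence[tuple[str, float, float]],
    detections: Sequence[tuple[float, float]],
    max_displacement_px: float,
) -> dict[str, int | None]:
    """Assign detections to t0 organoid positions.

    Returns a map from organoid ID to the index of its matched
    detection, or ``None`` for a gap (no detection within
    ``max_displacement_px``).  Each detection is used at most once.
    """
    if isinstance(t0_positions, Mapping):
        items = list(t0_positions.items())
    else:
        ids = [t[0] for t in t0_positions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate t0 organoid IDs")
        items = [(t[0], (t[1], t[2])) for t in t0_positions]
    if len({i for i, _ in items}) != len(items):
        raise ValueError("duplicate t0 organoid IDs")

    candidates = []
    for oi, (oid, (oy, ox)) in enumerate(items):
        for di, (dy, dx) in enumerate(detections):
            dist = float(np.hypot(oy - dy, ox - dx))
            if dist <= max_displacement_px:
                candidates.append((dist, oi, di))
    candidates.sort()

    assignment: dict[str, int | None] = {oid: None for oid, _ in items}
    used_det: set[int] = set()
    matched: set[int] = set()
    for dist, oi, di in candidates:
        if oi in matched or di in used_det:
            continue
        assignment[items[oi][0]] = di
        matched.add(oi)
        used_det.add(di)
    return assignment


def track_metrics(
    organoid_id: str,
    series: Sequence[tuple[float, ChannelQuant]],
) -> Track:
    """Build a :class:`Track` from matched per-timepoint quantifications.

    ``series`` holds (time, quantification) pairs for one organoid; it
    is sorted by time internally.  At least two matched timepoints are
    required.
    """
    if len(series) < 2:
        raise ValueError("track metrics need >= 2 matched timepoints")
    ordered = sorted(series, key=lambda tq: tq[0])
    times = [float(t) for t, _ in ordered]
    if len(set(times)) != len(times):
        raise ValueError("duplicate timepoints in track series")
    body = [q.intact_area_px for _, q in ordered]
    det_area = [q.detached_area_px for _, q in ordered]
    det_count = [q.n_detached for _, q in ordered]
    return Track(
        organoid_id=organoid_id,
        times=times,
        body_area_px=body,
        detached_area_px=det_area,
        detached_count=det_count,
        body_area_delta=[b1 - b0 for b0, b1 in zip(body, body[1:])],
        detached_count_delta=[c1 - c0 for c0, c1 in zip(det_count, det_count[1:])],
    )


def analyze_series(
    frames: Sequence[tuple[float, MultiChannelImage]],
    t0_positions: Mapping[str, tuple[float, float]],
    backgrounds: Mapping[str, float],
    seg_params: SegmentationParams,
    channel: str = "PODXL",
    max_displacement_px: float = 20.0,
) -> list[Track]:
    """Quantify and track every t0 organoid across a time series.

    Each frame's channel is segmented; intact-component centroids are
    matched to the t0 positions, and detached components are attributed
    to the nearest matched body.  Frames where an organoid finds no
    match within ``max_displacement_px`` are recorded as gaps.
    """
    from scipy import ndimage

    from .segmentation import quantify_channel

    per_id: dict[str, dict[str, list]] = {
        oid: {"times": [], "body": [], "darea": [], "dcount": [], "gaps": []}
        for oid in t0_positions
    }
    for time, image in sorted(frames, key=lambda f: f[0]):
        q = quantify_channel(image, channel, backgrounds[channel], seg_params)
        labels = q.label_map
        areas = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
        intact_centroids = ndimage.center_of_mass(
            labels > 0, labels, q.intact_labels
        )
        detections = [tuple(map(float, c)) for c in intact_centroids]
        assignment = match_tracks(t0_positions, detections, max_displacement_px)

        # attribute each detached component to the nearest matched body
        det_centroids = (
            ndimage.center_of_mass(labels > 0, labels, q.detached_labels)
            if q.detached_labels
            else []
        )
        matched = {oid: di for oid, di in assignment.items() if di is not None}
        det_owner: dict[str, list[int]] = {oid: [] for oid in matched}
        for lab, (cy, cx) in zip(q.detached_labels, det_centroids):
            if not matched:
                break
            owner = min(
                matched,
                key=lambda oid: np.hypot(
                    cy - detections[matched[oid]][0], cx - detections[matched[oid]][1]
                ),
            )
            det_owner[owner].append(lab)

        for oid, di in assignment.items():
            rec = per_id[oid]
            if di is None:
                rec["gaps"].append(float(time))
                continue
            body_label = q.intact_labels[di]
            rec["times"].append(float(time))
            rec["body"].append(int(areas[body_label]))
            owned = det_owner.get(oid, [])
            rec["darea"].append(int(sum(areas[l] for l in owned)))
            rec["dcount"].append(len(owned))

    tracks = []
    for oid, rec in per_id.items():
        tracks.append(
            Track(
                organoid_id=oid,
                times=rec["times"],
                body_area_px=rec["body"],
                detached_area_px=rec["darea"],
                detached_count=rec["dcount"],
                body_area_delta=[b1 - b0 for b0, b1 in zip(rec["body"], rec["body"][1:])],
                detached_count_delta=[
                    c1 - c0 for c0, c1 in zip(rec["dcount"], rec["dcount"][1:])
                ],
                gaps=rec["gaps"],
            )
        )
    return tracks
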