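"""Synthetic fluorescence images, time-lapse series, DE tables and count
matrices with exact ground truth.

The raw microscopy and sequencing data behind the detachment phenotype
are not publicly deposited, so every downstream module is exercised on
generated data whose truth is known by construction:

* **Organoid images** — each organoid body is a union of overlapping
  discs (a lobed aggregate).  The three nephron markers occupy
  contiguous sub-regions of the body: PODXL central, ECAD and LTL
  anchored at the periphery, each covering ``marker_overlap_fraction``
  of the body area.  Detached cells are small isolated discs placed in
  a distance band around the body, never touching it.  Pixels are
  ``background + foreground + N(0, noise_sd)`` clipped at zero; the
  truth masks are exactly the noiseless object supports.
* **Condition experiments** — per-condition multipliers scale the body
  area (via sqrt on the radius) and the detached-cell count; defaults
  mirror a 3-fold intact-area reduction between a control and a
  high-glucose-like condition.
* **Time-lapse series** — a single organoid sheds ``shed_rate``
  detached cells per day while its body area shrinks by
  ``shrink_rate`` per day; the whole scene drifts by a small jitter so
  position-based tracking is exercised but solvable.
* **DE-table pairs** — two gene tables with a prescribed overlap and
  prescribed numbers of direction-concordant genes, all rows passing
  the significance cutoffs by construction.
* **Count matrices** — cells constructed to pass all four QC rules
  comfortably, except designated violators built to break exactly one
  rule each.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .transcriptomics import CellQCThresholds
from .types import GroundTruth, MultiChannelImage, NEPHRON_MARKERS

__all__ = [
    "ImageSpec",
    "EffectSpec",
    "ExperimentRecord",
    "ExperimentDataset",
    "make_organoid_image",
    "make_image_with_intact_fraction",
    "make_condition_experiment",
    "make_census_series",
    "make_timelapse",
    "make_de_pair",
    "make_count_matrix",
]

# minimum rasterized gap (px) between any detached object and any body,
# so 8-connectivity can never merge them
_MIN_GAP = 2.0


# --------------------------------------------------------------------------
# specs


@dataclass
class ImageSpec:
    """Parameters of one synthetic multi-channel well image.

    Distances and areas are in pixels, intensities in arbitrary units.
    ``detached_ring_px`` is the (min, max) distance band, measured from
    the body edge, in which detached cells are placed; its lower bound
    must be positive so detached objects never touch the body.
    """

    well_size_px: tuple[int, int] = (128, 128)
    n_organoids: int = 1
    body_radius_px: tuple[float, float] = (10.0, 14.0)
    detached_cell_count: int = 4
    detached_cell_radius_px: tuple[float, float] = (2.0, 3.5)
    detached_ring_px: tuple[float, float] = (3.0, 20.0)
    channel_means: dict[str, float] = field(
        default_factory=lambda: {"PODXL": 100.0, "ECAD": 100.0, "LTL": 100.0}
    )
    background_mean: float = 20.0
    noise_sd: float = 10.0
    marker_overlap_fraction: float | Mapping[str, float] = 0.7
    z_slices: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detached_ring_px[0] <= 0:
            raise ValueError("detached_ring_px lower bound must be > 0")
        if self.detached_ring_px[1] <= self.detached_ring_px[0]:
            raise ValueError("detached_ring_px must be an increasing (min, max) band")
        if self.background_mean < 0 or self.noise_sd < 0:
            raise ValueError("intensities must be non-negative")
        if any(v < 0 for v in self.channel_means.values()):
            raise ValueError("channel means must be non-negative")
        missing = set(NEPHRON_MARKERS) - set(self.channel_means)
        if missing:
            raise ValueError(f"channel set must include the nephron markers; missing {sorted(missing)}")
        if self.n_organoids < 1:
            raise ValueError("n_organoids must be >= 1")
        if self.detached_cell_count < 0:
            raise ValueError("detached_cell_count must be >= 0")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")

    def marker_fraction(self, channel: str) -> float:
        if isinstance(self.marker_overlap_fraction, Mapping):
            return float(self.marker_overlap_fraction.get(channel, 1.0))
        return float(self.marker_overlap_fraction)


@dataclass
class EffectSpec:
    """Per-condition effect sizes for a synthetic experiment.

    The default mirrors the headline phenotype: a 3-fold reduction of
    the intact marker area (area multiplier 1/3) with more detached
    cells under the stressed condition.  Multipliers are relative to
    the control, whose multiplier must be 1.
    """

    area_multipliers: dict[str, float] = field(
        default_factory=lambda: {"11mM": 1.0, "33mM": 1.0 / 3.0}
    )
    detached_multipliers: dict[str, float] | None = field(
        default_factory=lambda: {"11mM": 1.0, "33mM": 2.0}
    )
    control: str = "11mM"
    n_organoids_per_condition: int = 30
    organoid_loss_fraction: dict[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.area_multipliers:
            raise ValueError(f"control condition {self.control!r} missing from multipliers")
        if abs(self.area_multipliers[self.control] - 1.0) > 1e-12:
            raise ValueError("control condition must have multiplier 1")
        if any(m <= 0 for m in self.area_multipliers.values()):
            raise ValueError("multipliers must be > 0")
        if self.n_organoids_per_condition < 2:
            raise ValueError("n_organoids_per_condition must be >= 2 (stats needs replicates)")

    def detached_multiplier(self, condition: str) -> float:
        if self.detached_multipliers is None:
            return 1.0
        return float(self.detached_multipliers.get(condition, 1.0))


# --------------------------------------------------------------------------
# geometry helpers


@dataclass
class _Organoid:
    center: tuple[float, float]  # (y, x)
    radius: float
    lobes: list[tuple[float, float, float]]  # (dy, dx, radius) relative to center
    anchor_offsets: dict[str, tuple[float, float]]  # marker -> (dy, dx)

    @property
    def extent(self) -> float:
        ext = self.radius
        for dy, dx, lr in self.lobes:
            ext = max(ext, math.hypot(dy, dx) + lr)
        return ext

    def scaled(self, scale: float) -> "_Organoid":
        return _Organoid(
            center=self.center,
            radius=self.radius * scale,
            lobes=[(dy * scale, dx * scale, lr * scale) for dy, dx, lr in self.lobes],
            anchor_offsets={
                ch: (dy * scale, dx * scale) for ch, (dy, dx) in self.anchor_offsets.items()
            },
        )

    def shifted(self, offset: tuple[float, float]) -> "_Organoid":
        return replace(self, center=(self.center[0] + offset[0], self.center[1] + offset[1]))


def _disc_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _body_mask(shape: tuple[int, int], org: _Organoid) -> np.ndarray:
    cy, cx = org.center
    mask = _disc_mask(shape, cy, cx, org.radius)
    for dy, dx, lr in org.lobes:
        mask |= _disc_mask(shape, cy + dy, cx + dx, lr)
    return mask


def _marker_submask(body: np.ndarray, anchor: tuple[float, float], fraction: float) -> np.ndarray:
    """Contiguous sub-region: the ``fraction`` of body pixels closest to ``anchor``."""
    if fraction >= 1.0:
        return body.copy()
    ys, xs = np.nonzero(body)
    k = int(math.ceil(fraction * len(ys)))
    d2 = (ys - anchor[0]) ** 2 + (xs - anchor[1]) ** 2
    order = np.argsort(d2, kind="stable")[:k]
    out = np.zeros_like(body)
    out[ys[order], xs[order]] = True
    return out


def _margin(spec: ImageSpec, extra: float = 0.0) -> float:
    return (
        1.15 * spec.body_radius_px[1]
        + spec.detached_ring_px[1]
        + spec.detached_cell_radius_px[1]
        + _MIN_GAP
        + extra
    )


def _check_bounds(spec: ImageSpec, extra: float = 0.0) -> None:
    m = _margin(spec, extra)
    h, w = spec.well_size_px
    for dim, size in (("height", h), ("width", w)):
        if 2 * m >= size:
            raise ValueError(
                f"detached ring band exceeds image {dim}: need > {2 * m:.0f} px, got {size}"
            )


def _make_layout(spec: ImageSpec, rng: np.random.Generator, extra_margin: float = 0.0) -> list[_Organoid]:
    """Sample organoid bodies (lobed disc unions) with non-interacting rings."""
    _check_bounds(spec, extra_margin)
    h, w = spec.well_size_px
    organoids: list[_Organoid] = []
    for i in range(spec.n_organoids):
        r = rng.uniform(*spec.body_radius_px)
        lobes = []
        for _ in range(2):
            ang = rng.uniform(0, 2 * math.pi)
            off = 0.55 * r
            lobes.append((off * math.sin(ang), off * math.cos(ang), 0.55 * r))
        theta0 = rng.uniform(0, 2 * math.pi)
        anchors = {"PODXL": (0.0, 0.0)}
        for j, ch in enumerate(("ECAD", "LTL")):
            a = theta0 + j * 2 * math.pi / 3
            anchors[ch] = (r * math.sin(a), r * math.cos(a))
        org = _Organoid(center=(0.0, 0.0), radius=r, lobes=lobes, anchor_offsets=anchors)
        m = org.extent + spec.detached_ring_px[1] + spec.detached_cell_radius_px[1] + _MIN_GAP + extra_margin
        placed = False
        for _ in range(5000):
            cy = rng.uniform(m, h - 1 - m)
            cx = rng.uniform(m, w - 1 - m)
            min_sep_ok = all(
                math.hypot(cy - o.center[0], cx - o.center[1])
                >= org.extent + o.extent + max(8.0, 2 * spec.detached_ring_px[0] + 4.0)
                for o in organoids
            )
            if min_sep_ok:
                organoids.append(replace(org, center=(cy, cx)))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place organoid {i + 1}/{spec.n_organoids}: well too small"
            )
    return organoids


def _place_detached(
    spec: ImageSpec,
    organoids: list[_Organoid],
    body_all: np.ndarray,
    counts: Mapping[str, int],
    rng: np.random.Generator,
    existing: Mapping[str, list[tuple[float, float, float]]] | None = None,
) -> dict[str, list[tuple[float, float, float]]]:
    """Place isolated detached discs per channel inside the ring band.

    Returns per-channel lists of the newly placed (cy, cx, radius).
    Cells of the same channel keep a >=2 px gap from each other, from
    any ``existing`` cells, and from every body.
    """
    h, w = spec.well_size_px
    dist_out = ndimage.distance_transform_edt(~body_all)
    ring_lo, ring_hi = spec.detached_ring_px
    gap_lo = max(ring_lo, _MIN_GAP)
    cells: dict[str, list[tuple[float, float, float]]] = {}
    for ch in sorted(counts):
        placed: list[tuple[float, float, float]] = (
            list(existing[ch]) if existing and ch in existing else []
        )
        n_existing = len(placed)
        for j in range(counts[ch]):
            org = organoids[j % len(organoids)]
            ok = False
            for _ in range(6000):
                rho = rng.uniform(*spec.detached_cell_radius_px)
                ang = rng.uniform(0, 2 * math.pi)
                d = org.extent + rng.uniform(gap_lo + rho, ring_hi + rho)
                cy = org.center[0] + d * math.sin(ang)
                cx = org.center[1] + d * math.cos(ang)
                if not (rho + 1 <= cy <= h - 2 - rho and rho + 1 <= cx <= w - 2 - rho):
                    continue
                gap = dist_out[int(round(cy)), int(round(cx))] - rho
                if not (gap_lo <= gap <= ring_hi):
                    continue
                if any(
                    math.hypot(cy - py, cx - px) < rho + pr + _MIN_GAP
                    for py, px, pr in placed
                ):
                    continue
                placed.append((cy, cx, rho))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place detached cell {j + 1} in channel {ch}: "
                    "ring band too crowded or image too small"
                )
        cells[ch] = placed[n_existing:]
    return cells


def _render(
    spec: ImageSpec,
    organoids: list[_Organoid],
    counts: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Rasterize bodies + detached cells, add noise, emit truth masks."""
    shape = tuple(spec.well_size_px)
    body_all = np.zeros(shape, dtype=bool)
    body_masks = [_body_mask(shape, o) for o in organoids]
    for bm in body_masks:
        body_all |= bm

    marker_counts = {ch: counts.get(ch, 0) if organoids else 0 for ch in NEPHRON_MARKERS}
    if organoids:
        cells = _place_detached(spec, organoids, body_all, marker_counts, rng)
    else:
        cells = {ch: [] for ch in NEPHRON_MARKERS}

    intact_masks: dict[str, np.ndarray] = {}
    detached_masks: dict[str, np.ndarray] = {}
    for ch in NEPHRON_MARKERS:
        frac = spec.marker_fraction(ch)
        intact = np.zeros(shape, dtype=bool)
        for org, bm in zip(organoids, body_masks):
            anchor = (
                org.center[0] + org.anchor_offsets[ch][0],
                org.center[1] + org.anchor_offsets[ch][1],
            )
            intact |= _marker_submask(bm, anchor, frac)
        detached = np.zeros(shape, dtype=bool)
        for cy, cx, rho in cells[ch]:
            detached |= _disc_mask(shape, cy, cx, rho)
        intact_masks[ch] = intact
        detached_masks[ch] = detached

    all_detached = np.zeros(shape, dtype=bool)
    for ch in NEPHRON_MARKERS:
        all_detached |= detached_masks[ch]

    channels: dict[str, np.ndarray] = {}
    for ch in sorted(spec.channel_means):
        if ch in NEPHRON_MARKERS:
            support = intact_masks[ch] | detached_masks[ch]
        else:  # nuclei or any extra channel: whole scene
            support = body_all | all_detached
            intact_masks.setdefault(ch, body_all.copy())
            detached_masks.setdefault(ch, all_detached.copy())
        fg = spec.channel_means[ch] * support.astype(float)
        if spec.z_slices == 1:
            plane = spec.background_mean + fg
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, shape)
            channels[ch] = np.clip(plane, 0.0, None)
        else:
            zc = (spec.z_slices - 1) / 2.0
            stack = np.empty((spec.z_slices, *shape))
            for z in range(spec.z_slices):
                w_z = math.exp(-0.5 * ((z - zc) / (0.35 * spec.z_slices)) ** 2)
                plane = spec.background_mean + fg * w_z
                if spec.noise_sd > 0:
                    plane = plane + rng.normal(0.0, spec.noise_sd, shape)
                stack[z] = np.clip(plane, 0.0, None)
            channels[ch] = stack

    fractions = {}
    det_counts = {}
    for ch in NEPHRON_MARKERS:
        a_int = int(intact_masks[ch].sum())
        a_det = int(detached_masks[ch].sum())
        fractions[ch] = a_int / (a_int + a_det) if a_int + a_det else float("nan")
        det_counts[ch] = len(cells[ch])

    truth = GroundTruth(
        intact_masks=intact_masks,
        detached_masks=detached_masks,
        intact_fraction=fractions,
        n_organoids=len(organoids),
        detached_counts=det_counts,
        organoid_centroids=[o.center for o in organoids],
    )
    return MultiChannelImage(channels=channels), truth


# --------------------------------------------------------------------------
# public generators


def make_organoid_image(spec: ImageSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate one multi-channel organoid image with exact truth masks."""
    rng = np.random.default_rng(spec.seed)
    organoids = _make_layout(spec, rng)
    counts = {ch: spec.detached_cell_count for ch in NEPHRON_MARKERS}
    return _render(spec, organoids, counts, rng)


def make_image_with_intact_fraction(
    f: float, spec: ImageSpec
) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate an image whose true intact fraction is close to ``f``.

    The detached-cell count is chosen so that the total detached marker
    area balances the realized intact marker area at the requested
    fraction; the exact realized fraction is recorded in the truth.
    """
    if not 0 < f <= 1:
        raise ValueError("intact fraction must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    organoids = _make_layout(spec, rng)
    shape = tuple(spec.well_size_px)
    frac = spec.marker_fraction("PODXL")
    area_intact = sum(
        int(math.ceil(frac * _body_mask(shape, o).sum())) for o in organoids
    )
    rho_mean = sum(spec.detached_cell_radius_px) / 2.0
    probe = 2 * int(math.ceil(rho_mean)) + 3
    cell_area = int(_disc_mask((probe, probe), probe // 2, probe // 2, rho_mean).sum())
    n = int(round(area_intact * (1 - f) / (f * cell_area)))
    counts = {ch: n for ch in NEPHRON_MARKERS}
    return _render(spec, organoids, counts, rng)


@dataclass
class ExperimentRecord:
    organoid_id: str
    condition: str
    image: MultiChannelImage
    truth: GroundTruth


@dataclass
class ExperimentDataset:
    records: list[ExperimentRecord]
    manifest: pd.DataFrame
    counts_by_day: dict[str, dict[float, int]] | None = None


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_condition_experiment(effects: EffectSpec, base: ImageSpec) -> ExperimentDataset:
    """One synthetic image per organoid per condition, effects applied.

    The intact-area multiplier scales the body radius by its square
    root (area scales linearly); the detached multiplier scales the
    detached-cell count.  A manifest maps every image to its condition
    and organoid ID.
    """
    ss = np.random.SeedSequence(effects.seed)
    records: list[ExperimentRecord] = []
    rows = []
    for cond in effects.area_multipliers:
        amult = effects.area_multipliers[cond]
        dmult = effects.detached_multiplier(cond)
        rscale = math.sqrt(amult)
        for i in range(effects.n_organoids_per_condition):
            child = ss.spawn(1)[0]
            spec_i = replace(
                base,
                n_organoids=1,
                body_radius_px=(
                    base.body_radius_px[0] * rscale,
                    base.body_radius_px[1] * rscale,
                ),
                detached_cell_count=int(round(base.detached_cell_count * dmult)),
                seed=_child_seed(child),
            )
            image, truth = make_organoid_image(spec_i)
            oid = f"{cond}/org{i:03d}"
            records.append(ExperimentRecord(oid, cond, image, truth))
            rows.append(
                {
                    "organoid_id": oid,
                    "condition": cond,
                    "true_intact_area_PODXL": int(truth.intact_masks["PODXL"].sum()),
                    "true_detached_count_PODXL": truth.detached_counts["PODXL"],
                }
            )
    counts_by_day = None
    if effects.organoid_loss_fraction is not None:
        n = effects.n_organoids_per_condition
        counts_by_day = {}
        for cond in effects.area_multipliers:
            per_day = {0.0: n}
            for day, loss in sorted(effects.organoid_loss_fraction.items()):
                per_day[float(day)] = int(round(n * (1 - loss)))
            counts_by_day[cond] = per_day
    return ExperimentDataset(
        records=records, manifest=pd.DataFrame(rows), counts_by_day=counts_by_day
    )


def make_census_series(
    spec: ImageSpec, loss_fraction: Mapping[float, float]
) -> list[tuple[float, MultiChannelImage, GroundTruth]]:
    """Whole-well images over days with organoids progressively lost.

    Day 0 carries all ``spec.n_organoids`` organoids; on day *d* only
    ``round(n * (1 - loss_fraction[d]))`` survive.  Survivor sets are
    nested (an organoid lost on day 3 stays lost on day 6).  Each
    frame's truth records the surviving count and centroids.
    """
    rng = np.random.default_rng(spec.seed)
    organoids = _make_layout(spec, rng)
    order = rng.permutation(spec.n_organoids)
    frames = []
    days = [0.0] + [float(d) for d in sorted(loss_fraction)]
    for day in days:
        loss = 0.0 if day == 0.0 else loss_fraction[day]
        if not 0 <= loss < 1:
            raise ValueError("loss fractions must be in [0, 1)")
        k = int(round(spec.n_organoids * (1 - loss)))
        keep = sorted(order[:k])
        survivors = [organoids[i] for i in keep]
        day_rng = np.random.default_rng((spec.seed, int(day)))
        counts = {ch: spec.detached_cell_count for ch in NEPHRON_MARKERS}
        image, truth = _render(spec, survivors, counts, day_rng)
        frames.append((day, image, truth))
    return frames


def make_timelapse(
    spec: ImageSpec,
    days: int,
    shed_rate: float,
    shrink_rate: float,
    drift_px: float = 0.5,
) -> list[tuple[float, MultiChannelImage, GroundTruth]]:
    """Single-organoid time series: progressive shedding and shrinkage.

    On day *d* (0-based) the body area is scaled by
    ``(1 - shrink_rate) ** d`` and ``round(shed_rate * d)`` detached
    cells have accumulated per channel; cells placed on earlier days
    persist at their body-relative positions.  The whole scene drifts
    by at most ``drift_px`` per day, so centroid tracking is solvable.
    """
    if days < 2:
        raise ValueError("days must be >= 2")
    if shrink_rate >= 1:
        raise ValueError("shrink_rate must be < 1 (full loss in one day is not modeled)")
    if shrink_rate < 0 or shed_rate < 0:
        raise ValueError("rates must be non-negative")
    if spec.n_organoids != 1:
        raise ValueError("time-lapse tracking generator models a single organoid per field")

    rng = np.random.default_rng(spec.seed)
    base_org = _make_layout(spec, rng, extra_margin=drift_px * days)[0]
    shape = tuple(spec.well_size_px)

    # body-relative detached-cell store: channel -> [(dy, dx, rho)]
    rel_cells: dict[str, list[tuple[float, float, float]]] = {ch: [] for ch in NEPHRON_MARKERS}
    offset = np.zeros(2)
    frames = []
    for d in range(days):
        if d > 0:
            offset = offset + rng.uniform(-drift_px, drift_px, 2)
        scale = (1 - shrink_rate) ** (d / 2.0)  # radius scale; area scales by (1-shrink)^d
        org = base_org.scaled(scale).shifted((float(offset[0]), float(offset[1])))
        body = _body_mask(shape, org)
        target = int(round(shed_rate * d))
        need = {ch: max(0, target - len(rel_cells[ch])) for ch in NEPHRON_MARKERS}
        existing_abs = {
            ch: [
                (org.center[0] + dy, org.center[1] + dx, rho)
                for dy, dx, rho in rel_cells[ch]
            ]
            for ch in NEPHRON_MARKERS
        }
        new_cells = _place_detached(spec, [org], body, need, rng, existing=existing_abs)
        for ch in NEPHRON_MARKERS:
            for cy, cx, rho in new_cells[ch]:
                rel_cells[ch].append((cy - org.center[0], cx - org.center[1], rho))

        intact_masks, detached_masks = {}, {}
        for ch in NEPHRON_MARKERS:
            anchor = (
                org.center[0] + org.anchor_offsets[ch][0],
                org.center[1] + org.anchor_offsets[ch][1],
            )
            intact_masks[ch] = _marker_submask(body, anchor, spec.marker_fraction(ch))
            det = np.zeros(shape, dtype=bool)
            for dy, dx, rho in rel_cells[ch]:
                det |= _disc_mask(shape, org.center[0] + dy, org.center[1] + dx, rho)
            detached_masks[ch] = det

        channels = {}
        for ch in sorted(spec.channel_means):
            if ch in NEPHRON_MARKERS:
                support = intact_masks[ch] | detached_masks[ch]
            else:
                support = body.copy()
                for m in detached_masks.values():
                    support |= m
            plane = spec.background_mean + spec.channel_means[ch] * support.astype(float)
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, shape)
            channels[ch] = np.clip(plane, 0.0, None)

        fractions = {}
        for ch in NEPHRON_MARKERS:
            a_i = int(intact_masks[ch].sum())
            a_d = int(detached_masks[ch].sum())
            fractions[ch] = a_i / (a_i + a_d) if a_i + a_d else float("nan")
        truth = GroundTruth(
            intact_masks=intact_masks,
            detached_masks=detached_masks,
            intact_fraction=fractions,
            n_organoids=1,
            detached_counts={ch: len(rel_cells[ch]) for ch in NEPHRON_MARKERS},
            organoid_centroids=[org.center],
        )
        frames.append((float(d), MultiChannelImage(channels=channels), truth))
    return frames


def make_de_pair(
    n_genes_a: int,
    n_genes_b: int,
    overlap: int = 56,
    concordant_up: int = 15,
    concordant_down: int = 21,
    seed: int = 0,
    alpha: float = 0.05,
    lfc_min: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two DE tables with a prescribed overlap and directionality mix.

    Every row passes the significance cutoffs (adjusted p <= ``alpha``
    and |log2FC| >= ``lfc_min``) by construction.  The defaults mirror
    the reported organoid-vs-biopsy comparison: 56 shared genes of
    which 15 are up- and 21 down-regulated in both tables.
    """
    if min(n_genes_a, n_genes_b, overlap, concordant_up, concordant_down) < 0:
        raise ValueError("inconsistent counts: all counts must be non-negative")
    if concordant_up + concordant_down > overlap or overlap > min(n_genes_a, n_genes_b):
        raise ValueError(
            "inconsistent counts: need concordant_up + concordant_down <= overlap "
            "<= min(n_genes_a, n_genes_b)"
        )
    rng = np.random.default_rng(seed)
    total = n_genes_a + n_genes_b - overlap
    genes = [f"G{i:05d}" for i in rng.permutation(total * 2)[:total]]
    shared = genes[:overlap]
    a_only = genes[overlap : n_genes_a]
    b_only = genes[n_genes_a :]

    def lfc(sign: int) -> float:
        return float(sign * rng.uniform(lfc_min, lfc_min + 3.0))

    def padj() -> float:
        return float(rng.uniform(1e-8, alpha))

    rows_a, rows_b = [], []
    n_disc = overlap - concordant_up - concordant_down
    for i, g in enumerate(shared):
        if i < concordant_up:
            sa, sb = 1, 1
        elif i < concordant_up + concordant_down:
            sa, sb = -1, -1
        else:  # discordant, alternating orientation
            sa, sb = (1, -1) if (i - concordant_up - concordant_down) % 2 == 0 else (-1, 1)
        rows_a.append({"gene": g, "log2fc": lfc(sa), "padj": padj()})
        rows_b.append({"gene": g, "log2fc": lfc(sb), "padj": padj()})
    for g in a_only:
        rows_a.append({"gene": g, "log2fc": lfc(1 if rng.random() < 0.5 else -1), "padj": padj()})
    for g in b_only:
        rows_b.append({"gene": g, "log2fc": lfc(1 if rng.random() < 0.5 else -1), "padj": padj()})

    df_a = pd.DataFrame(rows_a).sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df_b = pd.DataFrame(rows_b).sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    truth = GroundTruth(
        n_overlap=overlap,
        n_concordant=concordant_up + concordant_down,
        concordant_fraction=(concordant_up + concordant_down) / overlap if overlap else float("nan"),
    )
    return df_a, df_b, truth


def make_count_matrix(
    n_cells: int = 100,
    n_genes: int = 300,
    violate_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    thresholds: CellQCThresholds | None = None,
) -> tuple[sparse.csr_matrix, list[str], list[str], GroundTruth]:
    """Sparse cell-by-gene count matrix with designated QC violators.

    ``violate_fractions`` maps rule names (``umi``, ``genes``, ``mito``,
    ``ribo``) to the fraction of cells constructed to violate exactly
    that rule; all remaining cells pass every rule with a wide margin.
    Thresholds default to a desk-scale analogue of the study's QC
    (UMI < 2000, genes < 150, mito < 10%, ribo < 40%).
    """
    thresholds = thresholds or CellQCThresholds(
        max_umi=2000, max_genes=150, max_mito_fraction=0.10, max_ribo_fraction=0.40
    )
    violate_fractions = dict(violate_fractions or {})
    bad_keys = set(violate_fractions) - {"umi", "genes", "mito", "ribo"}
    if bad_keys:
        raise ValueError(f"unknown QC rules: {sorted(bad_keys)}")
    if any(not 0 <= f <= 1 for f in violate_fractions.values()):
        raise ValueError("violate fractions must be in [0, 1]")
    if sum(violate_fractions.values()) > 1 + 1e-9:
        raise ValueError("violate fractions must sum to at most 1")
    if n_genes < 100:
        raise ValueError("n_genes too small to realize thresholds (need >= 100)")
    if violate_fractions.get("genes", 0) > 0 and n_genes < thresholds.max_genes + 120:
        raise ValueError(
            "n_genes too small to realize thresholds: the detected-genes rule "
            f"needs n_genes >= max_genes + 120 = {thresholds.max_genes + 120}"
        )

    rng = np.random.default_rng(seed)
    mito = [f"MT-G{i:02d}" for i in range(20)]
    ribo = [f"RPS{i:02d}" for i in range(30)] + [f"RPL{i:02d}" for i in range(30)]
    other = [f"GENE{i:04d}" for i in range(n_genes - len(mito) - len(ribo))]
    gene_names = mito + ribo + other
    mito_idx = np.arange(len(mito))
    ribo_idx = np.arange(len(mito), len(mito) + len(ribo))
    other_idx = np.arange(len(mito) + len(ribo), n_genes)

    perm = rng.permutation(n_cells)
    rule_of_cell = np.full(n_cells, "", dtype=object)
    start = 0
    for rule in ("umi", "genes", "mito", "ribo"):
        k = int(round(violate_fractions.get(rule, 0.0) * n_cells))
        for c in perm[start : start + k]:
            rule_of_cell[c] = rule
        start += k

    max_umi, max_genes = thresholds.max_umi, thresholds.max_genes

    def compose(T, n_det, mito_share, ribo_share):
        counts = np.zeros(n_genes, dtype=np.int64)
        t_m = int(round(mito_share * T))
        t_r = int(round(ribo_share * T))
        t_o = T - t_m - t_r
        n_m = 0 if t_m == 0 else min(len(mito_idx), max(1, int(round(n_det * t_m / T))), t_m)
        n_r = 0 if t_r == 0 else min(len(ribo_idx), max(1, int(round(n_det * t_r / T))), t_r)
        n_o = n_det - n_m - n_r
        if not 1 <= n_o <= min(len(other_idx), t_o):
            raise AssertionError("cell composition out of range; widen margins")
        for idx_pool, n_g, t_g in (
            (mito_idx, n_m, t_m),
            (ribo_idx, n_r, t_r),
            (other_idx, n_o, t_o),
        ):
            if n_g == 0:
                continue
            chosen = rng.choice(idx_pool, size=n_g, replace=False)
            counts[chosen] += 1
            extra = t_g - n_g
            if extra > 0:
                counts[chosen] += rng.multinomial(extra, np.full(n_g, 1.0 / n_g))
        return counts

    mat = np.zeros((n_cells, n_genes), dtype=np.int64)
    for c in range(n_cells):
        rule = rule_of_cell[c]
        if rule == "umi":
            T = int(rng.integers(max_umi, 2 * max_umi))
            row = compose(T, int(rng.integers(50, 120)), rng.uniform(0.01, 0.05), rng.uniform(0.05, 0.2))
        elif rule == "genes":
            n_det = int(rng.integers(max_genes, max_genes + 40))
            row = compose(2 * n_det, n_det, 0.02, 0.05)
        elif rule == "mito":
            T = int(rng.integers(500, 1000))
            row = compose(T, int(rng.integers(50, 120)), rng.uniform(0.15, 0.30), rng.uniform(0.05, 0.2))
        elif rule == "ribo":
            T = int(rng.integers(500, 1000))
            row = compose(T, int(rng.integers(50, 120)), rng.uniform(0.01, 0.05), rng.uniform(0.45, 0.60))
        else:
            T = int(rng.integers(500, 1000))
            row = compose(T, int(rng.integers(50, 120)), rng.uniform(0.01, 0.05), rng.uniform(0.05, 0.2))
        mat[c] = row

    kept = np.array([r == "" for r in rule_of_cell], dtype=bool)
    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    truth = GroundTruth(kept_cells=kept)
    return sparse.csr_matrix(mat), gene_names, barcodes, truth
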