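# Methods

This note documents the models, parameters and numerical choices behind
`organoidquant`, and what the synthetic benchmarks do and do not
establish about real data.

## Segmentation model

Each marker channel is treated as background plus object signal. The
scalar background of a channel is the arithmetic mean, over all images
of an acquisition set, of each image's minimum pixel intensity (stacks
are z-projected first). This deliberately simple estimator matches the
acquisition-set normalization convention the pipeline is built around;
it assumes a spatially flat background, and no illumination-field
correction is attempted.

Thresholding uses a single global offset Δ above the background for the
whole experiment (`SegmentationParams.threshold_offset`, default 50
intensity units; the test suite uses 60–70 against the generator's
foreground of 100 over background 20). Pixels strictly above *b* + Δ
form the foreground; components smaller than `min_object_px` (default
4 px) are discarded as shot noise. The partition rule is purely
area-based: components with area ≥ `main_body_min_px` (default 100 px)
are *intact* main bodies, everything else is *detached*. "Geometrically
isolated" is thus operationalized as "not part of a component large
enough to be a body", which matches the visual phenotype (tiny outlying
specks around a large aggregate) without introducing a distance
parameter. If no component reaches the body threshold the largest
component is taken as intact, since every analyzed field is assumed to
contain an organoid. Region delineation is fully automated; no manual
ROI circling is supported, by design.

Numerical conventions: 8-connectivity by default (diagonal pixels of
one cell must not split an object; 4 is available), component labels in
deterministic raster order, z-projection by per-pixel maximum (mean and
sum selectable), background-subtracted intensities clipped at zero
(negative differences are subtraction artifacts, not signal), and the
intact/detached ratio computed with the denominator floored at
`ratio_epsilon_px` (default 1 px) plus a flag — fully intact organoids
then remain finite and plottable instead of being dropped. Scaling the
image, background and offset jointly by any c > 0 leaves all masks
unchanged (tested exactly).

Whether reported intensities should be means or integrated densities
over the union mask is an open choice; the mean is implemented (the
integrated density is the mean times the reported area).

## Organoid census and time-lapse tracking

A census region is a connected component of the union of the
above-background marker masks with area ≥ `min_organoid_px` (default
100 px) that contains above-background pixels of **every** required
marker (default ECAD, PODXL, LTL). The count is invariant to marker
order. Per-day counts are normalized to day 0 as percent remaining.

Tracking matches recorded t0 positions to per-frame intact-body
centroids by greedy nearest-neighbour assignment in ascending distance
order, with deterministic tie-breaks (t0 order, then region label) and
an explicit gap when no detection lies within `max_displacement_px`.
Organoids are sparse and near-sessile, so the greedy scheme is adequate
and avoids a global assignment solver. Detached components are
attributed to the nearest matched body. Mitosis, merging and subpixel
registration are out of scope.

## Statistics

Group comparisons follow the convention used throughout this assay
family: one-way fixed-effects ANOVA (F = MSB/MSW with (k−1, N−k)
degrees of freedom) followed by Fisher's LSD pairwise tests — pooled
MSE, two-sided p on the within df — with **no** multiple-comparison
correction. With two groups the LSD p equals both the ANOVA p and the
pooled two-sample t-test p, which the suite checks exactly. Summaries
are mean ± SEM (sample SD, n−1). qPCR fold changes use 2^−ΔΔCt with
per-condition means of Ct differences against a housekeeping gene.
Fold changes are ratios of condition means to the control mean (1/3 ≡
"3-fold reduction"). No values are ever auto-excluded; an explicit
exclusion list with reasons is accepted at the CLI and logged.
Well/experiment nesting is not modeled (observations are pooled).

## QC and concordance arithmetic

The cell filter keeps a cell iff total counts, detected genes,
mitochondrial fraction and ribosomal fraction are all strictly below
their thresholds (defaults 40,000 / 8,500 / 10% / 40%); mitochondrial
and ribosomal genes are identified by configurable name prefixes
("MT-", {"RPS","RPL"}) since no canonical gene sets are assumed. DE
significance is inclusive: p-adj ≤ 0.05 and |log2FC| ≥ 0.8. The
boundary asymmetry (strict vs inclusive) is intentional and follows
each rule as stated. Concordance between two DE tables is the fraction
of shared gene IDs whose fold-change signs agree; zero fold changes
count as discordant with a warning. Because "fraction of all analyzed"
has no single natural denominator, the overlap is reported against
three referents (table A, table B, union) with explicit labels.

## Synthetic data: what it emulates

The generator produces the statistical structure the estimators must
cope with, not microscope physics:

* **Bodies** are unions of three overlapping discs (radius r plus two
  lobes of 0.55 r at 0.55 r offsets), giving lobed aggregates whose
  connectivity matches what the segmentation relies on. Default body
  radius 10–14 px in a 128×128 well.
* **Markers** occupy contiguous sub-regions covering
  `marker_overlap_fraction` (default 0.7) of the body: the fraction of
  body pixels nearest an anchor — body centre for PODXL, peripheral
  anchors 120° apart for ECAD and LTL — loosely mirroring nephron
  organization while guaranteeing three-marker coincidence for the
  census.
* **Detached cells** are isolated discs (radius 2–3.5 px, 4 per channel
  by default) placed in a ring band 3–20 px from the body edge, with a
  ≥ 2 px rasterized gap from every body and from one another so they
  can never merge under 8-connectivity.
* **Noise** is additive Gaussian (sd 10 by default; 20 in the SNR-5
  recovery benchmark), clipped at zero, over a uniform background
  offset (20). Z-stacks modulate the foreground with a Gaussian axial
  profile peaking mid-stack.
* **Effects**: per-condition multipliers scale body *area* (via sqrt on
  the radius) and detached count. Defaults are a control ("11mM") and a
  stressed condition ("33mM") with area multiplier 1/3 — the headline
  3-fold intact-area reduction — and a doubled detached count; the
  count multiplier is capped by ring-band geometry (only so many
  non-touching discs fit around a shrunken body). 30 organoids per
  condition by default, one per image, matching per-organoid analysis.
* **Time-lapse**: round(shed_rate·d) accumulated detached cells and
  body area × (1−shrink_rate)^d on day d, with whole-scene drift ≤
  `drift_px`/day (default 0.5) so relative geometry is preserved and
  tracking stays solvable.
* **Census time-course**: a fixed well layout with a seeded, nested
  survivor subset per day (an organoid lost on day 3 stays lost).
* **Count matrices / DE pairs**: violators are constructed to break
  exactly one QC rule each (at desk-scale thresholds 2,000 UMI / 150
  genes / 10% / 40%); DE pairs realize an exact overlap and
  directionality mix, defaulting to 56 shared genes with 15 up- and 21
  down-concordant (64.3%).

Every generator is bit-deterministic given its seed; ground-truth masks
are exactly the noiseless object supports.

**What passing tests do not show:** real immunofluorescence has PSF
blur, uneven illumination, marker bleed-through, touching organoids,
irregular cell shapes and out-of-focus signal, none of which are
modeled. Recovery results on this benchmark demonstrate correctness of
the estimators' logic (areas, partitions, counts, statistics) under the
assumed noise model — not robustness to optical artifacts. The absent
physical pixel size means all quantities are in pixel units.

## Problem sizes

The shipped benchmarks use 128×128 px wells (400×400 for multi-organoid
census wells), 20–50 replicate experiments, 30 organoids per condition
for effect recovery, 20 seeds per QC/recovery sweep, and 100 random
masks for the labeling oracle — sizes chosen so the full suite and the
acceptance script each complete in well under a minute while keeping
sampling error far below the tested tolerances.

## Known limitations

Scalar background only; no volumetric (3-D) quantification — stacks are
projected; greedy (not globally optimal) tracking; no upper size bound
on detached components; the detached-count effect multiplier is
geometry-limited as noted; concordance treats tables as given and fits
no DE model.
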