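# organoidquant

Quantification of epithelial **detachment phenotypes** in kidney organoid
fluorescence microscopy, together with a fully synthetic benchmark suite.

## The problem

Kidney organoids exposed to stressors such as high glucose or inflammatory
cytokines shed podocytes and other epithelial cells: small marker-positive
cells detach from the main organoid body and scatter around it. The severity
of this phenotype is captured by segmenting each nephron-marker channel
(PODXL for podocytes, ECAD for distal tubule, LTL for proximal tubule) into

* **intact area** — above-background signal in the main organoid body, and
* **detached area** — above-background signal in small components
  geometrically isolated from the body,

and reporting areas, the intact/detached ratio, background-subtracted
intensities, whole-well organoid counts (a region is an organoid only when
all three nephron markers coincide), live/dead area ratios, and per-organoid
time-lapse trajectories of detachment. The statistical layer is the field's
standard one: mean ± SEM, one-way ANOVA with Fisher's LSD post-hoc tests
(uncorrected), two-sample t-tests, fold changes, and 2^−ΔΔCt for qPCR.
A transcriptomics module supplies the four-rule single-cell QC filter
(UMI < 40,000, genes < 8,500, mitochondrial < 10%, ribosomal < 40%, all
strict), DE-table thresholding (p-adj ≤ 0.05, |log2FC| ≥ 0.8), and the
overlap / directionality-concordance arithmetic used to compare an organoid
stress condition against patient-biopsy data.

## The method in brief

For a channel grid *I* and an acquisition set of images, the background *b*
is the mean over images of each image's minimum pixel intensity. Confocal
z-stacks are collapsed by per-pixel maximum. The foreground mask is
*I* > *b* + Δ with one global offset Δ per experiment; components smaller
than `min_object_px` are removed. Connected components (8-connectivity by
default) with area ≥ `main_body_min_px` are *intact*, the remainder
*detached*, so by construction

```
intact_area + detached_area = total surviving above-threshold area   (exact)
```

and the headline statistic is `intact_area / max(detached_area, ε)` with a
flag when the denominator is floored.

Because the raw data behind this phenotype are not publicly deposited, the
package ships a first-class generator (`organoidquant.synthetic`) that
emulates the study's statistical structure — lobed organoid bodies, isolated
detached cells in a ring band, per-condition effect sizes (default: a 3-fold
intact-area reduction), time-lapse shedding/shrinkage, QC-violating cells in
count matrices, DE-table pairs with a fixed overlap and concordance — with
exact ground-truth masks and counts, so every estimator can be validated
against known truth.

## Worked example

```python
from organoidquant import (SegmentationParams, estimate_background,
                           quantify_channel, fold_change, one_way_anova, fisher_lsd)
from organoidquant.synthetic import EffectSpec, ImageSpec, make_condition_experiment

effects = EffectSpec(n_organoids_per_condition=12, seed=0)   # 11mM control vs 33mM
dataset = make_condition_experiment(effects, ImageSpec())
images = [r.image for r in dataset.records]
bg = estimate_background(images, "PODXL")
params = SegmentationParams(threshold_offset=60)

groups = {}
for rec in dataset.records:
    q = quantify_channel(rec.image, "PODXL", bg, params)
    groups.setdefault(rec.condition, []).append(float(q.intact_area_px))

fc = fold_change(groups, "11mM")
anova = one_way_anova(groups)
lsd = fisher_lsd(groups, anova)
print(f"PODXL intact area fold change (33 mM vs control): {fc['33mM']:.3f}")
print(f"i.e. a {1/fc['33mM']:.1f}-fold reduction")
print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = {anova.F:.1f}, p = {anova.p:.2e}")
print(f"Fisher's LSD 11mM vs 33mM: p = {float(lsd.loc[0,'p']):.2e}")
```

prints

```
PODXL intact area fold change (33 mM vs control): 0.378
i.e. a 2.6-fold reduction
one-way ANOVA: F(1,22) = 93.8, p = 2.15e-09
Fisher's LSD 11mM vs 33mM: p = 2.15e-09
```

— the generated 3-fold reduction is recovered (2.6-fold at this n and seed,
within sampling error of organoid size jitter) and is overwhelmingly
significant by the ANOVA/LSD route.

A command-line surface mirrors the library
(`organoidquant simulate|quantify|census|track|stats|qc|concord|pipeline`);
`organoidquant pipeline run --config cfg.yaml --out DIR` runs
simulate → quantify → stats end-to-end, and identical configs reproduce all
output files byte-for-byte.

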