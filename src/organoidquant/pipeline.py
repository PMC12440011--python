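"""Config-driven end-to-end runs: simulate -> quantify -> stats -> report.

A single YAML (or dict) config drives the whole demo pipeline; every
stochastic stage draws from an explicit seed, and a metadata JSON
records versions, seeds, parameters and an output digest, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .segmentation import estimate_background, quantify_channel
from .stats import fisher_lsd, fold_change, one_way_anova, summarize
from .synthetic import EffectSpec, ImageSpec, make_condition_experiment
from .types import NEPHRON_MARKERS, SegmentationParams

__all__ = ["PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _build_specs(config: Mapping[str, Any]) -> tuple[EffectSpec, ImageSpec, SegmentationParams]:
    exp = dict(config.get("experiment", {}))
    image = dict(config.get("image", {}))
    seg = dict(config.get("segmentation", {}))
    for key in ("well_size_px", "body_radius_px", "detached_cell_radius_px", "detached_ring_px"):
        if key in image:
            image[key] = tuple(image[key])
    effects = EffectSpec(seed=int(config.get("seed", 0)), **exp)
    base = ImageSpec(**image)
    params = SegmentationParams(**seg)
    return effects, base, params


def validate_config(config: Mapping[str, Any]) -> None:
    """Fail fast — before any compute — on an invalid configuration."""
    effects, _, _ = _build_specs(config)
    control = config.get("control_condition", effects.control)
    if control not in effects.area_multipliers:
        raise ValueError(
            f"control condition {control!r} absent from experiment conditions "
            f"{sorted(effects.area_multipliers)}"
        )


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Run the synthetic demo end-to-end and write the result tables.

    Outputs in ``out_dir``: ``results.csv`` (one row per organoid x
    channel), ``summary.csv`` (mean +/- SEM per condition),
    ``anova.csv`` + ``lsd.csv`` (one-way ANOVA and Fisher's LSD on the
    configured measure), ``fold_change.csv``, and ``metadata.json``.
    """
    validate_config(config)
    effects, base, seg_params = _build_specs(config)
    control = config.get("control_condition", effects.control)
    stats_cfg = dict(config.get("stats", {}))
    channel = stats_cfg.get("channel", "PODXL")
    measure = stats_cfg.get("measure", "intact_area_px")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        dataset = make_condition_experiment(effects, base)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage simulate failed: {e}") from e

    images = [r.image for r in dataset.records]
    channels = sorted(set(NEPHRON_MARKERS) & set(base.channel_means))
    try:
        backgrounds = {ch: estimate_background(images, ch) for ch in channels}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage background failed: {e}") from e

    rows = []
    for rec in dataset.records:
        for ch in channels:
            try:
                q = quantify_channel(rec.image, ch, backgrounds[ch], seg_params)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(
                    f"stage quantify failed for {rec.organoid_id}/{ch}: {e}"
                ) from e
            rows.append(
                {
                    "organoid_id": rec.organoid_id,
                    "condition": rec.condition,
                    "channel": ch,
                    "intact_area_px": q.intact_area_px,
                    "detached_area_px": q.detached_area_px,
                    "intact_detached_ratio": q.intact_detached_ratio,
                    "ratio_floored": q.ratio_floored,
                    "n_detached": q.n_detached,
                    "mean_intensity": q.mean_intensity,
                }
            )
    results = pd.DataFrame(rows)

    # intensity normalization against the control condition, per channel
    ctrl_means = (
        results[results["condition"] == control]
        .groupby("channel")["mean_intensity"]
        .mean()
    )
    results["normalized_intensity"] = results.apply(
        lambda r: r["mean_intensity"] / ctrl_means[r["channel"]], axis=1
    )
    results.to_csv(out / "results.csv", index=False)

    sub = results[results["channel"] == channel]
    groups = {
        cond: sub.loc[sub["condition"] == cond, measure].to_numpy(dtype=float)
        for cond in effects.area_multipliers
    }
    try:
        summaries = {c: summarize(v) for c, v in groups.items()}
        anova = one_way_anova(groups)
        lsd = fisher_lsd(groups, anova)
        folds = fold_change(groups, control)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage stats failed for measure {measure!r}: {e}") from e

    pd.DataFrame(
        [
            {"condition": c, "mean": s.mean, "sem": s.sem, "n": s.n}
            for c, s in summaries.items()
        ]
    ).to_csv(out / "summary.csv", index=False)
    pd.DataFrame(
        [
            {
                "F": anova.F,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p": anova.p,
                "mse": anova.mse,
            }
        ]
    ).to_csv(out / "anova.csv", index=False)
    lsd.to_csv(out / "lsd.csv", index=False)
    pd.DataFrame(
        [{"condition": c, "fold_vs_control": f} for c, f in folds.items()]
    ).to_csv(out / "fold_change.csv", index=False)

    digest = hashlib.sha256((out / "results.csv").read_bytes()).hexdigest()
    metadata = {
        "organoidquant_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": int(config.get("seed", 0)),
        "config": _jsonable(config),
        "segmentation_params": asdict(seg_params),
        "backgrounds": backgrounds,
        "results_sha256": digest,
        "n_images": len(dataset.records),
    }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=1, sort_keys=True))
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
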