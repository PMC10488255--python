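"""End-to-end orchestration: simulate -> segment -> profile -> fit.

:func:`run_pipeline` executes a full in-silico experiment from an
:class:`~bactvolt.config.ExperimentConfig`: it renders every
condition/replicate/image, measures per-cell intensities, sets the
depolarization threshold from the control condition, summarizes percent
depolarization, writes mode-normalized histograms, and runs all pairwise
GEE comparisons.  Every artifact is recorded in a :class:`RunManifest`.

Per-stage seeds are derived from the master seed by stable hashing of
``(seed, stage, condition, replicate, image)``, so any single stage can be
re-run in isolation and reproduce its part of the experiment byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .imgseg import segment_and_measure, write_cell_table
from .profile import (
    depolarization_threshold,
    mode_normalized_histogram,
    summarize_conditions,
    summarize_experiment,
)
from .stats import cells_to_gee_data, pairwise_comparisons
from .synthgen import render_image_pair, sample_population

__all__ = ["RunManifest", "derive_seed", "run_pipeline"]

logger = logging.getLogger("bactvolt")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from the master seed and a stage/condition/replicate path."""
    key = ":".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Record of one pipeline run: config identity, seeds and artifacts."""

    config_hash: str
    master_seed: int
    version: str
    started: str
    artifacts: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    finished: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: ExperimentConfig, out_dir, write_images: bool = True) -> RunManifest:
    """Execute all stages for every condition and replicate.

    Returns the manifest; artifacts are written under *out_dir*:
    per-scene TIFF pairs and ground-truth CSVs, the pooled cell table,
    per-replicate and per-condition summaries, per-condition histogram CSVs,
    the threshold, and the pairwise GEE comparisons.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.content_hash(),
        master_seed=config.seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    params = config.segmentation_params()
    stage = "simulate/segment"
    try:
        tables = []
        for cond, spec in sorted(config.conditions.items()):
            for rep in range(1, config.replicates + 1):
                for img in range(1, config.images_per_replicate + 1):
                    scene_id = f"{cond}_R{rep}_I{img}"
                    seed_scene = derive_seed(config.seed, "scene", cond, rep, img)
                    seed_render = derive_seed(config.seed, "render", cond, rep, img)
                    manifest.seeds[f"scene/{scene_id}"] = seed_scene
                    manifest.seeds[f"render/{scene_id}"] = seed_render
                    truth = sample_population(spec, config.imaging, seed_scene)
                    pair = render_image_pair(
                        truth, config.imaging, seed_render, scene_id=scene_id
                    )
                    if write_images:
                        bf_path, fl_path = pair.write_tiffs(out_dir)
                        truth_path = os.path.join(out_dir, f"{scene_id}_truth.csv")
                        truth.to_csv(truth_path)
                        manifest.artifacts[f"bf/{scene_id}"] = bf_path
                        manifest.artifacts[f"fitc/{scene_id}"] = fl_path
                        manifest.artifacts[f"truth/{scene_id}"] = truth_path
                    tables.append(
                        segment_and_measure(
                            pair.brightfield,
                            pair.fluorescence,
                            params,
                            condition=cond,
                            replicate=f"R{rep}",
                            image_id=scene_id,
                        )
                    )
                    logger.info("segmented %s: %d cells", scene_id, len(tables[-1]))
        cells = pd.concat(tables, ignore_index=True)
        cells_path = os.path.join(out_dir, "cells.csv")
        write_cell_table(cells, cells_path)
        manifest.artifacts["cells"] = cells_path
    except Exception as exc:
        raise PipelineError(stage, manifest, exc) from exc

    stage = "profile"
    try:
        threshold = depolarization_threshold(cells, config.control)
        with open(os.path.join(out_dir, "threshold.json"), "w") as fh:
            json.dump(
                {
                    "value": threshold.value,
                    "control_condition": threshold.control_condition,
                    "n_cells_used": threshold.n_cells_used,
                },
                fh,
                indent=2,
            )
        manifest.artifacts["threshold"] = os.path.join(out_dir, "threshold.json")

        summaries = summarize_conditions(cells, threshold)
        report = summarize_experiment(summaries)
        for name, frame in report.items():
            path = os.path.join(out_dir, f"{name}.csv")
            frame.to_csv(path, index=False)
            manifest.artifacts[name] = path

        for cond, grp in cells.groupby("condition", sort=True):
            hist = mode_normalized_histogram(
                grp, bin_width=config.histogram_bin_width, threshold=threshold
            )
            path = os.path.join(out_dir, f"hist_{cond}.csv")
            hist.to_frame().to_csv(path, index=False)
            manifest.artifacts[f"hist/{cond}"] = path
    except Exception as exc:
        raise PipelineError(stage, manifest, exc) from exc

    stage = "stats"
    try:
        if len(config.conditions) >= 2:
            gee_data = cells_to_gee_data(cells, threshold.value)
            comparisons = pairwise_comparisons(
                gee_data, working_correlation=config.working_correlation
            )
            comp_path = os.path.join(out_dir, "comparisons.csv")
            pd.DataFrame(
                [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "rr": c.rr,
                        "p_value": c.p_value,
                        "method": c.method,
                    }
                    for c in comparisons
                ]
            ).to_csv(comp_path, index=False)
            manifest.artifacts["comparisons"] = comp_path
    except Exception as exc:
        raise PipelineError(stage, manifest, exc) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    manifest.artifacts["manifest"] = os.path.join(out_dir, "manifest.json")
    return manifest
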