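"""Label-fraction study orchestration: generate scenes, split, subsample
label fractions, train supervised and semi-supervised runs, evaluate on a
fixed test set and emit comparison tables.

Reported numbers follow the field's convention: test mAP@[0.5:0.95] on a
0-100 scale, aggregated as the median over seeds, with a relative-
performance row (semi-supervised mAP as a percentage of the supervised
run trained on 100% of the labels).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import numpy as np

from .detector_core import (
    DenseDetector,
    DetectorConfig,
    infer,
    save_checkpoint,
    detections_to_coco_results,
)
from .eval_metrics import evaluate_detections, relative_performance
from .scene_forge import (
    AnnotatedImage,
    SceneConfig,
    generate_dataset,
    split_dataset,
    subsample_labeled,
    write_coco,
)
from .teacher_student import TrainSchedule, train_semi_supervised, train_supervised

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study grid: scene, variants, label fractions, seeds, schedule."""

    scene: SceneConfig = field(default_factory=lambda: SceneConfig(seed=7))
    n_images: int = 300
    variants: tuple[str, ...] = ("anchor_free",)
    fractions: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 100.0)
    seeds: tuple[int, ...] = (0, 1, 2)
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    split_ratios: tuple[float, float, float] = (0.65, 0.20, 0.15)
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one seed")
        for f in self.fractions:
            if not (0.0 < f <= 100.0):
                raise ValueError(f"label fraction {f} outside (0, 100]")

    def detector_for(self, variant: str) -> DetectorConfig:
        return dataclasses.replace(
            self.detector, variant=variant, num_classes=self.scene.num_classes
        )


@dataclass
class ResultsTable:
    """Every configured cell, present or explicitly failed; medians over
    seeds; relative-performance column against supervised-100%."""

    fractions: tuple[float, ...]
    seeds: tuple[int, ...]
    variants: tuple[str, ...]
    cells: dict = field(default_factory=dict)  # key string -> cell dict

    @staticmethod
    def key(variant: str, supervision: str, fraction: float, seed: int) -> str:
        return f"{variant}|{supervision}|{fraction:g}|{seed}"

    def add(self, variant, supervision, fraction, seed, **payload) -> None:
        self.cells[self.key(variant, supervision, fraction, seed)] = payload

    def get(self, variant, supervision, fraction, seed) -> dict | None:
        return self.cells.get(self.key(variant, supervision, fraction, seed))

    def median_map(self, variant: str, supervision: str, fraction: float) -> float | None:
        vals = []
        for seed in self.seeds:
            cell = self.get(variant, supervision, fraction, seed)
            if cell and cell.get("status") == "ok":
                vals.append(cell["map_50_95"])
        if not vals:
            return None
        return float(np.median(vals))

    def to_dict(self) -> dict:
        summary = {}
        for variant in self.variants:
            ref = self.median_map(variant, "supervised", 100.0)
            for supervision in ("supervised", "semi"):
                for fraction in self.fractions:
                    med = self.median_map(variant, supervision, fraction)
                    entry = {
                        "median_map_50_95_pct": None
                        if med is None
                        else round(100.0 * med, 2)
                    }
                    if med is not None and ref:
                        entry["relative_to_sup100_pct"] = relative_performance(
                            100.0 * med, 100.0 * ref
                        )
                    summary[f"{variant}|{supervision}|{fraction:g}"] = entry
        return {
            "fractions": list(self.fractions),
            "seeds": list(self.seeds),
            "variants": list(self.variants),
            "cells": self.cells,
            "summary": summary,
        }


def _images_by_id(dataset: list[AnnotatedImage]) -> dict[int, AnnotatedImage]:
    return {im.image_id: im for im in dataset}


def _evaluate_model(
    model: DenseDetector, images: list[AnnotatedImage]
) -> tuple[float, dict, dict]:
    dets = {im.image_id: infer(model, im.pixels) for im in images}
    gts = {im.image_id: im.annotations for im in images}
    report = evaluate_detections(dets, gts, model.config.num_classes)
    return report.map_50_95, report.to_dict(), dets


def run_label_fraction_study(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ResultsTable:
    """Run the full (variant, fraction, seed) x (supervised, semi) grid.

    The test set is fixed across all cells; test-set isolation is asserted
    on every run.  Failed cells are recorded with diagnostics and the
    study continues.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        for sub in ("data", "checkpoints", "detections", "tables"):
            (out / sub).mkdir(parents=True, exist_ok=True)

    dataset = generate_dataset(config.scene, config.n_images)
    by_id = _images_by_id(dataset)
    split = split_dataset(
        [im.image_id for im in dataset], config.split_ratios, config.split_seed
    )
    test_images = [by_id[i] for i in split.test_ids]
    val_images = [by_id[i] for i in split.val_ids]
    if out is not None:
        write_coco(dataset, out / "data" / "dataset.json",
                   class_names=config.scene.class_names)
        (out / "data" / "split.json").write_text(json.dumps({
            "train": list(split.train_ids),
            "val": list(split.val_ids),
            "test": list(split.test_ids),
        }))

    table = ResultsTable(config.fractions, config.seeds, config.variants)
    for variant in config.variants:
        det_config = config.detector_for(variant)
        for fraction in config.fractions:
            # the labeled/unlabeled partition belongs to the dataset split
            # (nested across fractions); seeds replicate the training runs
            part = subsample_labeled(
                split.train_ids, fraction, seed=config.split_seed
            )
            for seed in config.seeds:
                labeled = [by_id[i] for i in part.labeled_ids]
                unlabeled = [by_id[i] for i in part.unlabeled_ids]
                train_pool = set(part.labeled_ids) | set(part.unlabeled_ids)
                assert not (train_pool & set(split.test_ids)), "test leakage"
                for supervision in ("supervised", "semi"):
                    tag = f"{variant}_{supervision}_{fraction:g}pct_seed{seed}"
                    try:
                        if supervision == "supervised":
                            # same labeled batch size as the semi student's
                            # labeled half-batch: both arms see an identical
                            # labeled stream and differ only in unlabeled use
                            model = train_supervised(
                                labeled, config.schedule, det_config,
                                seed=seed,
                                batch_size=config.schedule.n_labeled,
                                val_images=val_images,
                            )
                        else:
                            model, _ = train_semi_supervised(
                                labeled, unlabeled, config.schedule,
                                det_config, seed=seed, val_images=val_images,
                            )
                        test_map, report, dets = _evaluate_model(model, test_images)
                        table.add(
                            variant, supervision, fraction, seed,
                            status="ok", map_50_95=test_map, report=report,
                            n_labeled=len(labeled), n_unlabeled=len(unlabeled),
                        )
                        if out is not None:
                            save_checkpoint(model, out / "checkpoints" / f"{tag}.npz")
                            (out / "detections" / f"{tag}.json").write_text(
                                json.dumps(detections_to_coco_results(dets))
                            )
                    except Exception as exc:  # study continues past failed cells
                        logger.exception("cell %s failed", tag)
                        table.add(
                            variant, supervision, fraction, seed,
                            status="failed", error=f"{type(exc).__name__}: {exc}",
                        )
    if out is not None:
        emit_tables(
            table,
            text_path=out / "tables" / "results.txt",
            json_path=out / "tables" / "results.json",
        )
    return table


def render_table_text(table: ResultsTable) -> str:
    """Plain-text rendering: rows (variant x supervision), columns label
    fractions, cells median test mAP@[0.5:0.95] on the 0-100 scale, plus a
    relative-performance row against supervised-100%."""
    d = table.to_dict()
    cols = [f"{f:g}%" for f in table.fractions]
    width = 12
    lines = []
    header = "Variant".ljust(16) + "Supervision".ljust(16) + "".join(
        c.rjust(width) for c in cols
    )
    lines.append(header)
    lines.append("-" * len(header))
    if not table.cells:
        lines.append("(no results)")
        return "\n".join(lines) + "\n"
    for variant in table.variants:
        for supervision in ("supervised", "semi"):
            row = variant.ljust(16) + supervision.ljust(16)
            rel_row = "".ljust(16) + "  % of sup-100".ljust(16)
            any_rel = False
            for fraction in table.fractions:
                entry = d["summary"][f"{variant}|{supervision}|{fraction:g}"]
                v = entry["median_map_50_95_pct"]
                row += (f"{v:.2f}" if v is not None else "—").rjust(width)
                r = entry.get("relative_to_sup100_pct")
                rel_row += (f"{r:.2f}" if r is not None else "—").rjust(width)
                any_rel = any_rel or r is not None
            lines.append(row)
            if supervision == "semi" and any_rel:
                lines.append(rel_row)
    return "\n".join(lines) + "\n"


def emit_tables(
    table: ResultsTable,
    text_path: str | Path,
    json_path: str | Path,
) -> None:
    """Write numerically identical plain-text and JSON renderings."""
    text = render_table_text(table)
    if not table.cells:
        logger.warning("emitting header-only table: no results")
    Path(text_path).write_text(text)
    Path(json_path).write_text(json.dumps(table.to_dict(), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# YAML config plumbing


def _tupled(seq):
    return tuple(seq) if seq is not None else None


def experiment_config_from_dict(raw: dict) -> ExperimentConfig:
    scene_raw = dict(raw.get("scene", {}))
    if "image_size" in scene_raw:
        scene_raw["image_size"] = tuple(scene_raw["image_size"])
    if scene_raw.get("class_weights") is not None:
        scene_raw["class_weights"] = tuple(scene_raw["class_weights"])
    if "object_scale_range" in scene_raw:
        scene_raw["object_scale_range"] = tuple(scene_raw["object_scale_range"])
    sched_raw = dict(raw.get("schedule", {}))
    if "weak_scale_range" in sched_raw:
        sched_raw["weak_scale_range"] = tuple(sched_raw["weak_scale_range"])
    det_raw = dict(raw.get("detector", {}))
    for key in ("anchor_sizes", "anchor_aspects"):
        if det_raw.get(key) is not None:
            det_raw[key] = tuple(det_raw[key])
    return ExperimentConfig(
        scene=SceneConfig(**scene_raw),
        n_images=raw.get("n_images", 300),
        variants=_tupled(raw.get("variants")) or ("anchor_free",),
        fractions=_tupled(raw.get("fractions")) or (5.0, 10.0, 20.0, 50.0, 100.0),
        seeds=_tupled(raw.get("seeds")) or (0, 1, 2),
        schedule=TrainSchedule(**sched_raw),
        detector=DetectorConfig(**det_raw),
        split_ratios=_tupled(raw.get("split_ratios")) or (0.65, 0.20, 0.15),
        split_seed=raw.get("split_seed", 0),
    )


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return experiment_config_from_dict(raw)
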