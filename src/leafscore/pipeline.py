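"""End-to-end scoring of one scan task.

Runs the full measurement chain on an ordered frame sequence:
channel correction → HSL conversion → band segmentation → frame
mosaicking (with boundary reconnection) → impurity removal → whole-leaf
extraction → per-leaf morphometrics → 29-trait aggregation.  Output is a
per-leaf table and a one-row per-plant table; both are deterministic for
fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .channels import ScanFrame, correct_channels
from .config import PipelineConfig, default_config
from .errors import InputError
from .morphometrics import LeafRecord, measure_leaf
from .mosaic import bridge_frame_boundaries, extract_leaves, stitch
from .segmentation import band_mask, class_areas, remove_impurities, rgb_to_hsl8
from .traits import TRAIT_NAMES, aggregate

__all__ = ["TaskManifest", "ScoreResult", "read_frames", "score_task"]

logger = logging.getLogger("leafscore")

PER_LEAF_COLUMNS = [
    "task_id", "leaf_id", "LL_mm", "LW_mm", "perimeter_mm", "area_mm2",
    "compactness", "area_g2_mm2", "area_g3_mm2", "area_g4_mm2",
    "area_yellow_mm2", "dominant_class",
]


@dataclass
class TaskManifest:
    """Frame files of one scan task, in acquisition order."""

    task_id: str
    frame_paths: list[Path]

    def __post_init__(self) -> None:
        self.frame_paths = [Path(p) for p in self.frame_paths]
        if not self.frame_paths:
            raise InputError(f"task {self.task_id!r} lists no frames")


@dataclass
class ScoreResult:
    per_leaf: pd.DataFrame
    per_plant: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    leaf_records: list[LeafRecord] = field(default_factory=list)
    leaf_objects: list = field(default_factory=list)  # LeafObject, canvas coords


def _load_frame(path: Path, index: int, task_id: str) -> ScanFrame:
    try:
        data = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read frame {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[-1] == 4:
        logger.warning("%s: dropping alpha channel", path)
        data = data[..., :3]
    if data.ndim != 3 or data.shape[-1] != 3:
        raise InputError(f"{path}: expected an RGB image, got shape {data.shape}")
    if data.dtype == np.uint16:
        logger.warning("%s: 16-bit input rescaled to 8-bit", path)
        data = (data.astype(np.uint32) * 255 // 65535).astype(np.uint8)
    elif data.dtype != np.uint8:
        raise InputError(f"{path}: unsupported dtype {data.dtype}")
    return ScanFrame(data, frame_index=index, task_id=task_id)


def read_frames(manifest: TaskManifest) -> list[ScanFrame]:
    """Load the manifest's frames, validating format and width agreement."""
    frames = [
        _load_frame(path, i, manifest.task_id)
        for i, path in enumerate(manifest.frame_paths)
    ]
    widths = {f.width for f in frames}
    if len(widths) != 1:
        raise InputError(
            f"task {manifest.task_id!r}: frame widths disagree: {sorted(widths)}"
        )
    return frames


def score_task(
    frames: list[ScanFrame] | TaskManifest,
    config: PipelineConfig | None = None,
) -> ScoreResult:
    """Score one task's frames into per-leaf and per-plant trait tables."""
    config = config or default_config()
    if isinstance(frames, TaskManifest):
        frames = read_frames(frames)
    if not frames:
        raise InputError("no frames to score")
    task_id = frames[0].task_id
    cal = config.calibration
    offsets = cal.channel_offsets
    frame_height = frames[0].height

    corrected = [
        correct_channels(f, offsets, fill=config.background_rgb) for f in frames
    ]
    canvas = stitch(corrected)
    hsl = rgb_to_hsl8(canvas)

    total = band_mask(hsl, config.bands.green) | band_mask(hsl, config.bands.yellow)
    n_raw = int(total.sum())
    total = remove_impurities(total, config.min_impurity_px)
    n_clean = int(total.sum())
    total = bridge_frame_boundaries(total, frame_height, max(offsets))
    cmasks = class_areas(total, hsl, config.bands)

    leaves = extract_leaves(total, cmasks, config.min_leaf_px)
    records = [
        measure_leaf(
            obj.full_mask(total.shape), cal, obj.class_pixel_counts, leaf_id=i + 1
        )
        for i, obj in enumerate(leaves)
    ]

    diagnostics = {
        "n_frames": len(frames),
        "impurity_px_removed": n_raw - n_clean,
        "n_leaves": len(records),
    }
    logger.info("task %s: %s", task_id, diagnostics)

    per_leaf = pd.DataFrame(
        [
            {
                "task_id": task_id,
                "leaf_id": r.leaf_id,
                "LL_mm": r.length_mm,
                "LW_mm": r.width_mm,
                "perimeter_mm": r.perimeter_mm,
                "area_mm2": r.area_mm2,
                "compactness": r.compactness,
                "area_g2_mm2": r.class_areas_mm2.get("green-2", 0.0),
                "area_g3_mm2": r.class_areas_mm2.get("green-3", 0.0),
                "area_g4_mm2": r.class_areas_mm2.get("green-4", 0.0),
                "area_yellow_mm2": r.class_areas_mm2.get("yellow", 0.0),
                "dominant_class": r.dominant_class,
            }
            for r in records
        ],
        columns=PER_LEAF_COLUMNS,
    )

    if records:
        trait_values = aggregate(records).to_dict()
    else:
        logger.warning("task %s: no leaves found", task_id)
        trait_values = {name: float("nan") for name in TRAIT_NAMES}
        trait_values["LN"] = 0
    per_plant = pd.DataFrame([{"task_id": task_id, **trait_values}])

    return ScoreResult(
        per_leaf=per_leaf,
        per_plant=per_plant,
        diagnostics=diagnostics,
        leaf_records=records,
        leaf_objects=leaves,
    )
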