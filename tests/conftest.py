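"""Shared fixtures: configuration and pre-scored synthetic tasks.

The heavy end-to-end artefacts (rendered + scored tasks) are session-scoped
so that pipeline, trait and acceptance tests share one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from leafscore.config import PipelineConfig, default_config
from leafscore.pipeline import ScoreResult, score_task
from leafscore.synthetic import (
    RenderedScan,
    SyntheticTask,
    distort_channels,
    match_leaves_to_truth,
    render_scan,
    sample_plant,
    split_frames,
)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return default_config()


@dataclass
class ScoredTask:
    """A synthetic task pushed through the full acquisition + scoring chain."""

    task: SyntheticTask
    scan: RenderedScan
    result: ScoreResult
    truth_ids: list[int]  # truth leaf id per per-leaf output row


def run_full_chain(task: SyntheticTask, cfg: PipelineConfig) -> ScoredTask:
    """Render, distort, frame-split and score a task; map leaves to truth."""
    cal = cfg.calibration
    scan = render_scan(task, cal)
    rgb = distort_channels(scan.rgb, cal.channel_offsets)
    frames = split_frames(rgb, task.frame_height_px, task_id=task.plant_id)
    result = score_task(frames, cfg)
    truth_ids = match_leaves_to_truth(result.leaf_objects, scan.leaf_labels)
    return ScoredTask(task=task, scan=scan, result=result, truth_ids=truth_ids)


@pytest.fixture(scope="session")
def scored_rectangles(cfg) -> ScoredTask:
    """Ten rectangle-only leaves, mixed classes, spanning a frame boundary."""
    task = sample_plant(
        10, seed=11, shapes=("rectangle",), frame_height_px=1200, dust_density=0.0
    )
    return run_full_chain(task, cfg)


@pytest.fixture(scope="session")
def scored_mixed(cfg) -> ScoredTask:
    """Twelve leaves of all three shapes and all four colour classes."""
    task = sample_plant(12, seed=3, frame_height_px=1500, dust_density=5.0)
    return run_full_chain(task, cfg)
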