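"""Scaled-down end-to-end benchmark: simulate, train, track, evaluate.

One seeded function reproduces the whole experiment at desk scale:
a 30/10/10 synthetic split on downscaled 360x270 frames, short training
of the Siamese tracker, one-pass tracking of the 10 test sequences from a
30x30 frame-0 box, and the full metric suite.  Used by both the test
suite and the acceptance report.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np

from .metrics import UnitCalibration, aggregate, evaluate_sequence
from .siamfc import BackboneConfig, PatchSpec, TrainConfig, track_sequence, train
from .synthetic import SceneParams, TrajectoryParams, generate_sequence
from .trace import GroundTruthTrack

logger = logging.getLogger("hyotrack.benchmark")

__all__ = ["benchmark_scene", "make_split", "run_benchmark"]


def benchmark_scene() -> SceneParams:
    """Half-resolution scene (360x270 px, 0.65 mm/px) for CPU-scale runs."""
    return SceneParams(
        frame_width=360,
        frame_height=270,
        mm_per_px=0.65,
        echo_radii=(7.0, 4.0),
        shadow_width=14.0,
        muscle_line_geometry=((-80.0, 30.0), (-4.0, 2.0)),
    )


def make_split(
    seed: int,
    scene: SceneParams | None = None,
    n_train: int = 30,
    n_val: int = 10,
    n_test: int = 10,
    traj_template: TrajectoryParams | None = None,
) -> dict:
    """Seeded in-memory 30/10/10 split of lazily rendered sequences."""
    scene = scene or benchmark_scene()
    template = traj_template or TrajectoryParams()
    template = dataclasses.replace(template, mm_per_px=scene.mm_per_px)
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    seq_seeds = np.random.SeedSequence(seed).generate_state(len(splits)).tolist()
    out: dict = {"train": [], "val": [], "test": []}
    for i, (split, sseed) in enumerate(zip(splits, seq_seeds)):
        traj = dataclasses.replace(template, seed=int(sseed)).resolve(scene)
        seq = generate_sequence(traj, scene)
        seq.sequence_id = f"seq_{i:03d}"
        out[split].append(seq)
    return out


def run_benchmark(
    seed: int,
    pairs_per_epoch: int = 256,
    epochs: int = 6,
    channels: tuple = (16, 32, 32, 32, 24),
    scene: SceneParams | None = None,
    init_box_side: float = 30.0,
    train_search_size: int = 191,
    n_track_scales: int = 1,
    progress: bool = False,
) -> dict:
    """Run the full scaled-down experiment; returns metrics and the summary.

    The tracker is trained on the 30-sequence train split and evaluated
    with one-pass evaluation on the 10 test sequences, initialized from a
    30x30 box centered on each sequence's frame-0 ground-truth point.
    Ground truth beyond frame 0 is never shown to the tracker.

    CPU-scale economies (vs. the package defaults): training search patches
    of 191 px instead of 255, and a single-scale search at track time --
    the synthetic target has a fixed physical size, so the scale pyramid
    only adds cost here.  Both remain configurable.
    """
    t0 = time.perf_counter()
    scene = scene or benchmark_scene()
    split = make_split(seed, scene)
    logger.info("generated split in %.1fs", time.perf_counter() - t0)

    config = TrainConfig(
        pairs_per_epoch=pairs_per_epoch,
        epochs=epochs,
        lr_start=1e-2,
        lr_end=1e-3,
        seed=seed,
    )
    train_spec = PatchSpec(search_size=train_search_size)
    spec = PatchSpec(n_scales=n_track_scales)
    t1 = time.perf_counter()
    backbone, head, history = train(
        {"train": split["train"], "val": split["val"]},
        config,
        backbone_config=BackboneConfig(channels=channels, seed=seed),
        spec=train_spec,
        progress=progress,
    )
    logger.info("trained %d epochs in %.1fs", epochs, time.perf_counter() - t1)

    calibration = UnitCalibration(scene.mm_per_px)
    reports = []
    for seq in split["test"]:
        t2 = time.perf_counter()
        cx, cy = seq.gt_points[0]
        trace = track_sequence(
            seq.frames, (cx, cy, init_box_side, init_box_side), backbone, spec
        )
        trace.sequence_id = seq.sequence_id
        gt = GroundTruthTrack(seq.gt_points, seq.events)
        report = evaluate_sequence(trace, gt, calibration)
        reports.append(report)
        logger.info(
            "tracked %s (%d frames) in %.1fs: rmse=%.2f px, p@10=%.3f",
            seq.sequence_id, len(seq.frames), time.perf_counter() - t2,
            report.rmse, report.precision_at_10,
        )

    summary = aggregate(reports)
    return {
        "seed": seed,
        "precision_at_10_pct": 100.0 * summary["precision_at_10"]["mean"],
        "precision_at_5_pct": 100.0 * summary["precision_at_5"]["mean"],
        "rmse_px": summary["rmse"]["mean"],
        "ae_px": summary["ae"]["mean"],
        "pearson_x": summary["pearson_x"]["mean"],
        "pearson_y": summary["pearson_y"]["mean"],
        "summary": summary,
        "history": history,
        "elapsed_s": time.perf_counter() - t0,
        "n_test_sequences": len(reports),
        "n_test_frames": int(sum(r.n_frames for r in reports)),
    }
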