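"""Online Siamese tracking: fixed first-frame template, per-frame search.

The exemplar embedding is computed once from the initialization box and
never updated; each subsequent frame is searched with a small scale
pyramid of crops centered on the previous estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..trace import Trace
from .model import Backbone, _prepare_patch
from .ops import (
    PatchSpec,
    ScoreMap,
    cosine_window,
    crop_patch,
    cross_correlate,
    displacement_to_image,
    exemplar_side,
    select_peak,
)

__all__ = ["TrackerState", "track_sequence"]


@dataclass
class TrackerState:
    """Mutable per-frame tracker state."""

    center: tuple[float, float]
    box_size: tuple[float, float] = (30.0, 30.0)
    scale_state: float = 1.0

    def __post_init__(self) -> None:
        if min(self.box_size) <= 0:
            raise ValueError("box_size must be positive")


def _embed_batch(patches: np.ndarray, backbone: Backbone) -> np.ndarray:
    """(N, H, W) grayscale patches -> (N, F, h, w) eval-mode embeddings.

    Processed one patch at a time: on a single core the smaller working set
    is markedly faster than a batched pass.
    """
    outs = [
        backbone.forward(_prepare_patch(p, backbone.config.in_channels), train=False)
        for p in patches
    ]
    return np.concatenate(outs)


def track_sequence(
    frames,
    init_box: tuple[float, float, float, float],
    backbone: Backbone,
    spec: PatchSpec | None = None,
) -> Trace:
    """Track one sequence; returns one predicted center per frame.

    ``init_box`` is (cx, cy, w, h).  Frame 0's output is the init center
    exactly; the exemplar embedding is computed once from frame 0.
    Predicted centers are clamped to frame bounds.
    """
    spec = spec or PatchSpec()
    n_frames = len(frames)
    if n_frames == 0:
        raise ValueError("empty frame list")
    cx, cy, bw, bh = init_box
    frame0 = np.asarray(frames[0])
    h, w = frame0.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"init box center {(cx, cy)} outside first frame")

    state = TrackerState(center=(float(cx), float(cy)), box_size=(float(bw), float(bh)))
    s_z = exemplar_side(bw, bh, spec)
    s_x = s_z * spec.search_size / spec.exemplar_size

    ex_patch = crop_patch(frame0, state.center, s_z, spec.exemplar_size)
    ex_feat = _embed_batch(ex_patch[None], backbone)[0]

    raw_side = (
        backbone.output_size(spec.search_size)
        - backbone.output_size(spec.exemplar_size)
        + 1
    )
    up_side = raw_side * spec.upsample_factor
    window = cosine_window(up_side)
    grid_center = ((up_side - 1) / 2.0, (up_side - 1) / 2.0)
    scale_mults = spec.scale_step ** (
        np.arange(spec.n_scales) - spec.n_scales // 2
    )

    centers = np.empty((n_frames, 2), dtype=np.float64)
    centers[0] = state.center
    for t in range(1, n_frames):
        frame = np.asarray(frames[t])
        sides = s_x * state.scale_state * scale_mults
        patches = np.stack(
            [crop_patch(frame, state.center, side, spec.search_size) for side in sides]
        )
        feats = _embed_batch(patches, backbone)
        maps = [
            ScoreMap.from_raw(cross_correlate(ex_feat, feats[k]), spec.upsample_factor)
            for k in range(spec.n_scales)
        ]
        peak, k = select_peak(
            [m.upsampled_grid for m in maps], window, spec.window_weight,
            spec.scale_penalty,
        )
        maps[k].peak, maps[k].peak_scale_index = peak, k
        search_scale = sides[k] / spec.search_size
        dx, dy = displacement_to_image(
            peak, grid_center, backbone.total_stride, spec.upsample_factor, search_scale
        )
        nx = min(max(state.center[0] + dx, 0.0), w - 1.0)
        ny = min(max(state.center[1] + dy, 0.0), h - 1.0)
        state.center = (nx, ny)
        state.scale_state *= (1.0 - spec.scale_damping) + spec.scale_damping * scale_mults[k]
        state.scale_state = float(np.clip(state.scale_state, 0.2, 5.0))
        centers[t] = state.center
    return Trace(centers)
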