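"""Patch cropping, cross-correlation and score-map geometry.

These are the stateless building blocks of the Siamese tracking loop:
crop a context-padded square around the target, correlate embedded
exemplar/search grids, upsample the score map bicubically, select the
penalized/windowed peak, and convert the peak offset back to an image
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import ndimage

__all__ = [
    "PatchSpec",
    "ScoreMap",
    "crop_patch",
    "cross_correlate",
    "upsample_score",
    "select_peak",
    "displacement_to_image",
    "cosine_window",
    "exemplar_side",
]


@dataclass(frozen=True)
class PatchSpec:
    """Crop geometry and scale-pyramid settings for Siamese tracking."""

    exemplar_size: int = 127
    search_size: int = 255
    context_factor: float = 0.5  # margin = context_factor * (w + h)
    n_scales: int = 3
    scale_step: float = 1.025
    scale_penalty: float = 0.9745
    scale_damping: float = 0.59
    window_weight: float = 0.176
    upsample_factor: int = 16

    def __post_init__(self) -> None:
        if self.exemplar_size >= self.search_size:
            raise ValueError("exemplar_size must be smaller than search_size")
        if self.n_scales % 2 != 1:
            raise ValueError("n_scales must be odd")
        if self.scale_step <= 1.0:
            raise ValueError("scale_step must exceed 1")


@dataclass
class ScoreMap:
    """Similarity grid for one scale: raw, upsampled, and its peak.

    ``peak``/``peak_scale_index`` are filled once the winning peak has been
    selected across scales.
    """

    raw_grid: np.ndarray
    upsampled_grid: np.ndarray
    upsample_factor: int
    peak: tuple[int, int] | None = None
    peak_scale_index: int | None = None

    @classmethod
    def from_raw(cls, raw_grid: np.ndarray, upsample_factor: int) -> "ScoreMap":
        return cls(
            raw_grid=np.asarray(raw_grid),
            upsampled_grid=upsample_score(raw_grid, upsample_factor),
            upsample_factor=upsample_factor,
        )


def exemplar_side(box_w: float, box_h: float, spec: PatchSpec) -> float:
    """Context-padded square crop side for a target box."""
    margin = spec.context_factor * (box_w + box_h)
    return float(np.sqrt((box_w + margin) * (box_h + margin)))


def crop_patch(
    image: np.ndarray,
    center: tuple[float, float],
    crop_side: float,
    out_size: int,
    fill: float | None = None,
) -> np.ndarray:
    """Crop a square of side *crop_side* centered at *center* (x, y), resampled
    to ``out_size x out_size`` with bilinear interpolation.

    Out-of-frame regions are filled with the image mean intensity (or
    *fill*).  Sub-pixel centers are honored.
    """
    cx, cy = center
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise ValueError(f"non-finite crop center {center}")
    if crop_side <= 0:
        raise ValueError("crop_side must be positive")
    img = np.asarray(image, dtype=np.float32)
    cval = float(img.mean()) if fill is None else float(fill)
    step = crop_side / out_size
    # sample at the centers of out_size bins spanning [c - side/2, c + side/2]
    offs = (np.arange(out_size, dtype=np.float64) + 0.5) * step - crop_side / 2.0
    xs = cx + offs
    ys = cy + offs
    coords = np.stack(
        [np.broadcast_to(ys[:, None], (out_size, out_size)),
         np.broadcast_to(xs[None, :], (out_size, out_size))]
    )
    return ndimage.map_coordinates(
        img, coords, order=1, mode="constant", cval=cval
    ).astype(np.float32)


def cross_correlate(exemplar_feat: np.ndarray, search_feat: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation summed over channels.

    ``exemplar_feat``: (C, h, w), ``search_feat``: (C, H, W) with
    ``h <= H`` and ``w <= W``.  Returns an ``(H-h+1, W-w+1)`` score grid.
    """
    ex = np.asarray(exemplar_feat)
    se = np.asarray(search_feat)
    if ex.ndim != 3 or se.ndim != 3 or ex.shape[0] != se.shape[0]:
        raise ValueError("feature grids must be (C, H, W) with equal channels")
    c, h, w = ex.shape
    _, hh, ww = se.shape
    if h > hh or w > ww:
        raise ValueError("exemplar grid larger than search grid")
    ho, wo = hh - h + 1, ww - w + 1
    sc, sh, sw = se.strides
    win = as_strided(
        se, shape=(ho, wo, c, h, w), strides=(sh, sw, sc, sh, sw)
    ).reshape(ho * wo, c * h * w)
    return (win @ ex.reshape(-1)).reshape(ho, wo)


def upsample_score(raw_grid: np.ndarray, factor: int) -> np.ndarray:
    """Bicubic upsampling of a score grid by an integer factor."""
    if int(factor) != factor or factor < 1:
        raise ValueError("upsample factor must be an integer >= 1")
    grid = np.asarray(raw_grid, dtype=np.float64)
    if factor == 1:
        return grid.copy()
    return ndimage.zoom(grid, factor, order=3, mode="nearest", grid_mode=True)


def cosine_window(size: int) -> np.ndarray:
    """Outer-product Hann window normalized to unit sum."""
    hann = np.hanning(size + 2)[1:-1]
    win = np.outer(hann, hann)
    return win / win.sum()


def _normalize_response(grid: np.ndarray) -> np.ndarray:
    g = grid - grid.min()
    s = g.sum()
    if s > 0:
        g = g / s
    return g


def select_peak(
    grids: list[np.ndarray],
    window: np.ndarray | None = None,
    window_weight: float = 0.0,
    scale_penalty: float = 1.0,
) -> tuple[tuple[int, int], int]:
    """Pick the global peak across per-scale score grids.

    Each grid is min-shifted and sum-normalized, non-central scales are
    multiplied by *scale_penalty*, and the result is blended with the
    cosine *window* by *window_weight*.  Returns ``((row, col), scale_idx)``
    with ties broken by the smallest (scale, row, col) lexicographically.
    """
    if not grids:
        raise ValueError("no score grids given")
    center_scale = len(grids) // 2
    best_val = -np.inf
    best: tuple[tuple[int, int], int] | None = None
    for k, grid in enumerate(grids):
        g = _normalize_response(np.asarray(grid, dtype=np.float64))
        if k != center_scale:
            g = g * scale_penalty
        if window is not None and window_weight > 0:
            g = (1.0 - window_weight) * g + window_weight * window
        flat_idx = int(np.argmax(g))  # first occurrence: (row, col) lexicographic
        val = g.flat[flat_idx]
        if val > best_val:  # strict: keeps smallest scale index on ties
            best_val = val
            best = (np.unravel_index(flat_idx, g.shape), k)
    peak, k = best
    return (int(peak[0]), int(peak[1])), k


def displacement_to_image(
    peak: tuple[int, int],
    grid_center: tuple[float, float],
    total_stride: int,
    upsample_factor: int,
    search_scale: float,
) -> tuple[float, float]:
    """Convert a score-map peak into an image-plane displacement (dx, dy).

    *peak* and *grid_center* are (row, col) on the upsampled grid;
    *search_scale* is image pixels per search-patch pixel.
    """
    dr = (peak[0] - grid_center[0]) * total_stride / upsample_factor * search_scale
    dc = (peak[1] - grid_center[1]) * total_stride / upsample_factor * search_scale
    return (float(dc), float(dr))
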