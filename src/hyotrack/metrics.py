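"""Kinematic evaluation of hyoid traces against ground truth.

Per-frame center error, one-pass-evaluation precision at distance
thresholds, RMSE and average error, per-axis Pearson correlation, range
of motion between hyoid onset and offset, and its relative error, with
per-sequence reports and equal-weight aggregation across sequences.
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .trace import GroundTruthTrack, Trace

__all__ = [
    "UnitCalibration",
    "EvalReport",
    "center_error",
    "precision_at",
    "precision_curve",
    "rmse",
    "ae",
    "pearson_axis",
    "rom",
    "rom_relative_error",
    "convert_px_mm",
    "round_mm_display",
    "evaluate_sequence",
    "aggregate",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = np.arange(1.0, 51.0)


@dataclass(frozen=True)
class UnitCalibration:
    """Pixel <-> millimetre conversion for the imaging geometry."""

    mm_per_px: float = 0.325
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.px_per_mm is None:
            object.__setattr__(self, "px_per_mm", 1.0 / self.mm_per_px)
        if abs(self.mm_per_px * self.px_per_mm - 1.0) > 1e-3:
            raise ValueError("mm_per_px and px_per_mm are not reciprocal within 0.1%")

    @classmethod
    def from_px_per_mm(cls, px_per_mm: float) -> "UnitCalibration":
        """Build from the pixels-per-mm calibration via the reciprocal invariant."""
        return cls(mm_per_px=1.0 / px_per_mm, px_per_mm=px_per_mm)


def _points(track) -> np.ndarray:
    if isinstance(track, (Trace, GroundTruthTrack)):
        return track.points
    return np.asarray(track, dtype=np.float64).reshape(-1, 2)


def center_error(trace, gt) -> np.ndarray:
    """Per-frame Euclidean distance between predicted and annotated centers."""
    p = _points(trace)
    g = _points(gt)
    if len(p) != len(g):
        raise ValueError(f"length mismatch: trace {len(p)} vs gt {len(g)}")
    return np.hypot(p[:, 0] - g[:, 0], p[:, 1] - g[:, 1])


def precision_at(delta: np.ndarray, threshold: float) -> float:
    """Fraction of frames with center error <= threshold (inclusive)."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.size == 0:
        raise ValueError("empty center-error series")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.mean(delta <= threshold))


def precision_curve(delta: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """(threshold, precision) pairs over ascending thresholds (OPE)."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    vals = np.array([precision_at(delta, t) for t in thresholds])
    return np.column_stack([thresholds, vals])


def rmse(delta: np.ndarray) -> float:
    """Root-mean-square of the center-error series."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.size == 0:
        raise ValueError("empty center-error series")
    return float(np.sqrt(np.mean(delta**2)))


def ae(delta: np.ndarray) -> float:
    """Arithmetic mean of the center-error series."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.size == 0:
        raise ValueError("empty center-error series")
    return float(np.mean(delta))


def pearson_axis(trace, gt, axis: str) -> float:
    """Pearson r between predicted and annotated coordinates on one axis.

    Returns NaN (with a warning) when either series has zero variance.
    """
    col = {"x": 0, "y": 1}[axis]
    p = _points(trace)[:, col]
    g = _points(gt)[:, col]
    if len(p) != len(g):
        raise ValueError("length mismatch")
    if len(p) < 2:
        raise ValueError("need at least 2 frames")
    if np.ptp(p) == 0 or np.ptp(g) == 0:
        warnings.warn(f"zero variance on axis {axis}; Pearson r undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(p, g).statistic)


def rom(track, onset: int, offset: int) -> tuple[float, float, float]:
    """Range of motion between *onset* and *offset* (inclusive), in pixels.

    Relative to the onset point: per-axis maxima of |x - x_onset| and
    |y - y_onset| (possibly attained at different frames) and the maximum
    straight-line distance.
    """
    pts = _points(track)
    if not (0 <= onset < offset < len(pts)):
        raise ValueError(f"invalid event frames onset={onset} offset={offset}")
    seg = pts[onset : offset + 1] - pts[onset]
    rom_x = float(np.max(np.abs(seg[:, 0])))
    rom_y = float(np.max(np.abs(seg[:, 1])))
    rom_line = float(np.max(np.hypot(seg[:, 0], seg[:, 1])))
    return rom_x, rom_y, rom_line


def rom_relative_error(rom_gt: float, rom_pred: float) -> float:
    """``|rom_gt - rom_pred| / rom_gt * 100`` (percent).

    Returns NaN with a warning for zero ground-truth ROM.
    """
    if rom_gt == 0:
        warnings.warn("zero ground-truth ROM; relative error undefined",
                      stacklevel=2)
        return float("nan")
    return float(abs(rom_gt - rom_pred) / rom_gt * 100.0)


def convert_px_mm(value, calibration: UnitCalibration, direction: str):
    """Convert between pixels and millimetres.

    *direction* is ``"px_to_mm"`` or ``"mm_to_px"``.
    """
    if direction == "px_to_mm":
        return value * calibration.mm_per_px
    if direction == "mm_to_px":
        return value / calibration.mm_per_px
    raise ValueError(f"unknown direction {direction!r}")


def round_mm_display(value: float, decimals: int = 2) -> float:
    """Round half away from zero, as used for printed mm values."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class EvalReport:
    """All per-sequence evaluation metrics."""

    sequence_id: str
    n_frames: int
    ce_series: np.ndarray
    precision_curve: np.ndarray  # (n_thresholds, 2)
    precision_at_5: float
    precision_at_10: float
    rmse: float
    ae: float
    pearson_x: float
    pearson_y: float
    rom_gt: tuple[float, float, float]  # (x, y, line) px
    rom_pred: tuple[float, float, float]
    rel_rom_x: float
    rel_rom_y: float
    rel_rom_line: float
    mm_per_px: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ce_series"] = np.asarray(self.ce_series).tolist()
        d["precision_curve"] = np.asarray(self.precision_curve).tolist()
        d["rmse_mm"] = round_mm_display(self.rmse * self.mm_per_px)
        d["ae_mm"] = round_mm_display(self.ae * self.mm_per_px)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def evaluate_sequence(
    trace: Trace,
    gt: GroundTruthTrack,
    calibration: UnitCalibration | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Compute the full metric suite for one sequence."""
    calibration = calibration or UnitCalibration()
    delta = center_error(trace, gt)
    curve = precision_curve(delta, thresholds)
    onset = gt.events["hyoid_onset"]
    offset = gt.events["hyoid_offset"]
    rom_gt = rom(gt, onset, offset)
    rom_pred = rom(trace, onset, offset)
    return EvalReport(
        sequence_id=trace.sequence_id,
        n_frames=len(delta),
        ce_series=delta,
        precision_curve=curve,
        precision_at_5=precision_at(delta, 5.0),
        precision_at_10=precision_at(delta, 10.0),
        rmse=rmse(delta),
        ae=ae(delta),
        pearson_x=pearson_axis(trace, gt, "x"),
        pearson_y=pearson_axis(trace, gt, "y"),
        rom_gt=rom_gt,
        rom_pred=rom_pred,
        rel_rom_x=rom_relative_error(rom_gt[0], rom_pred[0]),
        rel_rom_y=rom_relative_error(rom_gt[1], rom_pred[1]),
        rel_rom_line=rom_relative_error(rom_gt[2], rom_pred[2]),
        mm_per_px=calibration.mm_per_px,
    )


_AGG_FIELDS = (
    "precision_at_5",
    "precision_at_10",
    "rmse",
    "ae",
    "pearson_x",
    "pearson_y",
    "rel_rom_x",
    "rel_rom_y",
    "rel_rom_line",
)


def aggregate(reports: list[EvalReport], pool_frames: bool = False) -> dict:
    """Mean and sample SD of each metric across sequences.

    Each sequence is weighted equally; precision curves are averaged
    pointwise.  With ``pool_frames=True``, precision/RMSE/AE are instead
    recomputed over the pooled per-frame errors of all sequences.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict = {"n_sequences": len(reports)}
    if len(reports) == 1:
        out["sd_note"] = "single sequence: SD reported as 0 by convention"
    for name in _AGG_FIELDS:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[name] = {"mean": float("nan"), "sd": float("nan")}
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[name] = {"mean": float(np.mean(vals)), "sd": sd}
    curves = np.stack([np.asarray(r.precision_curve) for r in reports])
    out["precision_curve"] = np.column_stack(
        [curves[0, :, 0], curves[:, :, 1].mean(axis=0)]
    ).tolist()
    if pool_frames:
        pooled = np.concatenate([np.asarray(r.ce_series) for r in reports])
        out["pooled"] = {
            "precision_at_5": precision_at(pooled, 5.0),
            "precision_at_10": precision_at(pooled, 10.0),
            "rmse": rmse(pooled),
            "ae": ae(pooled),
        }
    return out
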