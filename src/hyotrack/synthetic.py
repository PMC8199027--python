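"""Seeded synthetic ultrasound swallowing-video generator.

Produces grayscale B-mode-like image sequences with exact per-frame
ground-truth hyoid positions and swallow event timestamps.  The hyoid is
rendered as a bright elliptical echo with a dark acoustic shadow extending
toward the top of the image, on top of a multiplicative Rayleigh speckle
background, with an oblique bright muscle line terminating near the
annotation point.

Coordinate convention: origin at the top-left pixel center, x rightward,
y downward, 0-based.  Elevation moves the hyoid in -x, anterior movement
in +y.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Sequence as _SequenceABC
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneParams",
    "TrajectoryParams",
    "SyntheticSequence",
    "generate_trajectory",
    "render_frame",
    "generate_sequence",
    "inject_double_shadow",
    "write_dataset",
]

#: frames kept after the end of the swallow when sequence length allows
TAIL_FRAMES = 50


@dataclass(frozen=True)
class SceneParams:
    """Geometry and appearance of one synthetic ultrasound scene."""

    frame_width: int = 720
    frame_height: int = 540
    mm_per_px: float = 0.325
    fps: float = 32.0
    speckle_scale: float = 0.35
    background_level: float = 55.0
    echo_intensity: float = 150.0
    echo_radii: tuple[float, float] = (9.0, 5.0)  # (rx, ry) semi-axes, px
    shadow_width: float = 22.0
    shadow_attenuation: float = 0.45
    # muscle-line endpoints, px offsets relative to the hyoid point
    muscle_line_geometry: tuple[tuple[float, float], tuple[float, float]] = (
        (-150.0, 55.0),
        (-6.0, 3.0),
    )
    muscle_line_intensity: float = 60.0
    muscle_line_thickness: float = 2.5
    speckle_smooth_sigma: float = 1.1

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        # 1.0 is allowed as the degenerate "no shadow" limit
        if not (0.0 <= self.shadow_attenuation <= 1.0):
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        if min(self.echo_radii) <= 0:
            raise ValueError("echo_radii must be positive")


@dataclass(frozen=True)
class TrajectoryParams:
    """Three-phase hyoid trajectory parameters.

    Fields left as ``None`` are drawn from the seed when the trajectory is
    resolved (see :meth:`resolve`), so that phase durations and ranges of
    motion vary across sequences in a dataset.
    """

    n_frames: int | None = None  # drawn uniformly from [330, 430]
    rest_point: tuple[float, float] | None = None
    onset_frame: int | None = None
    elevation_frames: int | None = None
    anterior_frames: int | None = None
    return_frames: int | None = None
    rom_x_mm: float | None = None  # drawn from [13, 17]
    rom_y_mm: float | None = None  # drawn from [13, 17]
    jitter_sd: float = 0.3
    mm_per_px: float = 0.325
    seed: int = 0

    def resolve(self, scene: SceneParams | None = None) -> "TrajectoryParams":
        """Fill unset fields with seeded draws; returns a fully concrete copy."""
        rng = np.random.default_rng([int(self.seed), 0x7261])
        n_frames = self.n_frames
        if n_frames is None:
            n_frames = int(rng.integers(330, 431))
        rest = self.rest_point
        if rest is None:
            w = scene.frame_width if scene is not None else 720
            h = scene.frame_height if scene is not None else 540
            rest = (
                0.55 * w + float(rng.uniform(-0.03, 0.03)) * w,
                0.45 * h + float(rng.uniform(-0.03, 0.03)) * h,
            )
        elev = self.elevation_frames
        if elev is None:
            elev = int(rng.integers(12, 26))
        ant = self.anterior_frames
        if ant is None:
            ant = int(rng.integers(12, 26))
        ret = self.return_frames
        if ret is None:
            ret = int(rng.integers(25, 46))
        onset = self.onset_frame
        if onset is None:
            latest = n_frames - elev - ant - ret - TAIL_FRAMES - 1
            onset = int(rng.integers(30, max(31, min(81, latest + 1))))
        rom_x = self.rom_x_mm
        if rom_x is None:
            rom_x = float(rng.uniform(13.0, 17.0))
        rom_y = self.rom_y_mm
        if rom_y is None:
            rom_y = float(rng.uniform(13.0, 17.0))
        out = dataclasses.replace(
            self,
            n_frames=n_frames,
            rest_point=rest,
            onset_frame=onset,
            elevation_frames=elev,
            anterior_frames=ant,
            return_frames=ret,
            rom_x_mm=rom_x,
            rom_y_mm=rom_y,
        )
        out.validate()
        return out

    def validate(self) -> None:
        if None in (
            self.n_frames,
            self.rest_point,
            self.onset_frame,
            self.elevation_frames,
            self.anterior_frames,
            self.return_frames,
            self.rom_x_mm,
            self.rom_y_mm,
        ):
            raise ValueError("trajectory has unresolved fields; call resolve()")
        total = (
            self.onset_frame
            + self.elevation_frames
            + self.anterior_frames
            + self.return_frames
        )
        if total >= self.n_frames:
            raise ValueError(
                f"phase lengths ({total} frames from onset through return) "
                f"exceed n_frames={self.n_frames}"
            )
        if self.rom_x_mm < 0 or self.rom_y_mm < 0:
            raise ValueError("rom values must be non-negative")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def _ease(t: np.ndarray) -> np.ndarray:
    """Cosine ease-in/ease-out on [0, 1] -> [0, 1], monotone."""
    return 0.5 * (1.0 - np.cos(np.pi * t))


def generate_trajectory(params: TrajectoryParams) -> np.ndarray:
    """Per-frame ground-truth hyoid points for a three-phase swallow.

    Phases: rest, elevation (-x by rom_x), anterior (+y by rom_y), return
    to the rest point, then rest until the end of the sequence.  Gaussian
    positional jitter (clipped at 3 sd) is added to every frame.

    Returns an array of shape ``(n_frames, 2)`` of (x, y) pixel points.
    Deterministic given ``params`` (including its seed).
    """
    p = params if params.n_frames is not None else params.resolve()
    p.validate()
    n = p.n_frames
    x0, y0 = p.rest_point
    rom_x_px = p.rom_x_mm / p.mm_per_px
    rom_y_px = p.rom_y_mm / p.mm_per_px

    onset = p.onset_frame
    t_elev_end = onset + p.elevation_frames
    t_ant_end = t_elev_end + p.anterior_frames  # hyoid offset event
    t_ret_end = t_ant_end + p.return_frames  # swallow end event

    pts = np.empty((n, 2), dtype=np.float64)
    pts[:, 0] = x0
    pts[:, 1] = y0

    idx = np.arange(onset, t_elev_end + 1)
    prog = _ease((idx - onset) / p.elevation_frames)
    pts[idx, 0] = x0 - rom_x_px * prog

    idx = np.arange(t_elev_end, t_ant_end + 1)
    prog = _ease((idx - t_elev_end) / p.anterior_frames)
    pts[idx, 0] = x0 - rom_x_px
    pts[idx, 1] = y0 + rom_y_px * prog

    idx = np.arange(t_ant_end, min(t_ret_end + 1, n))
    prog = _ease((idx - t_ant_end) / p.return_frames)
    pts[idx, 0] = x0 - rom_x_px * (1.0 - prog)
    pts[idx, 1] = y0 + rom_y_px * (1.0 - prog)

    if p.jitter_sd > 0:
        rng = np.random.default_rng([int(p.seed), 0x6A69])
        jitter = rng.normal(0.0, p.jitter_sd, size=(n, 2))
        np.clip(jitter, -3.0 * p.jitter_sd, 3.0 * p.jitter_sd, out=jitter)
        pts += jitter
    return pts


def _paint_echo(img: np.ndarray, point: tuple[float, float], scene: SceneParams) -> None:
    """Add a bright Gaussian-profile ellipse centered on *point* (in place)."""
    px, py = point
    rx, ry = scene.echo_radii
    h, w = img.shape
    x0 = max(0, int(np.floor(px - 4 * rx)))
    x1 = min(w, int(np.ceil(px + 4 * rx)) + 1)
    y0 = max(0, int(np.floor(py - 4 * ry)))
    y1 = min(h, int(np.ceil(py + 4 * ry)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float64)
    ys = np.arange(y0, y1, dtype=np.float64)
    r2 = ((xs[None, :] - px) / rx) ** 2 + ((ys[:, None] - py) / ry) ** 2
    img[y0:y1, x0:x1] += scene.echo_intensity * np.exp(-r2)


def _paint_muscle_line(
    img: np.ndarray, point: tuple[float, float], scene: SceneParams
) -> None:
    """Add a bright oblique line segment terminating near *point* (in place)."""
    (dx1, dy1), (dx2, dy2) = scene.muscle_line_geometry
    ax, ay = point[0] + dx1, point[1] + dy1
    bx, by = point[0] + dx2, point[1] + dy2
    h, w = img.shape
    th = scene.muscle_line_thickness
    pad = 4.0 * th
    x0 = max(0, int(np.floor(min(ax, bx) - pad)))
    x1 = min(w, int(np.ceil(max(ax, bx) + pad)) + 1)
    y0 = max(0, int(np.floor(min(ay, by) - pad)))
    y1 = min(h, int(np.ceil(max(ay, by) + pad)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float64)[None, :]
    ys = np.arange(y0, y1, dtype=np.float64)[:, None]
    vx, vy = bx - ax, by - ay
    len2 = vx * vx + vy * vy
    if len2 == 0:
        return
    t = ((xs - ax) * vx + (ys - ay) * vy) / len2
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (xs - (ax + t * vx)) ** 2 + (ys - (ay + t * vy)) ** 2
    img[y0:y1, x0:x1] += scene.muscle_line_intensity * np.exp(-d2 / (th * th))


def _shadow_mask(
    shape: tuple[int, int], point: tuple[float, float], scene: SceneParams
) -> np.ndarray:
    """Boolean mask of the acoustic shadow wedge above the echo."""
    h, w = shape
    px, py = point
    _, ry = scene.echo_radii
    top = py - ry
    mask = np.zeros(shape, dtype=bool)
    y_max = int(np.floor(top))
    if y_max < 0:
        return mask
    ys = np.arange(0, min(y_max + 1, h), dtype=np.float64)
    # wedge widens slightly toward the top edge of the image
    frac = np.where(top > 0, (top - ys) / max(top, 1.0), 0.0)
    half_w = 0.5 * scene.shadow_width * (1.0 + 0.5 * frac)
    xs = np.arange(w, dtype=np.float64)[None, :]
    mask[: ys.size] = np.abs(xs - px) <= half_w[:, None]
    return mask


def _render_points(
    points: _SequenceABC,
    scene: SceneParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one frame containing an echo+shadow complex at each point."""
    h, w = scene.frame_height, scene.frame_width
    base = np.full((h, w), scene.background_level, dtype=np.float64)
    for pt in points:
        _paint_muscle_line(base, pt, scene)
    for pt in points:
        _paint_echo(base, pt, scene)
    if scene.speckle_scale > 0:
        tex = rng.rayleigh(scale=1.0, size=(h, w))
        if scene.speckle_smooth_sigma > 0:
            tex = gaussian_filter(tex, scene.speckle_smooth_sigma)
        tex /= tex.mean()
        base *= 1.0 + scene.speckle_scale * (tex - 1.0)
    if scene.shadow_attenuation < 1.0:
        for pt in points:
            mask = _shadow_mask((h, w), pt, scene)
            base[mask] *= scene.shadow_attenuation
    np.clip(base, 0.0, 255.0, out=base)
    return base.astype(np.uint8)


def render_frame(
    point: tuple[float, float],
    scene: SceneParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a single synthetic B-mode frame with the hyoid at *point*.

    Returns a uint8 image of shape (frame_height, frame_width).
    """
    px, py = point
    if not (0 <= px < scene.frame_width and 0 <= py < scene.frame_height):
        raise ValueError(f"point {point} outside frame bounds")
    return _render_points([point], scene, rng)


class FrameStore(_SequenceABC):
    """Lazy, deterministic per-frame renderer backing a SyntheticSequence.

    Frame ``i`` is rendered on access from an independent seeded stream, so
    repeated access is bit-identical and sequences never need to hold all
    frames in memory.
    """

    def __init__(
        self,
        gt_points: np.ndarray,
        scene: SceneParams,
        base_seed: int,
        overrides: dict[int, np.ndarray] | None = None,
    ) -> None:
        self._gt = np.asarray(gt_points, dtype=np.float64)
        self._scene = scene
        self._seed = int(base_seed)
        self._overrides = dict(overrides or {})

    def __len__(self) -> int:
        return len(self._gt)

    def _frame_rng(self, i: int) -> np.random.Generator:
        return np.random.default_rng([self._seed, 0xF5A0, i])

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        n = len(self)
        if i < 0:
            i += n
        if not (0 <= i < n):
            raise IndexError(i)
        if i in self._overrides:
            return self._overrides[i].copy()
        return _render_points([tuple(self._gt[i])], self._scene, self._frame_rng(i))

    def with_override(self, idx: int, frame: np.ndarray) -> "FrameStore":
        ov = dict(self._overrides)
        ov[idx] = np.asarray(frame)
        return FrameStore(self._gt, self._scene, self._seed, ov)


@dataclass
class SyntheticSequence:
    """One synthetic recording: frames, ground truth and event timestamps."""

    frames: FrameStore
    gt_points: np.ndarray
    events: dict[str, int]
    scene: SceneParams
    trajectory: TrajectoryParams

    def __post_init__(self) -> None:
        if len(self.gt_points) != len(self.frames):
            raise ValueError("gt_points and frames must have equal length")
        ev = self.events
        if not (
            0
            <= ev["hyoid_onset"]
            < ev["hyoid_offset"]
            < ev["swallow_end"]
            < len(self.frames)
        ):
            raise ValueError(f"events out of order or out of range: {ev}")


def generate_sequence(
    traj: TrajectoryParams, scene: SceneParams | None = None
) -> SyntheticSequence:
    """Build a full synthetic sequence from trajectory and scene parameters."""
    scene = scene or SceneParams()
    traj = traj.resolve(scene) if traj.n_frames is None or traj.rest_point is None else traj
    traj.validate()
    pts = generate_trajectory(traj)
    rx, ry = scene.echo_radii
    if (
        pts[:, 0].min() < rx
        or pts[:, 0].max() >= scene.frame_width - rx
        or pts[:, 1].min() < ry
        or pts[:, 1].max() >= scene.frame_height - ry
    ):
        raise ValueError("trajectory carries the echo outside the frame")
    onset = traj.onset_frame
    offset = onset + traj.elevation_frames + traj.anterior_frames
    end = offset + traj.return_frames
    if end + TAIL_FRAMES >= traj.n_frames:
        warnings.warn(
            f"swallow ends at frame {end} with fewer than {TAIL_FRAMES} tail "
            f"frames (n_frames={traj.n_frames})",
            stacklevel=2,
        )
    events = {"hyoid_onset": onset, "hyoid_offset": offset, "swallow_end": end}
    frames = FrameStore(pts, scene, traj.seed)
    return SyntheticSequence(frames, pts, events, scene, traj)


def inject_double_shadow(
    seq: SyntheticSequence, frame_idx: int, offset_px: tuple[float, float]
) -> SyntheticSequence:
    """Re-render one frame with a duplicated echo+shadow complex.

    Emulates the line-scanning artifact in which a fast-moving hyoid appears
    at two positions within a single frame.  The ground-truth annotation is
    kept at the unshifted point.
    """
    n = len(seq.frames)
    if not (0 <= frame_idx < n):
        raise ValueError(f"frame_idx {frame_idx} out of range [0, {n})")
    ox, oy = offset_px
    if ox == 0 and oy == 0:
        raise ValueError("offset_px must be nonzero")
    pt = tuple(seq.gt_points[frame_idx])
    ghost = (pt[0] + ox, pt[1] + oy)
    rx, ry = seq.scene.echo_radii
    if not (
        rx <= ghost[0] < seq.scene.frame_width - rx
        and ry <= ghost[1] < seq.scene.frame_height - ry
    ):
        raise ValueError(f"offset {offset_px} pushes the second echo out of frame")
    rng = seq.frames._frame_rng(frame_idx)
    frame = _render_points([pt, ghost], seq.scene, rng)
    return SyntheticSequence(
        frames=seq.frames.with_override(frame_idx, frame),
        gt_points=seq.gt_points,
        events=seq.events,
        scene=seq.scene,
        trajectory=seq.trajectory,
    )


def _scene_to_jsonable(scene: SceneParams) -> dict:
    return dataclasses.asdict(scene)


def write_dataset(
    out_dir: str | Path,
    n_train: int = 30,
    n_val: int = 10,
    n_test: int = 10,
    seed: int = 0,
    scene: SceneParams | None = None,
    traj_template: TrajectoryParams | None = None,
) -> dict:
    """Write a train/val/test dataset of synthetic sequences to disk.

    Emits, per sequence, a PNG image directory (``frame_%06d.png``), an
    annotation CSV (``frame,x,y``) and an events JSON, plus a top-level
    ``manifest.json`` describing the split.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = scene or SceneParams()
    traj_template = traj_template or TrajectoryParams()
    traj_template = dataclasses.replace(traj_template, mm_per_px=scene.mm_per_px)

    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    seed_seq = np.random.SeedSequence(seed)
    seq_seeds = seed_seq.generate_state(len(splits)).tolist()

    records = []
    for i, (split, sseed) in enumerate(zip(splits, seq_seeds)):
        seq_id = f"seq_{i:03d}"
        traj = dataclasses.replace(traj_template, seed=int(sseed)).resolve(scene)
        seq = generate_sequence(traj, scene)
        seq_dir = out_dir / seq_id
        frames_dir = seq_dir / "frames"
        frames_dir.mkdir(parents=True, exist_ok=True)
        try:
            for t in range(len(seq.frames)):
                iio.imwrite(frames_dir / f"frame_{t:06d}.png", seq.frames[t])
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing frames under {frames_dir}: {exc}") from exc
        ann_path = seq_dir / "annotations.csv"
        with open(ann_path, "w") as fh:
            fh.write("frame,x,y\n")
            for t, (x, y) in enumerate(seq.gt_points):
                fh.write(f"{t},{x:.4f},{y:.4f}\n")
        ev_path = seq_dir / "events.json"
        ev_path.write_text(json.dumps(seq.events, indent=1))
        records.append(
            {
                "id": seq_id,
                "split": split,
                "frames_dir": str(frames_dir.relative_to(out_dir)),
                "annotations": str(ann_path.relative_to(out_dir)),
                "events": str(ev_path.relative_to(out_dir)),
                "n_frames": len(seq.frames),
                "trajectory": {
                    k: v
                    for k, v in dataclasses.asdict(traj).items()
                    if not isinstance(v, np.ndarray)
                },
            }
        )

    manifest = {
        "root": str(out_dir),
        "seed": seed,
        "calibration": {"mm_per_px": scene.mm_per_px},
        "scene": _scene_to_jsonable(scene),
        "sequences": records,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
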