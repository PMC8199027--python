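"""Per-frame center traces and ground-truth tracks (shared data types)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "GroundTruthTrack"]


@dataclass
class Trace:
    """Predicted hyoid centers, one (x, y) pixel point per frame."""

    points: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trace contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.points)),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sequence_id: str = "") -> "Trace":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(), sequence_id or Path(path).stem)


@dataclass
class GroundTruthTrack:
    """Annotated hyoid points plus swallow event frame indices."""

    points: np.ndarray
    events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        ev = self.events
        if ev and not (ev.get("hyoid_onset", 0) < ev.get("hyoid_offset", 1)):
            raise ValueError("hyoid_onset must precede hyoid_offset")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_files(cls, annotations_csv, events_json=None) -> "GroundTruthTrack":
        df = pd.read_csv(annotations_csv)
        events = {}
        if events_json is not None:
            events = json.loads(Path(events_json).read_text())
        return cls(df[["x", "y"]].to_numpy(), events)
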