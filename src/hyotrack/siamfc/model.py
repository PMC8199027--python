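"""Padding-free AlexNet-style backbone and score-map head.

The backbone is fully convolutional with total stride 8 and no spatial
padding anywhere, so a shift of the input by 8 px shifts the feature grid
by exactly one cell.  A 127x127 input maps to a 6x6 feature grid and a
255x255 input to 22x22, giving a 17x17 raw score map.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, MaxPool2d, ReLU, Sequential

__all__ = ["BackboneConfig", "Backbone", "ScoreHead", "embed", "save_weights", "load_weights"]

TOTAL_STRIDE = 8


@dataclass(frozen=True)
class BackboneConfig:
    """Layer widths of the five-conv backbone (kernel/stride layout fixed)."""

    channels: tuple[int, int, int, int, int] = (16, 32, 32, 32, 24)
    in_channels: int = 3
    seed: int = 0


def _min_input_side() -> int:
    # inverse of output_size(...) >= 1 through all layers
    return 87


class Backbone:
    """Five-conv, two-pool feature extractor with exact stride-8 equivariance."""

    total_stride = TOTAL_STRIDE

    def __init__(self, config: BackboneConfig | None = None):
        self.config = config or BackboneConfig()
        c1, c2, c3, c4, c5 = self.config.channels
        rng = np.random.default_rng([self.config.seed, 0xBB])
        cin = self.config.in_channels
        self.net = Sequential(
            [
                Conv2d(cin, c1, 11, stride=2, rng=rng),
                BatchNorm2d(c1),
                ReLU(),
                MaxPool2d(3, 2),
                Conv2d(c1, c2, 5, rng=rng),
                BatchNorm2d(c2),
                ReLU(),
                MaxPool2d(3, 2),
                Conv2d(c2, c3, 3, rng=rng),
                BatchNorm2d(c3),
                ReLU(),
                Conv2d(c3, c4, 3, rng=rng),
                BatchNorm2d(c4),
                ReLU(),
                Conv2d(c4, c5, 3, rng=rng),
            ]
        )
        self.out_channels = c5

    @staticmethod
    def output_size(n: int) -> int:
        """Spatial output extent for an n x n input."""
        m = (n - 11) // 2 + 1
        m = (m - 3) // 2 + 1
        m = m - 4
        m = (m - 3) // 2 + 1
        m = m - 2
        m = m - 2
        m = m - 2
        if m < 1:
            raise ValueError(f"input size {n} below backbone minimum {_min_input_side()}")
        return m

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) float32 -> (N, F, h, w) feature grids."""
        self.net.set_train(train)
        self.output_size(min(x.shape[2], x.shape[3]))
        return self.net.forward(x.astype(np.float32, copy=False))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class ScoreHead:
    """Affine calibration of the raw correlation map: score = gain*x + bias.

    The gain is fixed small (raw correlations are large sums) and the bias
    is trained, following the usual fully-convolutional Siamese recipe.
    """

    def __init__(self, gain: float = 1e-3):
        self.gain = gain
        self.bias = np.zeros(1, dtype=np.float32)
        self.dbias = np.zeros(1, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.gain * x + self.bias[0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dbias += dout.sum()
        return self.gain * dout

    def named_params(self):
        yield "head.bias", self.bias, self.dbias


def _prepare_patch(patch: np.ndarray, in_channels: int) -> np.ndarray:
    """Grayscale HxW (or HxWxC) patch -> (1, C, H, W) float32 in [0, 1]."""
    p = np.asarray(patch, dtype=np.float32)
    if p.ndim == 2:
        p = np.repeat(p[None, :, :], in_channels, axis=0)
    elif p.ndim == 3:
        p = p.transpose(2, 0, 1)
    else:
        raise ValueError(f"patch must be 2D or 3D, got shape {patch.shape}")
    return (p / 255.0)[None]


def embed(patch: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Embed a single grayscale patch; returns a (F, h, w) feature grid.

    Raises ValueError if the patch is smaller than the backbone's receptive
    field allows.
    """
    x = _prepare_patch(patch, backbone.config.in_channels)
    if min(x.shape[2], x.shape[3]) < _min_input_side():
        raise ValueError(
            f"patch side {min(x.shape[2:])} below backbone minimum {_min_input_side()}"
        )
    return backbone.forward(x, train=False)[0]


def save_weights(path, backbone: Backbone, head: ScoreHead | None = None, extra: dict | None = None) -> None:
    """Serialize backbone (+head) parameters and config into one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for name, p, _ in backbone.net.named_params():
        arrays["param/" + name] = p
    for i, lay in enumerate(backbone.net.layers):
        if isinstance(lay, BatchNorm2d):
            for k, v in lay.state().items():
                arrays[f"state/layer{i}.{k}"] = v
    if head is not None:
        arrays["param/head.bias"] = head.bias
        arrays["meta/head.gain"] = np.array([head.gain])
    meta = {"config": {"channels": list(backbone.config.channels),
                       "in_channels": backbone.config.in_channels,
                       "seed": backbone.config.seed}}
    if extra:
        meta["extra"] = extra
    arrays["meta/json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_weights(path) -> tuple[Backbone, ScoreHead, dict]:
    """Inverse of :func:`save_weights`."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta/json")).decode())
    cfg = meta["config"]
    backbone = Backbone(
        BackboneConfig(tuple(cfg["channels"]), cfg["in_channels"], cfg["seed"])
    )
    for name, p, _ in backbone.net.named_params():
        p[...] = arrays["param/" + name]
    for i, lay in enumerate(backbone.net.layers):
        if isinstance(lay, BatchNorm2d):
            lay.running_mean = arrays[f"state/layer{i}.running_mean"]
            lay.running_var = arrays[f"state/layer{i}.running_var"]
    gain = float(arrays.get("meta/head.gain", np.array([1e-3]))[0])
    head = ScoreHead(gain)
    if "param/head.bias" in arrays:
        head.bias[...] = arrays["param/head.bias"]
    return backbone, head, meta.get("extra", {})
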