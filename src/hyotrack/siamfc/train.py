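"""Offline pair-sampling training of the Siamese tracker.

Pairs are two frames from one sequence no more than ``max_pair_gap_frames``
apart; the exemplar is cropped on the first frame's annotation, the search
patch on the second with random center jitter and stretch.  The score map
is trained against a radius-thresholded +-1 label grid with a
class-balanced weighted binary cross-entropy, SGD with momentum and an
exponentially annealed learning rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .model import Backbone, BackboneConfig, ScoreHead, _prepare_patch, save_weights
from .nn import SGD
from .ops import PatchSpec, crop_patch, exemplar_side

__all__ = [
    "TrainConfig",
    "sample_pair",
    "augment_pair",
    "make_label",
    "weighted_bce_loss",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    pairs_per_epoch: int = 5000
    epochs: int = 50
    eval_checkpoint_epoch: int = 30
    max_pair_gap_frames: int = 100
    lr_start: float = 1e-2
    lr_end: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 8
    label_radius_px: float = 16.0
    jitter_px: float = 8.0
    stretch_range: float = 0.05
    box_size: tuple[float, float] = (30.0, 30.0)
    n_val_pairs: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_start > self.lr_end > 0):
            raise ValueError("require lr_start > lr_end > 0")
        if self.max_pair_gap_frames < 0:
            raise ValueError("max_pair_gap_frames must be >= 0")


def sample_pair(dataset, rng: np.random.Generator, max_gap: int = 100):
    """Draw (exemplar frame+point, search frame+point) from a random sequence.

    The sequence is chosen uniformly; the two frame indices differ by at
    most *max_gap*.  Sequences shorter than 2 frames are skipped with a
    warning.
    """
    if not dataset:
        raise ValueError("empty dataset")
    usable = [s for s in dataset if len(s.frames) >= 2]
    if len(usable) < len(dataset):
        warnings.warn("skipping sequences shorter than 2 frames", stacklevel=2)
    if not usable:
        raise ValueError("no sequence has at least 2 frames")
    seq = usable[int(rng.integers(len(usable)))]
    n = len(seq.frames)
    i = int(rng.integers(n))
    lo, hi = max(0, i - max_gap), min(n - 1, i + max_gap)
    j = int(rng.integers(lo, hi + 1))
    return (
        (seq.frames[i], tuple(seq.gt_points[i])),
        (seq.frames[j], tuple(seq.gt_points[j])),
    )


@dataclass
class AugmentedPair:
    """Cropped training example with a consistent target offset label."""

    exemplar: np.ndarray
    search: np.ndarray
    offset_px: tuple[float, float]  # target offset within search patch, px
    jitter: tuple[float, float]
    stretch: float


def augment_pair(
    pair,
    jitter_px: float,
    stretch_range: float,
    rng: np.random.Generator,
    spec: PatchSpec | None = None,
    box_size: tuple[float, float] = (30.0, 30.0),
) -> AugmentedPair:
    """Crop a sampled pair into exemplar/search patches with augmentation.

    The search crop center is jittered uniformly within ``+-jitter_px`` and
    its side stretched by a uniform factor in ``1 +- stretch_range``; the
    returned ``offset_px`` is the target's true offset from the search-patch
    center, in search-patch pixels.
    """
    if jitter_px < 0 or stretch_range < 0:
        raise ValueError("augmentation amplitudes must be >= 0")
    spec = spec or PatchSpec()
    (ex_frame, ex_pt), (se_frame, se_pt) = pair
    s_z = exemplar_side(*box_size, spec)
    s_x = s_z * spec.search_size / spec.exemplar_size

    jx = float(rng.uniform(-jitter_px, jitter_px)) if jitter_px > 0 else 0.0
    jy = float(rng.uniform(-jitter_px, jitter_px)) if jitter_px > 0 else 0.0
    stretch = float(rng.uniform(-stretch_range, stretch_range)) if stretch_range > 0 else 0.0

    exemplar = crop_patch(ex_frame, ex_pt, s_z, spec.exemplar_size)
    se_center = (se_pt[0] + jx, se_pt[1] + jy)
    side = s_x * (1.0 + stretch)
    search = crop_patch(se_frame, se_center, side, spec.search_size)
    factor = spec.search_size / side
    offset = (-jx * factor, -jy * factor)
    return AugmentedPair(exemplar, search, offset, (jx, jy), stretch)


def make_label(
    grid_size: int,
    label_radius: float,
    total_stride: int,
    target_cell: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius-thresholded +-1 label grid and class-balancing weight grid.

    Cells whose distance to *target_cell* (default: grid center), measured
    in image pixels (cells x *total_stride*), is within *label_radius* are
    +1, all others -1.  Weights make the summed positive and negative
    weights equal, with overall mean weight 1.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    if target_cell is None:
        target_cell = ((grid_size - 1) / 2.0, (grid_size - 1) / 2.0)
    rr, cc = np.mgrid[0:grid_size, 0:grid_size].astype(np.float64)
    dist = np.hypot(rr - target_cell[0], cc - target_cell[1]) * total_stride
    label = np.where(dist <= label_radius, 1.0, -1.0)
    n = label.size
    n_pos = int((label > 0).sum())
    n_neg = n - n_pos
    weight = np.ones_like(label)
    if n_pos > 0 and n_neg > 0:
        weight[label > 0] = n / (2.0 * n_pos)
        weight[label < 0] = n / (2.0 * n_neg)
    return label, weight


def weighted_bce_loss(
    score: np.ndarray, label: np.ndarray, weight: np.ndarray
) -> float:
    """Mean over cells of ``weight * log(1 + exp(-label * score))``."""
    if score.shape != label.shape or score.shape != weight.shape:
        raise ValueError("score, label and weight shapes must match")
    return float(np.mean(weight * np.logaddexp(0.0, -label * score)))


def _bce_grad(score: np.ndarray, label: np.ndarray, weight: np.ndarray) -> np.ndarray:
    z = -label * score
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return (weight * (-label) * sig / score.size).astype(np.float32)


def _xcorr_forward(ex: np.ndarray, se: np.ndarray) -> np.ndarray:
    c, h, w = ex.shape
    _, hh, ww = se.shape
    ho, wo = hh - h + 1, ww - w + 1
    sc, sh, sw = se.strides
    win = as_strided(se, shape=(ho, wo, c, h, w), strides=(sh, sw, sc, sh, sw))
    return np.tensordot(win, ex, axes=([2, 3, 4], [0, 1, 2]))


def _xcorr_backward(
    ex: np.ndarray, se: np.ndarray, dscore: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    c, h, w = ex.shape
    ho, wo = dscore.shape
    sc, sh, sw = se.strides
    win = as_strided(se, shape=(ho, wo, c, h, w), strides=(sh, sw, sc, sh, sw))
    d_ex = np.tensordot(dscore, win, axes=([0, 1], [0, 1]))
    d_se = np.zeros_like(se)
    for i in range(h):
        for j in range(w):
            d_se[:, i : i + ho, j : j + wo] += ex[:, i, j][:, None, None] * dscore
    return d_ex.astype(np.float32), d_se


def _alias_backbone(src: Backbone) -> Backbone:
    """Second Backbone sharing the same parameter/grad/state arrays.

    Needed because layer caches are overwritten per forward pass, while a
    training step must backpropagate through both branches.
    """
    twin = Backbone(src.config)
    for lay_t, lay_s in zip(twin.net.layers, src.net.layers):
        for name in lay_s.params():
            setattr(lay_t, {"W": "W", "b": "b", "gamma": "gamma", "beta": "beta"}[name],
                    lay_s.params()[name])
        for name, g in lay_s.grads().items():
            attr = {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}[name]
            setattr(lay_t, attr, g)
        if hasattr(lay_s, "running_mean"):
            lay_t.running_mean = lay_s.running_mean
            lay_t.running_var = lay_s.running_var
    return twin


def _epoch_lr(config: TrainConfig, epoch: int) -> float:
    if config.epochs <= 1:
        return config.lr_start
    frac = epoch / (config.epochs - 1)
    return float(config.lr_start * (config.lr_end / config.lr_start) ** frac)


def _batch_step(
    backbone: Backbone,
    twin: Backbone,
    head: ScoreHead,
    batch: list[AugmentedPair],
    label_radius: float,
    train_mode: bool,
    optimizer: SGD | None = None,
    lr: float = 0.0,
) -> float:
    """Forward (and optionally backward+update) one batch; returns mean loss.

    Samples are processed one at a time (gradients accumulate across the
    batch before the single SGD step): the per-sample working set stays in
    cache, which on one core is much faster than a batched pass.
    """
    cin = backbone.config.in_channels
    stride = backbone.total_stride
    if train_mode:
        backbone.net.zero_grad()
        head.dbias[...] = 0.0
    losses = []
    inv_n = 1.0 / len(batch)
    for pair in batch:
        f_ex = backbone.forward(_prepare_patch(pair.exemplar, cin), train=train_mode)[0]
        f_se = twin.forward(_prepare_patch(pair.search, cin), train=train_mode)[0]
        raw = _xcorr_forward(f_ex, f_se)
        score = head.forward(raw)
        gsize = score.shape[0]
        center = (gsize - 1) / 2.0
        target_cell = (
            center + pair.offset_px[1] / stride,
            center + pair.offset_px[0] / stride,
        )
        label, weight = make_label(gsize, label_radius, stride, target_cell)
        losses.append(weighted_bce_loss(score, label, weight))
        if train_mode:
            draw = head.backward(_bce_grad(score, label, weight) * inv_n)
            d_ex, d_se = _xcorr_backward(f_ex, f_se, draw)
            twin.backward(d_se[None])
            backbone.backward(d_ex[None])
    if train_mode:
        named = list(backbone.net.named_params()) + list(head.named_params())
        optimizer.step(named, lr)
    return float(np.mean(losses))


def train(
    dataset: dict,
    config: TrainConfig,
    backbone: Backbone | None = None,
    spec: PatchSpec | None = None,
    backbone_config: BackboneConfig | None = None,
    out_dir: str | Path | None = None,
    progress: bool = False,
):
    """Train the Siamese backbone on sampled pairs.

    *dataset* maps split names to lists of sequences (objects exposing
    ``frames`` and ``gt_points``).  Returns ``(backbone, head, history)``
    where history is a list of per-epoch dicts (epoch, lr, train_loss,
    val_loss).  Fully deterministic given ``config.seed``.
    """
    spec = spec or PatchSpec()
    rng = np.random.default_rng([config.seed, 0x51A3])
    if backbone is None:
        backbone = Backbone(backbone_config or BackboneConfig(seed=config.seed))
    twin = _alias_backbone(backbone)
    head = ScoreHead()
    optimizer = SGD(config.momentum, config.weight_decay)
    train_seqs = dataset["train"]
    val_seqs = dataset.get("val", [])

    def draw_batch(seqs, size, generator):
        out = []
        for _ in range(size):
            pair = sample_pair(seqs, generator, config.max_pair_gap_frames)
            out.append(
                augment_pair(
                    pair,
                    config.jitter_px,
                    config.stretch_range,
                    generator,
                    spec,
                    config.box_size,
                )
            )
        return out

    val_batches: list[list[AugmentedPair]] = []
    if val_seqs and config.n_val_pairs > 0:
        vrng = np.random.default_rng([config.seed, 0x7AE])
        pairs = draw_batch(val_seqs, config.n_val_pairs, vrng)
        val_batches = [
            pairs[i : i + config.batch_size]
            for i in range(0, len(pairs), config.batch_size)
        ]

    history: list[dict] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    iterator = range(config.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        lr = _epoch_lr(config, epoch)
        n_batches = max(1, config.pairs_per_epoch // config.batch_size)
        epoch_losses = []
        for _ in range(n_batches):
            batch = draw_batch(train_seqs, config.batch_size, rng)
            loss = _batch_step(
                backbone, twin, head, batch, config.label_radius_px,
                True, optimizer, lr,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            epoch_losses.append(loss)
        val_loss = np.nan
        if val_batches:
            val_loss = float(
                np.mean(
                    [
                        _batch_step(backbone, twin, head, vb,
                                    config.label_radius_px, False)
                        for vb in val_batches
                    ]
                )
            )
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if out_dir is not None:
            save_weights(
                out_dir / f"checkpoint_{epoch:03d}.npz", backbone, head,
                extra={"epoch": epoch},
            )
    if out_dir is not None:
        import pandas as pd

        pd.DataFrame(history).to_csv(out_dir / "training_log.csv", index=False)
        save_weights(out_dir / "weights.npz", backbone, head)
    return backbone, head, history
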