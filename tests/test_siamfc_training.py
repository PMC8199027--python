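"""Tests of pair sampling, augmentation, labels, loss and the train loop."""

import numpy as np
import pytest

from hyotrack.siamfc import (
    Backbone,
    BackboneConfig,
    PatchSpec,
    TrainConfig,
    augment_pair,
    make_label,
    sample_pair,
    train,
    weighted_bce_loss,
)
from hyotrack.siamfc.ops import crop_patch, exemplar_side


class _FakeSeq:
    """Cheap stand-in sequence: flat frames, linear ground truth."""

    def __init__(self, n, seed=0):
        rng = np.random.default_rng(seed)
        self.frames = [np.full((64, 64), 50, dtype=np.uint8)] * n
        self.gt_points = np.column_stack(
            [np.linspace(20, 40, n), np.linspace(30, 35, n)]
        ) + rng.normal(0, 0.1, (n, 2))


class TestSamplePair:
    def test_zero_gap_forces_same_frame(self, rng):
        ds = [_FakeSeq(50)]
        for _ in range(100):
            (f1, p1), (f2, p2) = sample_pair(ds, rng, max_gap=0)
            assert np.array_equal(p1, p2)

    def test_empirical_gap_bound(self, rng):
        ds = [_FakeSeq(400, seed=s) for s in range(3)]
        # indices are recoverable from the gt points (monotone in x)
        for _ in range(10_000):
            (_, p1), (_, p2) = sample_pair(ds, rng, max_gap=100)
        # spot-check via direct index draws on one long sequence
        seq = _FakeSeq(400)
        xs = seq.gt_points[:, 0]
        gaps = []
        for _ in range(10_000):
            (_, p1), (_, p2) = sample_pair([seq], rng, max_gap=100)
            i = int(np.argmin(np.abs(xs - p1[0])))
            j = int(np.argmin(np.abs(xs - p2[0])))
            gaps.append(abs(i - j))
        assert max(gaps) <= 100

    def test_single_sequence_always_chosen(self, rng):
        seq = _FakeSeq(10)
        for _ in range(20):
            pair = sample_pair([seq], rng)
            assert pair is not None

    def test_short_sequences_skipped_with_warning(self, rng):
        ds = [_FakeSeq(1), _FakeSeq(20)]
        with pytest.warns(UserWarning, match="skipping"):
            sample_pair(ds, rng)

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_pair([], rng)


class TestAugmentPair:
    def _pair(self, rng):
        frame = (rng.random((120, 160)) * 255).astype(np.float32)
        return ((frame, (80.0, 60.0)), (frame, (82.0, 58.0)))

    def test_zero_amplitudes_identity(self, rng):
        pair = self._pair(rng)
        spec = PatchSpec()
        out = augment_pair(pair, 0.0, 0.0, rng, spec)
        assert out.offset_px == (0.0, 0.0)
        assert out.jitter == (0.0, 0.0) and out.stretch == 0.0
        s_z = exemplar_side(30, 30, spec)
        ref = crop_patch(pair[0][0], pair[0][1], s_z, spec.exemplar_size)
        assert np.array_equal(out.exemplar, ref)

    def test_jitter_bounds(self, rng):
        pair = self._pair(rng)
        jits = []
        for _ in range(200):
            out = augment_pair(pair, 8.0, 0.0, rng)
            jits.append(out.jitter)
        jits = np.array(jits)
        assert np.all(np.abs(jits) <= 8.0)
        assert jits.std() > 1.0  # actually random

    def test_label_offset_matches_jitter(self, rng):
        """Plant-and-recover: the offset written into the label equals the
        applied jitter mapped into search-patch pixels, with opposite sign."""
        pair = self._pair(rng)
        spec = PatchSpec()
        s_x = exemplar_side(30, 30, spec) * spec.search_size / spec.exemplar_size
        for _ in range(50):
            out = augment_pair(pair, 8.0, 0.05, rng, spec)
            side = s_x * (1.0 + out.stretch)
            expect = (
                -out.jitter[0] * spec.search_size / side,
                -out.jitter[1] * spec.search_size / side,
            )
            assert out.offset_px == pytest.approx(expect, abs=1e-9)

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_pair(self._pair(rng), -1.0, 0.0, rng)


class TestMakeLabel:
    def test_radius_zero_single_positive(self):
        label, weight = make_label(15, 0.0, 8)
        assert label[7, 7] == 1
        assert (label > 0).sum() == 1

    def test_weight_balance(self):
        label, weight = make_label(17, 16.0, 8)
        pos = weight[label > 0].sum()
        neg = weight[label < 0].sum()
        assert pos == pytest.approx(neg, rel=1e-12)
        assert weight.mean() == pytest.approx(1.0, rel=1e-12)

    def test_full_coverage_all_positive(self):
        label, weight = make_label(9, 1000.0, 8)
        assert np.all(label == 1)
        assert np.all(weight == 1)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            make_label(0, 8.0, 8)


class TestWeightedBceLoss:
    def test_zero_scores_log2(self):
        score = np.zeros((7, 7))
        label = np.where(np.arange(49).reshape(7, 7) < 10, 1.0, -1.0)
        loss = weighted_bce_loss(score, label, np.ones_like(score))
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_separable_limit_zero(self):
        label, weight = make_label(9, 8.0, 8)
        score = label * 100.0
        assert weighted_bce_loss(score, label, weight) < 1e-12

    def test_matches_hand_oracle(self, rng):
        score = rng.standard_normal((3, 3))
        label = np.sign(rng.standard_normal((3, 3)))
        weight = rng.random((3, 3)) + 0.5
        total = 0.0
        for i in range(3):
            for j in range(3):
                total += weight[i, j] * np.log(1 + np.exp(-label[i, j] * score[i, j]))
        assert weighted_bce_loss(score, label, weight) == pytest.approx(
            total / 9, rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce_loss(np.zeros((3, 3)), np.zeros((4, 4)), np.zeros((3, 3)))


def _tiny_dataset(tiny_scene):
    import warnings

    from hyotrack.synthetic import TrajectoryParams, generate_sequence

    seqs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for seed in (31, 32):
            traj = TrajectoryParams(
                n_frames=20, rest_point=(90.0, 55.0), onset_frame=3,
                elevation_frames=4, anterior_frames=4, return_frames=5,
                rom_x_mm=3.0, rom_y_mm=2.0, jitter_sd=0.2, seed=seed,
            )
            seqs.append(generate_sequence(traj, tiny_scene))
    return seqs


# small patches keep the optimization-sanity run fast; 103 px is the
# smallest exemplar that still gives a multi-cell (3x3) feature grid
_SMALL_SPEC = PatchSpec(exemplar_size=103, search_size=135)
_TINY_BB = dict(channels=(4, 8, 8, 8, 8), seed=3)


class TestTrain:
    def test_overfit_sanity(self, tiny_scene):
        """Repeated steps on a small fixed pool cut the loss by >= 50%.

        The narrow test net needs a larger step size than the full-width
        backbone: its raw correlation sums (and hence the gradients through
        the fixed score gain) are an order of magnitude smaller.
        """
        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(
            pairs_per_epoch=10, epochs=60, batch_size=10,
            lr_start=0.3, lr_end=0.03, n_val_pairs=0,
            jitter_px=4.0, label_radius_px=16.0, seed=9,
        )
        _, _, history = train(
            {"train": seqs}, config,
            backbone_config=BackboneConfig(**_TINY_BB), spec=_SMALL_SPEC,
        )
        losses = [h["train_loss"] for h in history]
        assert losses[-1] <= 0.5 * losses[0]

    def test_deterministic_history(self, tiny_scene):
        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(
            pairs_per_epoch=8, epochs=2, batch_size=4,
            lr_start=1e-2, lr_end=1e-3, n_val_pairs=4, seed=17,
        )
        runs = []
        for _ in range(2):
            _, _, history = train(
                {"train": seqs, "val": seqs}, config,
                backbone_config=BackboneConfig(**_TINY_BB), spec=_SMALL_SPEC,
            )
            runs.append([(h["train_loss"], h["val_loss"]) for h in history])
        assert runs[0] == runs[1]

    def test_zero_epochs_initial_weights(self, tiny_scene):
        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(epochs=0, n_val_pairs=0, seed=3)
        backbone, _, history = train(
            {"train": seqs}, config, backbone_config=BackboneConfig(**_TINY_BB)
        )
        assert history == []
        fresh = Backbone(BackboneConfig(**_TINY_BB))
        for (_, p1, _), (_, p2, _) in zip(
            backbone.net.named_params(), fresh.net.named_params()
        ):
            assert np.array_equal(p1, p2)

    def test_lr_schedule_geometric(self, tiny_scene):
        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(
            pairs_per_epoch=4, epochs=3, batch_size=4,
            lr_start=1e-1, lr_end=1e-3, n_val_pairs=0, seed=1,
        )
        _, _, history = train(
            {"train": seqs}, config,
            backbone_config=BackboneConfig(**_TINY_BB), spec=_SMALL_SPEC,
        )
        lrs = [h["lr"] for h in history]
        assert lrs[0] == pytest.approx(1e-1)
        assert lrs[-1] == pytest.approx(1e-3)
        ratios = np.diff(np.log(lrs))
        assert np.allclose(ratios, ratios[0])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_start=1e-5, lr_end=1e-2)

    def test_checkpoints_and_log_written(self, tiny_scene, tmp_path):
        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(
            pairs_per_epoch=4, epochs=2, batch_size=4, n_val_pairs=0, seed=2
        )
        train(
            {"train": seqs}, config,
            backbone_config=BackboneConfig(**_TINY_BB), spec=_SMALL_SPEC,
            out_dir=tmp_path,
        )
        assert (tmp_path / "weights.npz").exists()
        assert (tmp_path / "checkpoint_000.npz").exists()
        assert (tmp_path / "checkpoint_001.npz").exists()
        log = (tmp_path / "training_log.csv").read_text()
        assert log.splitlines()[0] == "epoch,lr,train_loss,val_loss"


class TestWeightsRoundTrip:
    def test_save_load_identical_embeddings(self, tiny_scene, tmp_path, rng):
        from hyotrack.siamfc import ScoreHead, embed, load_weights, save_weights

        seqs = _tiny_dataset(tiny_scene)
        config = TrainConfig(
            pairs_per_epoch=4, epochs=1, batch_size=4, n_val_pairs=0, seed=8
        )
        backbone, head, _ = train(
            {"train": seqs}, config,
            backbone_config=BackboneConfig(**_TINY_BB), spec=_SMALL_SPEC,
        )
        path = tmp_path / "w.npz"
        save_weights(path, backbone, head, extra={"note": "test"})
        loaded, head2, extra = load_weights(path)
        assert extra == {"note": "test"}
        assert head2.bias == pytest.approx(head.bias)
        patch = rng.random((127, 127)) * 255
        assert np.array_equal(embed(patch, backbone), embed(patch, loaded))
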