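"""Model assembly, inference contracts, loss-graph consistency and training."""

import numpy as np
import pytest

from echoseg import losses as ls
from echoseg import network as net
from echoseg import phantom as ph
from echoseg import preprocess as pp
from echoseg.nn.autodiff import Tensor


@pytest.fixture(scope="module")
def reduced_model():
    return net.build_model(net.NetworkConfig.reduced(seed=0))


@pytest.fixture(scope="module")
def tiny_dataset(small_spec):
    """Two short phantom sequences resized to the reduced input shape."""
    from dataclasses import replace

    cfg = net.NetworkConfig.reduced()
    out = []
    for seed in (5, 6):
        spec = replace(small_spec, seed=seed)
        seq = ph.generate_phantom_sequence(spec)
        frames = np.stack([pp.preprocess_frame(f, cfg.input_shape)
                           for f in seq.frames])
        masks = np.stack([pp.resize_mask_nearest(m, cfg.input_shape)
                          for m in seq.masks])
        out.append((frames, masks))
    return out


class TestBuildModel:
    def test_reduced_pyramid_levels_and_channels(self, reduced_model, rng):
        cfg = reduced_model.config
        x = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        r = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        pyramids = reduced_model.features(x, r)
        assert len(pyramids) == 5
        h, w = cfg.input_shape
        for p, stride in zip(pyramids, cfg.anchor.strides):
            assert p.shape[1] == cfg.pyramid_channels
            assert p.shape[2] == int(np.ceil(h / stride))
            assert p.shape[3] == int(np.ceil(w / stride))

    def test_full_preset_emits_256_channel_pyramids(self, rng):
        model = net.build_model(net.NetworkConfig.full(seed=0))
        cfg = model.config
        x = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        r = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        pyramids = model.features(x, r)
        assert len(pyramids) == 5
        assert all(p.shape[1] == 256 for p in pyramids)

    def test_head_output_shapes_and_ranges(self, reduced_model, rng):
        from scipy.special import expit

        cfg = reduced_model.config
        x = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        r = Tensor(rng.random((1, 2, *cfg.input_shape)).astype(np.float32))
        pyramids = reduced_model.features(x, r)
        cls_logits, reg_deltas = reduced_model.detection_outputs(pyramids)
        n_anchors = len(reduced_model.anchors)
        assert cls_logits.shape == (1, n_anchors)
        assert reg_deltas.shape == (1, n_anchors, 4)
        probs = expit(cls_logits.data)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_invalid_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            net.NetworkConfig.reduced(input_shape=(60, 100)).validate()


class TestForwardFrame:
    def test_result_contract(self, reduced_model, rng):
        cfg = reduced_model.config
        frame = rng.random(cfg.input_shape).astype(np.float32)
        mask = np.zeros(cfg.input_shape, dtype=np.float32)
        mask[20:40, 30:70] = 1
        main = np.stack([frame, mask])
        result = net.forward_frame(reduced_model, main, main)
        assert result.mask.shape == cfg.input_shape
        assert set(np.unique(result.mask)) <= {0, 1}

    def test_inference_is_deterministic(self, reduced_model, rng):
        cfg = reduced_model.config
        main = rng.random((2, *cfg.input_shape)).astype(np.float32)
        r1 = net.forward_frame(reduced_model, main, main)
        r2 = net.forward_frame(reduced_model, main, main)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.best_score == r2.best_score


class TestSegmentSequence:
    def test_output_length_and_first_mask_verbatim(self, reduced_model,
                                                   tiny_dataset):
        frames, masks = tiny_dataset[0]
        out = net.segment_sequence(reduced_model, list(frames), masks[0])
        assert len(out) == len(frames)
        np.testing.assert_array_equal(out.masks[0], masks[0])

    def test_feedback_chain_stays_binary(self, reduced_model, tiny_dataset):
        frames, masks = tiny_dataset[0]
        out = net.segment_sequence(reduced_model, list(frames), masks[0])
        for m in out.masks:
            assert m.dtype == np.uint8
            assert set(np.unique(m)) <= {0, 1}

    def test_short_sequence_rejected(self, reduced_model, tiny_dataset):
        frames, masks = tiny_dataset[0]
        with pytest.raises(ValueError, match="2 frames"):
            net.segment_sequence(reduced_model, [frames[0]], masks[0])


class TestLossGraph:
    def test_graph_losses_match_numpy_reference(self, tiny_dataset):
        """The autodiff loss graph must agree with the numpy loss surface."""
        from scipy.special import expit

        model = net.build_model(net.NetworkConfig.reduced(seed=3))
        cfg = net.TrainConfig()
        frames, masks = tiny_dataset[0]
        seq = net._prepare_sequence(model, frames, masks, cfg)
        total, cls_l, reg_l, mask_l = net._graph_losses(model, seq, cfg)

        pyramids = model.features(Tensor(seq["main"]), Tensor(seq["ref"]))
        cls_logits, reg_deltas = model.detection_outputs(pyramids)
        probs = expit(cls_logits.data.astype(np.float64))
        want_cls = ls.focal_loss(seq["labels"].ravel(), probs.ravel(),
                                 cfg.focal)
        pos = seq["labels"].ravel() == 1
        resid = (reg_deltas.data.reshape(-1, 4)[pos]
                 - seq["reg_targets"].reshape(-1, 4)[pos])
        want_reg = ls.smooth_l1(resid, cfg.smooth)
        logits = model.mask_logits(pyramids[0], seq["gt_boxes"],
                                   np.arange(len(seq["gt_boxes"])))
        want_mask = ls.mask_bce(seq["mask_targets"][:, None],
                                expit(logits.data.astype(np.float64)))

        assert float(cls_l.data) == pytest.approx(want_cls, rel=1e-4)
        assert float(reg_l.data) == pytest.approx(want_reg, rel=1e-4)
        assert float(mask_l.data) == pytest.approx(want_mask, rel=1e-4)
        assert float(total.data) == pytest.approx(
            want_cls + want_reg + want_mask, rel=1e-4)


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self, tiny_dataset):
        model = net.build_model(net.NetworkConfig.reduced(seed=1))
        before = [p.data.copy() for p in model.parameters()]
        cfg = net.TrainConfig(learning_rate=0.0, iterations=2, seed=0)
        net.train_model(model, tiny_dataset, cfg)
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_teacher_forced_loss_is_reducible(self, tiny_dataset):
        model = net.build_model(net.NetworkConfig.reduced(seed=2))
        cfg = net.TrainConfig(learning_rate=0.01, momentum=0.9,
                              iterations=25, seed=0)
        before = net.evaluate_loss(model, tiny_dataset[:1], cfg)
        net.train_model(model, tiny_dataset[:1], cfg)
        after = net.evaluate_loss(model, tiny_dataset[:1], cfg)
        assert after["total"] < before["total"]

    def test_empty_dataset_rejected(self):
        model = net.build_model(net.NetworkConfig.reduced(seed=0))
        with pytest.raises(ValueError):
            net.train_model(model, [], net.TrainConfig())

    def test_history_is_logged_to_csv(self, tiny_dataset, tmp_path):
        import pandas as pd

        model = net.build_model(net.NetworkConfig.reduced(seed=0))
        log = tmp_path / "loss.csv"
        cfg = net.TrainConfig(learning_rate=1e-4, iterations=3, seed=0,
                              log_csv=str(log))
        history = net.train_model(model, tiny_dataset, cfg)
        assert len(history) == 3
        frame = pd.read_csv(log)
        assert list(frame.columns) == ["iteration", "total", "cls", "reg",
                                       "mask"]
        assert len(frame) == 3


class TestSerializationAndTransfer:
    def test_save_load_roundtrip_preserves_inference(self, reduced_model,
                                                     tmp_path, rng):
        cfg = reduced_model.config
        path = tmp_path / "model.npz"
        net.save_model(reduced_model, path)
        loaded = net.load_model(path, cfg)
        main = rng.random((2, *cfg.input_shape)).astype(np.float32)
        r1 = net.forward_frame(reduced_model, main, main)
        r2 = net.forward_frame(loaded, main, main)
        np.testing.assert_array_equal(r1.mask, r2.mask)

    def test_transfer_copies_backbone_bit_exactly(self):
        source = net.build_model(net.NetworkConfig.reduced(seed=10))
        target = net.build_model(net.NetworkConfig.reduced(seed=11))
        head_before = [p.data.copy() for p in target.cls_head.parameters()]
        net.transfer_backbone(target, source)
        for s, t in zip(source.backbone.parameters(),
                        target.backbone.parameters()):
            np.testing.assert_array_equal(s.data, t.data)
        for b, p in zip(head_before, target.cls_head.parameters()):
            np.testing.assert_array_equal(b, p.data)
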