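"""The two-stream reference-guided segmentation network.

A Siamese residual encoder (shared weights) processes two two-channel
inputs: the main stream sees the current frame stacked with the previous
frame's mask, the reference stream sees the user-annotated first frame with
its ground-truth mask.  Stage 3/4/5 features of each stream feed a shared
feature pyramid (P3-P7); corresponding pyramid levels of the two streams
are fused by channel concatenation plus a 1x1 reduction.  A classification
subnet scores A anchors per location, a regression subnet refines them, and
a segmentation subnet predicts a mask over the RoIAligned crop of the
winning detection.  The winning mask is thresholded, pasted back into its
box and fed forward as the next frame's guidance mask.

Two presets are provided: ``full`` mirrors the five-stage bottleneck
backbone (ResNet50-like widths, 256 pyramid channels, 128x256 inputs) and
``reduced`` is a narrow shallow variant for CPU-scale experiments
(32 pyramid channels, 64x128 inputs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from skimage.transform import resize

from echoseg import anchors as anc
from echoseg.anchors import AnchorConfig, AnchorSet, Detections
from echoseg.losses import EPS, FocalParams, SmoothL1Params
from echoseg.nn import autodiff as ad
from echoseg.nn.autodiff import Tensor
from echoseg.nn.layers import (BasicBlock, BottleneckBlock, Conv2d, ConvReLU,
                               Module, SGD)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "FrameResult",
    "MaskSequence",
    "TwoStreamModel",
    "build_model",
    "forward_frame",
    "segment_sequence",
    "train_model",
    "evaluate_loss",
    "save_model",
    "load_model",
    "transfer_backbone",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; see :meth:`full` and :meth:`reduced`."""

    preset: str = "full"
    input_shape: tuple[int, int] = (128, 256)
    stem_channels: int = 64
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)
    bottleneck: bool = True
    pyramid_channels: int = 256
    roi_size: int = 14
    mask_size: int = 28
    mask_threshold: float = 0.5
    cls_prior: float = 0.01
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    seed: int = 0

    @classmethod
    def full(cls, **overrides) -> "NetworkConfig":
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides) -> "NetworkConfig":
        """Narrow, shallow preset for CPU-scale training experiments."""
        defaults = dict(preset="reduced", input_shape=(64, 128),
                        stem_channels=8, stage_widths=(16, 32, 64, 128),
                        stage_blocks=(1, 1, 1, 1), bottleneck=False,
                        pyramid_channels=32, cls_prior=0.5)
        defaults.update(overrides)
        return cls(**defaults)

    def validate(self) -> None:
        h, w = self.input_shape
        if h % 32 or w % 32:
            raise ValueError("input shape must be divisible by 32 "
                             "(five stride-2 reductions)")
        if len(self.stage_widths) != 4 or len(self.stage_blocks) != 4:
            raise ValueError("need widths/blocks for stages 2-5")
        if not (0 < self.cls_prior < 1):
            raise ValueError("cls_prior must be in (0, 1)")


@dataclass
class TrainConfig:
    """End-to-end training settings (SGD, sequence-level batching)."""

    learning_rate: float = 1e-5
    momentum: float = 0.9
    iterations: int = 200
    seed: int = 0
    teacher_forcing: bool = True
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    focal: FocalParams = field(default_factory=FocalParams)
    smooth: SmoothL1Params = field(default_factory=SmoothL1Params)
    log_csv: str | None = None

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class FrameResult:
    detections: Detections
    mask: np.ndarray = field(repr=False)
    best_score: float = 0.0
    fallback_used: bool = False


@dataclass
class MaskSequence:
    masks: list[np.ndarray] = field(repr=False)
    fallback_flags: list[bool] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.masks)


class ResidualEncoder(Module):
    """Five-stage residual feature extractor on two-channel inputs."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.stem = ConvReLU(2, cfg.stem_channels, 7, rng, stride=2)
        block_cls = BottleneckBlock if cfg.bottleneck else BasicBlock
        expansion = block_cls.expansion if cfg.bottleneck else 1
        self.stages: list[list[Module]] = []
        in_ch = cfg.stem_channels
        for width, n_blocks in zip(cfg.stage_widths, cfg.stage_blocks):
            blocks: list[Module] = []
            for b in range(n_blocks):
                stride = 2 if b == 0 else 1
                blocks.append(block_cls(in_ch, width, rng, stride=stride))
                in_ch = width * expansion
            self.stages.append(blocks)
        self.out_channels = [w * expansion for w in cfg.stage_widths]

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        feats = []
        for blocks in self.stages:
            for block in blocks:
                x = block(x)
            feats.append(x)
        return feats[1], feats[2], feats[3]  # C3 (s8), C4 (s16), C5 (s32)


class FeaturePyramid(Module):
    """Lateral + top-down construction of P3-P7 at a fixed channel width."""

    def __init__(self, in_channels: tuple[int, int, int], out_ch: int,
                 rng: np.random.Generator):
        c3, c4, c5 = in_channels
        self.lat3 = Conv2d(c3, out_ch, 1, rng)
        self.lat4 = Conv2d(c4, out_ch, 1, rng)
        self.lat5 = Conv2d(c5, out_ch, 1, rng)
        self.smooth3 = Conv2d(out_ch, out_ch, 3, rng)
        self.smooth4 = Conv2d(out_ch, out_ch, 3, rng)
        self.p6 = Conv2d(c5, out_ch, 3, rng, stride=2)
        self.p7 = Conv2d(out_ch, out_ch, 3, rng, stride=2)

    def __call__(self, c3: Tensor, c4: Tensor, c5: Tensor) -> list[Tensor]:
        p5 = self.lat5(c5)
        p4 = self.smooth4(self.lat4(c4) + ad.upsample_nearest2x(p5))
        p3 = self.smooth3(self.lat3(c3) + ad.upsample_nearest2x(p4))
        p6 = self.p6(c5)
        p7 = self.p7(ad.relu(p6))
        return [p3, p4, p5, p6, p7]


class PredictionHead(Module):
    """Four 3x3 conv+ReLU layers and a final 3x3 conv (shared across levels)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 final_bias: float = 0.0):
        self.tower = [ConvReLU(in_ch, in_ch, 3, rng) for _ in range(4)]
        self.final = Conv2d(in_ch, out_ch, 3, rng, bias_init=final_bias,
                            weight_scale=0.1)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.tower:
            x = layer(x)
        return self.final(x)


class MaskHead(Module):
    """Four 3x3 conv+ReLU, x2 upsample, two final convs -> one logit map."""

    def __init__(self, in_ch: int, rng: np.random.Generator):
        self.tower = [ConvReLU(in_ch, in_ch, 3, rng) for _ in range(4)]
        self.post = ConvReLU(in_ch, in_ch, 3, rng)
        self.final = Conv2d(in_ch, 1, 1, rng, weight_scale=0.1)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.tower:
            x = layer(x)
        x = ad.upsample_nearest2x(x)
        return self.final(self.post(x))


class TwoStreamModel(Module):
    """Siamese encoder + shared FPN + fusion + detection/segmentation heads."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        rng = np.random.default_rng(config.seed)
        self.config = config
        pc = config.pyramid_channels
        self.backbone = ResidualEncoder(config, rng)
        self.fpn = FeaturePyramid(tuple(self.backbone.out_channels[1:]), pc, rng)
        self.fusion = [Conv2d(2 * pc, pc, 1, rng) for _ in range(5)]
        a = config.anchor.anchors_per_location
        prior = config.cls_prior
        self.cls_head = PredictionHead(pc, a, rng,
                                       final_bias=float(np.log(prior / (1 - prior))))
        self.reg_head = PredictionHead(pc, 4 * a, rng)
        self.mask_head = MaskHead(pc, rng)
        self.anchors: AnchorSet = anc.generate_anchors(config.anchor,
                                                       config.input_shape)

    # -- forward pieces ------------------------------------------------------
    def features(self, main: Tensor, ref: Tensor) -> list[Tensor]:
        """Fused pyramid levels for a batch of main frames and one reference."""
        n = main.shape[0]
        main_pyr = self.fpn(*self.backbone(main))
        ref_pyr = self.fpn(*self.backbone(ref))
        fused = []
        for fuse, pm, pr in zip(self.fusion, main_pyr, ref_pyr):
            pr_tiled = ad.tile_batch(pr, n) if n > 1 else pr
            fused.append(fuse(ad.concat([pm, pr_tiled], axis=1)))
        return fused

    def detection_outputs(self, pyramids: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Flattened per-anchor cls logits (N, K) and reg deltas (N, K, 4).

        Flattening is (level, row, col, anchor), matching the anchor set.
        """
        a = self.config.anchor.anchors_per_location
        cls_parts, reg_parts = [], []
        n = pyramids[0].shape[0]
        for level in pyramids:
            cl = self.cls_head(level)  # (N, A, H, W)
            h, w = cl.shape[2], cl.shape[3]
            cls_parts.append(ad.reshape(ad.transpose(cl, (0, 2, 3, 1)),
                                        (n, h * w * a)))
            rg = self.reg_head(level)  # (N, 4A, H, W)
            rg = ad.reshape(rg, (n, a, 4, h, w))
            rg = ad.transpose(rg, (0, 3, 4, 1, 2))  # (N, H, W, A, 4)
            reg_parts.append(ad.reshape(rg, (n, h * w * a, 4)))
        return ad.concat(cls_parts, axis=1), ad.concat(reg_parts, axis=1)

    def mask_logits(self, p3: Tensor, boxes: np.ndarray,
                    batch_idx: np.ndarray) -> Tensor:
        """Mask-head logits over RoIAligned crops of fused P3 (stride 8)."""
        crops = ad.roi_align(p3, boxes, batch_idx,
                             (self.config.roi_size, self.config.roi_size),
                             spatial_scale=1.0 / self.config.anchor.strides[0])
        return self.mask_head(crops)


def build_model(config: NetworkConfig) -> TwoStreamModel:
    """Construct the two-stream model with seeded random initialization."""
    return TwoStreamModel(config)


def _paste_mask(probs: np.ndarray, box: np.ndarray, shape: tuple[int, int],
                threshold: float) -> np.ndarray:
    """Resize a crop-level probability map into its box and threshold."""
    h, w = shape
    x1 = int(np.clip(np.floor(box[0]), 0, w - 1))
    y1 = int(np.clip(np.floor(box[1]), 0, h - 1))
    x2 = int(np.clip(np.ceil(box[2]), x1 + 1, w))
    y2 = int(np.clip(np.ceil(box[3]), y1 + 1, h))
    region = resize(probs.astype(np.float64), (y2 - y1, x2 - x1), order=1,
                    mode="edge", anti_aliasing=False, preserve_range=True)
    out = np.zeros(shape, dtype=np.uint8)
    out[y1:y2, x1:x2] = (region >= threshold).astype(np.uint8)
    return out


def forward_frame(model: TwoStreamModel, main_input: np.ndarray,
                  ref_input: np.ndarray) -> FrameResult:
    """Segment one frame given its guidance mask and the reference pair.

    If no detection survives filtering, the guidance mask (channel 1 of the
    main input) is reused and ``fallback_used`` is set.
    """
    cfg = model.config
    main = Tensor(main_input[None])
    ref = Tensor(ref_input[None])
    pyramids = model.features(main, ref)
    cls_logits, reg_deltas = model.detection_outputs(pyramids)
    scores = expit(cls_logits.data[0].astype(np.float64))
    deltas = reg_deltas.data[0].astype(np.float64)
    boxes = anc.decode_boxes(model.anchors.boxes, deltas, cfg.anchor.delta_std)
    boxes = anc.clip_boxes(boxes, cfg.input_shape)
    dets = anc.filter_detections(boxes, scores, model.anchors.levels, cfg.anchor)
    if len(dets) == 0:
        guidance = (main_input[1] >= 0.5).astype(np.uint8)
        return FrameResult(detections=dets, mask=guidance, best_score=0.0,
                           fallback_used=True)
    best_box = dets.boxes[0]
    logits = model.mask_logits(pyramids[0], best_box[None], np.zeros(1, int))
    probs = expit(logits.data[0, 0].astype(np.float64))
    mask = _paste_mask(probs, best_box, cfg.input_shape, cfg.mask_threshold)
    return FrameResult(detections=dets, mask=mask,
                       best_score=float(dets.scores[0]), fallback_used=False)


def segment_sequence(model: TwoStreamModel, frames, ref_annotation) -> MaskSequence:
    """Propagate the reference annotation through a whole sequence.

    ``frames`` are preprocessed grayscale frames at the model's input shape;
    ``ref_annotation`` is the binary mask of the first frame.  The first
    output mask is the annotation itself, returned verbatim; every later
    frame is guided by the previous frame's prediction.
    """
    frames = [np.asarray(f, dtype=np.float32) for f in frames]
    if len(frames) < 2:
        raise ValueError("sequence must have at least 2 frames")
    shape = tuple(model.config.input_shape)
    if frames[0].shape != shape:
        raise ValueError(f"frames must be preprocessed to {shape}")
    ref_mask = np.asarray(ref_annotation)
    if ref_mask.shape != shape:
        raise ValueError("annotation shape must match the frame shape")
    ref_mask = (ref_mask >= 0.5).astype(np.uint8)
    ref_input = np.stack([frames[0], ref_mask.astype(np.float32)], axis=0)

    out = MaskSequence(masks=[ref_mask.copy()], fallback_flags=[False],
                       scores=[1.0])
    guidance = ref_mask
    for t in range(1, len(frames)):
        main_input = np.stack([frames[t], guidance.astype(np.float32)], axis=0)
        result = forward_frame(model, main_input, ref_input)
        guidance = result.mask
        out.masks.append(result.mask)
        out.fallback_flags.append(result.fallback_used)
        out.scores.append(result.best_score)
    return out


# -- training ---------------------------------------------------------------

def mask_to_box(mask: np.ndarray) -> np.ndarray:
    """Tight (x1, y1, x2, y2) bounding box of a non-empty binary mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if len(rows) == 0:
        raise ValueError("empty mask has no bounding box")
    return np.array([cols[0], rows[0], cols[-1] + 1, rows[-1] + 1], dtype=float)


def _mask_target(mask: np.ndarray, box: np.ndarray, size: int) -> np.ndarray:
    x1, y1, x2, y2 = box.astype(int)
    crop = mask[y1:y2, x1:x2].astype(np.float64)
    t = resize(crop, (size, size), order=0, mode="edge", anti_aliasing=False,
               preserve_range=True)
    return (t >= 0.5).astype(np.float32)


def _one_minus(t: Tensor) -> Tensor:
    return ad.add(ad.mul(t, -1.0), 1.0)


def _graph_losses(model: TwoStreamModel, seq, cfg: TrainConfig):
    """Build the loss graph for one sequence under teacher forcing.

    Returns (total, cls, reg, mask) scalar tensors.  ``seq`` is a dict with
    precomputed inputs, anchor labels, regression targets, GT boxes and
    28x28 mask targets.
    """
    pyramids = model.features(Tensor(seq["main"]), Tensor(seq["ref"]))
    cls_logits, reg_deltas = model.detection_outputs(pyramids)

    labels = seq["labels"]                      # (N, K)
    n_pos = max(1, int((labels == anc.POSITIVE).sum()))
    probs = ad.clip(ad.sigmoid(cls_logits), EPS, 1 - EPS)
    flat = ad.reshape(probs, (-1,))
    pos_idx = np.flatnonzero(labels.ravel() == anc.POSITIVE)
    bg_idx = np.flatnonzero(labels.ravel() == anc.BACKGROUND)
    fp = cfg.focal
    terms = []
    if len(pos_idx):
        p_pos = ad.gather(flat, pos_idx)
        terms.append(ad.tsum(ad.mul(ad.power(_one_minus(p_pos), fp.gamma),
                                    ad.mul(ad.log(p_pos), -1.0))))
    if len(bg_idx):
        p_bg = ad.gather(flat, bg_idx)
        terms.append(ad.tsum(ad.mul(ad.power(p_bg, fp.gamma),
                                    ad.mul(ad.log(_one_minus(p_bg)), -1.0))))
    if terms:
        cls_loss = ad.mul(sum(terms[1:], terms[0]), fp.alpha_t / n_pos)
    else:
        cls_loss = Tensor(0.0)

    if len(pos_idx):
        comp_idx = (pos_idx[:, None] * 4 + np.arange(4)).ravel()
        pred = ad.gather(ad.reshape(reg_deltas, (-1,)), comp_idx)
        target = seq["reg_targets"].ravel()[comp_idx]
        resid = ad.add(pred, -target)
        a_resid = ad.tabs(resid)
        sig = cfg.smooth.sigma
        quad = ad.mul(ad.mul(resid, resid), 0.5 / sig)
        lin = ad.add(a_resid, -0.5 * sig)
        reg_loss = ad.tmean(ad.where_mask(a_resid.data < sig, quad, lin))
    else:
        reg_loss = Tensor(0.0)

    logits = model.mask_logits(pyramids[0], seq["gt_boxes"],
                               np.arange(len(seq["gt_boxes"])))
    p = ad.clip(ad.sigmoid(logits), EPS, 1 - EPS)
    y = seq["mask_targets"][:, None]            # (N, 1, S, S)
    bce = ad.add(ad.mul(ad.mul(Tensor(y), ad.log(p)), -1.0),
                 ad.mul(ad.mul(Tensor(1.0 - y), ad.log(_one_minus(p))), -1.0))
    mask_loss = ad.tmean(bce)

    wc, wr, wm = cfg.loss_weights
    total = ad.add(ad.add(ad.mul(cls_loss, wc), ad.mul(reg_loss, wr)),
                   ad.mul(mask_loss, wm))
    return total, cls_loss, reg_loss, mask_loss


def _prepare_sequence(model: TwoStreamModel, frames: np.ndarray,
                      masks: np.ndarray, cfg: TrainConfig) -> dict:
    """Precompute network inputs and training targets for one sequence."""
    frames = np.asarray(frames, dtype=np.float32)
    masks = np.asarray(masks)
    if frames.ndim != 3 or frames.shape != masks.shape:
        raise ValueError("frames and masks must be (T, H, W) and aligned")
    if frames.shape[0] < 2:
        raise ValueError("training sequences need at least 2 frames")
    if frames.shape[1:] != tuple(model.config.input_shape):
        raise ValueError(f"sequences must be at the model input shape "
                         f"{model.config.input_shape}")
    binary = (masks >= 0.5).astype(np.float32)
    ref = np.stack([frames[0], binary[0]], axis=0)[None]
    guidance = binary[:-1]  # teacher forcing: previous ground truth
    main = np.stack([frames[1:], guidance], axis=1)

    acfg = model.config.anchor
    labels, targets, boxes, mtargets = [], [], [], []
    for t in range(1, frames.shape[0]):
        box = mask_to_box(binary[t])
        assign = anc.assign_anchors(model.anchors, box[None], acfg)
        labels.append(assign.labels)
        targets.append(assign.reg_targets)
        boxes.append(box)
        mtargets.append(_mask_target(binary[t], box, model.config.mask_size))
    return {
        "main": main, "ref": ref,
        "labels": np.stack(labels), "reg_targets": np.stack(targets),
        "gt_boxes": np.stack(boxes), "mask_targets": np.stack(mtargets),
    }


def evaluate_loss(model: TwoStreamModel, dataset, cfg: TrainConfig) -> dict:
    """Mean branch losses over a dataset, without updating weights."""
    prepared = [_prepare_sequence(model, f, m, cfg) for f, m in dataset]
    sums = np.zeros(4)
    for seq in prepared:
        out = _graph_losses(model, seq, cfg)
        sums += [float(t.data) for t in out]
    sums /= len(prepared)
    return {"total": sums[0], "cls": sums[1], "reg": sums[2], "mask": sums[3]}


def train_model(model: TwoStreamModel, dataset, cfg: TrainConfig) -> list[dict]:
    """Train end-to-end with SGD; returns the per-iteration loss history.

    ``dataset`` is a list of (frames, masks) arrays of shape (T, H, W) at
    the model's input shape, with full mask annotation.  Each iteration
    draws one sequence at random: the first frame feeds the reference
    stream, the remaining frames form the main-stream batch (guided by the
    previous frame's ground-truth mask under teacher forcing).
    """
    cfg.validate()
    if not dataset:
        raise ValueError("empty training dataset")
    if not cfg.teacher_forcing:
        raise NotImplementedError("only teacher-forced training is implemented")
    prepared = [_prepare_sequence(model, f, m, cfg) for f, m in dataset]
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    history: list[dict] = []
    for it in range(cfg.iterations):
        seq = prepared[int(rng.integers(len(prepared)))]
        total, cls_l, reg_l, mask_l = _graph_losses(model, seq, cfg)
        opt.zero_grad()
        total.backward()
        opt.step()
        history.append({"iteration": it, "total": float(total.data),
                        "cls": float(cls_l.data), "reg": float(reg_l.data),
                        "mask": float(mask_l.data)})
    if cfg.log_csv:
        with open(cfg.log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
    return history


# -- serialization ----------------------------------------------------------

def save_model(model: TwoStreamModel, path: str | Path) -> None:
    """Save all weights as an .npz archive."""
    np.savez(path, **model.state_dict())


def load_model(path: str | Path, config: NetworkConfig) -> TwoStreamModel:
    """Rebuild a model from a config and a saved .npz weight archive."""
    model = build_model(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def transfer_backbone(target: TwoStreamModel, source: TwoStreamModel) -> None:
    """Copy backbone weights from a trained model (heads stay as initialized)."""
    src = source.backbone.parameters()
    dst = target.backbone.parameters()
    if len(src) != len(dst):
        raise ValueError("backbone architectures differ")
    for s, d in zip(src, dst):
        if s.data.shape != d.data.shape:
            raise ValueError("backbone shapes differ; cannot transfer")
        d.data = s.data.copy()
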