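"""Anchor machinery for the single-class detection stage.

Anchors are prior boxes tiled over the five pyramid levels P3-P7 (strides
8-128, base areas 32^2-512^2), nine per location (three aspect ratios x
three scale multipliers).  This module generates them, assigns them to
ground-truth boxes by IoU bands ([0.5, 1] positive, [0, 0.4) background,
[0.4, 0.5) ignored), encodes/decodes box regression deltas, clips boxes to
the image, and filters raw predictions (per-level top-k, score threshold,
greedy non-maximum suppression).

Boxes are (x1, y1, x2, y2) float pixel coordinates, origin top-left,
x rightward, y downward, inclusive float extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnchorConfig",
    "AnchorSet",
    "BoxAssignment",
    "Detections",
    "generate_anchors",
    "iou_matrix",
    "assign_anchors",
    "encode_deltas",
    "decode_boxes",
    "clip_boxes",
    "filter_detections",
]

POSITIVE, BACKGROUND, IGNORE = 1, 0, -1


@dataclass(frozen=True)
class AnchorConfig:
    pyramid_levels: tuple[int, ...] = (3, 4, 5, 6, 7)
    strides: tuple[int, ...] = (8, 16, 32, 64, 128)
    base_sizes: tuple[int, ...] = (32, 64, 128, 256, 512)  # sqrt of base areas
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)     # width / height
    scale_multipliers: tuple[float, ...] = (2 ** 0, 2 ** (1 / 3), 2 ** (2 / 3))
    iou_positive: float = 0.5
    iou_background_upper: float = 0.4
    nms_iou: float = 0.5
    score_threshold: float = 0.5
    top_k_per_level: int = 1000
    delta_std: tuple[float, float, float, float] = (0.1, 0.1, 0.2, 0.2)

    @property
    def anchors_per_location(self) -> int:
        return len(self.aspect_ratios) * len(self.scale_multipliers)

    def validate(self) -> None:
        if not (len(self.pyramid_levels) == len(self.strides) == len(self.base_sizes)):
            raise ValueError("per-level tuples must have equal length")
        if not (0 <= self.iou_background_upper < self.iou_positive <= 1):
            raise ValueError("require 0 <= iou_background_upper < iou_positive <= 1")


@dataclass
class AnchorSet:
    boxes: np.ndarray            # (N, 4)
    levels: np.ndarray           # (N,) pyramid level of each box

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class BoxAssignment:
    labels: np.ndarray           # (N,) in {POSITIVE, BACKGROUND, IGNORE}
    matched_gt: np.ndarray       # (N,) gt index for positives, -1 otherwise
    reg_targets: np.ndarray      # (N, 4) encoded deltas, zeros for non-positives


@dataclass
class Detections:
    boxes: np.ndarray            # (K, 4), sorted by descending score
    scores: np.ndarray           # (K,)
    levels: np.ndarray           # (K,)

    def __len__(self) -> int:
        return len(self.boxes)


def _level_anchors(base_size: float, ratios, scales) -> np.ndarray:
    """The A anchor templates centred at the origin, ordered ratio-major."""
    templates = []
    for r in ratios:
        for s in scales:
            size = base_size * s
            w = size * np.sqrt(r)
            h = size / np.sqrt(r)
            templates.append([-w / 2, -h / 2, w / 2, h / 2])
    return np.asarray(templates, dtype=float)


def feature_shapes(config: AnchorConfig, input_shape) -> list[tuple[int, int]]:
    """Per-level feature-map shapes via ceil division of the input shape."""
    h, w = input_shape
    return [(int(np.ceil(h / s)), int(np.ceil(w / s))) for s in config.strides]


def generate_anchors(config: AnchorConfig, input_shape) -> AnchorSet:
    """Tile the A templates over every location of every pyramid level.

    Flattening order is (row, col, anchor) within each level, levels in
    ascending order — this must match how the head outputs are flattened.
    """
    config.validate()
    all_boxes, all_levels = [], []
    for level, stride, base in zip(config.pyramid_levels, config.strides,
                                   config.base_sizes):
        fh = int(np.ceil(input_shape[0] / stride))
        fw = int(np.ceil(input_shape[1] / stride))
        templates = _level_anchors(base, config.aspect_ratios,
                                   config.scale_multipliers)
        cx = (np.arange(fw) + 0.5) * stride
        cy = (np.arange(fh) + 0.5) * stride
        shift_x, shift_y = np.meshgrid(cx, cy)  # (fh, fw)
        shifts = np.stack([shift_x, shift_y, shift_x, shift_y], axis=-1)
        boxes = (shifts[:, :, None, :] + templates[None, None, :, :])
        all_boxes.append(boxes.reshape(-1, 4))
        all_levels.append(np.full(fh * fw * len(templates), level, dtype=int))
    return AnchorSet(boxes=np.concatenate(all_boxes),
                     levels=np.concatenate(all_levels))


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU with continuous box areas; zero-area boxes give IoU 0."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def _centers_extents(boxes: np.ndarray):
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    cx = boxes[:, 0] + 0.5 * w
    cy = boxes[:, 1] + 0.5 * h
    return cx, cy, w, h


def encode_deltas(anchor_boxes: np.ndarray, gt_boxes: np.ndarray,
                  std=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Normalized offsets (dx, dy, dw, dh) from anchors to target boxes."""
    a = np.asarray(anchor_boxes, dtype=float).reshape(-1, 4)
    g = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    ax, ay, aw, ah = _centers_extents(a)
    gx, gy, gw, gh = _centers_extents(g)
    if np.any(aw <= 0) or np.any(ah <= 0):
        raise ValueError("zero-extent anchor cannot be encoded")
    deltas = np.stack([(gx - ax) / aw, (gy - ay) / ah,
                       np.log(gw / aw), np.log(gh / ah)], axis=1)
    return deltas / np.asarray(std, dtype=float)


def decode_boxes(anchor_boxes: np.ndarray, deltas: np.ndarray,
                 std=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Exact inverse of :func:`encode_deltas`."""
    a = np.asarray(anchor_boxes, dtype=float).reshape(-1, 4)
    d = np.asarray(deltas, dtype=float).reshape(-1, 4) * np.asarray(std, dtype=float)
    ax, ay, aw, ah = _centers_extents(a)
    cx = ax + d[:, 0] * aw
    cy = ay + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def assign_anchors(anchors: AnchorSet | np.ndarray, gt_boxes: np.ndarray,
                   config: AnchorConfig) -> BoxAssignment:
    """Label each anchor by its best-IoU ground-truth match.

    max IoU >= 0.5 -> positive (matched to the argmax GT box), < 0.4 ->
    background, in [0.4, 0.5) -> ignored during training.  With no GT boxes
    every anchor is background.
    """
    boxes = anchors.boxes if isinstance(anchors, AnchorSet) else np.asarray(anchors)
    boxes = boxes.reshape(-1, 4)
    n = len(boxes)
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    labels = np.full(n, BACKGROUND, dtype=np.int8)
    matched = np.full(n, -1, dtype=int)
    targets = np.zeros((n, 4), dtype=float)
    if len(gt) == 0:
        return BoxAssignment(labels=labels, matched_gt=matched, reg_targets=targets)
    iou = iou_matrix(boxes, gt)
    best = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best]
    labels[(best_iou >= config.iou_background_upper)
           & (best_iou < config.iou_positive)] = IGNORE
    pos = best_iou >= config.iou_positive
    labels[pos] = POSITIVE
    matched[pos] = best[pos]
    if pos.any():
        targets[pos] = encode_deltas(boxes[pos], gt[best[pos]], config.delta_std)
    return BoxAssignment(labels=labels, matched_gt=matched, reg_targets=targets)


def clip_boxes(boxes: np.ndarray, input_shape) -> np.ndarray:
    """Clamp coordinates into [0, W] x [0, H] for an (H, W) image."""
    h, w = input_shape
    b = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    b[:, [0, 2]] = np.clip(b[:, [0, 2]], 0, w)
    b[:, [1, 3]] = np.clip(b[:, [1, 3]], 0, h)
    return b


def _greedy_nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Indices kept by greedy NMS; ties in score break to the lower index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        iou = iou_matrix(boxes[i], boxes).ravel()
        suppressed |= iou > iou_thr
        suppressed[i] = True
    return np.asarray(keep, dtype=int)


def filter_detections(boxes: np.ndarray, scores: np.ndarray, levels: np.ndarray,
                      config: AnchorConfig) -> Detections:
    """Per-level top-k, score threshold, then greedy NMS across levels.

    Survivors are returned sorted by descending score (ties by lower index).
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).ravel()
    levels = np.asarray(levels).ravel()
    cand = []
    for level in np.unique(levels):
        idx = np.flatnonzero(levels == level)
        if len(idx) > config.top_k_per_level:
            top = np.argsort(-scores[idx], kind="stable")[:config.top_k_per_level]
            idx = idx[top]
        cand.append(idx)
    idx = np.sort(np.concatenate(cand)) if cand else np.array([], dtype=int)
    idx = idx[scores[idx] >= config.score_threshold]
    if len(idx) == 0:
        empty = np.empty((0, 4))
        return Detections(boxes=empty, scores=np.empty(0), levels=np.empty(0, int))
    keep = _greedy_nms(boxes[idx], scores[idx], config.nms_iou)
    kept = idx[keep]
    order = np.lexsort((kept, -scores[kept]))
    kept = kept[order]
    return Detections(boxes=boxes[kept], scores=scores[kept], levels=levels[kept])
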