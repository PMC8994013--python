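"""Independent brute-force oracles shared by the anchor-machinery tests."""

import numpy as np

from echoseg import anchors as anc


def rasterized_iou(box_a, box_b, grid=40):
    """Pixel-counting IoU oracle on an integer grid (unit-cell coverage)."""
    canvas_a = np.zeros((grid, grid), dtype=bool)
    canvas_b = np.zeros((grid, grid), dtype=bool)
    x1, y1, x2, y2 = [int(v) for v in box_a]
    canvas_a[y1:y2, x1:x2] = True
    x1, y1, x2, y2 = [int(v) for v in box_b]
    canvas_b[y1:y2, x1:x2] = True
    union = (canvas_a | canvas_b).sum()
    return (canvas_a & canvas_b).sum() / union if union else 0.0


def brute_force_nms(boxes, scores, thr):
    """Independent O(n^2) greedy suppression with explicit loops."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep, dead = [], set()
    for i in order:
        if i in dead:
            continue
        keep.append(i)
        for j in order:
            if j == i or j in dead:
                continue
            if anc.iou_matrix(boxes[i], boxes[j])[0, 0] > thr:
                dead.add(j)
    return keep
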