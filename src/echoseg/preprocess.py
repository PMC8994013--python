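"""Sequence loading and network input preparation.

Frames are converted to single-channel grayscale, resized to 128x256
(height x width, preserving the landscape aspect of scan-converted echo
frames) and min-max normalized to [0, 1].  Annotation masks are binarized
and resized with nearest-neighbour interpolation so they stay strictly
binary.  Network inputs are two-channel stacks: the grayscale frame plus a
guidance mask (the previous frame's prediction for the main stream, the
user's ground-truth annotation for the reference stream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

TARGET_SHAPE = (128, 256)  # (height, width)

__all__ = [
    "EchoSequence",
    "TARGET_SHAPE",
    "load_sequence",
    "preprocess_frame",
    "binarize_mask",
    "resize_mask_nearest",
    "build_stream_input",
]


@dataclass
class EchoSequence:
    """A preprocessed grayscale sequence; values in [0, 1]."""

    frames: list[np.ndarray] = field(repr=False)
    original_height: int = 0
    original_width: int = 0
    pixel_spacing: float | None = None


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(np.float64)


def load_sequence(path: str | Path, spacing: float | None = None,
                  target_shape: tuple[int, int] = TARGET_SHAPE) -> EchoSequence:
    """Load an image stack (PNG/TIFF directory) or a video file as a sequence.

    Directory entries are taken in sorted filename order.  Every frame is
    preprocessed (grayscale, resize, min-max normalize).
    """
    import imageio.v3 as iio

    path = Path(path)
    raw: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        raw = [iio.imread(f) for f in files]
    elif path.is_file():
        raw = [np.asarray(fr) for fr in iio.imiter(path)]
        if not raw:
            raise ValueError(f"no frames decoded from {path}")
    else:
        raise ValueError(f"unreadable path: {path}")

    shapes = {np.asarray(f).shape[:2] for f in raw}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
    oh, ow = next(iter(shapes))
    frames = [preprocess_frame(_to_gray(f), target_shape) for f in raw]
    return EchoSequence(frames=frames, original_height=oh, original_width=ow,
                        pixel_spacing=spacing)


def preprocess_frame(frame: np.ndarray,
                     target_shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Resize (bilinear) to ``target_shape`` and min-max scale into [0, 1].

    A constant frame has no contrast to rescale; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if frame.shape != tuple(target_shape):
        frame = resize(frame, target_shape, order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    lo, hi = float(frame.min()), float(frame.max())
    if hi == lo:
        warnings.warn("constant frame: min-max normalization undefined, returning zeros")
        return np.zeros(target_shape, dtype=np.float32)
    return ((frame - lo) / (hi - lo)).astype(np.float32)


def binarize_mask(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold to {0, 1}: value 1 where mask >= threshold."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return (mask >= threshold).astype(np.uint8)


def resize_mask_nearest(mask: np.ndarray,
                        target_shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (keeps values in {0, 1})."""
    mask = np.asarray(mask)
    if mask.shape == tuple(target_shape):
        return mask.astype(np.uint8)
    out = resize(mask.astype(np.float64), target_shape, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out >= 0.5).astype(np.uint8)


def build_stream_input(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Stack [image, guidance mask] into a (2, H, W) network input."""
    frame = np.asarray(frame)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError(f"frame shape {frame.shape} != mask shape {mask.shape}")
    return np.stack([frame.astype(np.float32), mask.astype(np.float32)], axis=0)
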