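"""Clinical parameter extraction from ventricular mask sequences.

Left ventricle: three landmarks (apex and the two mitral-valve joints) are
located on the convex hull of each mask; the chamber length L is the
apex-to-mitral-midpoint distance, the area S is the foreground pixel count
scaled by the pixel spacing, and the single-plane area-length (modified
Simpson) rule V = 8*S^2 / (3*pi*L) converts them to a volume.  The frame of
maximal volume is end-diastole (ED), the minimal one end-systole (ES), and
EF = 100*(EDV - ESV)/EDV.

Right ventricle: the volume model does not apply and no reliable volumetric
ED/ES definition exists, so the phase frames must be supplied by the
operator; the module tracks the area over time and reports
FAC = 100*(EDA - ESA)/EDA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Keypoints",
    "LVReport",
    "RVReport",
    "find_lv_keypoints",
    "lv_length",
    "region_area",
    "simpson_volume",
    "detect_ed_es",
    "ejection_fraction",
    "quantify_lv_sequence",
    "quantify_rv_sequence",
]


@dataclass(frozen=True)
class Keypoints:
    """LV landmarks in (row, col) pixel coordinates, all on the convex hull."""

    apex: tuple[float, float]
    mitral_a: tuple[float, float]
    mitral_b: tuple[float, float]

    @property
    def mitral_mid(self) -> tuple[float, float]:
        return ((self.mitral_a[0] + self.mitral_b[0]) / 2.0,
                (self.mitral_a[1] + self.mitral_b[1]) / 2.0)


@dataclass
class LVReport:
    lengths: np.ndarray          # cm, per frame
    areas: np.ndarray            # cm^2, per frame
    volumes: np.ndarray          # mL, per frame
    empty_frames: np.ndarray = field(repr=False)  # bool flags, interpolated frames
    ed_index: int = 0
    es_index: int = 0
    edv: float = 0.0
    esv: float = 0.0
    ef: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": np.arange(len(self.volumes)),
            "length_cm": self.lengths,
            "area_cm2": self.areas,
            "volume_ml": self.volumes,
            "interpolated": self.empty_frames.astype(bool),
        })

    def summary(self) -> dict:
        return {"ed_index": int(self.ed_index), "es_index": int(self.es_index),
                "edv_ml": float(self.edv), "esv_ml": float(self.esv),
                "ef_percent": float(self.ef)}


@dataclass
class RVReport:
    areas: np.ndarray            # cm^2, per frame
    ed_index: int = 0
    es_index: int = 0
    eda: float = 0.0
    esa: float = 0.0
    fac: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frame": np.arange(len(self.areas)),
                             "area_cm2": self.areas})

    def summary(self) -> dict:
        return {"ed_index": int(self.ed_index), "es_index": int(self.es_index),
                "eda_cm2": float(self.eda), "esa_cm2": float(self.esa),
                "fac_percent": float(self.fac)}


def find_lv_keypoints(mask: np.ndarray, basal_band_frac: float = 0.3) -> Keypoints:
    """Locate apex and mitral joints on the mask's convex hull.

    The basal (mitral) side is the image top by convention.  The mitral
    joints are the endpoints of the longest hull edge whose midpoint lies in
    the basal band (top ``basal_band_frac`` of the mask's row extent) — on a
    chamber with a roughly flat mitral plane that plane is by far the
    longest near-basal hull edge.  The apex is the hull vertex farthest
    from the mitral chord line.
    """
    mask = np.asarray(mask)
    pts = np.argwhere(mask > 0).astype(float)  # (row, col)
    if pts.shape[0] == 0:
        raise ValueError("empty mask: no foreground pixels")
    if pts.shape[0] < 3:
        raise ValueError("mask too small for hull-based keypoints")
    try:
        hull = ConvexHull(pts[:, ::-1])  # (x=col, y=row) for qhull
    except QhullError as err:
        raise ValueError("degenerate mask: convex hull undefined") from err
    verts = pts[hull.vertices]  # (row, col), in hull order

    r_min, r_max = verts[:, 0].min(), verts[:, 0].max()
    band = r_min + max(1.0, basal_band_frac * (r_max - r_min))
    edges = np.stack([verts, np.roll(verts, -1, axis=0)], axis=1)  # (E, 2, 2)
    mid_rows = edges[:, :, 0].mean(axis=1)
    lengths = np.hypot(edges[:, 0, 0] - edges[:, 1, 0],
                       edges[:, 0, 1] - edges[:, 1, 1])
    in_band = mid_rows <= band
    if not in_band.any():
        in_band = mid_rows <= np.partition(mid_rows, 0)[0] + 1.0
    cand = np.flatnonzero(in_band)
    best = cand[np.argmax(lengths[cand])]
    left, right = edges[best, 0], edges[best, 1]
    if np.allclose(left, right):
        order = np.argsort(verts[:, 0])
        left, right = verts[order[0]], verts[order[1]]

    # apex: hull vertex with maximal perpendicular distance from the chord
    chord = right - left
    norm = np.hypot(*chord)
    if norm == 0:
        raise ValueError("mitral joints coincide; cannot define chord")
    rel = verts - left
    d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    apex = verts[int(np.argmax(d))]
    return Keypoints(apex=tuple(apex), mitral_a=tuple(left), mitral_b=tuple(right))


def lv_length(keypoints: Keypoints, spacing: float) -> float:
    """Chamber length in cm: apex to mitral-chord midpoint, times spacing."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    mid = keypoints.mitral_mid
    d = np.hypot(keypoints.apex[0] - mid[0], keypoints.apex[1] - mid[1])
    if d == 0:
        raise ValueError("apex coincides with the mitral midpoint")
    return float(d * spacing)


def region_area(mask: np.ndarray, spacing: float) -> float:
    """Area in cm^2: foreground pixel count times spacing^2."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask) * spacing * spacing)


def simpson_volume(area: float, length: float) -> float:
    """Single-plane area-length volume V = 8*S^2 / (3*pi*L), in mL.

    Assumes the chamber is symmetric about its long axis (prolate-ellipsoid
    single-plane model); cm^2 and cm in, cm^3 == mL out.
    """
    if length <= 0:
        raise ValueError("length must be strictly positive")
    if area < 0:
        raise ValueError("area must be nonnegative")
    return float(8.0 * area * area / (3.0 * np.pi * length))


def detect_ed_es(volumes) -> tuple[int, int]:
    """ED = argmax of the volume curve, ES = argmin; ties pick the earliest frame."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size < 2:
        raise ValueError("need at least 2 frames to detect ED/ES")
    if np.allclose(volumes, volumes[0]):
        warnings.warn("constant volume curve: ED/ES undefined, returning (0, 0)")
        return 0, 0
    return int(np.argmax(volumes)), int(np.argmin(volumes))


def ejection_fraction(edv: float, esv: float) -> float:
    """EF in percent: 100 * (EDV - ESV) / EDV."""
    if edv <= 0:
        raise ValueError("EDV must be strictly positive")
    if esv < 0:
        raise ValueError("ESV must be nonnegative")
    if esv > edv:
        raise ValueError("ESV exceeds EDV: ED/ES frames are mislabeled")
    return float(100.0 * (edv - esv) / edv)


def _interpolate_gaps(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linear interpolation over flagged frames (nearest-edge at the ends)."""
    out = values.astype(float).copy()
    good = ~bad
    idx = np.arange(len(values))
    out[bad] = np.interp(idx[bad], idx[good], values[good])
    return out


def quantify_lv_sequence(masks, spacing: float, keypoint_fn=find_lv_keypoints) -> LVReport:
    """Per-frame LV measures, ED/ES detection and EF from a mask sequence.

    Empty-mask frames are flagged and their measures linearly interpolated
    from neighbouring frames so a transient segmentation dropout cannot
    masquerade as end-systole.
    """
    masks = [np.asarray(m) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least 2 frames")
    n = len(masks)
    lengths = np.zeros(n)
    areas = np.zeros(n)
    empty = np.zeros(n, dtype=bool)
    for i, m in enumerate(masks):
        if np.count_nonzero(m) < 3:
            empty[i] = True
            continue
        kp = keypoint_fn(m)
        lengths[i] = lv_length(kp, spacing)
        areas[i] = region_area(m, spacing)
    if empty.all():
        raise ValueError("all frames are empty: nothing to quantify")
    if empty.any():
        lengths = _interpolate_gaps(lengths, empty)
        areas = _interpolate_gaps(areas, empty)
    volumes = np.array([simpson_volume(s, l) for s, l in zip(areas, lengths)])
    ed, es = detect_ed_es(volumes)
    edv, esv = float(volumes[ed]), float(volumes[es])
    ef = ejection_fraction(edv, esv) if edv > 0 else 0.0
    return LVReport(lengths=lengths, areas=areas, volumes=volumes,
                    empty_frames=empty, ed_index=ed, es_index=es,
                    edv=edv, esv=esv, ef=ef)


def quantify_rv_sequence(masks, spacing: float, ed_index: int, es_index: int) -> RVReport:
    """RV area trace and FAC between operator-chosen ED/ES frames.

    RV phase frames carry no volumetric definition in a single view, so
    ``ed_index``/``es_index`` must come from the operator; they are not
    inferred from the area curve.
    """
    if ed_index is None or es_index is None:
        raise ValueError("RV quantification requires operator-supplied ED/ES indices")
    masks = [np.asarray(m) for m in masks]
    n = len(masks)
    if not (0 <= ed_index < n and 0 <= es_index < n):
        raise ValueError("ED/ES indices out of range")
    areas = np.array([region_area(m, spacing) for m in masks])
    eda, esa = float(areas[ed_index]), float(areas[es_index])
    if eda <= 0:
        raise ValueError("end-diastolic area is zero: empty ED mask")
    fac = 100.0 * (eda - esa) / eda
    return RVReport(areas=areas, ed_index=ed_index, es_index=es_index,
                    eda=eda, esa=esa, fac=float(fac))
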