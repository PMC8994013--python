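"""Synthetic beating-ventricle phantom sequences.

Clinical four-chamber echocardiography series are rarely shareable, so this
module generates stand-in sequences with exact ground truth: a bright-walled
bullet-shaped chamber (an ellipse truncated by a flat basal plane, the
standard idealization of the LV in a four-chamber view) contracts smoothly
from end-diastole (ED) to end-systole (ES) and relaxes, rendered over a
dark cavity and a mid-gray background with multiplicative speckle-like
noise.  Every frame comes with its exact binary cavity mask, and the
cycle's volumes, ED/ES frame indices and ejection fraction are known in
closed form from the truncated-ellipse geometry and the single-plane
area-length rule V = 8*S^2 / (3*pi*L).

The chamber's long axis runs along image rows with the basal (mitral) side
at the image top, matching the convention used by the quantification
module.  The rendered clip starts at ED and ends at ``cycle_coverage`` of
the cycle (default 0.9), i.e. just before full relaxation, as cine clips
of a single beat typically do; this keeps the discrete ED frame unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from echoseg.quantify import simpson_volume

__all__ = [
    "PhantomSpec",
    "PhantomSequence",
    "generate_phantom_sequence",
    "analytic_cycle_truth",
    "random_phantom_spec",
    "save_sequence",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cardiac cycle.

    Lengths are in pixels, intensities in [0, 1], ``pixel_spacing`` in
    cm/pixel.  ``semi_axis_long_ed`` runs along rows (apex-to-base),
    ``semi_axis_short_ed`` along columns.  ``contraction_long`` and
    ``contraction_short`` are the fractional shrinkage of each semi-axis at
    end-systole; ``es_frame_fraction`` places ES within the unit cycle.
    ``basal_truncation`` is the fraction of the long semi-axis above the
    centre at which the flat mitral plane cuts the ellipse (0 = plane
    through the centre, i.e. a half-ellipse; 1 = no truncation).
    ``cycle_coverage`` is the portion of the cycle spanned by the clip.
    """

    n_frames: int = 14
    height: int = 384
    width: int = 288
    center: tuple[float, float] = (192.0, 144.0)
    semi_axis_long_ed: float = 150.0
    semi_axis_short_ed: float = 88.0
    contraction_long: float = 0.15
    contraction_short: float = 0.25
    es_frame_fraction: float = 0.4
    wall_intensity: float = 0.85
    cavity_intensity: float = 0.08
    background_intensity: float = 0.18
    wall_thickness: float = 12.0
    speckle_strength: float = 0.35
    pixel_spacing: float = 0.03
    basal_truncation: float = 0.6
    cycle_coverage: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a cycle needs at least 2 frames")
        if not (0.0 < self.es_frame_fraction < 1.0):
            raise ValueError("es_frame_fraction must be in (0, 1)")
        for name in ("contraction_long", "contraction_short"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.semi_axis_long_ed <= 0 or self.semi_axis_short_ed <= 0:
            raise ValueError("semi-axes must be strictly positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        if not (0.0 <= self.basal_truncation < 1.0):
            raise ValueError("basal_truncation must be in [0, 1)")
        if not (self.es_frame_fraction < self.cycle_coverage <= 1.0):
            raise ValueError("cycle_coverage must be in (es_frame_fraction, 1]")
        cr, cc = self.center
        margin_r = self.semi_axis_long_ed + self.wall_thickness
        margin_c = self.semi_axis_short_ed + self.wall_thickness
        if (cr - margin_r < 0 or cr + margin_r > self.height - 1
                or cc - margin_c < 0 or cc + margin_c > self.width - 1):
            raise ValueError(
                "end-diastolic ellipse (including wall ring) does not fit "
                f"inside the {self.height}x{self.width} image")


@dataclass
class PhantomSequence:
    """A rendered cycle with its exact ground truth."""

    spec: PhantomSpec
    frames: list[np.ndarray] = field(repr=False)
    masks: list[np.ndarray] = field(repr=False)
    true_volumes: list[float]
    true_ed_index: int
    true_es_index: int
    true_ef: float


def contraction_phase(t: np.ndarray | float, es_fraction: float) -> np.ndarray:
    """Smooth 0->1->0 contraction weight over one unit cycle.

    Piecewise half-cosine: 0 at t=0 (ED), 1 at t=es_fraction (ES), back to 0
    at t=1.  Single ED and single ES per cycle by construction.
    """
    t = np.asarray(t, dtype=float)
    w = np.where(
        t <= es_fraction,
        0.5 * (1.0 - np.cos(np.pi * t / es_fraction)),
        0.5 * (1.0 + np.cos(np.pi * (t - es_fraction) / (1.0 - es_fraction))),
    )
    return w


def _axes_at(spec: PhantomSpec, frame_index: np.ndarray | int):
    """Semi-axes (long, short) at the given frame index/indices.

    Frame k sits at t = k * cycle_coverage / (n_frames - 1), so frame 0 is
    exactly ED and the last frame stops short of the next ED.
    """
    t = (np.asarray(frame_index, dtype=float) * spec.cycle_coverage
         / (spec.n_frames - 1))
    w = contraction_phase(t, spec.es_frame_fraction)
    a = spec.semi_axis_long_ed * (1.0 - spec.contraction_long * w)
    b = spec.semi_axis_short_ed * (1.0 - spec.contraction_short * w)
    return a, b


def _chamber_mask(spec: PhantomSpec, a_row: float, b_col: float,
                  extra: float = 0.0) -> np.ndarray:
    """Filled truncated ellipse (bullet shape), optionally dilated by ``extra``."""
    rr, cc = np.ogrid[:spec.height, :spec.width]
    cr, ccen = spec.center
    a, b = a_row + extra, b_col + extra
    ell = ((rr - cr) / a) ** 2 + ((cc - ccen) / b) ** 2 <= 1.0
    plane_row = cr - spec.basal_truncation * a_row - extra
    return ell & (rr >= plane_row)


def _analytic_measures(spec: PhantomSpec, a: float, b: float):
    """Exact area (cm^2), length (cm) and Simpson volume (mL) of the chamber.

    For an ellipse with semi-axes (a, b) truncated at a flat plane a
    fraction ``t`` of the long semi-axis above the centre:
    S = a*b*(pi/2 + t*sqrt(1-t^2) + asin(t)), L = a*(1+t).
    """
    sp = spec.pixel_spacing
    t = spec.basal_truncation
    area = a * b * (np.pi / 2 + t * np.sqrt(1 - t * t) + np.arcsin(t)) * sp * sp
    length = a * (1.0 + t) * sp
    return area, length, simpson_volume(area, length)


def generate_phantom_sequence(spec: PhantomSpec) -> PhantomSequence:
    """Render one seeded cycle: frames, exact masks and analytic truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    volumes: list[float] = []
    for k in range(spec.n_frames):
        a, b = _axes_at(spec, k)
        cavity = _chamber_mask(spec, a, b)
        outer = _chamber_mask(spec, a, b, extra=spec.wall_thickness)
        img = np.full((spec.height, spec.width), spec.background_intensity)
        img[outer] = spec.wall_intensity
        img[cavity] = spec.cavity_intensity
        if spec.speckle_strength > 0:
            noise = rng.uniform(-1.0, 1.0, size=img.shape)
            img = img * (1.0 + spec.speckle_strength * noise)
        img = np.clip(img, 0.0, 1.0)
        frames.append(img.astype(np.float32))
        masks.append(cavity.astype(np.uint8))
        volumes.append(_analytic_measures(spec, a, b)[2])

    ed, es, ef = analytic_cycle_truth(spec)
    return PhantomSequence(spec=spec, frames=frames, masks=masks,
                           true_volumes=volumes, true_ed_index=ed,
                           true_es_index=es, true_ef=ef)


def analytic_cycle_truth(spec: PhantomSpec) -> tuple[int, int, float]:
    """ED/ES frame indices and ejection fraction from the analytic shapes.

    EF = 100 * (V_ED - V_ES) / V_ED with volumes from V = 8*S^2/(3*pi*L)
    evaluated on the exact per-frame ellipse area and length.  Ties in the
    volume curve resolve to the earliest frame.
    """
    spec.validate()
    k = np.arange(spec.n_frames)
    a, b = _axes_at(spec, k)
    vols = np.array([_analytic_measures(spec, ai, bi)[2] for ai, bi in zip(a, b)])
    ed = int(np.argmax(vols))
    es = int(np.argmin(vols))
    ef = 100.0 * (vols[ed] - vols[es]) / vols[ed]
    return ed, es, float(ef)


def random_phantom_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Draw a realistic random cycle specification.

    Ranges bracket adult four-chamber LV geometry rendered at a native
    resolution fine enough for pixel-level quantification: ED long
    semi-axis 135-175 px, short 70-105 px, longitudinal shortening
    12-20 %, radial shortening 20-30 %, spacing 0.025-0.04 cm/px (so
    lengths span 7-10 cm and ED volumes roughly 60-140 mL).  The ES
    position is snapped onto the frame grid, and the temporal sampling
    (10-14 frames over 90 % of a cycle) keeps adjacent-frame volume gaps
    comfortably above pixel-rounding noise, so the discrete ED/ES frames
    are unambiguous.
    """
    n_frames = int(overrides.pop("n_frames", rng.integers(10, 15)))
    coverage = float(overrides.pop("cycle_coverage", 0.9))
    # snap ES onto the frame grid so the discrete volume minimum is unambiguous
    es_target = float(rng.uniform(0.35, 0.45))
    es_k = int(np.clip(round(es_target * (n_frames - 1) / coverage),
                       2, n_frames - 2))
    defaults = dict(
        n_frames=n_frames,
        cycle_coverage=coverage,
        semi_axis_long_ed=float(rng.uniform(135, 175)),
        semi_axis_short_ed=float(rng.uniform(70, 105)),
        contraction_long=float(rng.uniform(0.12, 0.20)),
        contraction_short=float(rng.uniform(0.20, 0.30)),
        es_frame_fraction=es_k * coverage / (n_frames - 1),
        speckle_strength=float(rng.uniform(0.2, 0.5)),
        pixel_spacing=float(rng.uniform(0.025, 0.04)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    defaults.update(overrides)
    spec = PhantomSpec(**defaults)
    # recentre so the chamber always fits
    margin_r = spec.semi_axis_long_ed + spec.wall_thickness
    margin_c = spec.semi_axis_short_ed + spec.wall_thickness
    if (margin_r > spec.height / 2 - 1) or (margin_c > spec.width / 2 - 1):
        raise ValueError("sampled chamber does not fit the default image size")
    return spec


def save_sequence(seq: PhantomSequence, outdir: str | Path) -> Path:
    """Write frames/masks as PNG stacks plus a JSON manifest; returns the dir."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for i, (frame, mask) in enumerate(zip(seq.frames, seq.masks)):
        iio.imwrite(outdir / "frames" / f"frame_{i:04d}.png",
                    (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        iio.imwrite(outdir / "masks" / f"mask_{i:04d}.png",
                    (mask * 255).astype(np.uint8))
    manifest = {
        "spec": asdict(seq.spec),
        "pixel_spacing": seq.spec.pixel_spacing,
        "true_volumes": seq.true_volumes,
        "true_ed_index": seq.true_ed_index,
        "true_es_index": seq.true_es_index,
        "true_ef": seq.true_ef,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
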