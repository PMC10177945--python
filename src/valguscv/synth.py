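"""Synthetic marker photographs and simulated measurement tables.

The study's raw photographs are not deposited, so every pipeline stage is
exercised against generated data with exact ground truth:

* :func:`render_scene` draws anti-aliased colored disc markers (plus
  optional disc/bar distractors) on a plain or gradient background, adds
  Gaussian pixel noise and an optional JPEG round-trip, and emits a truth
  record with the landmark coordinates and analytic angle.
* :func:`scene_for_angle` constructs marker placements whose patella
  vertex angle equals a prescribed value to machine precision.
* :func:`simulate_table` draws measurement tables from the two-way
  random-effects model Y[i,j] = mu + s_i + c_j + e_ij that underlies the
  ICC analysis, at the study scale (42 athletes, 2 conditions, grand mean
  158.54 deg, total SD 5.22 deg).

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from PIL import Image

from .detect import ImageFrame, LandmarkTriple
from .errors import DoesNotFit, Infeasible, SpecOutOfBounds
from .geometry import AngleRecord, knee_valgus_angle
from .reliability import MeasurementTable

MARKER_RGB = {"red": (220, 30, 30), "blue": (30, 60, 220)}
#: adversarial distractor palette: desaturated skin tone and clothing colors
SKIN_RGB = (224, 172, 138)
SHIRT_RGB = (40, 160, 60)

__all__ = [
    "Distractor",
    "SceneSpec",
    "TableSpec",
    "render_scene",
    "scene_for_angle",
    "simulate_table",
    "icc_to_variances",
]


@dataclass(frozen=True)
class Distractor:
    """A non-marker blob: a disc (radius set) or a bar (length/width set)."""

    center_xy: tuple[float, float]
    rgb: tuple[int, int, int]
    radius_px: Optional[float] = None
    bar_length_px: Optional[float] = None
    bar_width_px: Optional[float] = None
    bar_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        is_disc = self.radius_px is not None
        is_bar = self.bar_length_px is not None and self.bar_width_px is not None
        if is_disc == is_bar:
            raise SpecOutOfBounds("distractor must be either a disc or a bar")


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic marker photograph."""

    landmarks_truth: LandmarkTriple
    image_size: tuple[int, int] = (800, 1200)  # (width, height)
    marker_radius_px: float = 9.0
    marker_color: Literal["red", "blue"] = "red"
    noise_sigma: float = 0.0  # on the 0-1 intensity scale
    jpeg_quality: Optional[int] = None  # None = lossless PNG semantics
    background: Literal["plain", "gradient"] = "plain"
    distractors: tuple[Distractor, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if not (0.0 <= self.noise_sigma <= 0.25):
            raise SpecOutOfBounds(f"noise_sigma must lie in [0, 0.25], got {self.noise_sigma}")
        if self.jpeg_quality is not None and not (1 <= self.jpeg_quality <= 100):
            raise SpecOutOfBounds("jpeg_quality must lie in [1, 100]")
        if self.marker_color not in MARKER_RGB:
            raise SpecOutOfBounds(f"marker_color must be one of {sorted(MARKER_RGB)}")
        lm = self.landmarks_truth
        r = self.marker_radius_px
        for x, y in (lm.asis_xy, lm.patella_xy, lm.att_xy):
            if not (r <= x <= w - 1 - r and r <= y <= h - 1 - r):
                raise SpecOutOfBounds(f"marker at ({x:.0f}, {y:.0f}) r={r} exceeds {w}x{h} canvas")
        for d in self.distractors:
            extent = d.radius_px if d.radius_px is not None else max(d.bar_length_px, d.bar_width_px) / 2
            x, y = d.center_xy
            if not (extent <= x <= w - 1 - extent and extent <= y <= h - 1 - extent):
                raise SpecOutOfBounds(f"distractor at ({x:.0f}, {y:.0f}) exceeds canvas")

    @property
    def truth_angle_deg(self) -> float:
        return knee_valgus_angle(self.landmarks_truth)


def _disc_coverage(shape: tuple[int, int], center_xy: tuple[float, float], radius: float) -> np.ndarray:
    """Per-pixel coverage of an anti-aliased disc, in [0, 1].

    Linear edge model: full inside radius-0.5, zero outside radius+0.5.
    """
    h, w = shape
    cx, cy = center_xy
    pad = int(math.ceil(radius)) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.zeros(shape, dtype=np.float64)
    cov[y0:y1, x0:x1] = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return cov


def _bar_coverage(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    length: float,
    width: float,
    angle_deg: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(angle_deg)
    u = (xx - center_xy[0]) * math.cos(th) + (yy - center_xy[1]) * math.sin(th)
    v = -(xx - center_xy[0]) * math.sin(th) + (yy - center_xy[1]) * math.cos(th)
    along = np.clip(length / 2 + 0.5 - np.abs(u), 0.0, 1.0)
    across = np.clip(width / 2 + 0.5 - np.abs(v), 0.0, 1.0)
    return along * across


def _composite(canvas: np.ndarray, coverage: np.ndarray, rgb: tuple[int, int, int]) -> None:
    color = np.array(rgb, dtype=np.float64) / 255.0
    canvas *= (1.0 - coverage)[..., None]
    canvas += coverage[..., None] * color


def render_scene(spec: SceneSpec) -> tuple[ImageFrame, dict]:
    """Render one scene; returns the image and its ground-truth record.

    Deterministic for a fixed spec (two renders from the same seed are
    byte-identical). The truth record carries the landmark coordinates,
    the analytic vertex angle, and the render settings.
    """
    w, h = spec.image_size
    if spec.background == "plain":
        canvas = np.full((h, w, 3), 110.0 / 255.0, dtype=np.float64)
    else:
        ramp = np.linspace(0.30, 0.60, h)[:, None, None]
        canvas = np.broadcast_to(ramp, (h, w, 3)).copy()

    for d in spec.distractors:
        if d.radius_px is not None:
            cov = _disc_coverage((h, w), d.center_xy, d.radius_px)
        else:
            cov = _bar_coverage((h, w), d.center_xy, d.bar_length_px, d.bar_width_px, d.bar_angle_deg)
        _composite(canvas, cov, d.rgb)

    lm = spec.landmarks_truth
    for xy in (lm.asis_xy, lm.patella_xy, lm.att_xy):
        _composite(canvas, _disc_coverage((h, w), xy, spec.marker_radius_px), MARKER_RGB[spec.marker_color])

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)

    pixels = np.clip(np.round(canvas * 255.0), 0, 255).astype(np.uint8)

    if spec.jpeg_quality is not None:
        buf = _io.BytesIO()
        Image.fromarray(pixels).save(buf, format="JPEG", quality=spec.jpeg_quality)
        buf.seek(0)
        pixels = np.asarray(Image.open(buf).convert("RGB"), dtype=np.uint8)

    truth = {
        "landmarks": lm.as_dict(),
        "angle_deg": spec.truth_angle_deg,
        "marker_radius_px": spec.marker_radius_px,
        "marker_color": spec.marker_color,
        "noise_sigma": spec.noise_sigma,
        "jpeg_quality": spec.jpeg_quality,
        "image_size": [w, h],
        "seed": spec.seed,
    }
    return ImageFrame(pixels=pixels, source_path="<synthetic>"), truth


def write_scene(spec: SceneSpec, image_path: str | Path, truth_path: str | Path | None = None) -> dict:
    """Render and save a scene to PNG/JPEG plus a truth JSON sidecar."""
    frame, truth = render_scene(spec)
    image_path = Path(image_path)
    image_path.parent.mkdir(parents=True, exist_ok=True)
    im = Image.fromarray(frame.pixels)
    if image_path.suffix.lower() in (".jpg", ".jpeg"):
        im.save(image_path, quality=spec.jpeg_quality or 95)
    else:
        im.save(image_path)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=1))
    return truth


def scene_for_angle(
    theta_deg: float,
    image_size: tuple[int, int] = (800, 1200),
    upper_ray_px: float = 420.0,
    lower_ray_px: float = 360.0,
    vertex_xy: Optional[tuple[float, float]] = None,
    marker_radius_px: float = 9.0,
    **scene_kwargs,
) -> SceneSpec:
    """Build a SceneSpec whose vertex angle equals ``theta_deg`` exactly.

    The patella sits at ``vertex_xy`` (default slightly below canvas
    center); the ASIS and ATT rays leave it at bearings +/-(180-theta)/2
    about the vertical, so the included angle is theta by construction and
    the top-to-bottom landmark ordering holds for theta > 10 deg.
    """
    if not (10.0 < theta_deg <= 180.0):
        raise DoesNotFit(f"theta must lie in (10, 180], got {theta_deg}")
    w, h = image_size
    if vertex_xy is None:
        vertex_xy = (w / 2.0, h * 0.55)
    half = math.radians((180.0 - theta_deg) / 2.0)
    px, py = vertex_xy
    asis = (px + upper_ray_px * math.sin(half), py - upper_ray_px * math.cos(half))
    att = (px + lower_ray_px * math.sin(half), py + lower_ray_px * math.cos(half))
    r = marker_radius_px
    for x, y in (asis, vertex_xy, att):
        if not (r <= x <= w - 1 - r and r <= y <= h - 1 - r):
            raise DoesNotFit(
                f"landmark ({x:.0f}, {y:.0f}) with radius {r} does not fit {w}x{h} canvas"
            )
    triple = LandmarkTriple(asis_xy=asis, patella_xy=vertex_xy, att_xy=att)
    return SceneSpec(
        landmarks_truth=triple,
        image_size=image_size,
        marker_radius_px=marker_radius_px,
        **scene_kwargs,
    )


# ----------------------------------------------------------------------
# measurement tables


@dataclass(frozen=True)
class TableSpec:
    """Two-way random-effects simulation spec for a measurement table.

    Defaults mirror the validation study's scale: 42 athletes measured
    twice, cohort mean 158.54 deg. Under this model the population
    ICC(2,1) is sigma_s^2 / (sigma_s^2 + sigma_c^2 + sigma_e^2).
    """

    n_subjects: int = 42
    grand_mean_deg: float = 158.54
    sd_subject: float = 5.04
    sd_condition: float = 0.5
    sd_error: float = 1.26
    n_conditions: int = 2
    design: str = "test_retest"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_subject, self.sd_condition, self.sd_error) < 0:
            raise ValueError("all SDs must be >= 0")
        if self.n_subjects < 1 or self.n_conditions < 2:
            raise ValueError("need n_subjects >= 1 and n_conditions >= 2")

    @property
    def implied_icc(self) -> float:
        tot = self.sd_subject**2 + self.sd_condition**2 + self.sd_error**2
        return self.sd_subject**2 / tot if tot > 0 else 0.0


#: condition labels per design: (column values for condition j=0, j=1, ...)
_CONDITION_LABELS = {
    "test_retest": [("R1", 1, "cv_app"), ("R1", 2, "cv_app")],
    "inter_rater": [("R1", 1, "cv_app"), ("R2", 1, "cv_app")],
    "inter_instrument": [("R1", 1, "cv_app"), ("R3", 1, "kinovea")],
}


def simulate_table(spec: TableSpec) -> MeasurementTable:
    """Draw a long-format measurement table from the two-way model.

    Y[i,j] = mu + s_i + c_j + e_ij with independent zero-mean Gaussian
    subject, condition and error effects at the spec's SDs. Angles are
    clipped to (0, 180] only in the pathological tail (the defaults sit
    ~4 SD from either bound).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_conditions
    s = rng.normal(0.0, spec.sd_subject, size=n)
    c = rng.normal(0.0, spec.sd_condition, size=k)
    e = rng.normal(0.0, spec.sd_error, size=(n, k))
    y = spec.grand_mean_deg + s[:, None] + c[None, :] + e
    y = np.clip(y, 1e-6, 180.0)

    labels = _CONDITION_LABELS.get(spec.design)
    if labels is None or len(labels) < k:
        labels = [(f"R{j + 1}", 1, "cv_app") for j in range(k)]
    records = []
    width = len(str(n))
    for i in range(n):
        for j in range(k):
            rater, occ, instr = labels[j]
            records.append(
                AngleRecord(
                    angle_deg=float(y[i, j]),
                    subject_id=f"S{i + 1:0{width}d}",
                    rater_id=rater,
                    occasion=occ,
                    instrument=instr,
                )
            )
    return MeasurementTable.from_records(records, design=spec.design)


def icc_to_variances(
    target_icc: float, total_sd: float, condition_sd: float = 0.0
) -> tuple[float, float]:
    """Solve for (sd_subject, sd_error) achieving a target population ICC.

    Given the total SD and condition SD, sets sigma_s^2 = ICC * sigma_tot^2
    and sigma_e^2 = sigma_tot^2 - sigma_s^2 - sigma_c^2. Raises
    :class:`Infeasible` when the condition variance exceeds the non-subject
    share of the total variance.
    """
    if not (0.0 <= target_icc < 1.0):
        raise Infeasible(f"target ICC must lie in [0, 1), got {target_icc}")
    if total_sd < 0 or condition_sd < 0:
        raise Infeasible("SDs must be >= 0")
    var_tot = total_sd**2
    var_s = target_icc * var_tot
    var_e = var_tot - var_s - condition_sd**2
    if var_e < -1e-12:
        raise Infeasible(
            f"condition variance {condition_sd**2:.4g} exceeds the non-subject "
            f"variance {(1 - target_icc) * var_tot:.4g}"
        )
    return math.sqrt(var_s), math.sqrt(max(var_e, 0.0))
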