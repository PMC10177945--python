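"""Colored-marker detection for frontal single-leg-squat photographs.

The measurement protocol places three saturated circular markers (red or
blue) on the anterior superior iliac spine (ASIS), the midpoint of the
patella, and the anterior tibial tuberosity (ATT). This module finds those
markers by HSV thresholding + connected-component analysis, filters
candidates by area and circularity, and assigns the surviving centroids to
anatomical roles by their vertical order (ASIS topmost, ATT bottommost).

Coordinates are image-native: 0-based, origin at the top-left corner,
x rightward, y downward, sub-pixel centroids as floats.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from skimage import measure
from skimage.color import rgb2hsv

from .errors import (
    AmbiguousOrdering,
    ConfigInvalid,
    ImageTooSmall,
    TooFewMarkers,
)

MIN_IMAGE_SIDE = 64

__all__ = [
    "CaptureMeta",
    "ImageFrame",
    "MarkerBlob",
    "LandmarkTriple",
    "ColorWindow",
    "DetectionConfig",
    "segment_markers",
    "assign_landmarks",
    "detect_landmarks",
    "detection_report",
]


@dataclass(frozen=True)
class CaptureMeta:
    """Camera placement metadata, carried through verbatim.

    The study protocol fixes the camera 2 m from the subject at 1.05 m
    height; neither value enters the angle computation (the vertex angle is
    scale-free) but both are preserved for provenance.
    """

    camera_distance_m: float = 2.0
    camera_height_m: float = 1.05


@dataclass(frozen=True)
class ImageFrame:
    """An 8-bit RGB photograph plus provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_path: str = ""
    capture_meta: CaptureMeta | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ConfigInvalid(
                f"pixels must be (H, W, 3) uint8, got shape {px.shape} dtype {px.dtype}"
            )
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ImageTooSmall(
                f"image is {px.shape[1]}x{px.shape[0]} px; minimum is "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_file(cls, path: str | Path, capture_meta: CaptureMeta | None = None) -> "ImageFrame":
        """Read a PNG or JPEG; an alpha channel, if present, is dropped."""
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            px = np.asarray(rgb, dtype=np.uint8)
        return cls(pixels=px, source_path=str(path), capture_meta=capture_meta)


@dataclass(frozen=True)
class MarkerBlob:
    """A candidate marker: one connected component that passed all filters.

    ``circularity`` is 4*pi*area/perimeter^2 — 1 for a perfect disc. Digital
    discs can nominally exceed 1; values are clipped at 1.05.
    """

    centroid_xy: tuple[float, float]
    area_px: float
    circularity: float
    color_class: str  # "red" | "blue"

    def as_dict(self) -> dict:
        return {
            "centroid_xy": [round(c, 3) for c in self.centroid_xy],
            "area_px": float(self.area_px),
            "circularity": round(float(self.circularity), 4),
            "color_class": self.color_class,
        }


@dataclass(frozen=True)
class LandmarkTriple:
    """The three anatomical points in image coordinates (x, y).

    Invariants: strictly ordered top-to-bottom (asis.y < patella.y < att.y)
    and pairwise separated by more than 1 px.
    """

    asis_xy: tuple[float, float]
    patella_xy: tuple[float, float]
    att_xy: tuple[float, float]

    def __post_init__(self) -> None:
        a, p, t = self.asis_xy, self.patella_xy, self.att_xy
        if not (a[1] < p[1] < t[1]):
            raise AmbiguousOrdering(
                f"landmarks not strictly ordered top-to-bottom: "
                f"y = {a[1]:.2f}, {p[1]:.2f}, {t[1]:.2f}"
            )
        for u, v, names in ((a, p, "ASIS/patella"), (p, t, "patella/ATT"), (a, t, "ASIS/ATT")):
            if math.dist(u, v) <= 1.0:
                raise AmbiguousOrdering(f"{names} closer than 1 px")

    def as_dict(self) -> dict:
        return {
            "asis_xy": list(self.asis_xy),
            "patella_xy": list(self.patella_xy),
            "att_xy": list(self.att_xy),
        }


@dataclass(frozen=True)
class ColorWindow:
    """HSV acceptance window for one marker color.

    ``hue_deg`` is a list of [lo, hi] intervals in degrees; red wraps the
    hue origin so it needs two. ``sat_min``/``val_min`` floors exclude skin
    and shadow, which are desaturated relative to the markers (saturated
    disc interiors sit near S = 0.85; the 0.5 floor also trims low-coverage
    anti-aliased rim pixels so tiny speckles keep a small footprint).
    """

    hue_deg: tuple[tuple[float, float], ...]
    sat_min: float = 0.5
    val_min: float = 0.25


DEFAULT_WINDOWS: Mapping[str, ColorWindow] = {
    "red": ColorWindow(hue_deg=((345.0, 360.0), (0.0, 15.0))),
    "blue": ColorWindow(hue_deg=((200.0, 260.0),)),
}


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for marker segmentation.

    Area bounds are in pixel space (the physical marker diameter maps to an
    unknown pixel size, so no physical units here); defaults admit discs of
    radius roughly 3-40 px. ``min_circularity`` 0.6 rejects bars and
    irregular clothing blobs while tolerating partially occluded discs.
    """

    color_targets: tuple[str, ...] = ("red", "blue")
    min_area_px: float = 20.0
    max_area_px: float = 5000.0
    min_circularity: float = 0.6
    hue_windows: Mapping[str, ColorWindow] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    def validate(self) -> None:
        if not self.color_targets:
            raise ConfigInvalid("at least one color target required")
        unknown = set(self.color_targets) - set(self.hue_windows)
        if unknown:
            raise ConfigInvalid(f"no hue window for color target(s): {sorted(unknown)}")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ConfigInvalid(
                f"need 0 < min_area_px < max_area_px, got "
                f"[{self.min_area_px}, {self.max_area_px}]"
            )
        if not (0.0 <= self.min_circularity <= 1.0):
            raise ConfigInvalid("min_circularity must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hue_windows"] = {
            c: {"hue_deg": [list(iv) for iv in w.hue_deg], "sat_min": w.sat_min, "val_min": w.val_min}
            for c, w in self.hue_windows.items()
        }
        return d


def color_mask(hsv: np.ndarray, window: ColorWindow) -> np.ndarray:
    """Boolean mask of pixels inside one HSV window (hue of ``hsv`` in [0,1])."""
    hue_deg = hsv[..., 0] * 360.0
    in_hue = np.zeros(hsv.shape[:2], dtype=bool)
    for lo, hi in window.hue_deg:
        in_hue |= (hue_deg >= lo) & (hue_deg <= hi)
    return in_hue & (hsv[..., 1] >= window.sat_min) & (hsv[..., 2] >= window.val_min)


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # single-pixel / degenerate component: treat as round
    return min(4.0 * math.pi * area / perimeter**2, 1.05)


def segment_markers(image: ImageFrame, config: DetectionConfig | None = None) -> list[MarkerBlob]:
    """Find all marker-like blobs of the configured colors.

    Pixels are thresholded per color in HSV space; 8-connected components
    are filtered by area in [min_area_px, max_area_px] and circularity
    >= min_circularity. Each survivor is returned with a
    saturation*value-weighted sub-pixel centroid (near-constant weights
    inside a uniform disc, tapering at the anti-aliased rim), sorted by
    descending area. The list may be empty.
    """
    config = config or DetectionConfig()
    config.validate()

    rgb01 = image.pixels.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb01)
    weights = hsv[..., 1] * hsv[..., 2]

    blobs: list[MarkerBlob] = []
    for color in config.color_targets:
        mask = color_mask(hsv, config.hue_windows[color])
        if not mask.any():
            continue
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels, intensity_image=weights):
            area = float(region.area)
            if not (config.min_area_px <= area <= config.max_area_px):
                continue
            circ = _circularity(area, float(region.perimeter_crofton))
            if circ < config.min_circularity:
                continue
            cy, cx = region.centroid_weighted
            blobs.append(
                MarkerBlob(
                    centroid_xy=(float(cx), float(cy)),
                    area_px=area,
                    circularity=circ,
                    color_class=color,
                )
            )
    blobs.sort(key=lambda b: (-b.area_px, -b.circularity, b.centroid_xy[1]))
    return blobs


def assign_landmarks(blobs: Sequence[MarkerBlob]) -> LandmarkTriple:
    """Assign the three largest blobs to ASIS / patella / ATT by height.

    With more than three candidates the three with the largest area are
    kept (ties broken by higher circularity, then smaller y); the trio is
    then sorted by ascending y: topmost = ASIS, middle = patella midpoint,
    bottom = ATT. Raises :class:`TooFewMarkers` below three blobs and
    :class:`AmbiguousOrdering` when any two selected centroids are within
    2 px vertically (the top-to-bottom assignment would be unreliable).
    """
    if not blobs:
        raise TooFewMarkers("no candidate blobs")
    if len(blobs) < 3:
        raise TooFewMarkers(f"need 3 markers, found {len(blobs)}")
    ranked = sorted(blobs, key=lambda b: (-b.area_px, -b.circularity, b.centroid_xy[1]))
    chosen = sorted(ranked[:3], key=lambda b: b.centroid_xy[1])
    ys = [b.centroid_xy[1] for b in chosen]
    if ys[1] - ys[0] < 2.0 or ys[2] - ys[1] < 2.0:
        raise AmbiguousOrdering(
            f"selected centroids too close vertically (y = {ys[0]:.1f}, {ys[1]:.1f}, {ys[2]:.1f})"
        )
    return LandmarkTriple(
        asis_xy=chosen[0].centroid_xy,
        patella_xy=chosen[1].centroid_xy,
        att_xy=chosen[2].centroid_xy,
    )


def detect_landmarks(
    image: ImageFrame, config: DetectionConfig | None = None
) -> tuple[LandmarkTriple, list[MarkerBlob]]:
    """Convenience: segment then assign; returns (triple, all blobs)."""
    blobs = segment_markers(image, config)
    return assign_landmarks(blobs), blobs


def detection_report(
    image: ImageFrame,
    config: DetectionConfig | None = None,
    blobs: Iterable[MarkerBlob] | None = None,
    triple: LandmarkTriple | None = None,
    error: Exception | None = None,
) -> dict:
    """Build the per-image JSON-serializable detection report."""
    config = config or DetectionConfig()
    warnings: list[str] = []
    if blobs is not None and len(list(blobs)) > 3:
        warnings.append(f"{len(list(blobs)) - 3} extra blob(s) discarded as distractors")
    report = {
        "source_path": image.source_path,
        "image_size": [image.width_px, image.height_px],
        "capture_meta": dataclasses.asdict(image.capture_meta) if image.capture_meta else None,
        "config": config.as_dict(),
        "blobs": [b.as_dict() for b in (blobs or [])],
        "landmarks": triple.as_dict() if triple is not None else None,
        "warnings": warnings,
    }
    if error is not None:
        report["error"] = {"type": type(error).__name__, "message": str(error)}
    return report
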