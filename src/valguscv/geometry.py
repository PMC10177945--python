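"""Knee valgus angle from the three marker landmarks.

The knee valgus angle is the frontal-plane angle at the patella vertex
between the ray to the ASIS and the ray to the anterior tibial tuberosity:
180 deg is a perfectly straight limb; smaller values mean more medial
(valgus) collapse. Healthy single-leg-squat cohorts sit near 155-160 deg,
so the interior (obtuse-side) vertex angle is reported, never its
supplement. The angle is invariant under translation, rotation, uniform
scaling and mirroring of the image, so no pixel calibration is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .detect import LandmarkTriple
from .errors import DegenerateGeometry

INSTRUMENTS = ("cv_app", "kinovea", "other")

__all__ = ["knee_valgus_angle", "valgus_deviation", "AngleRecord", "records_to_frame"]


def knee_valgus_angle(triple: LandmarkTriple) -> float:
    """Interior angle (degrees) at the patella between the ASIS and ATT rays.

    Computed as the arc-cosine of the normalized dot product of
    patella->ASIS and patella->ATT; the result lies in (0, 180]. Raises
    :class:`DegenerateGeometry` if either ray is shorter than 1 px.
    """
    px, py = triple.patella_xy
    u = (triple.asis_xy[0] - px, triple.asis_xy[1] - py)
    v = (triple.att_xy[0] - px, triple.att_xy[1] - py)
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu < 1.0 or nv < 1.0:
        raise DegenerateGeometry(
            f"ray length below 1 px (ASIS ray {nu:.3f}, ATT ray {nv:.3f})"
        )
    cos_theta = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    cos_theta = max(-1.0, min(1.0, cos_theta))
    return math.degrees(math.acos(cos_theta))


def valgus_deviation(angle_deg: float) -> float:
    """Deviation from collinearity: 180 - angle, in [0, 180)."""
    if not (0.0 < angle_deg <= 180.0):
        raise ValueError(f"angle must lie in (0, 180], got {angle_deg}")
    return 180.0 - angle_deg


@dataclass(frozen=True)
class AngleRecord:
    """One measured knee valgus angle with its provenance.

    ``occasion`` 1 is the baseline assessment and 2 the one-week retest;
    ``instrument`` distinguishes the computer-vision app from the manual
    2D comparison tool.
    """

    angle_deg: float
    subject_id: str
    rater_id: str
    occasion: int
    instrument: str = "cv_app"
    landmarks: Optional[LandmarkTriple] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_deg <= 180.0):
            raise ValueError(f"angle_deg must lie in (0, 180], got {self.angle_deg}")
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"instrument must be one of {INSTRUMENTS}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.subject_id, self.rater_id, self.occasion, self.instrument)


def records_to_frame(records: Iterable[AngleRecord], include_landmarks: bool = False) -> pd.DataFrame:
    """Long-format DataFrame: subject_id, rater_id, occasion, instrument, angle_deg.

    With ``include_landmarks`` the six landmark coordinates are appended
    (NaN where a record carries no landmarks).
    """
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "rater_id": r.rater_id,
            "occasion": r.occasion,
            "instrument": r.instrument,
            "angle_deg": round(r.angle_deg, 2),
        }
        if include_landmarks:
            lm = r.landmarks
            for name, xy in (
                ("asis", lm.asis_xy if lm else (float("nan"),) * 2),
                ("patella", lm.patella_xy if lm else (float("nan"),) * 2),
                ("att", lm.att_xy if lm else (float("nan"),) * 2),
            ):
                row[f"{name}_x"], row[f"{name}_y"] = xy
        rows.append(row)
    return pd.DataFrame(rows)
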