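"""Landmark-based rigid alignment of dendritic-spine crops.

Manually classified mushroom/stubby spines carry landmark points (head
borders, neck top/bottom for mushrooms, shaft junction). Alignment applies
a rigid transform (rotation + translation, no scaling) that puts the head
centre on the crop's central pixel and points the head-to-shaft direction
straight down (towards increasing row), so population averages have the
spine head at the centre and the dendritic shaft at the bottom. Pixels
that fall outside the source are NaN (missing), not zero, and population
averages weight each pixel by its member count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .binavg import AverageImage, average_image

__all__ = [
    "SpineLandmarks",
    "head_centre",
    "align_spine_crop",
    "average_aligned",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

Point = Tuple[float, float]  # (row, col)

_MUSHROOM_POINTS = (
    "head_top", "head_bottom", "head_left", "head_right",
    "neck_top", "neck_bottom", "shaft_junction",
)
_STUBBY_POINTS = (
    "head_top", "head_bottom", "head_left", "head_right", "shaft_junction",
)


@dataclass
class SpineLandmarks:
    """Manual landmark set for one spine crop.

    Mushroom spines carry all seven points; stubby spines (no neck) carry
    the five non-neck points. Coordinates are (row, col) pixels within the
    crop.
    """

    crop_id: str
    spine_class: str
    head_top: Point
    head_bottom: Point
    head_left: Point
    head_right: Point
    shaft_junction: Point
    neck_top: Optional[Point] = None
    neck_bottom: Optional[Point] = None

    def __post_init__(self) -> None:
        if self.spine_class not in ("mushroom", "stubby"):
            raise ValueError(f"unknown spine class {self.spine_class!r}")
        if self.spine_class == "mushroom" and (
            self.neck_top is None or self.neck_bottom is None
        ):
            raise ValueError("mushroom spines require neck_top and neck_bottom")

    def points(self) -> dict[str, Point]:
        names = _MUSHROOM_POINTS if self.spine_class == "mushroom" else _STUBBY_POINTS
        return {name: getattr(self, name) for name in names}

    def validate_within(self, shape: Tuple[int, int]) -> None:
        h, w = shape
        for name, (r, c) in self.points().items():
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise ValueError(
                    f"landmark {name} = ({r}, {c}) outside crop of shape {shape}"
                )


def head_centre(landmarks: SpineLandmarks) -> Point:
    """Centroid of the four head border points."""
    pts = np.array(
        [landmarks.head_top, landmarks.head_bottom,
         landmarks.head_left, landmarks.head_right],
        dtype=float,
    )
    r, c = pts.mean(axis=0)
    return (float(r), float(c))


def align_spine_crop(
    crop: np.ndarray,
    landmarks: SpineLandmarks,
    output_shape: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Rigidly align one crop: head centre to the central pixel, shaft down.

    The rotation maps the unit vector from head centre to shaft junction
    onto (1, 0) in (row, col) coordinates, i.e. straight down in image
    display convention. Bilinear interpolation; out-of-field samples are
    NaN.

    Raises
    ------
    ValueError
        If the head centre coincides with the shaft junction (orientation
        undefined).
    """
    crop = np.asarray(crop, dtype=np.float64)
    landmarks.validate_within(crop.shape)
    hc = np.array(head_centre(landmarks))
    sj = np.array(landmarks.shaft_junction, dtype=float)
    v = sj - hc
    norm = float(np.hypot(*v))
    if norm == 0:
        raise ValueError(
            "head centre coincides with shaft junction; orientation undefined"
        )
    # angle needed so that R @ v points along +row
    theta = math.atan2(v[1], v[0])  # v = (norm) * (cos θ, sin θ)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # R rotates v onto (norm, 0): R = [[cos, sin], [-sin, cos]]
    rot = np.array([[cos_t, sin_t], [-sin_t, cos_t]])

    shape = output_shape or crop.shape
    out_centre = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    # output coordinate o samples input at  hc + R^T @ (o - out_centre)
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    dr = np.broadcast_to(rows - out_centre[0], shape)
    dc = np.broadcast_to(cols - out_centre[1], shape)
    src_r = hc[0] + rot[0, 0] * dr + rot[1, 0] * dc
    src_c = hc[1] + rot[0, 1] * dr + rot[1, 1] * dc

    aligned = ndimage.map_coordinates(
        crop, [src_r, src_c], order=1, mode="constant", cval=np.nan
    )
    return aligned


def average_aligned(
    aligned_crops: Sequence[np.ndarray],
    spine_class: Optional[str] = None,
    role: Optional[str] = None,
) -> AverageImage:
    """Pixelwise mean over aligned crops, ignoring missing (NaN) pixels."""
    if len(aligned_crops) == 0:
        raise ValueError("no aligned crops to average")
    avg = average_image(aligned_crops, role=role)
    avg.role = role or spine_class
    return avg


_CSV_COLUMNS = ["crop_id", "spine_class"] + [
    f"{name}_{ax}" for name in _MUSHROOM_POINTS for ax in ("x", "y")
]


def write_landmarks_csv(
    landmarks: Sequence[SpineLandmarks], path: Union[str, Path]
) -> Path:
    """Write landmarks with x = column, y = row; neck columns empty for stubby."""
    rows = []
    for lm in landmarks:
        row: dict = {"crop_id": lm.crop_id, "spine_class": lm.spine_class}
        for name in _MUSHROOM_POINTS:
            pt = getattr(lm, name)
            row[f"{name}_x"] = pt[1] if pt is not None else np.nan
            row[f"{name}_y"] = pt[0] if pt is not None else np.nan
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    return path


def read_landmarks_csv(path: Union[str, Path]) -> list[SpineLandmarks]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        def _pt(name: str) -> Optional[Point]:
            x, y = row.get(f"{name}_x"), row.get(f"{name}_y")
            if pd.isna(x) or pd.isna(y):
                return None
            return (float(y), float(x))
        out.append(
            SpineLandmarks(
                crop_id=str(row["crop_id"]),
                spine_class=str(row["spine_class"]),
                head_top=_pt("head_top"),
                head_bottom=_pt("head_bottom"),
                head_left=_pt("head_left"),
                head_right=_pt("head_right"),
                shaft_junction=_pt("shaft_junction"),
                neck_top=_pt("neck_top"),
                neck_bottom=_pt("neck_bottom"),
            )
        )
    return out
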