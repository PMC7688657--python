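"""Synapse punctum localization and fixed-size crop excision.

A synaptic-marker channel (homer, vGLUT1 or SYT1) is thresholded, its
connected components become candidate puncta, and a square region of
3 x 3 um is excised around each punctum's intensity-weighted centroid.
Crops overlapping the image border are flagged invalid and excluded from
averaging rather than zero-padded, since padding would bias the
peripheral ring of the radial statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import InvalidConfigError, PipelineConfig, ThresholdSpec
from .imgio import MultiChannelImage

__all__ = [
    "SynapseCrop",
    "threshold_marker",
    "find_synapse_centres",
    "extract_crop",
    "extract_all_crops",
    "punctum_table",
]


@dataclass
class SynapseCrop:
    """A square excision centred on a synaptic punctum.

    ``channels`` holds one ``side_px x side_px`` array per role. The
    punctum centre sits on the exact central pixel (odd side). ``valid``
    is False when the requested crop overlaps the source border; such
    crops carry no pixel data and are excluded downstream.
    """

    channels: dict[str, np.ndarray]
    centre_in_source: Tuple[int, int]
    side_px: int
    field_id: str = "field0"
    experiment_id: str = "exp0"
    valid: bool = True
    crop_id: Optional[str] = None
    mean_intensity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid:
            for role, arr in self.channels.items():
                if arr.shape != (self.side_px, self.side_px):
                    raise ValueError(
                        f"channel {role!r} has shape {arr.shape}, expected "
                        f"({self.side_px}, {self.side_px})"
                    )
            if not self.mean_intensity:
                self.mean_intensity = {
                    role: float(arr.mean()) for role, arr in self.channels.items()
                }

    @property
    def centre_px(self) -> Tuple[int, int]:
        """Index of the central pixel within the crop."""
        return (self.side_px // 2, self.side_px // 2)


def threshold_marker(channel: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Boolean mask of pixels strictly above the threshold.

    ``spec`` gives either an absolute intensity or a quantile of the
    channel's own pixel distribution; the resolved absolute value is what
    run manifests record.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if spec.kind == "absolute":
        t = float(spec.value)
    else:
        if not 0.0 < spec.value < 1.0:
            raise InvalidConfigError(f"quantile must lie in (0,1), got {spec.value}")
        t = float(np.quantile(channel, spec.value))
    return channel > t


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def find_synapse_centres(
    mask: np.ndarray,
    channel: np.ndarray,
    min_area_px: int = 4,
) -> list[dict]:
    """Locate punctum centres as intensity-weighted component centroids.

    Connected components (8-connectivity) of the mask with area >=
    ``min_area_px`` are kept; each centre is the intensity-weighted
    centroid rounded to the nearest pixel. Results are sorted by
    descending component total intensity.

    Returns a list of records with keys ``centre`` (row, col ints),
    ``area_px`` and ``total_intensity``.
    """
    mask = np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=np.float64)
    if mask.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labels, idx)
    totals = ndimage.sum_labels(channel, labels, idx)
    centroids = ndimage.center_of_mass(channel, labels, idx)

    records = []
    for area, total, com in zip(areas, totals, centroids):
        if area < min_area_px:
            continue
        centre = (int(round(com[0])), int(round(com[1])))
        records.append(
            {"centre": centre, "area_px": int(area), "total_intensity": float(total)}
        )
    records.sort(key=lambda r: -r["total_intensity"])
    return records


def extract_crop(
    image: MultiChannelImage,
    centre: Tuple[int, int],
    config: PipelineConfig | None = None,
) -> SynapseCrop:
    """Excise an odd-sided square crop with ``centre`` on the central pixel.

    A crop whose footprint would cross the image border is returned with
    ``valid=False`` and empty channel data (border crops are excluded, not
    padded).
    """
    cfg = config or PipelineConfig(pixel_size_nm=image.pixel_size_nm)
    side = cfg.side_px
    half = side // 2
    h, w = image.shape
    r, c = int(centre[0]), int(centre[1])
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"centre {centre} outside image of shape {image.shape}")

    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        return SynapseCrop(
            channels={},
            centre_in_source=(r, c),
            side_px=side,
            field_id=image.field_id,
            experiment_id=image.experiment_id,
            valid=False,
        )
    channels = {
        role: arr[r - half : r + half + 1, c - half : c + half + 1].copy()
        for role, arr in image.channels.items()
    }
    return SynapseCrop(
        channels=channels,
        centre_in_source=(r, c),
        side_px=side,
        field_id=image.field_id,
        experiment_id=image.experiment_id,
    )


def extract_all_crops(
    image: MultiChannelImage,
    marker_role: str,
    config: PipelineConfig | None = None,
) -> tuple[list[SynapseCrop], list[dict]]:
    """Threshold a marker channel, find puncta, and excise every crop.

    Returns the crops (including invalid border crops, flagged) and the
    punctum records from :func:`find_synapse_centres`.
    """
    cfg = config or PipelineConfig(pixel_size_nm=image.pixel_size_nm)
    if marker_role not in image.channels:
        raise InvalidConfigError(
            f"marker role {marker_role!r} missing from image channels "
            f"{sorted(image.channels)}"
        )
    channel = image.channels[marker_role]
    mask = threshold_marker(channel, cfg.synapse_threshold)
    puncta = find_synapse_centres(mask, channel, cfg.min_punctum_area_px)
    crops = []
    for i, rec in enumerate(puncta):
        crop = extract_crop(image, rec["centre"], cfg)
        crop.crop_id = f"{image.field_id}:{i}"
        crops.append(crop)
    return crops, puncta


def punctum_table(
    crops: Sequence[SynapseCrop], puncta: Sequence[dict]
) -> pd.DataFrame:
    """Flat per-punctum table (one row per located synapse)."""
    rows = []
    for crop, rec in zip(crops, puncta):
        rows.append(
            {
                "crop_id": crop.crop_id,
                "field_id": crop.field_id,
                "experiment_id": crop.experiment_id,
                "x": crop.centre_in_source[1],
                "y": crop.centre_in_source[0],
                "area_px": rec["area_px"],
                "total_intensity": rec["total_intensity"],
                "valid": crop.valid,
            }
        )
    cols = [
        "crop_id", "field_id", "experiment_id", "x", "y",
        "area_px", "total_intensity", "valid",
    ]
    return pd.DataFrame(rows, columns=cols)
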