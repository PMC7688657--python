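"""Multichannel image container and TIFF / CSV / manifest I/O.

Images are plain multi-page TIFFs (one page per channel) with a JSON
sidecar recording the channel order, pixel size and identifiers; OME or
vendor formats are out of scope. Arrays are converted to float64 on load
and never rescaled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "FormatError",
    "MultiChannelImage",
    "read_multichannel_tiff",
    "write_multichannel_tiff",
    "write_results",
]

#: Channel roles of a four-colour acquisition: the protein of interest,
#: the post-synaptic marker (homer), the pre-synaptic marker (vGLUT1 or
#: live-labelled SYT1), and the actin/morphology channel (confocal).
ROLES = ("poi", "post_marker", "pre_marker", "actin")


class FormatError(ValueError):
    """An input file does not match the expected layout."""


@dataclass
class MultiChannelImage:
    """2-D intensity arrays keyed by marker role, sharing one geometry.

    Attributes
    ----------
    channels:
        Mapping from role (see :data:`ROLES`) to a 2-D non-negative
        float array. All channels must have identical shape.
    pixel_size_nm:
        Physical pixel size; 30 nm in the reference acquisition.
    experiment_id, field_id:
        Identifiers used for per-experiment normalization and provenance.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = 30.0
    experiment_id: str = "exp0"
    field_id: str = "field0"

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("image must contain at least one channel")
        if self.pixel_size_nm <= 0:
            raise FormatError("pixel_size_nm must be positive")
        shapes = {role: np.asarray(arr).shape for role, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise FormatError(f"channels must be 2-D, got shape {first}")
        for role, shp in shapes.items():
            if shp != first:
                raise FormatError(
                    f"channel {role!r} has shape {shp}, expected {first}"
                )
        for role in list(self.channels):
            arr = np.asarray(self.channels[role], dtype=np.float64)
            if np.any(arr < 0):
                raise FormatError(f"channel {role!r} contains negative intensities")
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_multichannel_tiff(
    image: MultiChannelImage, path: Union[str, Path]
) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar with channel metadata."""
    path = Path(path)
    roles = [r for r in ROLES if r in image.channels]
    roles += [r for r in image.channels if r not in roles]
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channel_order": roles,
        "pixel_size_nm": image.pixel_size_nm,
        "experiment_id": image.experiment_id,
        "field_id": image.field_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_multichannel_tiff(
    path: Union[str, Path],
    channel_map: Optional[Mapping[str, int]] = None,
    pixel_size_nm: Optional[float] = None,
) -> MultiChannelImage:
    """Read a multi-page TIFF into a :class:`MultiChannelImage`.

    Parameters
    ----------
    path:
        TIFF file; a ``<name>.tif.json`` sidecar, if present, supplies the
        channel order, pixel size and identifiers.
    channel_map:
        Role -> plane-index mapping. Required when no sidecar exists;
        overrides the sidecar when given.
    pixel_size_nm:
        Fallback pixel size when neither sidecar nor argument metadata is
        present (a warning is logged and 30 nm assumed).

    Raises
    ------
    FormatError
        If a mapped plane index exceeds the plane count, or intensities
        are negative.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D or 3-D TIFF, got ndim={data.ndim}")
    n_planes = data.shape[0]

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if channel_map is None:
        order = meta.get("channel_order")
        if order is None:
            raise FormatError(
                f"{path}: no channel_map given and no sidecar channel order found"
            )
        channel_map = {role: i for i, role in enumerate(order)}

    for role, idx in channel_map.items():
        if not 0 <= idx < n_planes:
            raise FormatError(
                f"{path}: role {role!r} maps to plane {idx} but file has "
                f"{n_planes} planes"
            )

    px = meta.get("pixel_size_nm", pixel_size_nm)
    if px is None:
        logger.warning("%s: no pixel size metadata; assuming 30 nm", path)
        px = 30.0

    return MultiChannelImage(
        channels={role: data[idx] for role, idx in channel_map.items()},
        pixel_size_nm=float(px),
        experiment_id=str(meta.get("experiment_id", "exp0")),
        field_id=str(meta.get("field_id", path.stem)),
    )


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path_prefix: Union[str, Path],
    config=None,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Write result tables as CSV plus a JSON run manifest.

    Each table is written to ``<prefix>_<name>.csv`` (headers-only when
    empty). The manifest records the effective config, its hash, the seed,
    library versions and the emitted file list, so two runs with identical
    config and seed produce byte-identical CSV bodies.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        table.to_csv(out, index=False, float_format="%.10g")
        written[name] = out

    cfg_dict = config.to_dict() if hasattr(config, "to_dict") else (config or {})
    if dataclasses.is_dataclass(cfg_dict):
        cfg_dict = dataclasses.asdict(cfg_dict)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
        },
        "files": {name: str(p) for name, p in written.items()},
    }
    manifest_path = prefix.parent / f"{prefix.name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    written["manifest"] = manifest_path
    return written
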