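"""Validated run configuration for the punctum-centred analysis pipeline.

The defaults encode the study protocol: 3 x 3 um square crops at 30 nm
pixels, five equal-size intensity bins, a periphery/centre ratio built
from radii 35-45 px (periphery) and 0-9 px (centre), outlier exclusion at
mean +/- 3 SD, and a-trous spot detection at scale 2 with an 80 %
sensitivity threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidConfigError",
    "ThresholdSpec",
    "PipelineConfig",
    "load_config",
]


class InvalidConfigError(ValueError):
    """A configuration value violates a pipeline invariant."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How a marker channel is thresholded to find synapse puncta.

    The original protocol thresholds the synaptic-marker channel manually;
    here the step is explicit and logged so runs are reproducible.

    Parameters
    ----------
    kind:
        ``"absolute"`` (threshold is an intensity value) or ``"quantile"``
        (threshold is the q-quantile of the channel, q in (0, 1)).
    value:
        The threshold value or quantile.
    """

    kind: str = "quantile"
    value: float = 0.98

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "quantile"):
            raise InvalidConfigError(
                f"threshold kind must be 'absolute' or 'quantile', got {self.kind!r}"
            )
        if self.kind == "quantile" and not 0.0 < self.value < 1.0:
            raise InvalidConfigError(
                f"quantile threshold must lie in (0, 1), got {self.value}"
            )


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    crop_side_um:
        Side of the square region excised around each synaptic punctum, in
        micrometres. 3.0 um covers a whole post-synaptic site while limiting
        contamination from neighbouring synapses.
    n_bins:
        Number of equal-size ordinal intensity bins (bin 1 = dimmest).
    centre_radius_px:
        The centre window of the radial ratio spans integer radii
        ``0 .. centre_radius_px - 1`` (10 radial pixels by default).
    ring_range_px:
        Inclusive integer-radius window of the peripheral ring
        (11 radial pixels, 35..45, by default).
    outlier_k:
        Values outside mean +/- k*SD (single pass) are excluded.
    wavelet_scale:
        A-trous detail plane used for spot detection.
    wavelet_threshold_pct:
        Detection sensitivity s in (0, 100]; mapped to a MAD multiplier
        k = (100 - s)/10 + 1, so s = 80 gives k = 3.
    synapse_threshold:
        :class:`ThresholdSpec` for locating synapse puncta.
    min_punctum_area_px:
        Smallest connected component accepted as a synapse punctum.
    min_spot_area_px:
        Smallest connected component accepted as a detected spot.
    pixel_size_nm:
        Fallback pixel size when image metadata carries none.
    seed:
        Seed for any stochastic stage (simulation, permutation tests).
    """

    crop_side_um: float = 3.0
    n_bins: int = 5
    centre_radius_px: int = 10
    ring_range_px: tuple[int, int] = (35, 45)
    outlier_k: float = 3.0
    wavelet_scale: int = 2
    wavelet_threshold_pct: float = 80.0
    synapse_threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_punctum_area_px: int = 4
    min_spot_area_px: int = 2
    pixel_size_nm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.crop_side_um <= 0:
            raise InvalidConfigError("crop_side_um must be positive")
        if self.n_bins < 1:
            raise InvalidConfigError("n_bins must be a positive integer")
        if self.pixel_size_nm <= 0:
            raise InvalidConfigError("pixel_size_nm must be positive")
        lo, hi = self.ring_range_px
        if not lo < hi:
            raise InvalidConfigError(
                f"ring_range_px must be increasing, got ({lo}, {hi})"
            )
        if self.centre_radius_px < 1:
            raise InvalidConfigError("centre_radius_px must be >= 1")
        if self.centre_radius_px >= lo:
            raise InvalidConfigError(
                f"centre window (centre_radius_px={self.centre_radius_px}) must end "
                f"before the peripheral ring starts (ring_range_px[0]={lo})"
            )
        if self.outlier_k <= 0:
            raise InvalidConfigError("outlier_k must be positive")
        if self.wavelet_scale < 1:
            raise InvalidConfigError("wavelet_scale must be >= 1")
        if not 0.0 < self.wavelet_threshold_pct <= 100.0:
            raise InvalidConfigError("wavelet_threshold_pct must lie in (0, 100]")
        if self.min_punctum_area_px < 1 or self.min_spot_area_px < 1:
            raise InvalidConfigError("minimum areas must be >= 1 px")
        # The crop must contain the full peripheral ring.
        if self.crop_radius_px < hi:
            raise InvalidConfigError(
                f"crop_side_um={self.crop_side_um} gives a crop radius of "
                f"{self.crop_radius_px} px at {self.pixel_size_nm} nm/px, smaller "
                f"than the outer ring radius {hi} px"
            )

    @property
    def side_px(self) -> int:
        """Crop side in pixels, rounded to the nearest odd integer.

        An odd side gives the crop an exact central pixel, so 'centred on
        the punctum' is unambiguous for radial analysis (3.0 um at 30 nm/px
        -> nominal 100 px -> 101 px).
        """
        n = round(self.crop_side_um * 1000.0 / self.pixel_size_nm)
        return n if n % 2 == 1 else n + 1

    @property
    def crop_radius_px(self) -> int:
        return self.side_px // 2

    @property
    def mad_multiplier(self) -> float:
        """MAD multiplier k implied by the sensitivity percentage."""
        return (100.0 - self.wavelet_threshold_pct) / 10.0 + 1.0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ring_range_px"] = list(self.ring_range_px)
        d["side_px"] = self.side_px
        return d


def load_config(path: Union[str, Path, None] = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML/JSON document.

    Missing keys fall back to the protocol defaults; an empty document (or
    ``None``) yields the defaults themselves. The effective configuration is
    echoed to the log so every run records the parameters actually used.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InvalidConfigError(f"config document must be a mapping, got {type(loaded)}")
        raw = loaded

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")

    if "ring_range_px" in raw:
        raw["ring_range_px"] = tuple(raw["ring_range_px"])
    if "synapse_threshold" in raw and isinstance(raw["synapse_threshold"], dict):
        raw["synapse_threshold"] = ThresholdSpec(**raw["synapse_threshold"])

    cfg = PipelineConfig(**raw)
    logger.info("effective pipeline config: %s", cfg.to_dict())
    return cfg
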