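"""Radial intensity profiles and the periphery/centre ratio statistic.

The ratio divides the mean intensity over a peripheral ring of integer
radii (default 35-45 px inclusive) by the mean over the central radii
(default 0-9 px). On a punctum-centred average image a low ratio means the
signal is concentrated at the synaptic site; values near 1 mean it is as
bright far from the synapse as at it, i.e. spread out.

Pixels are assigned to integer radius bins by rounding their Euclidean
distance from the centre, which conserves total intensity: the
pixel-count-weighted sum of the profile equals the sum of all pixels
within the largest complete ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np

from .config import PipelineConfig

__all__ = [
    "RadialProfile",
    "UndefinedRatioError",
    "radial_profile",
    "periphery_centre_ratio",
    "ratio_trend",
]


class UndefinedRatioError(ZeroDivisionError):
    """The centre window has zero mean intensity; the ratio is undefined."""


@dataclass
class RadialProfile:
    """Mean intensity as a function of integer pixel radius from a centre.

    Attributes
    ----------
    radii:
        Integer radii 0..r_max where r_max is the largest radius whose
        full ring of pixels lies inside the image.
    mean_intensity:
        Mean of the pixels whose rounded distance equals each radius.
    n_pixels:
        Number of pixels contributing to each radius bin.
    centre:
        (row, col) the profile was computed about.
    """

    radii: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    centre: Tuple[float, float]

    @property
    def r_max(self) -> int:
        return int(self.radii[-1])


def radial_profile(image: np.ndarray, centre: Tuple[float, float]) -> RadialProfile:
    """Compute the integer-radius radial profile of ``image`` about ``centre``.

    ``centre`` is a (row, col) pixel coordinate (sub-pixel values allowed).
    Each pixel joins the bin ``round(distance)``; the profile stops at the
    largest radius whose ring lies entirely inside the image, so every bin
    is complete and unbiased by the image border.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got ndim={image.ndim}")
    cr, cc = float(centre[0]), float(centre[1])
    h, w = image.shape
    if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
        raise IndexError(f"centre {centre} outside image of shape {image.shape}")

    rows = np.arange(h, dtype=np.float64)[:, None] - cr
    cols = np.arange(w, dtype=np.float64)[None, :] - cc
    dist = np.hypot(rows, cols)
    rbin = np.rint(dist).astype(np.intp)

    # A pixel with round(d) = r satisfies |dr|, |dc| <= r, so ring r is
    # complete iff r does not exceed the distance to the nearest border.
    r_max = int(np.floor(min(cr, cc, h - 1 - cr, w - 1 - cc)))
    if r_max < 0:
        r_max = 0

    inside = rbin <= r_max
    counts = np.bincount(rbin[inside], minlength=r_max + 1)
    sums = np.bincount(rbin[inside], weights=image[inside], minlength=r_max + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    return RadialProfile(
        radii=np.arange(r_max + 1),
        mean_intensity=means,
        n_pixels=counts,
        centre=(cr, cc),
    )


def _window_mean(profile: RadialProfile, radii: Sequence[int]) -> float:
    radii = np.asarray(radii)
    if radii.max() > profile.r_max:
        raise ValueError(
            f"profile only reaches radius {profile.r_max}; window needs "
            f"{int(radii.max())}"
        )
    return float(np.mean(profile.mean_intensity[radii]))


def periphery_centre_ratio(
    profile: RadialProfile, config: PipelineConfig | None = None
) -> float:
    """Periphery/centre ratio of a radial profile.

    The ratio is mean(profile[ring_lo..ring_hi]) / mean(profile[0..c-1])
    with ring (35, 45) inclusive and c = 10 by default, i.e. the unweighted
    mean over radius bins in each window (each radius counts once,
    matching a radial-profile-plot readout rather than a pixel-area mean).
    """
    cfg = config or PipelineConfig()
    lo, hi = cfg.ring_range_px
    ring = _window_mean(profile, np.arange(lo, hi + 1))
    centre = _window_mean(profile, np.arange(0, cfg.centre_radius_px))
    if centre == 0:
        raise UndefinedRatioError("centre window mean is zero; ratio undefined")
    return ring / centre


def ratio_trend(
    avg_images: Mapping[int, np.ndarray],
    config: PipelineConfig | None = None,
) -> tuple[dict[int, float], float]:
    """Periphery/centre ratio per intensity bin, plus the bin-N minus bin-1 delta.

    Parameters
    ----------
    avg_images:
        Mapping bin_index -> average image (all the same odd-sided square
        geometry), typically from :func:`stedpuncta.binavg.average_image`.

    Returns
    -------
    (ratios, delta):
        Per-bin ratio and ``ratios[max_bin] - ratios[min_bin]``. A positive
        delta means the signal spreads out as the sorting marker grows
        brighter.
    """
    cfg = config or PipelineConfig()
    if not avg_images:
        raise ValueError("no average images given")
    # accept AverageImage objects or bare arrays
    avg_images = {
        b: getattr(img, "array", img) for b, img in avg_images.items()
    }
    bins = sorted(avg_images)
    expected = list(range(bins[0], bins[0] + len(bins)))
    if bins != expected:
        raise ValueError(f"missing bins: have {bins}")

    shapes = {np.asarray(img).shape for img in avg_images.values()}
    if len(shapes) != 1:
        raise ValueError(f"average images differ in geometry: {shapes}")

    ratios: dict[int, float] = {}
    for b in bins:
        img = np.asarray(avg_images[b])
        centre = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
        ratios[b] = periphery_centre_ratio(radial_profile(img, centre), cfg)
    delta = ratios[bins[-1]] - ratios[bins[0]]
    return ratios, delta
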