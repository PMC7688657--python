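"""Outlier exclusion, per-experiment normalization, quantile binning and
per-bin average images.

The analysis sorts synapse crops into five ordinal bins of (near) equal
size by the mean intensity of a synaptic marker, after excluding values
beyond mean +/- 3 SD and normalizing each synapse's intensity to the
median of its experiment. Average images are the pixelwise mean over the
un-normalized crop arrays of each bin (normalization applies to the scalar
intensity statistics; keeping raw arrays preserves physical contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AverageImage",
    "exclude_outliers",
    "normalize_to_experiment_median",
    "assign_quantile_bins",
    "average_image",
]


@dataclass
class AverageImage:
    """Pixelwise mean over a set of equally sized crops.

    ``n_members`` records how many crops entered the mean; ``counts`` is a
    per-pixel member count (differing from ``n_members`` only for aligned
    crops with missing pixels).
    """

    array: np.ndarray
    n_members: int
    bin_index: Optional[int] = None
    role: Optional[str] = None
    counts: Optional[np.ndarray] = None


def exclude_outliers(
    values: Sequence[float], k: float = 3.0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Single-pass mean +/- k*SD outlier exclusion.

    The mean and (sample) standard deviation are computed once on all
    values; indices with |v - mean| <= k*sd are kept. Note the criterion is
    deliberately weak at small n: a single extreme value inflates the SD
    enough to keep itself unless n is large.

    Returns
    -------
    (kept, (lo, hi)):
        Sorted array of kept indices and the bounds used.
    """
    values = np.asarray(values, dtype=np.float64)
    if k <= 0:
        raise ValueError("k must be positive")
    if values.size < 2:
        warnings.warn("fewer than 2 values; outlier exclusion skipped", stacklevel=2)
        return np.arange(values.size), (-np.inf, np.inf)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    lo, hi = mean - k * sd, mean + k * sd
    kept = np.flatnonzero((values >= lo) & (values <= hi))
    return kept, (lo, hi)


def normalize_to_experiment_median(
    values: Sequence[float], experiment_ids: Sequence
) -> np.ndarray:
    """Divide each value by the median of the values from its experiment.

    Removes per-experiment intensity scale (staining efficiency, laser
    power drift between sessions): after normalization every experiment's
    median is exactly 1, so synapses pooled across experiments are
    comparable.
    """
    values = np.asarray(values, dtype=np.float64)
    ids = np.asarray(experiment_ids)
    if values.shape != ids.shape:
        raise ValueError("values and experiment_ids must have equal length")
    out = np.empty_like(values)
    for exp in pd.unique(ids):
        sel = ids == exp
        med = float(np.median(values[sel]))
        if med == 0:
            raise ZeroDivisionError(
                f"experiment {exp!r} has zero median intensity; cannot normalize"
            )
        out[sel] = values[sel] / med
    return out


def assign_quantile_bins(values: Sequence[float], n_bins: int = 5) -> np.ndarray:
    """Sort values ascending and split into ``n_bins`` near-equal groups.

    Returns a 1-based bin index per input value; bin 1 holds the lowest
    intensities. Ties are broken by stable input order, and when the count
    is not divisible by ``n_bins`` the remainder goes to the lowest bins,
    so group sizes differ by at most one and the assignment is
    deterministic.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values to form {n_bins} bins, got {n}")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    bins = np.empty(n, dtype=np.intp)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start : start + size]] = b
        start += size
    return bins


def average_image(
    crops: Sequence[np.ndarray],
    bin_index: Optional[int] = None,
    role: Optional[str] = None,
) -> AverageImage:
    """Pixelwise arithmetic mean of equally sized 2-D crops.

    NaN pixels (missing data from landmark alignment) are ignored
    per-pixel; the returned ``counts`` array records how many crops
    contributed to each pixel.
    """
    if len(crops) == 0:
        raise ValueError("cannot average an empty crop set")
    arrays = [np.asarray(c, dtype=np.float64) for c in crops]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"crops differ in shape: {shapes}")
    stack = np.stack(arrays)
    counts = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean = np.where(counts > 0, mean, np.nan)
    return AverageImage(
        array=mean,
        n_members=len(arrays),
        bin_index=bin_index,
        role=role,
        counts=counts,
    )
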