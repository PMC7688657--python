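"""Correlation and summary statistics for intensity tables.

Spearman's rho relates per-synapse protein-of-interest intensities to the
synaptic-marker intensities; per-bin mean +/- SEM summaries and ordinary
least-squares fits on the bin means reproduce the binned correlation plots
of the protocol. Significance labels follow the standard star convention
with strict inequalities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "spearman",
    "bin_summary",
    "linear_fit",
    "significance_stars",
]

#: Below this sample size the Spearman p-value is computed by exhaustive
#: permutation of the ranks instead of the t approximation.
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CorrelationResult:
    """Spearman correlation of a POI against a synaptic marker, with the
    per-bin summary and linear fit that accompany it in the report tables."""

    marker: str
    poi: str
    n: int
    spearman_rho: float
    p_value: float
    fit_slope: float
    fit_intercept: float
    bin_means: Optional[pd.DataFrame] = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return np.nan
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a tie-corrected rho.

    rho is the Pearson correlation of average ranks. The two-sided p-value
    uses the exact permutation distribution of rho for n <= 9 (all n!
    orderings of the y ranks) and the t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) otherwise.

    Returns ``(nan, nan)`` when either variable is constant (rho is then
    undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        # The rank multiset is permutation-invariant, so the denominator of
        # rho is shared by every permutation and only the cross term varies.
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(ry)),
            dtype=np.float64,
        ).reshape(-1, n)
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(pc[0] @ pc[0]))
        rhos = (pc @ rxc) / denom
        # tolerance guards FP noise at the boundary |r| == |rho|
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def bin_summary(values: Sequence[float], bins: Sequence[int]) -> pd.DataFrame:
    """Mean +/- SEM of ``values`` per ordinal bin.

    Returns a frame with columns ``bin_index, n, mean, sem`` sorted by bin;
    SEM is sd(ddof=1)/sqrt(n) and is reported as NaN for singleton bins.
    """
    values = np.asarray(values, dtype=np.float64)
    bins = np.asarray(bins)
    if values.shape != bins.shape:
        raise ValueError("values and bins must have equal length")
    rows = []
    for b in np.unique(bins):
        v = values[bins == b]
        sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(
            {"bin_index": int(b), "n": int(v.size), "mean": float(v.mean()), "sem": sem}
        )
    return pd.DataFrame(rows)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares line ``y = slope*x + intercept``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)


def significance_stars(p: float) -> str:
    """Map a p-value to the star label used in the figures.

    Strict thresholds: p < 0.05 -> '*', < 0.01 -> '**', < 0.001 -> '***',
    < 0.0001 -> '****'; otherwise 'ns.'.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns."


def correlate(
    poi_values: Sequence[float],
    marker_values: Sequence[float],
    bins: Sequence[int],
    marker: str = "post_marker",
    poi: str = "poi",
) -> CorrelationResult:
    """Crop-level Spearman correlation plus the binned fit used for plotting.

    rho and p come from the per-synapse (crop-level) values; the linear fit
    is computed on the per-bin means of both variables, matching plots of
    binned data.
    """
    rho, p = spearman(marker_values, poi_values)
    marker_bins = bin_summary(marker_values, bins)
    poi_bins = bin_summary(poi_values, bins)
    slope, intercept = linear_fit(marker_bins["mean"], poi_bins["mean"])
    table = marker_bins.rename(columns={"mean": "marker_mean", "sem": "marker_sem"})
    table["poi_mean"] = poi_bins["mean"]
    table["poi_sem"] = poi_bins["sem"]
    return CorrelationResult(
        marker=marker,
        poi=poi,
        n=len(poi_values),
        spearman_rho=rho,
        p_value=p,
        fit_slope=slope,
        fit_intercept=intercept,
        bin_means=table,
    )
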