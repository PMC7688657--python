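"""End-to-end orchestration: localize -> bin -> average -> radial -> spots -> stats.

`run_crops` is the core: it takes punctum-centred crops (from automated
localization or from a generator fixture), applies outlier exclusion,
per-experiment median normalization and quantile binning to the scalar
intensities, builds per-bin average images of the protein of interest,
computes the periphery/centre ratio trend, detects spots, and correlates
POI with marker intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import binavg, localize, radial, spots, stats
from .config import PipelineConfig
from .imgio import MultiChannelImage, write_results
from .localize import SynapseCrop
from .synth import (
    SynthConfig,
    expected_gradient_ratios,
    make_spread_gradient_fixture,
    render_synapse_crop,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_crops", "run_pipeline", "run_recovery_benchmark"]

MARKER_MODES = {"post": "post_marker", "pre": "pre_marker"}


@dataclass
class PipelineResult:
    """Tables and statistics of one analysis run (one marker mode)."""

    per_synapse: pd.DataFrame
    per_bin: pd.DataFrame
    ratios: dict[int, float]
    ratio_delta: float
    correlation: stats.CorrelationResult
    avg_images: dict[int, binavg.AverageImage]
    spot_table: pd.DataFrame
    n_excluded: int

    def tables(self) -> dict[str, pd.DataFrame]:
        corr = self.correlation
        corr_df = pd.DataFrame(
            [
                {
                    "poi": corr.poi,
                    "marker": corr.marker,
                    "n": corr.n,
                    "spearman_rho": corr.spearman_rho,
                    "p_value": corr.p_value,
                    "stars": corr.stars,
                    "fit_slope": corr.fit_slope,
                    "fit_intercept": corr.fit_intercept,
                }
            ]
        )
        ratio_df = pd.DataFrame(
            [{"bin_index": b, "ratio": r} for b, r in sorted(self.ratios.items())]
        )
        ratio_df["ratio_delta"] = self.ratio_delta
        return {
            "per_synapse": self.per_synapse,
            "per_bin": self.per_bin,
            "correlation": corr_df,
            "ratios": ratio_df,
            "spots": self.spot_table,
        }


def run_crops(
    crops: Sequence[SynapseCrop],
    config: Optional[PipelineConfig] = None,
    marker_role: str = "post_marker",
    detect_spot_sets: bool = True,
) -> PipelineResult:
    """Run the binned-average analysis on a set of synapse crops."""
    cfg = config or PipelineConfig()
    crops = [c for c in crops if c.valid]
    if len(crops) < cfg.n_bins:
        raise ValueError(
            f"only {len(crops)} valid crops; need at least n_bins={cfg.n_bins}"
        )

    marker = np.array([c.mean_intensity[marker_role] for c in crops])
    poi = np.array([c.mean_intensity["poi"] for c in crops])
    exps = np.array([c.experiment_id for c in crops])

    # outlier exclusion per analysed variable, before normalization so
    # extreme synapses cannot shift the experiment medians
    kept_m, _ = binavg.exclude_outliers(marker, cfg.outlier_k)
    kept_p, _ = binavg.exclude_outliers(poi, cfg.outlier_k)
    kept = np.intersect1d(kept_m, kept_p)
    n_excluded = len(crops) - kept.size
    crops = [crops[i] for i in kept]
    marker, poi, exps = marker[kept], poi[kept], exps[kept]
    logger.info("outlier exclusion removed %d of %d crops", n_excluded, kept.size + n_excluded)

    marker_norm = binavg.normalize_to_experiment_median(marker, exps)
    poi_norm = binavg.normalize_to_experiment_median(poi, exps)

    bins = binavg.assign_quantile_bins(marker_norm, cfg.n_bins)

    avg_images: dict[int, binavg.AverageImage] = {}
    for b in range(1, cfg.n_bins + 1):
        members = [c.channels["poi"] for c, bi in zip(crops, bins) if bi == b]
        avg_images[b] = binavg.average_image(members, bin_index=b, role="poi")
    ratios, delta = radial.ratio_trend(avg_images, cfg)

    corr = stats.correlate(
        poi_norm, marker_norm, bins, marker=marker_role, poi="poi"
    )

    spot_rows = []
    spot_sets_by_bin: dict[int, list] = {b: [] for b in range(1, cfg.n_bins + 1)}
    if detect_spot_sets:
        for c, b in zip(crops, bins):
            ss = spots.detect_spots(
                c.channels["poi"], cfg, crop_id=c.crop_id
            )
            spot_sets_by_bin[b].append(ss)
            for k, sp in enumerate(ss.spots):
                spot_rows.append(
                    {
                        "crop_id": c.crop_id,
                        "bin_index": b,
                        "spot_id": k,
                        "x": sp.centroid[1],
                        "y": sp.centroid[0],
                        "area_px": sp.area_px,
                        "diameter_nm": sp.diameter_nm,
                        "total_intensity": sp.total_intensity,
                    }
                )
    spot_table = pd.DataFrame(
        spot_rows,
        columns=["crop_id", "bin_index", "spot_id", "x", "y", "area_px",
                 "diameter_nm", "total_intensity"],
    )

    per_synapse = pd.DataFrame(
        {
            "crop_id": [c.crop_id for c in crops],
            "experiment_id": exps,
            "bin_index": bins,
            f"{marker_role}_mean": marker,
            f"{marker_role}_norm": marker_norm,
            "poi_mean": poi,
            "poi_norm": poi_norm,
        }
    )
    per_bin = corr.bin_means.copy()
    per_bin["ratio"] = [ratios[b] for b in per_bin["bin_index"]]

    return PipelineResult(
        per_synapse=per_synapse,
        per_bin=per_bin,
        ratios=ratios,
        ratio_delta=delta,
        correlation=corr,
        avg_images=avg_images,
        spot_table=spot_table,
        n_excluded=n_excluded,
    )


def run_pipeline(
    images: Sequence[MultiChannelImage],
    config: Optional[PipelineConfig] = None,
    marker_mode: str = "post",
    out_prefix: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Localize synapses in full fields and run the crop analysis.

    ``marker_mode`` chooses the channel the analysis is centred on:
    ``"post"`` (homer) or ``"pre"`` (vGLUT1/SYT1).
    """
    cfg = config or PipelineConfig()
    if marker_mode not in MARKER_MODES:
        raise ValueError(f"marker_mode must be one of {sorted(MARKER_MODES)}")
    role = MARKER_MODES[marker_mode]
    if not images:
        raise ValueError("no input images")

    all_crops: list[SynapseCrop] = []
    for img in images:
        crops, _ = localize.extract_all_crops(img, role, cfg)
        n_valid = sum(c.valid for c in crops)
        logger.info(
            "field %s: %d puncta, %d valid crops", img.field_id, len(crops), n_valid
        )
        all_crops.extend(crops)

    result = run_crops(all_crops, cfg, marker_role=role)
    if out_prefix is not None:
        write_results(result.tables(), out_prefix, config=cfg, seed=cfg.seed)
    return result


def run_recovery_benchmark(
    synth_config: Optional[SynthConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
    n_per_bin: int = 100,
    sigma_list_nm: Sequence[float] = (150.0, 250.0, 350.0, 450.0, 550.0),
    null_n: int = 500,
    seed: Optional[int] = None,
) -> dict:
    """Simulate, analyse, and compare against the generator's analytics.

    Two simulated conditions:

    * spread gradient — POI spread steps through ``sigma_list_nm`` across
      five marker-intensity bins; the pipeline's per-bin ratios should be
      strictly increasing and the bin-5 minus bin-1 delta should match the
      analytic Gaussian ring/centre prediction.
    * null control — POI count and spread decoupled from the marker; the
      POI/marker Spearman rho and the ratio delta should both be near 0.

    Returns a report dict with measured values, analytic references and
    pass/fail flags.
    """
    scfg = synth_config or SynthConfig()
    if seed is not None:
        scfg = SynthConfig(**{**scfg.to_dict(), "seed": seed})
    pcfg = pipeline_config or PipelineConfig(pixel_size_nm=scfg.pixel_size_nm)

    # --- gradient condition -------------------------------------------------
    crops, _ = make_spread_gradient_fixture(
        n_per_bin, sigma_list_nm, scfg, pcfg, noise=True
    )
    res = run_crops(crops, pcfg, marker_role="post_marker", detect_spot_sets=False)
    measured = [res.ratios[b] for b in sorted(res.ratios)]
    analytic = expected_gradient_ratios(sigma_list_nm, scfg, pcfg)
    analytic_delta = analytic[-1] - analytic[0]
    monotone = all(b > a for a, b in zip(measured, measured[1:]))

    # --- null condition -----------------------------------------------------
    rng = np.random.default_rng(scfg.seed + 7919)
    null_crops = []
    for i in range(null_n):
        homer = scfg.homer_amp * float(np.exp(rng.normal(0.0, scfg.s_sigma_log)))
        count = int(rng.poisson(scfg.poi_spot_rate))
        sigma_px = scfg.poi_spread_nm / scfg.pixel_size_nm
        offsets = [tuple(rng.normal(0.0, sigma_px, size=2)) for _ in range(count)]
        amps = [
            scfg.poi_spot_amp * float(np.exp(rng.normal(0, scfg.amp_noise_sd_log)))
            for _ in range(count)
        ]
        null_crops.append(
            render_synapse_crop(
                scfg, pcfg.side_px, homer, scfg.pre_amp, offsets, amps,
                rng=rng, crop_id=f"null{i}",
            )
        )
    null_res = run_crops(null_crops, pcfg, marker_role="post_marker",
                         detect_spot_sets=False)

    report = {
        "gradient": {
            "sigma_list_nm": list(sigma_list_nm),
            "measured_ratios": measured,
            "analytic_ratios": analytic,
            "measured_delta": res.ratio_delta,
            "analytic_delta": analytic_delta,
            "ratio_monotone": bool(monotone),
            "delta_within_0.05": bool(abs(res.ratio_delta - analytic_delta) <= 0.05),
        },
        "null": {
            "spearman_rho": null_res.correlation.spearman_rho,
            "ratio_delta": null_res.ratio_delta,
            "rho_within_0.1": bool(abs(null_res.correlation.spearman_rho) < 0.1),
            "delta_within_0.03": bool(abs(null_res.ratio_delta) <= 0.03),
        },
    }
    report["all_pass"] = bool(
        report["gradient"]["ratio_monotone"]
        and report["gradient"]["delta_within_0.05"]
        and report["null"]["rho_within_0.1"]
        and report["null"]["delta_within_0.03"]
    )
    return report
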