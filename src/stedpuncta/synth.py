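"""Synthetic STED-like image generator with matching ground truth.

Emulates four-colour acquisitions of dendritic synapses: sparse synaptic
puncta (post-synaptic marker at each synapse centre, pre-synaptic marker
offset by a vesicle-cloud distance), punctate secretory-organelle spots
whose count and spatial spread around each synapse can be coupled to
latent per-synapse strength (S) and activity (A) variables, channel
specific Gaussian PSF blur (super-resolved marker channels vs a confocal
actin channel), mixed Poisson-Gaussian noise, and per-experiment
multiplicative intensity factors.

Every stochastic quantity flows from a single seed, so identical
(config, seed) pairs give bit-identical ground truth and images.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import InvalidConfigError, PipelineConfig
from .imgio import MultiChannelImage, ROLES
from .localize import SynapseCrop
from .spines import SpineLandmarks

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "sample_synapse_population",
    "render_field",
    "render_synapse_crop",
    "simulate_dataset",
    "make_spread_gradient_fixture",
    "make_spine_fixture",
    "expected_gaussian_ratio",
    "expected_gradient_ratios",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _default_psf() -> dict[str, float]:
    # STED resolution for the labelled protein channels, confocal for actin
    return {"poi": 60.0, "post_marker": 60.0, "pre_marker": 60.0, "actin": 250.0}


@dataclass
class SynthConfig:
    """Parameters of the synthetic acquisition.

    Latent model: per synapse, strength ``S`` and activity ``A`` are drawn
    independently log-normal (median 1), producing the right-skewed
    intensity distributions typical of synaptic markers. Marker amplitudes
    are proportional to their latent (times log-normal measurement noise),
    and the protein-of-interest (POI) spot count rate and spot spread are
    power-law coupled to a chosen latent:
    ``lambda = poi_spot_rate * L**poi_rate_coupling`` and
    ``sigma = poi_spread_nm * L**poi_spread_coupling``. Coupling exponents
    of zero decouple the POI from the synapse (null control); the defaults
    keep the maps monotone non-decreasing.

    Amplitudes are integrated photon counts per punctum/spot; the default
    spot rate of 3.5 gives the three-or-four organelle spots per spine
    head seen in such preparations.
    """

    image_size_px: tuple[int, int] = (400, 400)
    pixel_size_nm: float = 30.0
    n_synapses: int = 200
    n_experiments: int = 4
    # latent scales
    s_sigma_log: float = 0.5
    a_sigma_log: float = 0.5
    # marker rendering
    homer_amp: float = 1500.0
    pre_amp: float = 1500.0
    amp_noise_sd_log: float = 0.1
    punctum_size_nm: float = 80.0
    pre_offset_nm: float = 200.0
    # POI model
    poi_spot_rate: float = 3.5
    poi_rate_coupling: float = 0.0
    poi_spot_amp: float = 450.0
    poi_spot_size_nm: float = 50.0
    poi_spread_nm: float = 250.0
    poi_spread_coupling: float = 0.5
    poi_coupling_latent: str = "A"
    # morphology channel
    actin_amp: float = 40.0
    dendrite_sd_nm: float = 300.0
    # optics and noise
    psf_fwhm_nm: dict[str, float] = field(default_factory=_default_psf)
    gain: float = 1.0
    read_noise_sd: float = 2.0
    background: float = 5.0
    batch_sd_log: float = 0.15
    # layout
    min_separation_px: int = 40
    synapses_per_field: int = 12
    spine_fractions: tuple[float, float, float] = (0.3, 0.2, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_synapses < 1:
            raise InvalidConfigError("n_synapses must be positive")
        if self.n_experiments < 1:
            raise InvalidConfigError("n_experiments must be positive")
        for name in (
            "pixel_size_nm", "punctum_size_nm", "poi_spot_size_nm",
            "poi_spread_nm", "dendrite_sd_nm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")
        if min(self.image_size_px) < 1:
            raise InvalidConfigError("image_size_px must be positive")
        if self.poi_spot_rate < 0:
            raise InvalidConfigError("poi_spot_rate must be >= 0")
        if self.poi_coupling_latent not in ("S", "A"):
            raise InvalidConfigError("poi_coupling_latent must be 'S' or 'A'")
        if self.gain <= 0:
            raise InvalidConfigError("gain must be positive")
        if self.read_noise_sd < 0 or self.background < 0:
            raise InvalidConfigError("noise parameters must be non-negative")
        for role, fwhm in self.psf_fwhm_nm.items():
            if fwhm <= 0:
                raise InvalidConfigError(f"psf_fwhm_nm[{role!r}] must be positive")
            if fwhm < self.pixel_size_nm / 2:
                warnings.warn(
                    f"psf_fwhm_nm[{role!r}]={fwhm} is below half the pixel size; "
                    "the PSF is undersampled",
                    stacklevel=3,
                )

    def psf_sigma_px(self, role: str) -> float:
        return self.psf_fwhm_nm[role] * FWHM_TO_SIGMA / self.pixel_size_nm

    def render_sigma_px(self, role: str, physical_size_nm: float) -> float:
        """Effective Gaussian sd (px) of a punctum: physical size (+) PSF."""
        sigma_nm = math.hypot(physical_size_nm, self.psf_fwhm_nm[role] * FWHM_TO_SIGMA)
        return sigma_nm / self.pixel_size_nm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Latent variables and geometry of a simulated synapse population.

    ``synapses`` has one row per synapse (id, field/experiment, centre,
    latents S and A, rendered marker amplitudes, POI spot count and spread,
    spine class, bin label for gradient fixtures); ``spots`` has one row
    per POI spot (synapse id, position, amplitude).
    """

    synapses: pd.DataFrame
    spots: pd.DataFrame
    config: Optional[SynthConfig] = None

    def spots_of(self, synapse_id: int) -> pd.DataFrame:
        return self.spots[self.spots["synapse_id"] == synapse_id]


# ---------------------------------------------------------------------------
# population sampling

def sample_synapse_population(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Draw the per-synapse latent variables, positions and POI spots.

    S and A are independent by default, so rendered post- and pre-synaptic
    amplitudes are uncorrelated across the population (no built-in
    pre/post strength correlation). Spot counts are Poisson with the
    coupled rate; spot offsets are isotropic bivariate Gaussian with the
    coupled spread, redrawn (up to 100 times) if they fall outside the
    image bounds.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_synapses
    h, w = cfg.image_size_px

    margin = min(55, h // 4, w // 4)
    experiment_ids = np.array(
        [f"exp{i % cfg.n_experiments}" for i in range(n)]
    )
    # chunk each experiment's synapses into fields of synapses_per_field,
    # keeping per-field density realistic regardless of n_synapses
    within_exp_index = np.zeros(n, dtype=int)
    seen: dict[str, int] = {}
    for i, e in enumerate(experiment_ids):
        within_exp_index[i] = seen.get(e, 0)
        seen[e] = within_exp_index[i] + 1
    field_ids = np.array(
        [
            f"{e}_f{k // cfg.synapses_per_field}"
            for e, k in zip(experiment_ids, within_exp_index)
        ]
    )
    batch = {
        f"exp{e}": float(np.exp(rng.normal(0.0, cfg.batch_sd_log)))
        for e in range(cfg.n_experiments)
    }

    # positions: uniform with margin, rejecting pairs closer than the
    # minimum separation (within the same field)
    rows = np.empty(n)
    cols = np.empty(n)
    for i in range(n):
        for _ in range(200):
            r = rng.uniform(margin, h - 1 - margin)
            c = rng.uniform(margin, w - 1 - margin)
            same_field = [j for j in range(i) if field_ids[j] == field_ids[i]]
            if all(
                math.hypot(rows[j] - r, cols[j] - c) >= cfg.min_separation_px
                for j in same_field
            ):
                break
        rows[i], cols[i] = r, c

    S = np.exp(rng.normal(0.0, cfg.s_sigma_log, size=n))
    A = np.exp(rng.normal(0.0, cfg.a_sigma_log, size=n))
    bf = np.array([batch[e] for e in experiment_ids])
    homer_amp = cfg.homer_amp * S * np.exp(rng.normal(0, cfg.amp_noise_sd_log, n)) * bf
    pre_amp = cfg.pre_amp * A * np.exp(rng.normal(0, cfg.amp_noise_sd_log, n)) * bf

    latent = S if cfg.poi_coupling_latent == "S" else A
    rate = cfg.poi_spot_rate * latent**cfg.poi_rate_coupling
    spread_nm = cfg.poi_spread_nm * latent**cfg.poi_spread_coupling
    counts = rng.poisson(rate)

    spine_class = rng.choice(
        ["mushroom", "stubby", "none"], size=n, p=cfg.spine_fractions
    )

    spot_rows = []
    for i in range(n):
        sigma_px = spread_nm[i] / cfg.pixel_size_nm
        for _ in range(counts[i]):
            for _ in range(100):
                dr, dc = rng.normal(0.0, sigma_px, size=2)
                sr, sc = rows[i] + dr, cols[i] + dc
                if 0 <= sr <= h - 1 and 0 <= sc <= w - 1:
                    break
            amp = cfg.poi_spot_amp * float(
                np.exp(rng.normal(0, cfg.amp_noise_sd_log))
            ) * bf[i]
            spot_rows.append(
                {"synapse_id": i, "row": sr, "col": sc, "amp": amp}
            )

    synapses = pd.DataFrame(
        {
            "synapse_id": np.arange(n),
            "experiment_id": experiment_ids,
            "field_id": field_ids,
            "row": rows,
            "col": cols,
            "S": S,
            "A": A,
            "homer_amp": homer_amp,
            "pre_amp": pre_amp,
            "poi_spot_count": counts,
            "poi_spread_nm": spread_nm,
            "spine_class": spine_class,
        }
    )
    spots = pd.DataFrame(
        spot_rows, columns=["synapse_id", "row", "col", "amp"]
    )
    return GroundTruth(synapses=synapses, spots=spots, config=cfg)


# ---------------------------------------------------------------------------
# rendering

def _add_gaussian(
    canvas: np.ndarray, r: float, c: float, amp: float, sigma_px: float
) -> None:
    """Add an integrated-amplitude Gaussian punctum onto ``canvas`` in place."""
    h, w = canvas.shape
    half = int(math.ceil(4.0 * sigma_px + 1.0))
    r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=np.float64)[:, None] - r
    cc = np.arange(c0, c1, dtype=np.float64)[None, :] - c
    canvas[r0:r1, c0:c1] += (
        amp
        / (2.0 * math.pi * sigma_px**2)
        * np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))
    )


def _apply_noise(
    canvas: np.ndarray, cfg: SynthConfig, rng: Optional[np.random.Generator]
) -> np.ndarray:
    """Poisson (gain-scaled) then Gaussian read noise, clipped at zero.

    ``rng=None`` renders the noiseless expectation (signal + background).
    """
    x = canvas + cfg.background
    if rng is None:
        return x
    counts = rng.poisson(cfg.gain * x) / cfg.gain
    counts = counts + rng.normal(0.0, cfg.read_noise_sd, size=x.shape)
    return np.clip(counts, 0.0, None)


def render_field(
    truth: GroundTruth,
    config: SynthConfig,
    field_id: str,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> MultiChannelImage:
    """Render one simulated field (all synapses whose field_id matches).

    Channels share geometry: the post-synaptic marker is one punctum per
    synapse centre; the pre-synaptic marker sits a vesicle-cloud offset
    away; the POI channel is the sum of the ground-truth spots; the actin
    channel holds a dendrite band through each synapse row plus a spine
    head blob, blurred with the (wider) confocal PSF.
    """
    cfg = config
    sel = truth.synapses[truth.synapses["field_id"] == field_id]
    if sel.empty:
        raise ValueError(f"no synapses with field_id {field_id!r}")
    for role in ROLES:
        if role not in cfg.psf_fwhm_nm:
            raise InvalidConfigError(f"psf_fwhm_nm missing role {role!r}")
    h, w = cfg.image_size_px
    local = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    rng_noise = local if noise else None

    post = np.zeros((h, w))
    pre = np.zeros((h, w))
    poi = np.zeros((h, w))
    actin = np.zeros((h, w))

    sig_post = cfg.render_sigma_px("post_marker", cfg.punctum_size_nm)
    sig_pre = cfg.render_sigma_px("pre_marker", cfg.punctum_size_nm)
    sig_poi = cfg.render_sigma_px("poi", cfg.poi_spot_size_nm)
    sig_actin = cfg.render_sigma_px("actin", cfg.dendrite_sd_nm)

    offset_px = cfg.pre_offset_nm / cfg.pixel_size_nm
    for _, syn in sel.iterrows():
        r, c = float(syn["row"]), float(syn["col"])
        _add_gaussian(post, r, c, float(syn["homer_amp"]), sig_post)
        phi = local.uniform(0.0, 2.0 * math.pi)
        _add_gaussian(
            pre,
            r + offset_px * math.sin(phi),
            c + offset_px * math.cos(phi),
            float(syn["pre_amp"]),
            sig_pre,
        )
        # dendrite band through the synapse row (uniform along columns)
        rr = np.arange(h, dtype=np.float64)
        band = cfg.actin_amp * np.exp(-((rr - r) ** 2) / (2.0 * sig_actin**2))
        actin += band[:, None]
        _add_gaussian(actin, r, c, cfg.actin_amp * 30.0, sig_actin)

    spot_sel = truth.spots[truth.spots["synapse_id"].isin(sel["synapse_id"])]
    for _, sp in spot_sel.iterrows():
        _add_gaussian(poi, float(sp["row"]), float(sp["col"]), float(sp["amp"]), sig_poi)

    channels = {
        "poi": _apply_noise(poi, cfg, rng_noise),
        "post_marker": _apply_noise(post, cfg, rng_noise),
        "pre_marker": _apply_noise(pre, cfg, rng_noise),
        "actin": _apply_noise(actin, cfg, rng_noise),
    }
    exp_id = str(sel["experiment_id"].iloc[0])
    return MultiChannelImage(
        channels=channels,
        pixel_size_nm=cfg.pixel_size_nm,
        experiment_id=exp_id,
        field_id=field_id,
    )


def simulate_dataset(
    config: SynthConfig,
) -> tuple[list[MultiChannelImage], GroundTruth]:
    """Sample a population and render every field; fully seed-determined."""
    rng = np.random.default_rng(config.seed)
    truth = sample_synapse_population(config, rng)
    images = [
        render_field(truth, config, fid, rng=rng)
        for fid in truth.synapses["field_id"].unique()
    ]
    return images, truth


def render_synapse_crop(
    config: SynthConfig,
    side_px: int,
    homer_amp: float,
    pre_amp: float,
    spot_offsets_px: Sequence[tuple[float, float]],
    spot_amps: Sequence[float],
    rng: Optional[np.random.Generator] = None,
    crop_id: Optional[str] = None,
    experiment_id: str = "exp0",
) -> SynapseCrop:
    """Render a single punctum-centred crop directly (no localization step).

    Used by the fixture generators: the synaptic punctum sits exactly on
    the central pixel and POI spots at the given offsets from it.
    """
    centre = (side_px // 2, side_px // 2)
    post = np.zeros((side_px, side_px))
    pre = np.zeros((side_px, side_px))
    poi = np.zeros((side_px, side_px))

    _add_gaussian(
        post, centre[0], centre[1], homer_amp,
        config.render_sigma_px("post_marker", config.punctum_size_nm),
    )
    _add_gaussian(
        pre, centre[0], centre[1], pre_amp,
        config.render_sigma_px("pre_marker", config.punctum_size_nm),
    )
    sig_poi = config.render_sigma_px("poi", config.poi_spot_size_nm)
    for (dr, dc), amp in zip(spot_offsets_px, spot_amps):
        _add_gaussian(poi, centre[0] + dr, centre[1] + dc, amp, sig_poi)

    channels = {
        "poi": _apply_noise(poi, config, rng),
        "post_marker": _apply_noise(post, config, rng),
        "pre_marker": _apply_noise(pre, config, rng),
    }
    return SynapseCrop(
        channels=channels,
        centre_in_source=centre,
        side_px=side_px,
        field_id=crop_id or "synthetic",
        experiment_id=experiment_id,
        crop_id=crop_id,
    )


# ---------------------------------------------------------------------------
# gradient fixture

def make_spread_gradient_fixture(
    n_per_bin: int,
    sigma_list_nm: Sequence[float],
    config: Optional[SynthConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
    noise: bool = True,
    strict: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SynapseCrop], GroundTruth]:
    """Crops whose POI spread steps through ``sigma_list_nm`` across bins.

    Bin b (0-based) gets ``n_per_bin`` crops with POI spot offsets drawn
    isotropically with sd ``sigma_list_nm[b]``; the synaptic-marker
    amplitude grows with b (well separated between bins) so downstream
    quantile binning recovers the intended grouping. The true bin is
    stored in the ground-truth table for recovery checks.

    Unlike the population sampler, spot counts here follow the
    deterministic integer sequence ``floor(rate*(i+1)) - floor(rate*i)``
    (mean exactly ``poi_spot_rate``; 3,4,3,4,... at the default 3.5): the
    fixture is a calibration instrument for the spread -> ratio mapping,
    so count shot noise — irrelevant to that mapping — is excluded by
    design, while position scatter and pixel noise are kept.

    ``strict=True`` requires a strictly increasing sigma list; pass
    ``strict=False`` for degenerate (equal or reversed) designs used as
    controls.
    """
    cfg = config or SynthConfig()
    pcfg = pipeline_config or PipelineConfig(pixel_size_nm=cfg.pixel_size_nm)
    sigma_list = [float(s) for s in sigma_list_nm]
    if any(s <= 0 for s in sigma_list):
        raise InvalidConfigError("sigma_list_nm entries must be positive")
    if strict and any(b <= a for a, b in zip(sigma_list, sigma_list[1:])):
        raise InvalidConfigError(
            f"sigma_list_nm must be strictly increasing, got {sigma_list}"
        )
    if n_per_bin < 0:
        raise InvalidConfigError("n_per_bin must be >= 0")
    if n_per_bin == 0:
        warnings.warn("n_per_bin=0: empty fixture", stacklevel=2)
        empty = pd.DataFrame(
            columns=["synapse_id", "bin_true", "homer_amp", "poi_spread_nm",
                     "poi_spot_count", "experiment_id"]
        )
        return [], GroundTruth(
            synapses=empty, spots=pd.DataFrame(columns=["synapse_id"]), config=cfg
        )

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    side = pcfg.side_px
    crops: list[SynapseCrop] = []
    records = []
    spot_records = []
    sid = 0
    for b, sigma_nm in enumerate(sigma_list):
        sigma_px = sigma_nm / cfg.pixel_size_nm
        for i in range(n_per_bin):
            homer = cfg.homer_amp * (1.0 + b) * float(
                np.exp(rng.normal(0.0, 0.02))
            )
            pre = cfg.pre_amp * float(np.exp(rng.normal(0.0, cfg.amp_noise_sd_log)))
            count = int(
                math.floor(cfg.poi_spot_rate * (i + 1))
                - math.floor(cfg.poi_spot_rate * i)
            )
            offsets = [tuple(rng.normal(0.0, sigma_px, size=2)) for _ in range(count)]
            amps = [
                cfg.poi_spot_amp * float(np.exp(rng.normal(0, cfg.amp_noise_sd_log)))
                for _ in range(count)
            ]
            crop = render_synapse_crop(
                cfg, side, homer, pre, offsets, amps,
                rng=rng if noise else None,
                crop_id=f"bin{b}:{i}",
            )
            crops.append(crop)
            records.append(
                {
                    "synapse_id": sid,
                    "bin_true": b + 1,
                    "homer_amp": homer,
                    "pre_amp": pre,
                    "poi_spread_nm": sigma_nm,
                    "poi_spot_count": count,
                    "experiment_id": "exp0",
                }
            )
            for (dr, dc), amp in zip(offsets, amps):
                spot_records.append(
                    {"synapse_id": sid, "row": side // 2 + dr,
                     "col": side // 2 + dc, "amp": amp}
                )
            sid += 1
    truth = GroundTruth(
        synapses=pd.DataFrame(records),
        spots=pd.DataFrame(spot_records, columns=["synapse_id", "row", "col", "amp"]),
        config=cfg,
    )
    return crops, truth


# ---------------------------------------------------------------------------
# analytic expectations

def expected_gaussian_ratio(
    sigma_px: float,
    side_px: int = 101,
    centre_radius_px: int = 10,
    ring_range_px: tuple[int, int] = (35, 45),
    peak: float = 1.0,
    background: float = 0.0,
) -> float:
    """Analytic periphery/centre ratio of a centred isotropic Gaussian.

    Evaluates ``peak * exp(-d^2 / 2 sigma^2) + background`` on the pixel
    grid and averages per integer (rounded-distance) radius bin — the same
    binning the measured profile uses, but computed directly from the
    analytic law rather than from any rendered image.
    """
    half = side_px // 2
    coords = np.arange(side_px, dtype=np.float64) - half
    d = np.hypot(coords[:, None], coords[None, :])
    rbin = np.rint(d).astype(int)
    f = peak * np.exp(-(d**2) / (2.0 * sigma_px**2)) + background

    def window_mean(radii: Sequence[int]) -> float:
        vals = []
        for r in radii:
            m = rbin == r
            vals.append(f[m].mean())
        return float(np.mean(vals))

    lo, hi = ring_range_px
    ring = window_mean(range(lo, hi + 1))
    centre = window_mean(range(0, centre_radius_px))
    return ring / centre


def expected_gradient_ratios(
    sigma_list_nm: Sequence[float],
    config: Optional[SynthConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
) -> list[float]:
    """Analytic per-bin ratios for the spread-gradient fixture.

    The expected average image of bin b is a centred Gaussian with
    variance ``sigma_b^2 + spot_size^2 + psf_sigma^2`` (spot scatter
    convolved with the rendered spot profile), peak
    ``rate * amp_bar / (2 pi sigma_eff^2)`` counts, on a flat background,
    where ``amp_bar`` includes the log-normal amplitude-noise mean.
    """
    cfg = config or SynthConfig()
    pcfg = pipeline_config or PipelineConfig(pixel_size_nm=cfg.pixel_size_nm)
    render_sigma_nm = cfg.render_sigma_px("poi", cfg.poi_spot_size_nm) * cfg.pixel_size_nm
    amp_bar = cfg.poi_spot_amp * math.exp(cfg.amp_noise_sd_log**2 / 2.0)
    out = []
    for sigma_nm in sigma_list_nm:
        sigma_eff_px = math.hypot(sigma_nm, render_sigma_nm) / cfg.pixel_size_nm
        peak = cfg.poi_spot_rate * amp_bar / (2.0 * math.pi * sigma_eff_px**2)
        out.append(
            expected_gaussian_ratio(
                sigma_eff_px,
                side_px=pcfg.side_px,
                centre_radius_px=pcfg.centre_radius_px,
                ring_range_px=pcfg.ring_range_px,
                peak=peak,
                background=cfg.background,
            )
        )
    return out


# ---------------------------------------------------------------------------
# spine fixture

def make_spine_fixture(
    n: int,
    spine_class: str = "mushroom",
    config: Optional[SynthConfig] = None,
    side_px: int = 101,
    angles: Optional[Sequence[float]] = None,
    noise: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SynapseCrop], list[SpineLandmarks]]:
    """Synthetic landmarked spine crops at arbitrary orientations.

    Each crop holds an actin spine (head blob + neck + dendritic shaft
    band) rotated by a per-crop angle (default: uniform random), a
    post-synaptic punctum at the head centre, and POI spots placed on the
    dendritic side (between head and shaft), so aligned averages show the
    POI mass below the head centre. Landmarks are emitted in the rotated
    frame, exactly as a manual annotator would place them.
    """
    cfg = config or SynthConfig()
    if spine_class not in ("mushroom", "stubby"):
        raise InvalidConfigError(f"unknown spine class {spine_class!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if angles is None:
        angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    if len(angles) != n:
        raise InvalidConfigError("angles must have length n")

    centre = np.array([side_px // 2, side_px // 2], dtype=float)
    head_r_px = 8.0       # head radius ~240 nm
    neck_len_px = 10.0 if spine_class == "mushroom" else 3.0
    crops: list[SynapseCrop] = []
    landmarks: list[SpineLandmarks] = []

    sig_actin = cfg.render_sigma_px("actin", cfg.dendrite_sd_nm)
    sig_post = cfg.render_sigma_px("post_marker", cfg.punctum_size_nm)
    sig_poi = cfg.render_sigma_px("poi", cfg.poi_spot_size_nm)

    for i, phi in enumerate(angles):
        # unit vector from head centre towards the shaft, rotated by phi
        down = np.array([math.cos(phi), math.sin(phi)])
        perp = np.array([-down[1], down[0]])
        hc = centre.copy()
        junction = hc + (head_r_px + neck_len_px) * down

        actin = np.zeros((side_px, side_px))
        post = np.zeros((side_px, side_px))
        poi = np.zeros((side_px, side_px))

        # spine head
        _add_gaussian(actin, hc[0], hc[1], cfg.actin_amp * 150.0, head_r_px / 1.5)
        # neck: a few beads between head and junction
        for t in np.linspace(0.3, 1.0, 5):
            p = hc + t * (junction - hc)
            _add_gaussian(actin, p[0], p[1], cfg.actin_amp * 15.0, 2.0)
        # dendritic shaft: beads along the perpendicular through the junction
        for s in np.linspace(-side_px, side_px, 81):
            p = junction + s * perp
            _add_gaussian(actin, p[0], p[1], cfg.actin_amp * 20.0, sig_actin)

        _add_gaussian(post, hc[0], hc[1], cfg.homer_amp, sig_post)

        count = int(rng.poisson(cfg.poi_spot_rate))
        spot_sigma = cfg.poi_spread_nm / cfg.pixel_size_nm
        for _ in range(count):
            # biased towards the dendritic (shaft) side of the head
            t = rng.uniform(0.2, 1.6)
            lateral = rng.normal(0.0, spot_sigma)
            p = hc + t * (head_r_px + neck_len_px) * down + lateral * perp
            amp = cfg.poi_spot_amp * float(np.exp(rng.normal(0, cfg.amp_noise_sd_log)))
            _add_gaussian(poi, p[0], p[1], amp, sig_poi)

        channels = {
            "poi": _apply_noise(poi, cfg, rng if noise else None),
            "post_marker": _apply_noise(post, cfg, rng if noise else None),
            "actin": _apply_noise(actin, cfg, rng if noise else None),
        }
        crop = SynapseCrop(
            channels=channels,
            centre_in_source=(side_px // 2, side_px // 2),
            side_px=side_px,
            crop_id=f"spine{i}",
        )
        crops.append(crop)

        def _tup(p: np.ndarray) -> tuple[float, float]:
            return (float(p[0]), float(p[1]))

        lm = SpineLandmarks(
            crop_id=f"spine{i}",
            spine_class=spine_class,
            head_top=_tup(hc - head_r_px * down),
            head_bottom=_tup(hc + head_r_px * down),
            head_left=_tup(hc - head_r_px * perp),
            head_right=_tup(hc + head_r_px * perp),
            shaft_junction=_tup(junction),
            neck_top=_tup(hc + head_r_px * down) if spine_class == "mushroom" else None,
            neck_bottom=_tup(junction) if spine_class == "mushroom" else None,
        )
        landmarks.append(lm)
    return crops, landmarks
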