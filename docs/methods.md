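# Methods

This note documents the models, conventions and numerical choices behind
`stedpuncta`, in the spirit of a methods section a user could cite when
describing an analysis run.

## Geometry and conventions

* Pixel coordinates are 0-based `(row, col)`; a coordinate refers to the
  pixel's centre. User-facing CSV columns use `x = col`, `y = row`.
* Images are loaded as float64 and never rescaled. Plain multi-page TIFF
  with a JSON sidecar (channel order, pixel size, experiment/field ids) is
  the interchange format.
* Crops are squares of `round(crop_side_um · 1000 / pixel_size_nm)` pixels,
  adjusted upward to odd so "centred on the punctum" names an exact central
  pixel (3.0 µm at 30 nm/px → nominal 100 → 101 px). This one-pixel
  adjustment gives the radial analysis an unambiguous origin; the crop side
  remains configurable for strict even-sided replication.

## Radial profile and periphery/centre ratio

Each pixel joins radius bin `round(‖p − centre‖)`; the profile stops at
the largest radius whose complete ring fits inside the image, so every bin
is border-unbiased. This nearest-integer binning conserves intensity
exactly: the count-weighted profile sum equals the pixel sum inside the
largest ring (tested to machine precision). Fractional-radius weighting
(as some plot plugins use) was deliberately not adopted; the binning here
is declared, simple and testable.

The ratio divides the unweighted mean of profile values at radii 35–45
(inclusive, 11 bins ≙ 1.05–1.35 µm at 30 nm/px) by the mean at radii 0–9
(10 bins ≙ 0–0.3 µm). The two windows are configurable. Note an inclusive
35–45 ring spans eleven radius bins, one more than a literal "10-pixel-wide
ring" starting at 35; the inclusive reading is used and documented here.
On a uniform image the ratio is exactly 1 (the fully spread-out limit); a
ratio near 0 means complete concentration at the punctum. For a centred
isotropic Gaussian the ratio is strictly increasing in its width, which is
what makes the bin-5 − bin-1 delta a usable redistribution statistic.

## Ordering of the scalar-intensity steps

Outlier exclusion (single pass, keep `|v − mean| ≤ 3·SD`, moments computed
once on all values, sample SD) runs first, then per-experiment median
normalization, then pooled quantile binning. This order prevents extreme
synapses from shifting experiment medians. The exclusion is applied per
analysed variable (marker and POI) and the intersection of survivors is
kept. Note the ±3 SD rule is intentionally weak at small n — a single
extreme value inflates the SD enough to keep itself below n ≈ 60 — and the
tests document this property rather than hiding it.

Quantile binning sorts ascending with stable tie-breaking and splits into
contiguous groups whose sizes differ by at most one, remainder assigned to
the lowest bins; bin 1 is always the dimmest. Average images are computed
from the **un-normalized** POI crop arrays: normalization is a property of
the scalar statistics, and averaging raw arrays keeps the image contrast
physical.

## Spot detection

The à-trous (undecimated) B3-spline scheme smooths with the kernel
`[1,4,6,4,1]/16` whose taps are spaced `2^(j−1)` pixels at scale j (mirror
boundaries); detail planes are differences of successive smooths, so
reconstruction is exact by construction. Detection thresholds the scale-2
plane at `k · MAD/0.6745` with the sensitivity mapping
`k = (100 − s)/10 + 1` (s = 80 → k = 3; monotone: higher sensitivity,
lower threshold). This mapping is an explicit convention for the informal
"percent threshold" of interactive spot-detection GUIs and is not
bit-compatible with any of them.

A k = 3 cut on a spatially correlated detail plane leaves ~0.8 false
components per 64×64 crop, so detection is additionally restricted to the
supra-background support of the raw crop (pixel > median + 3·MAD-σ,
mirroring the empirical background threshold such workflows apply before
spot detection). The support cut is a mask conjunction, not a zeroing of
pixels, which would create step-edge artefacts in the wavelet planes. At
the reference operating point (peak SNR 8, spots ≥ 8 px apart) this gives
recall 1.0 and ~0.01 false positives per crop; the support multiplier is
not a knife-edge (2.5/3.0/3.5 → FP 0.075/0.010/0.000 per crop, recall 1.0
throughout). Components need ≥ 2 px; centroids are intensity-weighted on
the raw crop; spot size is reported as equivalent-disk diameter in nm.

## Spine alignment

Alignment is rigid (rotation + translation; no scaling or warping — spine
sizes are a biological signal). The head centre (centroid of the four head
border landmarks) maps to the crop's central pixel and the head→shaft
direction to "straight down". Bilinear interpolation; out-of-field pixels
are NaN and population averages are count-weighted per pixel, avoiding rim
artefacts that zero-filling would cause. Aligning an already-aligned crop
is the identity to machine precision, and a quarter-turned copy lands on
its reference within bilinear tolerance (< 2 % of peak in tests).

## Statistics

Spearman's rho is the Pearson correlation of average (tie-corrected)
ranks. The two-sided p-value is exact — full enumeration of the n!
permutations, vectorised — for n ≤ 9, and the t approximation
`t = ρ√((n−2)/(1−ρ²))` otherwise. Correlations are computed on crop-level
(per-synapse) normalized intensities pooled across experiments after
median normalization; linear fits are ordinary least squares on the bin
means, matching plots of binned data (raw-pair fits are available).
Significance labels use strict thresholds (p < 0.05/0.01/0.001/0.0001).
No multiple-testing correction is applied by default.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular culture:

* **Latents.** Per synapse, strength S and activity A are independent
  log-normals (median 1, log-sd 0.5), giving the right-skewed intensity
  distributions typical of synaptic markers and, by independence, near-zero
  correlation between rendered post- and pre-synaptic amplitudes.
* **Markers.** Integrated amplitudes: homer 1500·S, pre-synaptic marker
  1500·A counts, each with log-normal measurement noise (log-sd 0.1),
  rendered as Gaussians of physical size 80 nm convolved with the channel
  PSF.
* **POI.** Spot count ~ Poisson(λ·L^c_rate) and isotropic Gaussian spread
  σ = 250·L^c_spread nm around the synapse centre, L ∈ {S, A}. λ = 3.5
  matches the three-or-four organelle spots per spine head such stainings
  show; both couplings default to mild, configurable, and zero couplings
  give the null control. Spot amplitude 450 counts (~100-count peaks).
* **Optics.** Isotropic Gaussian PSFs, FWHM 60 nm for the STED channels
  and 250 nm for the confocal actin channel (configurable; resolution
  figures are nominal).
* **Noise.** Poisson (gain 1) then additive Gaussian read noise
  (sd 2 counts), clipped at zero. The background default is 5 counts so
  the clipping bias on expectations stays below ~0.04 counts.
* **Batch structure.** A per-experiment log-normal intensity factor
  (log-sd 0.15) exercises the median-normalization stage. Fields hold 12
  synapses each (~0.16 synapses/µm², a realistic culture density) with a
  1.2 µm minimum separation.

What the generator does **not** emulate: 3-D structure, photobleaching or
temporal dynamics, membrane-shaped ER (all markers are puncta), spectral
bleed-through, and detailed dendrite morphology (the actin channel is a
band plus blobs). Passing tests therefore demonstrate correctness of the
measurement pipeline under the stated statistical assumptions, not
robustness to every property of real tissue.

One emergent property worth knowing: at realistic densities, crops often
contain neighbouring synapses, which raises the marker crop mean and the
POI spot count together and produces a positive field-level POI–marker
correlation even with all couplings at zero. This is a property of
crowded fields (it is why a 3 µm crop is chosen to minimise neighbour
contributions), and it is why the decoupling null control is evaluated on
isolated single-synapse crops.

## Calibration fixtures and their analytics

The spread-gradient fixture emits five bins of crops whose POI spread
steps through a given σ list, with well-separated marker amplitudes so
quantile binning recovers the intended grouping. Spot counts in this
fixture follow the deterministic sequence `floor(λ(i+1)) − floor(λi)`
(3,4,3,4,… at λ = 3.5): the fixture is a calibration instrument for the
spread → ratio transfer function, so count shot noise — irrelevant to that
mapping — is excluded by design, while position scatter and pixel noise
are retained. With 100 crops per bin this puts the sampling sd of the
measured bin-5 − bin-1 delta at ≈ 0.017.

The expected average image of a bin is the analytic law
`λ·ā/(2π σ_eff²)·exp(−d²/2σ_eff²) + background`, with
`σ_eff² = σ_spread² + σ_spot² + σ_PSF²` and ā the log-normal-corrected
mean amplitude. The analytic periphery/centre ratio evaluates this law on
the pixel grid and averages over the same integer-radius bins as the
measured profile — computed directly, independent of the profile code —
so measured and expected ratios are comparable bin for bin.

## Problem sizes used in the checked examples

The bundled verification runs use 5 × 100 gradient crops, a 500-synapse
null control, 200 detection crops at SNR 8, and 50 random reconstruction
images; together they complete in well under a minute. All stochastic
stages take explicit seeds and identical (config, seed) pairs reproduce
bit-identical ground truth, images and result tables.

## Known limitations

* "Manual thresholding" of marker channels is replaced by an explicit,
  logged threshold (absolute or quantile); results depend on it the same
  way the original manual step did.
* Touching synapse puncta are not split; a minimum centre-to-centre
  distance filter exists but is off by default.
* Spot detection semantics approximate, but are not identical to,
  GUI-based wavelet spot detectors.
* No 3-D localization, no colocalization-based synapse definition, no
  automatic spine classification (landmarks are consumed from CSV).
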