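# stedpuncta

Punctum-centred average-image analysis for multichannel STED microscopy of
synapses, with a matched synthetic-image generator.

## The problem

In hippocampal neurons, secretory-pathway organelles (ER, ERGIC,
trans-Golgi, spine apparatus — marked by proteins such as calreticulin,
ERGIC53, TGN38 and synaptopodin) sit in and around dendritic spines. A
recurring question is how the abundance and spatial spread of such a
protein of interest (POI) around individual synapses relates to synaptic
strength (post-synaptic homer, pre-synaptic vGLUT1) and activity
(live-labelled SYT1). This package implements the quantitative pipeline
used to answer that question from four-colour images (POI + post-synaptic
marker + pre-synaptic marker + actin, ~30 nm pixels):

1. **localize** — threshold a synaptic-marker channel, find puncta
   (8-connected components, intensity-weighted centroids) and excise
   3 × 3 µm square crops centred on each punctum (101 px at 30 nm/px).
2. **binavg** — exclude outliers (mean ± 3 SD), normalize each synapse's
   mean intensity to the median of its experiment, sort crops into five
   equal-size ordinal bins by marker intensity, and average the POI crops
   of each bin pixelwise.
3. **radial** — reduce each average image to a radial profile (integer
   pixel radii) and the **periphery/centre ratio**

   $$R \;=\; \frac{\langle \bar I(r) \rangle_{r=35..45}}{\langle \bar I(r) \rangle_{r=0..9}}$$

   where $\bar I(r)$ is the mean intensity at rounded radius $r$ from the
   crop centre. $R \ll 1$ means the POI is concentrated at the synapse;
   $R \approx 1$ means it is spread out. The bin-5 minus bin-1 delta of
   $R$ quantifies redistribution with increasing marker intensity.
4. **spots** — detect POI puncta by an à-trous (undecimated) B3-spline
   wavelet decomposition: hard-threshold the scale-2 detail plane at
   3 × MAD-σ (80 % sensitivity), restricted to the supra-background
   support of the crop; report count, area and equivalent-disk diameter.
5. **spines** — rigidly align manually landmarked mushroom/stubby spine
   crops (head centre to the central pixel, head→shaft direction straight
   down) and average them with missing-pixel weighting.
6. **stats** — Spearman's rho (tie-corrected; exact permutation p for
   n ≤ 9) between POI and marker intensities, per-bin mean ± SEM, linear
   fits on bin means, significance stars.

Because the original microscopy data are not deposited, the **synth**
module simulates the whole acquisition — latent per-synapse strength and
activity variables, marker puncta, POI spot clouds whose count and spread
can be coupled to the latents, channel-specific PSF blur, Poisson–Gaussian
noise, per-experiment intensity factors — together with the ground truth
needed to verify every stage.

## Worked example

Simulate a small four-experiment dataset and analyse it end to end:

```bash
stedpuncta simulate --seed 1 --n-synapses 60 --n-experiments 4 --out sim
# -> wrote 8 fields and ground truth to sim

printf 'synapse_threshold: {kind: absolute, value: 20.0}\n' > cfg.yaml
stedpuncta analyze --config cfg.yaml --out results sim
# -> 55 synapses in 8 fields; ratio delta +0.057; Spearman rho 0.430 (**)
```

55 of the 60 simulated synapses are recovered (border crops are dropped).
`results/post_per_bin.csv` holds one row per homer-intensity bin:

```
bin_index,n,marker_mean,marker_sem,poi_mean,poi_sem,ratio
1,11,0.9723035184,0.003159023628,0.9832799927,0.005306204133,0.6427182488
2,11,0.9888087668,0.001055513248,0.9993018002,0.006754631647,0.5741984719
...
```

`marker_mean`/`poi_mean` are experiment-median-normalized intensities
(mean ± SEM per bin), and `ratio` is the periphery/centre ratio of that
bin's average POI image. The reported delta (+0.057) is bin 5 minus
bin 1; the Spearman rho (0.43, p < 0.01) reflects the crowding coupling
present in dense fields (neighbouring synapses raise both the marker crop
mean and the POI spot count), which is why crop-level controls matter —
see `docs/methods.md`.

The recovery benchmark simulates a five-step POI-spread gradient plus a
decoupled null control and compares the pipeline's output against the
generator's analytic expectations:

```bash
stedpuncta benchmark --seed 1
# -> ratio monotone: pass; delta vs analytic: pass; no-coupling control: pass
```

As a library:

```python
from stedpuncta import SynthConfig, PipelineConfig, simulate_dataset, run_pipeline

images, truth = simulate_dataset(SynthConfig(n_synapses=60, seed=1))
result = run_pipeline(images, PipelineConfig(), marker_mode="post")
result.ratios          # periphery/centre ratio per bin
result.correlation     # Spearman rho, p, stars, linear fit
```

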