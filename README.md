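# vppipe

Analysis pipeline for single-cell calcium imaging and anatomical count data
from ventral pallidum (VP) neuron subtypes studied across cocaine
self-administration, extinction, and cue-induced reinstatement — together
with a synthetic-data generator that produces every input with known ground
truth, so each stage of the analysis can be validated end to end.

The VP contains three partially overlapping neuron classes — glutamatergic
(VP_Glu, Vglut2⁺, ~23% of neurons), GABAergic (VP_GABA, Vgat⁺, ~73%) and an
enkephalin-expressing GABAergic subpopulation (VP_Penk, ~16%, nested inside
the Vgat⁺ class). Their activity is recorded with a head-mounted miniscope
(GCaMP6f, 15 Hz) while animals nose-poke for cocaine under an FR1 schedule
with 20-s cue timeouts, undergo extinction, and are re-exposed to
response-contingent cues.

## What the package computes

- **synth** — synthetic study inputs: Poisson-driven GCaMP6f-like ΔF/F
  traces at configurable event rates and SNR; one-photon movies with
  Gaussian footprints, rigid drift, and pixel noise; FR1 / extinction /
  reinstatement operant event logs; clustered (Thomas) vs completely
  spatially random (CSR) centroid fields; Bernoulli D1/D2 afferent labels;
  multinomial in-situ marker tables. All seed-deterministic, with exported
  ground truth.
- **extract** — the fixed preprocessing chain: 4× spatial block-mean
  downsampling → rigid motion correction (subpixel cross-correlation) →
  ΔF/F (running 20th-percentile or global-mean baseline) → PCA/ICA
  spatio-temporal source extraction → automated component QC.
- **events** — Ca²⁺ transient detection (prominence peak-finder plus a
  template-deconvolution pass that resolves overlapping transients),
  per-cell rates (events/min) and amplitudes restricted to the first
  60 min, cumulative event curves, and the extinction criterion
  (Ext10 active pokes < 40% of Ext1).
- **perievent** — nose-poke-aligned analysis: trial selection (≥ 20-s
  separation in extinction; cued pokes only in reinstatement), −10…+20 s
  windows smoothed with a running 10-point moving average and z-scored
  within the window, trial averaging, |z| population magnitude (pre −2–0 s
  vs post 0–2 s), and responder classification (> 2 SD above/below the
  pre-poke baseline ⇒ increased/decreased).
- **spatial** — the k-nearest-neighbor (k = 10) spatial clustering test
  against 1000 uniform shuffles, marker colocalization/density counting,
  rabies input-fraction quantification with pairwise Bonferroni-corrected
  chi-squares, and the subpopulation arithmetic (Penk share of the GABA
  class).
- **stats** — paired/one-sample t tests, repeated-measures ANOVA with
  Greenhouse–Geisser correction (one-way within and two-way mixed),
  Student–Newman–Keuls post hoc comparisons on the studentized range, and
  chi-square tests with Bonferroni adjustment.

## Worked example

```python
import numpy as np
from vppipe import synth, events, spatial
from vppipe.types import KernelParams

# a VP_Glu-like extinction-day-10 cohort: 50 cells, 60 min, 2.88 events/min
traces, truth = synth.gen_traces(50, 3600.0, rate_per_min=2.88,
                                 kernel=KernelParams(), snr=8.0, seed=0,
                                 cell_type="Glu", session="Ext10")
train = events.detect_events(traces)
stats = events.event_stats(train, limit_min=60.0)
print(stats.per_group)
#  cell_type session  n_cells  rate_mean  rate_sem  amp_mean  amp_sem
#        Glu   Ext10       50   2.806333  0.032964  0.271227 0.000903

# a clustered centroid field vs the CSR shuffle null
pattern = synth.gen_point_pattern(200, "clustered",
                                  synth.ClusterParams(n_parents=10, sigma_px=50.0),
                                  bounds=(0, 0, 1000, 1000), seed=1)
res = spatial.knn_clustering_test(pattern, k=10, n_shuffles=1000, seed=2)
print(res.observed, res.null.mean(), res.p, res.clustered)
# 69.44  135.80  0.0010  True

spatial.derive_subpopulation_fractions(penk_pct=16, vgat_pct=73)
# (22, 78)
```

The detected grand mean (2.81 ± 0.03 events/min) recovers the generating
rate of the cohort (the realised ground-truth mean for this seed is 2.83);
mean detected amplitude (0.27 ΔF/F) recovers the 0.25 mean event amplitude
with the expected small positive noise bias. The clustered field's mean
10-NN distance (69 px) falls far below the uniform-shuffle null (136 px),
so the test calls it clustered at p ≈ 0.001; 16% Penk and 73% Vgat
densities imply that 22% of the GABAergic class is enkephalinergic and 78%
is not.

A `vppipe` command-line tool wraps the same stages
(`vppipe simulate|extract|events|perievent|spatial|stats|all`), writing
HDF5 (movies, traces), CSV (events, behavior, tables) and JSON (statistics)
outputs.

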