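# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind each pipeline stage. Empirical figures quoted here
(null rates, recovery biases) are the quantities the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic data model

**Traces.** Each cell fires a homogeneous Poisson event train at
`rate_per_min`; every event adds a transient with the difference-of-
exponentials kernel

    h(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise),  t ≥ 0,

normalized to unit peak. Defaults τ_rise = 0.2 s, τ_decay = 0.6 s and mean
amplitude 0.25 ΔF/F describe a fast genetically encoded indicator
(GCaMP6f-class); the source study does not publish a kernel, so these are
package defaults, configurable via `KernelParams`. Event amplitudes are
lognormal with σ = 0.25 on the log scale and mean equal to `peak_dff`
(positive and right-skewed, as in real recordings). White Gaussian baseline
noise is scaled so that `peak_dff / noise_sd = snr`; an optional slow
sinusoidal baseline drift stresses the ΔF/F stage. Traces are sampled at
15 Hz, the study's acquisition rate, on a left-edge time convention
(sample *i* covers time *i*/fs).

**Movies.** Cells are rendered as isotropic Gaussian footprints (σ = 2 px)
modulated by `cell_baseline + trace` over a constant background, optionally
shifted frame-by-frame along a deterministic sinusoidal rigid-drift
schedule (amplitude `drift_px`, period 30 s; the planted shifts are
returned for recovery tests), with white pixel noise added last.

**Behavior.** Nose pokes follow a renewal process with exponential
inter-poke intervals and a 1-s refractory floor. Per-session mean active
rates are SA 0.8, Ext1 0.5, Ext10 0.1, Reinst 0.6 pokes/min over a 7200-s
session (analyses use the first 3600 s); the Ext10 rate is one fifth of
Ext1 so simulated subjects robustly satisfy the extinction criterion
(Ext10 < 40% of Ext1 responding). In SA sessions an active poke outside a
running 20-s timeout triggers an infusion plus a 5-s tone/light cue and
restarts the timeout; in reinstatement the cue only; in extinction nothing.
Pokes inside a timeout are logged `cued=False`. By construction no two cue
onsets are closer than the timeout.

**Spatial patterns.** CSR fields are uniform in the bounds. Clustered
fields are Thomas-type: uniformly placed parents, isotropic Gaussian
offspring (`sigma_px`), offspring falling outside the field redrawn so the
pattern has exactly *n* points. Upstream-input labels are i.i.d. Bernoulli
D1/D2 draws; in-situ marker tables draw each cell as Vglut2⁺ (p = 0.23),
Vgat⁺ (p = 0.73) or unlabeled, with the Penk⁺ subpopulation nested inside
the Vgat⁺ class at a conditional rate giving a 0.16 marginal.

What the generator does **not** emulate: bursty/periodic firing,
amplitude–rate correlations, overlapping or non-Gaussian footprints,
neuropil contamination, non-rigid motion, photobleaching, and
session-to-session cell registration. Recovery results on these synthetic
cohorts therefore validate the implementation of the analyses, not their
robustness to every property of real recordings.

## Extraction chain

The order is fixed — downsample → motion-correct → ΔF/F → PCA/ICA → QC —
matching the acquisition pipeline being re-implemented.

- **Downsampling**: block-mean pooling by an integer factor (default 4),
  cropping to the largest divisible region when needed.
- **Motion correction**: per-frame subpixel translation against the
  temporal mean image (or a chosen frame), estimated by upsampled
  cross-correlation (non-normalized variant, which is markedly more
  accurate than phase-normalized correlation on these smooth,
  low-texture frames); shifts are clamped to `max_shift_px` (default 10)
  and applied by linear interpolation. Planted ±3 px drifts are recovered
  to within 0.5 px.
- **ΔF/F**: (F − F₀)/F₀ with F₀ a running 20th percentile over a 30-s
  window (default) or the global temporal mean. Non-positive baselines are
  an error naming the offending pixel/cell.
- **PCA/ICA**: the movie (T × pixels) is reduced to `n_components`
  principal components; FastICA then unmixes the concatenation of the
  standardized temporal scores and spatial eigenimages weighted by
  `ica_weight` ∈ [0, 1] (default 0.1 — mostly temporal with a spatial
  term; the original acquisition software's parameter is unpublished).
  A practical default for `n_components` is ~1.5× the expected cell count
  (over-extraction, then QC). Component signs are fixed so each temporal
  trace has non-negative skewness — calcium transients are positive-going.
  Footprints are rectified; centroids are intensity-weighted over the
  footprint core (pixels ≥ 30% of the map's maximum) so diffuse residual
  noise cannot drag them toward the frame centre.
- **QC** (automated surrogate for manual curation): components pass when
  the footprint is compact (≥ 50% of its energy within 5 px of the
  centroid), the trace skewness is ≥ 0.2, and the active footprint area
  lies in [2, 400] px. Rejections are logged with reasons.

On planted ten-cell movies with ≥ 4-px separation and snr ≥ 5, at least
90% of cells are recovered with footprint correlation > 0.8 and trace
correlation > 0.7.

## Event detection

The study's acquisition software exposes an unparameterised "peak-finder";
the detector here is therefore defined from first principles and
calibrated on synthetic data.

**First pass.** The ΔF/F trace is smoothed with a 5-point moving average
(~0.33 s at 15 Hz, matched to the transient width), and local maxima are
kept when their prominence exceeds 6 robust SDs (1.4826 × MAD of the
smoothed trace), with the prominence window limited to ±2 s (a rise-time
gate) and maxima closer than 0.4 s merged keeping the larger. This pass
alone leaves a false-event rate on pure noise of ~0.01/min (well under the
0.1/min design ceiling) but undercounts Poisson trains in proportion to
their rate, because transients that overlap in time merge into a single
prominent maximum (−4 to −5% at 2.88 events/min).

**Second pass (overlap resolution).** The median waveform of isolated
first-pass events becomes a per-cell template; the trace is Wiener-
deconvolved against it (regularizer 0.05 × the template spectrum's peak
power), and impulses above 40% of the median single-event impulse height —
no closer than 2 samples — are the final events. This resolves pile-up to
the sampling limit: residual rate bias is ≈ +0.1% per event at
1.58 events/min and ≈ −1% per event at 2.88 events/min (events closer than
two samples at 15 Hz are physically unresolvable). Event times are
reported at the estimated transient onset (the 40%-rise crossing, which
sits within one sample of true onset at snr ≥ 10); amplitudes are the
peak-minus-preceding-trough heights, transferred through a median-ratio
calibration of the deconvolved impulse heights (mean amplitude recovered
within 10% at snr ≥ 8). When fewer than five isolated events exist the
first pass stands alone. Precision and recall both exceed 0.9 at snr ≥ 8.

**Session statistics.** Rates are event counts divided by the analysis
window (first 60 min, even when the recording is longer); amplitudes are
means over the same window; group summaries are mean ± SEM by
cell type × session. Cumulative event curves are per-cell counts
accumulated over 60-s bins. The extinction criterion is strict:
Ext10 active pokes < 0.40 × Ext1.

## Peri-event analysis

Trials are active pokes within the first 60 min that satisfy the session's
selection rule: in extinction, ≥ 20 s from both neighbouring active pokes;
in cued sessions, only cued pokes (outside any 20-s cue timeout). Each
−10…+20 s window is smoothed with a centered 10-point moving average
(even-length window: 5 samples left, 4 right, shrinking at the edges —
centered filters avoid phase lag in peri-event latencies), then z-scored
against that same windowed segment's mean and SD (a whole-trace
standardization is available via `zscore_scope="trace"`); smoothing
precedes z-scoring. Windows extending beyond the recording are dropped
with a log message; zero-variance windows yield NaN for that cell × trial.

Population magnitude uses the absolute value of the per-cell trial-averaged
z trace so activated and inhibited cells both contribute positively, with
pre = mean over (−2, 0] and post = mean over (0, 2] (half-open,
right-closed — the poke instant belongs to exactly one window).
Responder classification compares the post mean of the non-rectified
trial-averaged trace with the pre-window mean ± 2 SD; the baseline SD is
taken on the trial-averaged trace by default (`baseline_scope="average"`),
with a pooled per-trial alternative. Because smoothing and averaging
correlate neighbouring bins, the rule's empirical false-positive rate on
null cells is substantially above the nominal Gaussian 2-SD tail (~5–8%
for ten trials of noise); the test suite pins it against its own
Monte-Carlo estimate rather than a closed form. Heatmap rows order as
increased → unchanged → decreased, by post−pre magnitude within class,
with the cell index as a deterministic tiebreak.

## Spatial clustering test

The statistic is the mean over cells of the Euclidean distance to the
k-th nearest neighbour (k = 10; the "mean of the k nearest" reading is
available via `statistic="mean_of_k"`). The null redistributes the same
number of points uniformly — over the pattern's declared field bounds when
known, else over the observed bounding box — 1000 times. Distances are in
pixels; no physical calibration is applied.

Two summaries are reported. The one-sample t of the shuffle distribution
against the observed value (df = n_shuffles − 1) mirrors the original
analysis style, but its standard error shrinks as 1/√n_shuffles, so it
overstates significance for any fixed pattern; it is reported for
comparability only. The `clustered` decision instead uses the one-sided
empirical permutation p-value, (1 + #{null ≤ observed})/(n_shuffles + 1),
which is calibrated at the nominal level by construction: over 200 CSR
fields the rejection rate stays inside the 95% binomial interval around
α = 0.05, while Thomas-process fields with offspring SD at 5% of the field
width are detected with power > 0.9 at n = 200.

## Counting analyses

Colocalization tables report marker marginals and the full disjoint
combination partition (which must sum to the cell count). Input fractions
report per-starter-type D1 percentages and all pairwise 2 × 2 chi-square
tests, Bonferroni-adjusted across the number of pairs, without continuity
correction (an option exists). The subpopulation arithmetic derives the
Penk share of the GABAergic class as round(100 · Penk% / Vgat%) with its
complement — 22% / 78% at the 16% and 73% densities.

## Inferential statistics

t tests and chi-square use scipy; repeated-measures ANOVA uses pingouin
with the Greenhouse–Geisser epsilon computed from the sample covariance of
the repeated measures; corrected (possibly fractional) df are always
reported when the correction is on. For two-level designs sphericity holds
trivially and ε = 1 (and F equals the squared paired t). In the two-way
mixed design (cell type between × session within) one design-level ε from
the subject × session means scales the within and interaction effects.
"Newman–Keuls" is implemented as the Student–Newman–Keuls stepwise
procedure: means are ranked, each pair's studentized range statistic is
referred to the distribution with span-dependent r (scipy's
`studentized_range`), and non-significance propagates from wider spans
inward by carrying the largest blocking p value. Classical practice — no
post hoc when the omnibus F is non-significant — is a documented
convention, not enforced in code. Degenerate inputs (identical conditions
per subject, all-equal means, zero-variance differences) return F = 0 /
t = 0 with p = 1 rather than NaN.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; one global seed splits
into per-stage substreams via `SeedSequence([seed, crc32(stage_name)])`.
Test-suite cohorts are sized for precision at desk scale: event-rate
recovery uses 100 cells × 60 min at 1.58 events/min and 20 cells at
2.88 events/min (the 2-SE bands are computed from each sample);
`scripts/acceptance.py` uses the full 300-cell cohort at the 1.58 regime,
500 Bernoulli draws at 84% D1, and 200 CSR fields × 1000 shuffles for the
calibration estimate.

## Known limitations

- The detector's rate estimate retains a ≈ −1%-per-event bias at high
  event rates from sub-two-sample coincidences; at 15 Hz this is a
  sampling-rate limit, not a threshold choice.
- PCA/ICA is validated on well-separated Gaussian footprints; heavily
  overlapping or non-Gaussian cells are out of scope (no CNMF-style
  demixing, no neuropil subtraction, no non-rigid registration).
- The one-sample-t summary of the clustering test is anticonservative by
  construction (see above); downstream decisions should use the
  permutation p.
- Behavior simulation is a renewal process; it reproduces session-level
  counts and timeout structure, not within-session learning dynamics.
- No spike inference: "events" are fluorescence transients, not action
  potentials.
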