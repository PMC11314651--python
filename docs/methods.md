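# Methods

## Problem and signal model

A surgically created arteriovenous fistula (AVF) carries a palpable fine
vibration — the *thrill* — produced by pulsatile, partially turbulent flow at
the anastomosis. Stenosis weakens the thrill. In non-contact screening, the
skin over the fistula is filmed under controlled illumination; sub-pixel
vessel displacement modulates reflected luminance, so every pixel of the video
is a plethysmographic waveform. `avfthrill` quantifies the thrill from such
recordings and compares normal and stenotic cohorts.

The per-pixel waveform is modeled as the sum of

* an **arterial pulse**: a fundamental `f0` in the physiologic range
  (0.5–3 Hz) plus integer harmonics `n·f0`, `n ≤ 6`, with amplitudes that
  decay with order;
* a **thrill component** confined to the 5–10 Hz band, quasi-periodic rather
  than white (spiral laminar flow imprints regularity on the wall vibration);
* **wide-band noise** from diffuse skin reflection and the sensor, reaching
  up to the Nyquist frequency. The 15–20 Hz band contains no physiologic
  signal at rest and serves as a pure-noise reference.

Note that harmonics 5·f0 and 6·f0 of a typical pulse (≈6 and ≈7.2 Hz at
72 bpm) fall *inside* the thrill band. This overlap is physical, not an
artifact; it adds a floor to the thrill-band power that does not scale with
stenosis and is one reason group-level statistics, not per-recording
thresholds, are the endpoint here.

## The statistic

For one recording and odd kernel size `N`:

1. smooth every frame with the uniform `N × N` moving average;
2. take the time series of the analysis pixel;
3. band-pass to 5–10 Hz, cut the series into 256-sample segments with 75 %
   overlap, remove each segment's mean, apply a Hann taper, and FFT;
4. take each segment's peak power inside 5–10 Hz and reduce across segments
   by the median → `Peak_thrill(N)`;
5. repeat steps 3–4 with the 15–20 Hz band → `Peak_noise(N)`;
6. `SNR_thr(N) = Peak_thrill(N) / Peak_noise(N)`.

The ratio is dimensionless and exactly invariant to global luminance scaling,
which removes illumination and gain differences between sessions. Smoothing
suppresses spatially incoherent noise by ≈`N²` in power while the spatially
smooth vascular signal survives, so `SNR_thr(N)` rises with `N` until the
kernel outgrows the vessel's spatial footprint and starts diluting signal —
hence an optimum.

### Kernel-size optimization

Per-recording curves `SNR_thr(N)` over the odd grid 1…201 (101 sizes) are
averaged within each cohort, min–max normalized to [0, 1], and subtracted
(normal − stenosis). A 6th-order least-squares polynomial smooths this
residual; `N_opt` is the grid member maximizing the smoothed curve, ties
toward smaller `N`. The polynomial is fitted on an abscissa mapped to
[−1, 1]; raw powers `N⁶` with `N` in the hundreds are numerically
catastrophic.

Design choices that were genuinely open:

* **"Normalized" means per-curve min–max scaling.** This is invariant to
  positive affine transforms of each curve. Joint (pooled min/max)
  normalization is available via `joint_normalization=True`; it preserves the
  between-cohort level difference, whereas per-curve scaling isolates shape
  differences. The choice changes the residual's shape and therefore
  deserves this prominence.
* **Cohort curve = arithmetic mean** across recordings; median is available
  (`agg="median"`) for robustness to outlier recordings.
* `N_opt` maximizes the *smoothed* curve, not the raw residual.
* The same analysis pixel is reused across all kernel sizes of a recording.

### Group statistics

`SNR_thr(N_opt)` values are summarized per cohort by type-7
(linear-interpolation) quartiles and IQR. Normality is screened per cohort
with Shapiro–Wilk (Royston's AS R94, via `scipy.stats.shapiro`); SNR ratios
are right-skewed, so the primary comparison is the two-sided Mann–Whitney U
test regardless of that screen (the screen documents *why* the nonparametric
path is taken). The U test uses the exact null distribution when
`n₁·n₂ ≤ 64` and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. Each recording is treated
as an independent observation; repeated sessions of one patient are not
modeled as correlated, a simplification to flag when interpreting clinical
data.

## Analysis-pixel selection

Which pixel of the image the original system analyzed is not fixed by the
measurement principle, so the package makes it explicit:
`auto_select_roi` smooths the stack with a default 21 × 21 kernel and picks
the pixel with maximal 5–10 Hz band power (full-length DFT, mean removed),
ties broken in row-major order. It is deterministic and favors the vessel
ridge by construction.

## Spectral conventions

* 4th-order Butterworth filters, applied forward–backward (`sosfiltfilt`),
  i.e. zero phase: a pulse's peak time is preserved to within one sample.
* A band edge at or above 0.99 × Nyquist is clamped to 0.99 × Nyquist: the
  noise band's upper edge (20 Hz) equals Nyquist at 40 fps, where a literal
  corner is ill-posed. After clamping, a 17 Hz probe tone passes the
  15–20 Hz band with < 1.5 % amplitude loss.
* Segments: 256 samples, 75 % overlap, so a 10 s × 40 fps recording yields
  three segments — the minimum for a meaningful median. Per-segment mean
  removal keeps DC leakage out of band searches.
* One-sided power is scaled so its per-segment sum equals the tapered
  segment's energy (Parseval; checked to < 1e−8 relative error).
* "Median of peaks" is read as: median across segments of the per-segment
  in-band maximum. The alternative reading (median of several in-band local
  maxima within one spectrum) is noted but not implemented.
* Harmonic analysis reads harmonic `n` at the strongest bin within ±1 bin of
  `n × fundamental`, absorbing the drift that accumulates when a
  bin-quantized fundamental is multiplied up.

## Moving-average filter

Uniform `N × N` kernel, `N` odd, every weight `1/N²`, implemented with
`scipy.ndimage.uniform_filter` per frame. Borders use replicate padding, so
output shape equals input shape and constants are preserved exactly; what the
original acquisition software did at borders is unknowable, so this is a
documented convention. The implementation agrees with a nested-loop windowed
mean to < 1e−10 and `N = 1` is the exact identity. For kernel sweeps the
smoothed value is evaluated directly at the analysis pixel (window mean over
a replicate-padded copy), which is algebraically identical to filtering the
whole frame and keeps the 101-size sweep cheap.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is verified.

* **Pulse**: fundamental 1.2 Hz (≈72 bpm), harmonic amplitudes ∝ 1/n for
  n = 1…6, phases drawn uniformly per seed (phase structure is not
  constrained by the measurement).
* **Thrill**: an amplitude-modulated carrier at `thrill_center_hz`
  (default 7.5 Hz, modulation at the pulse rate, depth 0.5) with slow random
  phase drift, then projected onto 5–10 Hz by DFT masking so the band
  confinement is exact; normalized to unit RMS and scaled by
  `thrill_amp × stenosis_factor`. Default `thrill_amp = 0.3` relative to the
  unit-amplitude fundamental — a calibration choice (no quantitative
  thrill-to-pulse ratio is established for this modality), fixed once.
* **Noise**: `noise_sd` (default 1.0) is the per-pixel diffuse-reflection SD;
  a fraction `shared_noise_frac = 0.2` of it is spatially coherent sensor
  noise that smoothing cannot remove. This split reproduces the observed
  behavior that high-frequency noise shrinks but never disappears under
  large kernels, and it is what gives the SNR curve its interior structure.
* **Space**: a Gaussian vessel ridge (width 5 px, amplitude 0.85 over a 0.15
  baseline) along the center column multiplies the waveform;
  `halation_count` static saturated disc patches emulate residual specular
  glare (a polarizing filter removes most of it before capture, so what
  remains is static); per-pixel noise is independent.
* **Cohorts**: per-recording jitter — fundamental ±0.2 Hz uniform, thrill
  amplitude × exp(N(0, 0.3)), noise SD × U(0.8, 1.2), thrill center
  U(6, 9) Hz. Stenosis recordings multiply the thrill by
  `stenosis_factor = 0.5` by default.

What the generator does **not** emulate: subject or camera motion, skin-tone
and shading variation, breathing artifacts, flow-dependent waveform shape
changes, or within-patient correlation across sessions. Passing tests
therefore demonstrate that the pipeline measures what it claims on signals
with the assumed structure — not that it is robust to the full messiness of
clinical video.

## Problem sizes and reproducibility

Synthetic validation uses 32 × 32-pixel, 10 s × 40 fps recordings and kernel
grids clipped to the image (odd 1…31), with cohorts of 50 + 50 recordings and
20 cohort replicates; these sizes give stable Monte-Carlo estimates while
keeping a full run in minutes on one core. The default 101-point grid is
exercised on 201 × 201 stacks. All randomness flows through
`numpy.random.default_rng` seeds carried in the parameter objects; identical
parameters and seed give bit-identical waveforms, stacks, cohorts, and
pipeline outputs, and every output file records a hash of the configuration
that produced it.

## Numerical notes and edge cases

* A zero noise-band peak (noiseless synthetic input) makes `SNR_thr`
  undefined and is signaled as `DegenerateInputError`, not returned as ∞.
* Min–max normalization and Pearson correlation are undefined for constant
  inputs and are signaled likewise.
* Waveforms shorter than the filter warm-up (3 × the filter's state length)
  are rejected rather than filtered with dominant edge transients.
* A constant residual curve has `SS_tot = 0`; R² is undefined and signaled.
* TIFF round-trips preserve pixel values exactly for 8/16-bit integer and
  float data; the simulator quantizes to 16-bit with the offset/gain recorded
  in the YAML sidecar (the SNR statistic is scale-invariant, and
  mean-removal absorbs the offset).

## Known limitations

* The clinical effect size, `N_opt = 21`-scale optima, and reported p-values
  of real cohorts depend on properties of clinical recordings (313 sessions,
  92 patients in the motivating study) that the synthetic generator only
  emulates qualitatively; this package's numbers characterize the method, not
  any patient population.
* Single-pixel analysis after smoothing is one defensible reading of the
  measurement; ROI-mean variants would differ mainly in their effective
  smoothing.
* No per-patient diagnostic threshold, ROC analysis, or stenosis
  localization is provided; the endpoint is the group-level difference.
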