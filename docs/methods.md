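# Methods

## Problem and model

Thoracic electrical impedance tomography (EIT) monitors regional lung
ventilation from boundary-voltage measurements. With 16 electrodes in
adjacent-drive mode, each frame holds 16 × 13 = 208 voltages, sampled here at
20 Hz, and dynamic images are obtained linearly from the difference to a
reference frame, y = B(x_c − x_ref). Long recordings are corrupted by three
characteristic motion artifacts:

* **baseline drift** — slow additive wander (e.g. a pulsating air mattress),
* **step-like shifts** — abrupt, persistent baseline changes (postural change),
* **spike-like transients** — abrupt excursions that return to baseline.

The cleaning framework decomposes each channel with a multilevel discrete
wavelet transform (Daubechies db8 — 8 vanishing moments, 16-tap filters —
with half-sample symmetric boundary extension), suppresses the coefficients
that carry each artifact class, and resynthesises the channel:

* drift lives in the deep approximation band `a_6` (≈ [0, 0.156] Hz at
  20 Hz); excluding `a_6` from the rebuild acts as a high-pass filter that
  spares the 0.25 Hz respiratory band;
* steps produce isolated large finest-detail (`d_1`) coefficients, used to
  localize the change point; the offset is then estimated and subtracted in
  the time domain;
* spikes concentrate in detail levels `d_1`–`d_4`; outlier coefficients in
  those bands are hard-suppressed before the rebuild.

All thresholds are robust: τ = k · MAD/0.6745 with k = 5 by default, i.e.
five Gaussian-equivalent standard deviations about the median of the
coefficient band.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `drift_level` | 6 | approximation depth excluded by the drift stage; at fs = 20 Hz the cut-off is fs/2⁷ ≈ 0.156 Hz. For other rates use `drift_level_for_cutoff(fs, f_cut)` = ⌊log2(fs/2f_cut)⌋ |
| `step_detection_level` | 1 | detail band used for change-point localization (5–10 Hz) |
| `spike_levels` | (1, 4) | detail bands suppressed by the spike stage (0.625–10 Hz) |
| `threshold_k` | 5.0 | robust-threshold multiplier; larger = fewer detections |
| `step_offset_window` | 40 samples (2 s) | base window for step events; the offset regression fits over 3× this span on each side |
| `min_event_separation` | 40 samples | detections closer than this merge into one event |
| `spike_mode` | `threshold_local` | suppress only outlier coefficients; `zero_global` zeroes the bands wholesale |

Stage order defaults to **step → drift → spike**: a step must be corrected on
the raw signal, because high-passing first (drift removal) turns the
persistent offset into a decaying transient and biases the offset estimate
(measured bias ≈ 3× on the default simulation). The order is caller-selectable.

## Step detection, classification and offset estimation

Candidate change points are `d_1` coefficients with |d_1| > τ, mapped back to
sample indices (level-1 coefficient c covers samples near 2c), merged within
`min_event_separation`, and refined to the largest first difference inside
the merged support (± the db8 half-support of 8 samples).

Events are classified by **jump bipolarity**: a transient that returns to
baseline has a leading jump matched by an opposite-sign jump of at least half
its size inside the support (→ spike); a persistent shift does not (→ step).
A plain median-level persistence test is biased by the phase of the
oscillatory physiological background and misfires when the per-channel
breathing amplitude rivals the step size.

The subtracted offset is estimated by **harmonic-background regression**: the
two dominant oscillation frequencies around the change point are read off the
periodogram of a ±512-sample window (after removing a rough jump estimate),
and the jump is re-estimated by least squares over a ±120-sample window with
regressors {1, n, sin/cos at the two frequencies, unit step}. On the default
simulation this recovers a unit step to ≤ 0.011; the simpler
difference-minus-local-median-slope estimate serves as initializer and as
fallback near record edges. Two steps closer than the fit window may bias
each other's estimates; detections merged within `min_event_separation`
count as one event.

## Synthetic data

The clean channel is x[n] = ½ Σᵢ μᵢ sin(2π fᵢ n/fs) + λ g[n] with a
respiratory component (0.25 Hz, μ = 0.9), a cardiac component (1 Hz,
μ = 0.2), fs = 20 Hz and 5,000 samples. The noise amplitude defaults to
λ = 0.02, small enough that the oscillatory structure dominates (SNR ≈ 26 dB).
Artifacts are strictly additive — contaminated = truth + Σ artifacts with no
renormalization — with defaults: sinusoidal drift of amplitude 1.0 at
0.02 Hz; unit step at sample 2,500; five triangular spikes of amplitude 1.5
and base width 3. All generators are deterministic given their seeds.

What the generator does **not** emulate: respiratory-rate variability and
sighs/apneas, amplitude drift of physiological origin, electrode-contact
failures, correlated multi-channel noise, and cardiac waveform morphology
(a pure sinusoid stands in). Passing tests therefore demonstrate correct
behaviour of the decomposition/suppression machinery under the stated signal
model, not clinical performance.

## Imaging stage

The phantom is the unit disk with unit background conductivity, 16 equally
spaced point electrodes, and a structured triangular mesh (784 elements for
the default ~800-element target). Piecewise-linear finite elements give the
16 adjacent-injection potential fields; the sensitivity matrix uses the
adjoint formula J[(p,q),e] = −A_e ∇u_p·∇u_q, which makes drive/measurement
reciprocity exact by construction. The inverse is one-step Tikhonov,
B = (JᵀJ + αI)⁻¹Jᵀ with α = 10⁻³ · trace(JᵀJ)/n by default, rasterized to a
32 × 32 grid with a circular mask (off-mask pixels are NaN). GREIT — used for
the patient images this framework was motivated by — is intentionally not
reimplemented: all image metrics here compare like with like through the same
linear inverse, so absolute image-error magnitudes are not comparable to
GREIT-based values.

The image-level study (`run_phantom_study`) forward-projects two lung-shaped
inclusions breathing with the simulated waveform into 208-channel frames,
adds one artifact uniformly to all channels scaled to the median channel
amplitude of the ventilation signal (no published value exists for this
magnitude; "comparable to the signal" matches the patient recordings
qualitatively), cleans channel-wise, and compares end-inspiration difference
images against the artifact-free reconstruction. The phantom series uses
2,000 frames (100 s), which admits the level-6 drift decomposition with
margin while keeping multi-seed studies fast.

## Evaluation metrics

* **PRD** = 100 · Σ(x−y)² / Σx² — implemented exactly as the ratio of sums
  of squares (no square root); the classical square-root form is available
  via `prd(..., root=True)`.
* **R²** = Σ(y−x̄)² / Σ(x−x̄)², x̄ = mean(x) — a variance ratio, **not** the
  regression coefficient of determination: it is 1 for perfect agreement and
  exceeds 1 when the candidate is more variable than the reference (an
  artifact-contaminated signal typically is, e.g. 4.32 for the default drift
  scenario).
* **Image error** = Σ|Aᵢ−Bᵢ| / Σ|Rᵢ| and **image correlation** = Pearson r
  over in-mask pixels.
* **Improvement** = (before − after)/before · 100; displayed at 2 decimals,
  raw metrics at 4.

## Numerical choices and limitations

* Perfect reconstruction is asserted at 1e−8 relative max error;
  coefficient-level comparisons (library vs from-scratch convolution oracle)
  at 1e−10 absolute on unit-scale inputs.
* The drift stage inherently attenuates ~3.5% of the 0.25 Hz respiratory
  amplitude (the `a_6` filter rolls off at 0.156 Hz, not a brick wall), so an
  artifact-free channel passes the full pipeline with PRD ≈ 0.13 rather than
  0; the step and spike stages are pass-through to PRD ≤ 0.05. This matches
  the post-drift variance ratio ≈ 0.97 seen in the simulation study.
* In `threshold_local` spike mode the `d_4` threshold adapts to the cardiac
  component living in that band, so the part of a spike's energy below that
  threshold survives (~40–50% PRD residual in the spike scenario); the
  respiratory and cardiac content is preserved in exchange. `zero_global`
  removes spikes more aggressively but deletes the cardiac band with them.
* Sample indices are 0-based; t = n/fs. Ties in change-point refinement
  resolve to the earliest sample (`argmax` on the first difference).
* All processing is offline; streaming operation, electrode-fault
  compensation and complete-electrode-model corrections are out of scope.
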