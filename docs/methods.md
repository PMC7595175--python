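# Methods and design notes

This note records the models behind each stage of the pipeline, the
defaults and why they are set where they are, what the synthetic sessions
do and do not emulate, and the places where the design was genuinely open
and a choice had to be made.

## Signal model

A subject ROI's mean intensity is modelled as

    x(t) = B + a(t) · p(t) + Σ_k A_k cos(2π f̃_k t + φ_k) + s(t) + ε(t)

where `p(t)` is a pulse-shaped carrier at the instantaneous heart rate,
`a(t) = A·(1 + d·sin(2π ∫ rr/60))` its respiratory amplitude modulation
(RIAV) with depth `d`, the cosine terms are mains-flicker tones folded to
`f̃_k = alias(f_k, fps)` by the camera frame rate, `s(t)` a piecewise
constant illumination level, and `ε` white Gaussian noise. The background
ROI shares only the flicker, the steps and the noise statistics — that
shared structure is exactly what the ARk estimator exploits.

## Stage-by-stage notes

### Stability selection
Motion is the Euclidean centroid displacement between consecutive frames;
a frame is active when it exceeds 100 px (strictly), and a session must be
stable for at least one third of its frames (boundary kept). Missing
centroids count as active: an untracked face cannot contribute estimates.

### Band-limiting
Linear detrend followed by a windowed-sinc (Hamming) FIR band-pass,
0.6–4 Hz, order `4·fps` rounded even (61 taps at 15 Hz), applied
forward-backward. Zero-phase filtering matters because the beat detector's
onsets feed instantaneous-HR and RIAV timing; phase distortion would bias
both. At 15 Hz the design passes 1.2 Hz at gain 0.998 and attenuates 5 Hz
by far more than 20 dB. Pulses near the 0.6 Hz edge (≈40 beats/min
fundamentals) are reshaped by the filter; this is the main reason beat
localisation degrades at the bradycardic end (see Limitations).

### Step-change detection
The single-step Bayesian posterior is evaluated in log space — the bracket
term is raised to −(N−2)/2 and overflows immediately otherwise — and
normalised over the admissible split locations m ∈ [2, N−2] so that the
0.8 probability threshold used by the beat quality gate is well defined.
A constant window carries no evidence and is flagged with a uniform
posterior rather than an arbitrary argmax. Windows are 30 s advancing
25 s (5-s overlap, read literally; the hop is configurable because the
same phrase is used elsewhere for 5-s hops). Per-sample probability is the
maximum posterior mass any covering window assigns to that sample. The
detector runs on the *unfiltered* series: the band-pass would remove the
step itself.

### Beat detection
The SSF accumulates positive first differences over `round(0.170·fps)`
samples (the adult pulse upslope at rest); the window is fixed rather than
scaled with instantaneous rate. Two regimes break a literal zero-crossing
segmentation of the SSF: noise keeps it slightly positive between pulses,
and above ≈160 beats/min consecutive upslopes arrive inside the SSF window
so its floor never reaches zero. The box level therefore sits 20% of the
way between the rolling minimum and maximum of the SSF over a 2-s span
(longer than the longest physiological beat). The level crossing lands
partway up the rise, so each box start walks back to the preceding SSF
local minimum and begins at the first rising sample after the trough.
Onsets are declared by the adaptive threshold (initialised to the median
of the first 30 s of uBSSF values, +10% of the excess on detection,
−10% multiplicative decay below — the subtractive reading is selectable),
with one onset per box and a 0.25-s refractory period matching the
240 beats/min ceiling.

### Templates and DTW
Template stages: (1) inter-beat rate within 36–240 beats/min,
(2) zero-lag cross-correlation with the stage-1 template above 0.8 after
peak alignment, (3) amplitude below three standard deviations of the
stage-2-valid beats. "Amplitude" is read as the beat's maximum deviation
from its own mean and σ as the sample SD pooled over stage-2-valid beat
samples; for roughly sinusoidal pulses this retains nominal beats
(amp ≈ A against 3σ ≈ 2.1A) while rejecting multi-fold motion outliers.
Each stage must keep at least half the window's beats; the template length
is the median beat length.

DTW operates on slope (first-difference) sequences of beats that are
rotated (endpoint-to-endpoint trend removed) and min-max normalised, with
local cost `|Δx_i − Δy_j|`. Scales halve the series length down to 16
samples; the optimal path at each scale is projected up and refined within
±2 cells. With no band constraint the procedure reduces to classical DP
and is bit-exact against a brute-force oracle. The SQI divisor of 100 in
`1 − cost/100` is kept verbatim; under this normalisation typical beat
costs are well below 100, so the score concentrates near 1 for clean beats
and the binary gates do most of the rejection — the clamp at 0 handles
costs beyond the scale.

### Clipping detector
Saturation is detected on the window-normalised beat: a derivative sample
counts as clipped when its magnitude is below 0.1× the window's maximum
derivative while the signal sits in the outer 10% of the window's range;
the beat fails when more than a third of its derivative is clipped. All
three constants are configuration values.

### Heart-rate estimators
Beat counting uses (N−1) intervals over the first-to-last onset span (the
N/Δt reading is selectable). The FFT estimator Hamming-tapers and
zero-pads 8×. AR models are fitted with Burg's method (stable on 15-s
windows), order 8 everywhere.

ARk fits its AR models on per-window *detrended raw* series, not the
band-passed PPGi: band-passing colours the background noise, handing the
background model spurious strong in-band poles that can cancel the cardiac
pole, and raw windows also keep aliases outside the cardiac band visible.
A subject pole is cancelled when it lies within 2° of a background pole
that is either dominant (radius ≥ 0.8 — artefact tones are strong
narrowband components) or identical in radius within 0.1 (the same pole
fitted twice). Without the dominance requirement, a weak background noise
pole that happens to fall near the cardiac angle would cancel the pulse
itself. Each colour channel is cancelled against the same-channel
background model. The reconstructed spectrum is evaluated on a 4096-point
grid with ties broken toward the lower frequency.

A 15-s window is only estimated when its valid beats cover it: any
internal onset gap exceeding max(2 s, 2.5× the window's median inter-beat
interval) invalidates the window. Mean beat SQI alone cannot punish spans
where clipping suppressed beat detection entirely — absent beats do not
lower a mean — yet such spans corrupt the window's spectral fits.
Estimates are timestamped at window end and suppressed when that frame is
active (Act = 0).

### Fusion
The Kalman filters use F = H = 1, Q = 0.1 (quiet) / 0.2 (motion),
`R(k) = R_base·exp(1/SQI² − 1)` with `R_base = 4 bpm²` (set to the order
of per-window estimator noise on synthetic sessions; configuration value),
initial state from the first accepted measurement with P = 100, and
re-initialisation after measurement gaps longer than 60 s. Zero-SQI
windows are prediction-only steps. The ND combination uses normalised
inverse-variance weights on `σ_i² = (r_i/SQI_i)²`, algebraically equal to
the product form and verified so in the tests; zero-SQI streams are
excluded outright.

### Respiration
RIAV amplitudes (peak minus onset value) use parabolic sub-sample
refinement and skip beats within 2 s of the series edges: sampled extrema
of a pulse whose period is a non-integer number of frames alternate
beat-to-beat, planting a spurious tone at exactly half the beat rate, and
zero-phase filter transients corrupt edge amplitudes. Face and torso
candidates get the same preparation before PCA — linear detrend and a
1-Hz zero-phase low-pass — because only the respiratory band is
informative (beat-amplitude noise is broadband; torso series leak cardiac
motion). PCA components are kept, in descending variance order and up to
five, when their dominant frequency lies in 0.1–0.7 Hz.

Spectral moments for the SPI are discrete sums of the Hann-tapered,
4×-zero-padded periodogram against powers of normalised angular frequency.
The in-band SNR gate compares power within ±0.05 Hz of the peak against
the remaining in-band power (the SNR definition is a package choice; both
the half-width and the threshold are configuration values).

The per-window AR dominant-pole rule for RR additionally requires
candidate poles to carry periodogram support (≥ 25% of the in-band
spectral maximum at the pole frequency): pole radius alone is fragile when
a weak but perfectly narrowband artefact line shares the band with the
modulation-broadened respiratory peak. Component streams fuse with the
same ND scheme, one filter per component, timestamped at window centres
every 5 s, in three groups (face, torso, combined).

## The synthetic sessions

The generator emulates the statistical structure the pipeline assumes:
an asymmetric raised-cosine pulse (upslope 0.17 of the period — 170 ms at
60 beats/min — with a slower raised-cosine decay), respiratory amplitude
modulation at configurable depth (default 0.3, the middle of the typical
10–30% physiological modulation range), flicker tones written with
identical amplitude and phase into background and every subject ROI,
global illumination steps, hard saturation during clip intervals, centroid
jumps plus transient baseline swings during motion intervals, and white
Gaussian noise (default SD 0.05 against a unit pulse amplitude on a
baseline of 100 intensity units — the pulsatile signal is deliberately a
≈1% perturbation). One random stream is seeded per session and consumed
in fixed order, so sessions are bit-reproducible. Default sessions carry
nine subject ROIs — a scaled-down grid that keeps full-pipeline runs
fast; the pipeline itself accepts any ROI count, and the ROI-grid helper
still produces the full 81-tile layout from a face box.

What the generator does *not* emulate — and therefore what passing tests
cannot show about real video: heart-rate variability and beat-shape
variability (synthetic beats are metronomic given the HR trace), skin-tone
and sensor physics, motion that distorts rather than interrupts the pulse,
flicker whose aliased frequency wanders, and non-Gaussian sensor noise.
Estimator accuracy on real recordings is bounded by those effects, not by
the numbers reported here.

## Problem sizes in the verification runs

The acceptance script uses 100 15-s windows for the ARk/FFT comparison,
100 random pairs for the DTW oracle, 200 trials each for change-point
localisation (step/σ = 3) and false alarms, nine 60-s sessions spanning
40–200 beats/min for beat detection (recall and precision pooled over all
beats of the sweep), a 5-minute session for respiratory recovery, and a
10-minute session with drifting vitals, two steps, one clipping episode
and two motion gaps for the end-to-end check. These sizes make the whole
report reproducible in about a minute while keeping every proportion
estimate to within a few percent.

## Known limitations

* **Bradycardic and tachycardic extremes.** At 15 frames/s a 200 beats/min
  pulse spans 4.5 samples and a 40 beats/min fundamental sits on the
  band-pass edge; beat recall/precision per rate dips to ≈0.85–0.9 at the
  extremes while the pooled sweep statistics stay above 0.95.
* **AR dominant pole without cancellation** is fragile on harmonic-rich,
  drifting pulse trains — the second-harmonic pole can out-radius the
  smeared fundamental. It is retained as specified; ARk and the other two
  estimators are the accurate routes.
* **Flat-spectrum SPI floor.** The spectral-moment ratio of an ideal flat
  spectrum is (1/3)²/(1/5) = 5/9 ≈ 0.556; white-noise windows therefore
  concentrate *above* 0.5 and the SPI separates sinusoids from noise by
  the gap between ≈0.56 and ≈1, not by a 0.5 midpoint. The quality gate
  combines SPI with the variance-explained and SNR rules for this reason.
* **Residual-weighted ND fusion** favours self-consistent streams over
  accurate ones; a stream with a stable small bias draws weight. Median
  fusion is the robust alternative when many ROIs are available.
* The Kalman `R_base`, clipping constants, RIAV amplitude conventions and
  the RR pole-support fraction are package choices where the underlying
  method is silent; all are exposed in `PipelineConfig`.
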