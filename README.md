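# camvitals

Non-contact estimation of heart rate (HR) and respiratory rate (RR) from
camera-derived photoplethysmographic imaging (PPGi) signals.

A standard colour camera pointed at a person records, in the mean pixel
intensity of small skin regions, a tiny periodic colour variation driven by
the cardiac cycle, amplitude-modulated by breathing. This package turns
those per-ROI intensity time series — as extracted from video of, for
example, patients during multi-hour dialysis sessions — into continuous,
quality-gated HR and RR estimates. It is written for researchers in
camera-based physiological monitoring who have ROI mean-intensity traces
(plus a face-centroid track and one background-ROI trace) and need the full
estimation chain behind them.

## The estimation chain

Given per-ROI series sampled at the camera frame rate (15 Hz by default):

1. **Stability selection.** Frame-to-frame face-centroid displacement
   `M(i)` is thresholded at 100 px into a binary activity index `Act(i)`;
   sessions stable for less than a third of their length are discarded.
2. **Band-limiting.** Each raw series is detrended and zero-phase FIR
   band-passed to 0.6–4 Hz (36–240 beats/min).
3. **Step-change detection.** Illumination steps (lights switching,
   shadows) are found with a Bayesian single change-point model: with flat
   priors and the noise scale marginalised out, the posterior over the step
   location `m` in an `N`-sample window is

   `P(m|x) ∝ [m(N−m)]^(−1/2) [Σx² − (Σ₁..m x)²/m − (Σm+1..N x)²/(N−m)]^(−(N−2)/2)`

   normalised over `m ∈ [2, N−2]` and scanned over 30-s windows.
4. **Beat detection.** A slope sum function (SSF) accumulates positive
   first differences over a 170-ms window; SSF excursions are boxed, and an
   adaptive threshold over the box upslopes (uBSSF) declares beat onsets,
   with peaks at the waveform maxima between onsets.
5. **Beat quality.** Each 30-s window builds a three-stage pulse template
   (physiological inter-beat rate → cross-correlation > 0.8 → amplitude
   below 3 SD); each beat is compared with the template by a multi-scale
   dynamic time warping whose local cost is the absolute slope difference.
   Six indices multiply into the per-beat score:
   `SQI_beat = SQI_act · SQI_cp · SQI_freq · SQI_amp · SQI_clip · SQI_dtw`,
   with `SQI_dtw = 1 − DTW(X,Y)/100`.
6. **Four HR estimators per 15-s window (1-s step):** beat counting;
   the band-restricted FFT peak; the dominant pole of an order-8
   autoregressive (AR) model; and **ARk** — AR pole cancellation: mains
   flicker (100 Hz from 50 Hz supplies) aliases into the pass band at the
   15 Hz frame rate, and because it is shared between the skin ROIs and a
   background ROI, any subject-model pole within 2° of a dominant
   background-model pole is removed before reading the HR off the
   reconstructed spectrum `|H'(e^{jω})|²`.
7. **Fusion.** Median across ROIs with SQI > 0.8; a scalar Kalman filter
   over the median stream with `R(k) = R·exp(1/SQI_w² − 1)` so poor windows
   defer to the prediction; and Kalman ND — one filter per (ROI, channel)
   combined by inverse-variance weights built from `σ_i² = (r_i/SQI_i)²`.
8. **Respiration.** Beat amplitudes (RIAV) from the face and grey-level
   motion of the upper torso are resampled to 4 Hz, reduced by PCA to at
   most five in-band components, gated by the Spectral Purity Index
   `Γ = w̄₂²/(w̄₀·w̄₄)` plus variance-explained and SNR rules, tracked per
   30-s window with an order-8 AR model, and fused per group (face, torso,
   combined).

Since clinical video cannot be redistributed, the package ships a
first-class synthetic session generator (`camvitals.synthetic`) that
produces pulsatile PPGi with respiratory modulation, shared aliased
flicker, illumination steps, clipping and motion gaps — with exact ground
truth — in the same format real extracted signals use.

## Worked example

Simulate a two-minute session at 72 beats/min and 15 breaths/min, plus an
upper-torso recording, and run the full pipeline:

```
$ camvitals simulate --duration 120 --hr 72 --rr 15 --seed 5 --out session.csv
wrote session.csv (1800 frames at 15 fps)
$ camvitals simulate --duration 120 --rr 15 --seed 5 --torso --out torso.csv
wrote torso.csv (1800 frames at 15 fps)
$ camvitals estimate session.csv --torso torso.csv --out-dir results
wrote 1272 HR and 54 RR estimates to results
```

`results/hr_estimates.csv` holds one row per second per estimator per
fusion scheme. The ARk + Kalman-ND stream starts:

```
 time_s     value      sqi method   fusion
   15.0 70.040700 0.991657    ark kalmanNd
   16.0 69.535375 0.991872    ark kalmanNd
   17.0 70.276894 0.992002    ark kalmanNd
```

Its mean over the session is 69.9 beats/min across 106 one-per-second
estimates (the true rate is 72; each window's SQI near 0.99 says almost
every beat passed all six quality gates). The combined respiratory stream
in `results/rr_estimates.csv` averages 15.0 breaths/min against a true 15.
`results/beat_sqi.csv` lists every beat with its six quality components,
and `results/gap_histogram.csv` the distribution of gaps between
successive estimates.

The same run is available from Python:

```python
import camvitals as cv

cfg = cv.SyntheticConfig(duration_s=120, hr_trace=72.0, rr_trace=15.0, seed=5)
session, truth = cv.generate_session(cfg)
result = cv.run_pipeline(session, cv.PipelineConfig(),
                         torso_session=cv.generate_torso_session(cfg))
result.hr_table().head()
```

## Layout

```
src/camvitals/
  synthetic.py      session generator + ground truth
  preprocessing.py  activity index, ROI grid, band-limiting
  changepoint.py    Bayesian step-change posterior
  beats.py          slope-sum beat detection
  quality.py        pulse templates, multi-scale DTW, beat SQI
  heart_rate.py     beat-count / FFT / AR-pole / ARk estimators
  fusion.py         median, Kalman 1D, Kalman ND, gap statistics
  respiration.py    RIAV, PCA selection, SPI gating, RR estimation
  pipeline.py       end-to-end orchestration
  io.py, cli.py     CSV/HDF5/JSON/YAML I/O and the CLI
docs/methods.md     model and design notes
```
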