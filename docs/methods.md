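# Methods

## Signal model

The algorithm assumes a quasi-periodic cardiac pulse train observed through
a single optical channel, with respiration acting as one slow oscillator at
`f_r = RR/60` Hz that simultaneously modulates

1. beat timing (FM): `IBI_i = (60/HR) · (1 + m_fm · sin(2π f_r t_i))`,
   the respiratory-sinus-arrhythmia depth `m_fm` being a few percent;
2. pulse amplitude (AM): `a_i = a0 · (1 + m_am · sin(2π f_r t_i))`;
3. baseline intensity (BM): an additive component
   `b(t) = m_bm · a0 · sin(2π f_r t)`.

Because all three are driven by the same phase, agreement between
independently derived per-modality rate estimates is strong evidence that
the common respiratory frequency — and not an artefact — has been found.
That observation motivates the consensus fusion rule below.

## Pipeline

**Beat detection.** The waveform is band-passed to the cardiac band
0.5–8 Hz (3rd-order Butterworth, zero-phase), covering 30–200 bpm. Systolic
peaks must exceed an adaptive threshold of 0.3× the rolling 2-s
peak-to-peak range and respect a 0.3 s refractory period. A second pass
re-picks peaks with a minimum separation of 0.6× the cardiac period taken
from the *first strong peak* of the signal autocorrelation (searched over
plausible inter-beat lags 0.3–2.0 s). The second pass exists because the
bare threshold rule admits dicrotic-notch double detections at low heart
rates and spurious noise peaks at low SNR; the first-strong-peak rule, as
opposed to the global autocorrelation maximum, is what keeps a slower but
more energetic respiratory periodicity from masquerading as the beat
period. The pulse foot is the filtered-signal minimum between consecutive
peaks; amplitude (peak − foot) and baseline ((peak + foot)/2) are read off
the *raw* signal, since the cardiac band-pass removes exactly the baseline
modulation BM needs. Fewer than 8 beats marks the series unusable and the
affected windows report themselves unavailable — never an exception.
Detection runs once per record rather than per window, avoiding filter edge
transients at window seams.

**Signal quality index.** Per-beat SQI is the product of three [0, 1]
sub-scores: (i) both adjacent inter-beat intervals within 0.3–2.0 s;
(ii) amplitude plausibility, `1 − clip(dev, 0, 1)` where `dev` is the
relative deviation from *both* the rolling 15-beat median and the
record-level median — the record-level term matters because a multi-second
artefact burst spans enough beats to drag a short rolling median along with
it and would otherwise rate its own beats as plausible; (iii) Pearson
correlation (floored at 0) with the rolling template — the mean of the last
15 accepted beats — compared in beat-normalised time (±0.35 of the local
IBI, resampled to 32 points), so that rhythm irregularity, which stretches
a pulse without changing its shape, is not itself penalised. Beats with
SQI ≥ 0.5 are accepted.

**Surrogates** (uniform 4 Hz grid per 120-s window; 4 Hz is
Nyquist-adequate for the 1 Hz band top with margin).

* *FM*: 60/IBI placed at interval midpoints, using only intervals between
  adjacent accepted beats (quality gaps therefore never create fictitious
  long intervals), linearly interpolated onto the grid.
* *AM*: Hilbert-envelope of the signal band-passed to a ±1.1 Hz
  neighbourhood of the cardiac fundamental, low-passed at 1.1× the band
  top. Restricting to the fundamental keeps harmonic intermodulation
  products out of the envelope.
* *BM*: the raw signal low-passed at the same cutoff.

AM and BM are deliberately *continuous* rather than beat-sampled: a series
sampled once per beat cannot represent respiratory frequencies above half
the beat rate and folds them to `f_beat − f_r`, which is fatal for fast
breathing at slow heart rates (e.g. 40 breaths/min at HR 60). FM is
inherently a beat-interval quantity and keeps the limitation. A zero-phase
notch (Q = 6) at the measured beat rate is applied to AM/BM when the pulse
rate comes within 1.4× of the band top, removing residual pulse-rate
ripple. Before filtering, the signal is winsorised at the median ± 5 robust
SDs and stretches without beat support (no accepted beats within 3 s,
widened by a 1-s guard for filter settling) are excised by linear
interpolation, so artefact energy cannot ring into the usable segments.
All series are mean-removed and linearly detrended. Coverage — the
beat-supported fraction of the window — gates estimation at 75%.

**Spectral estimation.** Welch's method (60-s Hann segments, 50% overlap)
is applied separately to each contiguous valid run of at least 20 s and the
periodograms are averaged with run-length weights; artefact-bridged samples
therefore contribute no power at all. The FFT length is zero-padded 16×
for sub-bin peak localisation. The candidate rate is the frequency of the
largest *local maximum* inside 4–60 breaths/min (a band extended one
native bin downward for the peak test) — requiring a local maximum stops
1/f leakage from below the band from posing as a very slow rate at the
band edge. The candidate is trusted when the power within ±1 native bin of
the peak holds ≥ 20% of the in-band power (the ±1-native-bin integration
makes the 0.20 threshold invariant to the zero-padding).

**Fusion.** Among trusted candidates, the largest subset agreeing within
4 breaths/min is averaged; ties go to the tighter subset. A lone trusted
candidate is accepted only when the window's accepted-beat SQI is ≥ 0.7.
Two gates run first: if the window's IBI coefficient of variation exceeds
0.12 (atrial-fibrillation-like rhythm) the FM candidate is dropped, since
beat-interval modulation is uninformative when the rhythm itself is
irregular; and an FM/AM candidate within 2 breaths/min of the mirror
frequency `f_beat − f_bm` of a trusted BM candidate is dropped as a
sampling image (BM, being continuous, cannot alias — so when a genuine
mirror pair occurs near RR ≈ HR/2 the alias-free BM value wins).
Everything else is *unavailable*.

**Record level.** A temporal-consistency pass demotes window estimates
more than 10 breaths/min from the record median (when ≥ 3 windows are
available; with exactly 2 in conflict, the lower-SQI one is demoted) —
respiratory rate drifts slowly, so such a window is an artefact survivor.
The continuous trend is a causal 10-min moving average over available
windows; the record summary is the mean of the available fused values, or
absent when no window fused.

## Synthetic data

The generator renders each beat as a systolic Gaussian (width 0.10 IBI)
plus a delayed dicrotic Gaussian (0.35 amplitude, delay 0.35 IBI, width
0.15 IBI) — the minimal smooth two-lobe PPG morphology. Defaults:
`m_fm = 0.04`, `m_am = 0.10`, `m_bm = 0.10` (moderate modulation depths in
the range reported for adult PPG), `fs = 125 Hz`. White noise is scaled to
the pulsatile RMS (`snr_db`); artefacts are Poisson-scheduled bursts of
10-Hz band-limited noise at 5× pulse amplitude that *replace* the signal,
mimicking sensor-saturating motion; AF is multiplicative lognormal IBI
jitter of configurable CV (default 0.20) with the RSA term retained.
Everything is determined by a single integer seed.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real recordings: pulse-contour physiology (stiffness,
reflection waves), two-wavelength absorbance, ventilator-driven phase
inversion of AM, baseline wander unrelated to respiration, slow perfusion
drifts, sensor-specific transfer functions, and respiratory rates that vary
within a record. The validation cohorts show that the *signal-processing
chain* recovers the truth under the stated noise, artefact and rhythm
conditions; clinical performance requires clinical data.

## Validation cohorts and problem sizes

Two fixed-difficulty cohorts exercise the pipeline end to end (see
`scripts/acceptance.py`): 50 clean ten-minute records (RR ~ U(8, 40), HR ~
U(60, 120), 20 dB) and 30 degraded ten-minute records (10 dB, artefact
bursts 2/min × 5 s, a third with AF jitter CV 0.2). Agreement is
summarised exactly as method-comparison studies report it: Bland–Altman
bias and 1.96·SD limits with differences defined estimated − reference
(positive bias = overestimation), Pearson r, ICC(2,k) on per-record means,
and per-record availability. The parameter-recovery grid spans
RR ∈ {8…40} × HR ∈ {60, 90, 120} on 2.5-minute records, and the SNR
degradation check uses three seeds per level at {30, 20, 10, 5} dB; these
sizes give stable statistics while keeping the whole battery to a few
minutes on one CPU.

## Numerical choices and edge cases

* LoA multiplier fixed at 1.96 (no small-sample t correction), matching how
  limits of agreement are universally reported.
* ICC form fixed to two-way random effects, absolute agreement, average
  measures; computed from the ANOVA mean squares and cross-checked in the
  tests against an independent implementation.
* Flat or near-flat signals: an absolute floor on the adaptive threshold
  prevents numerical ripple from producing beats; the record reports
  unavailable.
* Trailing partial windows are discarded, not zero-padded (short-window
  spectra are biased); windows are half-open `[start, end)` so they
  partition the record exactly.
* Non-finite samples on ingestion are an error naming the first offending
  index, unless repair is requested (linear interpolation over gaps ≤ 1 s).
* All thresholds above live in `PipelineConfig` with the defaults stated
  here; YAML configuration rejects unknown keys.

## Known limitations

* FM-based estimation degrades inherently under irregular rhythm; the AF
  gate trades availability for accuracy there.
* Respiratory rates above ~the low-pass cutoff relative to the beat rate
  (breathing faster than the heart beats, or near it) are unrecoverable
  from a single PPG channel.
* Heavily artefacted records (coverage below 75% in every window) abstain
  entirely; this is by design — availability is reported, not imputed.
* The mean-of-windows record summary assumes a stable rate over the
  record; step changes within a record are visible in the trend output but
  blur the record mean.
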