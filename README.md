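# ppgresp

Respiratory rate from the pulse oximeter waveform.

Respiratory rate (RR) is one of the earliest vital signs to change in a
deteriorating patient, yet outside of fully monitored beds it is still
counted by eye. The photoplethysmogram (PPG) that every pulse oximeter
already records carries respiration in three ways:

* **FM** — respiratory sinus arrhythmia modulates the timing of beats
  (instantaneous heart rate rises on inspiration, falls on expiration);
* **AM** — ventilatory swings in venous return modulate the amplitude of
  each cardiac pulse;
* **BM** — respiration modulates the intensity of the signal baseline.

`ppgresp` turns a raw single-channel PPG (typically 125 Hz) into a
continuous RR estimate: beats are detected with an adaptive threshold and a
period-aware refractory rule, graded by a three-component signal quality
index (inter-beat-interval plausibility × amplitude plausibility ×
template-shape correlation), and converted into three respiratory surrogate
series. Each surrogate is taken to a Welch periodogram over 2-min windows
and the dominant frequency in the 4–60 breaths/min band becomes a
per-modality candidate `RR_x = 60 · argmax_f S_x(f)`. Candidates are fused
by consensus — the largest subset agreeing within 4 breaths/min is
averaged, with gates that drop the FM candidate under atrial-fibrillation-
like rhythm and drop beat-driven candidates that sit at the sampling-image
frequency `f_beat − f` of the alias-free baseline candidate — then smoothed
with a 10-min moving average. Windows without consensus are reported
*unavailable*, never imputed; availability is itself a primary output.

The package also contains:

* a seeded synthetic-PPG generator (`ppgresp.simulate`) producing
  two-Gaussian pulse trains that carry all three modulations from one
  respiratory oscillator, plus white noise, motion-artefact bursts and
  AF-like inter-beat jitter — so the whole pipeline is testable with known
  ground truth and no clinical data;
* the method-comparison statistics used to validate such algorithms
  (`ppgresp.agreement`): Bland–Altman bias and 95% limits of agreement
  `bias ± 1.96·SD(d)` with `d = estimated − reference`, Pearson r, and the
  two-way random-effects absolute-agreement average-measures intraclass
  correlation ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n).

## Worked example

Simulate a small cohort, run the estimator on every record, and compare the
estimates with the known ground truth:

```bash
ppgresp demo --n 8 --seed 42 --duration-s 300
```

```json
{
  "availability_pct": 100.0,
  "bias": 0.00040321538477039454,
  "icc_avg": 0.9999991924303872,
  "loa_lower": -0.033288260666249125,
  "loa_upper": 0.034094691435789914,
  "n": 8,
  "n_records": 8,
  "pearson_r": 0.9999982733493854,
  "sd_diff": 0.01718952859745894,
  "seed": 42,
  "tool": "ppgresp 0.1.0"
}
```

All 8 records produced an estimate (`availability_pct`), the mean
estimated-minus-true difference is 0.0004 breaths/min (`bias`) with 95%
limits of agreement of roughly ±0.03 breaths/min, and estimated and true
rates correlate at r ≈ 1.0 — on clean 20 dB records the spectral estimate
is essentially exact.

The same stages are available individually:

```bash
ppgresp simulate --out rec.csv --truth truth.csv --seed 3
ppgresp estimate --in rec.csv --out est.csv          # windowed + mean RR
ppgresp validate --pairs pairs.csv --out report.json --plots figs/
```

or from Python:

```python
from ppgresp import SimulationConfig, simulate_ppg, estimate_record

rec, truth = simulate_ppg(SimulationConfig(hr_bpm=90, rr_bpm=22, snr_db=15))
estimates, trend, mean_rr = estimate_record(rec)
```

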