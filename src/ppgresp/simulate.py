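"""Synthetic PPG generator with known ground-truth respiratory rate.

A single respiratory oscillator at ``f_r = rr_bpm / 60`` Hz drives the three
modulations a pulse oximeter waveform carries:

* **FM** — respiratory sinus arrhythmia: the inter-beat interval of beat *i*
  is ``(60/hr_bpm) * (1 + m_fm * sin(2*pi*f_r*t_i))``;
* **AM** — stroke-volume variation: beat amplitude
  ``a_i = a0 * (1 + m_am * sin(2*pi*f_r*t_i))``;
* **BM** — venous-return intensity drift: additive baseline
  ``b(t) = m_bm * a0 * sin(2*pi*f_r*t)``.

Each beat is a stereotyped two-Gaussian pulse (systolic lobe plus a smaller,
delayed dicrotic lobe, widths scaled to the local inter-beat interval) — the
minimal smooth PPG beat model. Atrial-fibrillation-like rhythm is modelled as
multiplicative lognormal jitter on the inter-beat interval; motion artefacts
as bursts of high-amplitude band-limited noise that replace the signal.
White Gaussian noise is added at ``snr_db`` relative to the pulsatile RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .types import PPGRecord

#: systolic Gaussian width / dicrotic delay / dicrotic width, as IBI fractions
_SYS_W, _DIC_DELAY, _DIC_W, _DIC_AMP = 0.10, 0.35, 0.15, 0.35
#: artefact burst RMS as a multiple of pulse amplitude (well above the
#: "at least 5x" saturation regime of a jolted reflectance sensor)
_ARTEFACT_RMS = 5.0


@dataclass
class SimulationConfig:
    hr_bpm: float = 75.0
    rr_bpm: float = 15.0
    m_fm: float = 0.04      # fractional RSA depth of the inter-beat interval
    m_am: float = 0.10      # fractional pulse-amplitude modulation depth
    m_bm: float = 0.10      # baseline swing as fraction of pulse amplitude
    snr_db: float = np.inf  # additive white noise vs pulsatile RMS
    artefact_rate: float = 0.0   # expected bursts per minute
    artefact_dur_s: float = 5.0
    af: bool = False
    af_cv: float = 0.20     # coefficient of variation of IBI under af
    fs: float = 125.0
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 <= self.hr_bpm <= 200.0:
            raise ValueError(f"hr_bpm {self.hr_bpm} outside [30, 200]")
        if not 4.0 <= self.rr_bpm <= 60.0:
            raise ValueError(f"rr_bpm {self.rr_bpm} outside [4, 60]")
        for name in ("m_fm", "m_am", "m_bm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} {v} outside [0, 0.5]")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


@dataclass
class GroundTruth:
    beat_times: np.ndarray
    beat_amplitudes: np.ndarray
    rr_bpm: float
    artefact_mask: np.ndarray


def _beat_schedule(cfg: SimulationConfig, rng: np.random.Generator):
    """Iterate the IBI recurrence; returns beat times and per-beat IBIs."""
    f_r = cfg.rr_bpm / 60.0
    base = 60.0 / cfg.hr_bpm
    if cfg.af:
        sigma = np.sqrt(np.log1p(cfg.af_cv**2))
        mu = -0.5 * sigma**2
    times, ibis = [], []
    t = 0.5 * base  # first systole half a period in, clear of the record edge
    while t < cfg.duration_s:
        ibi = base * (1.0 + cfg.m_fm * np.sin(2 * np.pi * f_r * t))
        if cfg.af:
            ibi *= float(rng.lognormal(mu, sigma))
        times.append(t)
        ibis.append(ibi)
        t += ibi
    return np.array(times), np.array(ibis)


def _render_pulses(
    beat_times: np.ndarray, ibis: np.ndarray, amps: np.ndarray, n: int, fs: float
) -> np.ndarray:
    x = np.zeros(n)
    for t_i, ibi, a in zip(beat_times, ibis, amps):
        lo = max(0, int((t_i - 4 * _SYS_W * ibi) * fs))
        hi = min(n, int((t_i + (_DIC_DELAY + 4 * _DIC_W) * ibi) * fs) + 1)
        tt = np.arange(lo, hi) / fs
        x[lo:hi] += a * (
            np.exp(-0.5 * ((tt - t_i) / (_SYS_W * ibi)) ** 2)
            + _DIC_AMP * np.exp(-0.5 * ((tt - t_i - _DIC_DELAY * ibi) / (_DIC_W * ibi)) ** 2)
        )
    return x


def _artefact_bursts(
    rng: np.random.Generator, n: int, fs: float, rate_per_min: float, dur_s: float
) -> np.ndarray:
    """Boolean mask of Poisson-scheduled artefact bursts."""
    mask = np.zeros(n, dtype=bool)
    duration = n / fs
    n_bursts = rng.poisson(rate_per_min * duration / 60.0)
    for onset in rng.uniform(0.0, max(duration - dur_s, 0.0), size=n_bursts):
        i0 = int(onset * fs)
        mask[i0 : min(n, i0 + int(dur_s * fs))] = True
    return mask


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    w = rng.standard_normal(n)
    if n > 30:
        sos = signal.butter(4, 10.0, btype="low", fs=fs, output="sos")
        w = signal.sosfiltfilt(sos, w)
    s = w.std()
    return w / s if s > 0 else w


def simulate_ppg(config: SimulationConfig) -> tuple[PPGRecord, GroundTruth]:
    """Generate one PPG record plus its ground truth; fully seed-determined."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    f_r = cfg.rr_bpm / 60.0
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    beat_times, ibis = _beat_schedule(cfg, rng)
    a0 = 1.0
    amps = a0 * (1.0 + cfg.m_am * np.sin(2 * np.pi * f_r * beat_times))
    pulses = _render_pulses(beat_times, ibis, amps, n, cfg.fs)

    pulsatile_rms = float(np.std(pulses))
    x = pulses + cfg.m_bm * a0 * np.sin(2 * np.pi * f_r * t)
    if np.isfinite(cfg.snr_db):
        x = x + rng.standard_normal(n) * pulsatile_rms * 10.0 ** (-cfg.snr_db / 20.0)

    mask = _artefact_bursts(rng, n, cfg.fs, cfg.artefact_rate, cfg.artefact_dur_s)
    if mask.any():
        burst = _bandlimited_noise(rng, n, cfg.fs) * _ARTEFACT_RMS * a0
        x = np.where(mask, burst, x)

    record = PPGRecord(
        samples=x,
        fs=cfg.fs,
        subject_id=f"sim{cfg.seed}",
        channel_meta={"simulated": True, "rr_bpm": cfg.rr_bpm, "hr_bpm": cfg.hr_bpm},
    )
    truth = GroundTruth(
        beat_times=beat_times,
        beat_amplitudes=amps,
        rr_bpm=cfg.rr_bpm,
        artefact_mask=mask,
    )
    return record, truth


def inject_artefacts(
    record: PPGRecord, rate_per_min: float, dur_s: float, seed: int
) -> tuple[PPGRecord, np.ndarray]:
    """Overwrite random stretches of an existing record with artefact noise."""
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be non-negative")
    if dur_s >= record.duration:
        raise ValueError(
            f"burst duration {dur_s} s must be shorter than the record "
            f"({record.duration:.1f} s)"
        )
    rng = np.random.default_rng(seed)
    n = record.samples.size
    mask = _artefact_bursts(rng, n, record.fs, rate_per_min, dur_s)
    x = record.samples.copy()
    if mask.any():
        lo, hi = np.percentile(record.samples, [2.5, 97.5])
        amp = (hi - lo) / 2.0 or 1.0
        x[mask] = (_bandlimited_noise(rng, n, record.fs) * _ARTEFACT_RMS * amp)[mask]
    out = PPGRecord(
        samples=x,
        fs=record.fs,
        t0=record.t0,
        subject_id=record.subject_id,
        channel_meta=dict(record.channel_meta),
    )
    return out, mask


def cohort_params(
    n_records: int,
    rr_range: tuple[float, float],
    hr_range: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-record (rr, hr, child seed) draws from a master seed."""
    rng = np.random.default_rng(seed)
    rrs = rng.uniform(*rr_range, size=n_records)
    hrs = rng.uniform(*hr_range, size=n_records)
    seeds = rng.integers(0, 2**31, size=n_records)
    return rrs, hrs, seeds


def simulate_cohort(
    n_records: int,
    rr_range: tuple[float, float],
    hr_range: tuple[float, float],
    base_config: Optional[SimulationConfig] = None,
    seed: int = 0,
    n_af: int = 0,
) -> list[tuple[PPGRecord, GroundTruth]]:
    """Simulate a cohort with RR and HR drawn uniformly from the given ranges.

    The first ``n_af`` records get atrial-fibrillation-like beat-interval
    jitter (the assignment is deterministic so cohorts are reproducible).
    """
    base = base_config if base_config is not None else SimulationConfig()
    rrs, hrs, seeds = cohort_params(n_records, rr_range, hr_range, seed)
    cohort = []
    for i in range(n_records):
        cfg = replace(
            base,
            rr_bpm=float(rrs[i]),
            hr_bpm=float(hrs[i]),
            seed=int(seeds[i]),
            af=base.af or i < n_af,
        )
        rec, truth = simulate_ppg(cfg)
        rec.subject_id = f"sim{seed:d}_{i:03d}"
        cohort.append((rec, truth))
    return cohort
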