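"""Domain containers shared by every pipeline stage.

All times are seconds from record start; analysis windows are half-open
``[start, end)`` so that consecutive windows partition the record exactly.
Respiratory rates are breaths per minute (b/min) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Respiratory search band in Hz (4–60 breaths/min).
RESP_BAND_HZ = (4.0 / 60.0, 1.0)


@dataclass
class PPGRecord:
    """Uniformly sampled raw photoplethysmogram.

    Parameters
    ----------
    samples : ndarray
        Raw intensity values, arbitrary units. Must be finite.
    fs : float
        Sampling rate in Hz (pulse-oximetry waveforms are typically 125 Hz).
    t0 : float
        Start time in seconds.
    subject_id : str
        Opaque label used to key cohort-level pairings.
    channel_meta : dict
        Free-form acquisition metadata.
    """

    samples: np.ndarray
    fs: float = 125.0
    t0: float = 0.0
    subject_id: str = ""
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("PPGRecord requires a non-empty sample array")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class ReferenceRR:
    """One reference respiratory-rate observation (e.g. a 30-s manual count)."""

    t: float
    rr: float
    method: str = "manual"

    _METHODS = ("manual", "ecg_impedance", "ventilator")

    def __post_init__(self) -> None:
        if not 0.0 <= self.rr <= 120.0:
            raise ValueError(f"reference RR {self.rr} outside [0, 120] b/min")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown reference method {self.method!r}")


@dataclass
class AnalysisWindow:
    """Half-open ``[start_s, end_s)`` view into a parent record."""

    start_s: float
    end_s: float
    samples: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BeatSeries:
    """Per-beat fiducials from pulse detection.

    ``amplitudes`` are systolic peak minus preceding foot on the raw
    waveform; ``baselines`` the midpoint (peak + foot)/2, which retains the
    slow respiratory intensity modulation that the cardiac band-pass removes.
    """

    peak_times: np.ndarray
    trough_times: np.ndarray
    amplitudes: np.ndarray
    baselines: np.ndarray
    sqi: np.ndarray
    usable: bool = True

    def __post_init__(self) -> None:
        n = len(self.peak_times)
        for name in ("trough_times", "amplitudes", "baselines", "sqi"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with peak_times")
        if n > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class SurrogateSignals:
    """FM/AM/BM respiratory surrogates on a shared uniform grid.

    Each series is linearly interpolated from beat-domain samples onto the
    ``fs_surr`` grid, then mean-removed and linearly detrended. ``valid_mask``
    flags samples supported by nearby beats (no interpolation across gaps
    longer than the configured limit).
    """

    t: np.ndarray
    fm: np.ndarray
    am: np.ndarray
    bm: np.ndarray
    valid_mask: np.ndarray
    fs_surr: float = 4.0
    ibi_cv: float = 0.0
    f_beat: float = 0.0
    coverage: float = 1.0


@dataclass
class ModalityCandidate:
    """Spectral RR candidate from one surrogate modality."""

    modality: str
    rr_bpm: float
    peak_power_ratio: float
    valid: bool


@dataclass
class RREstimate:
    """Fused RR for one analysis window; ``available`` iff a rate was fused."""

    t: float
    rr_fused: Optional[float]
    candidates: list
    window_sqi: float
    available: bool

    def __post_init__(self) -> None:
        if self.available != (self.rr_fused is not None):
            raise ValueError("available flag must mirror presence of rr_fused")


@dataclass
class RRTrend:
    """Causal 10-min moving average of available fused estimates."""

    times: np.ndarray
    rr_smoothed: np.ndarray


@dataclass
class PairedRR:
    """One subject's (reference, estimated) RR pair for method comparison."""

    subject_id: str
    rr_reference: float
    rr_estimated: float

    def __post_init__(self) -> None:
        for name in ("rr_reference", "rr_estimated"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass
class AgreementReport:
    """Bland–Altman, correlation and reliability summary of a comparison run."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pearson_r: float
    icc_avg: float
    availability_pct: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "pearson_r": self.pearson_r,
            "icc_avg": self.icc_avg,
            "availability_pct": self.availability_pct,
        }
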