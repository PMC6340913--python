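"""Pipeline configuration: every tunable threshold with its default.

Loaded from YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # windowing
    window_s: float = 120.0          # analysis window length (2-min periods)
    hop_s: float = 120.0             # hop between windows; = window_s -> non-overlapping

    # beat detection
    cardiac_band_hz: tuple = (0.5, 8.0)   # covers 30-200 bpm
    refractory_s: float = 0.3             # max 200 bpm
    adaptive_win_s: float = 2.0           # rolling window for the peak threshold
    adaptive_frac: float = 0.3            # threshold = frac x rolling peak-to-peak
    min_beats: int = 8                    # fewer -> window/record unusable

    # beat quality (SQI)
    ibi_bounds_s: tuple = (0.3, 2.0)
    sqi_median_win: int = 15              # beats, for amplitude plausibility + template
    sqi_accept: float = 0.5               # per-beat acceptance threshold

    # surrogates
    fs_surr: float = 4.0
    max_gap_s: float = 3.0                # interpolation across longer gaps is invalid
    edge_guard_s: float = 1.0             # extra invalid margin around gaps

    # spectral estimation
    resp_band_bpm: tuple = (4.0, 60.0)
    welch_seg_s: float = 60.0
    min_run_s: float = 20.0               # shortest valid run entering the PSD
    min_coverage: float = 0.75            # valid_mask fraction required per window
    peak_ratio_min: float = 0.20          # candidate validity cutoff

    # fusion
    fuse_spread_bpm: float = 4.0
    single_sqi_min: float = 0.7
    af_ibi_cv: float = 0.12               # above this, the FM candidate is excluded

    # record-level aggregation
    record_outlier_bpm: float = 10.0      # window estimates this far from the
                                          # record median are discarded

    # smoothing
    smooth_window_s: float = 600.0        # 10-min moving average

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise KeyError(f"unknown config keys: {', '.join(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**coerced)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
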