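"""Waveform and annotation I/O plus record windowing.

CSV is the interchange format: two columns ``time_s,value`` (the sampling
rate is inferred from the time column) or a single ``value`` column with the
rate passed explicitly. EDF files are read through :mod:`mne`. Reference RR
annotations are CSV with columns ``t_s,rr,method``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AnalysisWindow, PPGRecord, ReferenceRR, RREstimate

log = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["t_s", "rr_fused", "rr_fm", "rr_am", "rr_bm", "sqi", "available"]


def _repair_nonfinite(samples: np.ndarray, fs: float, max_gap_s: float = 1.0) -> np.ndarray:
    """Linearly interpolate non-finite runs no longer than ``max_gap_s``."""
    bad = ~np.isfinite(samples)
    if not bad.any():
        return samples
    # locate contiguous bad runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    longest = (stops - starts).max() / fs
    if longest > max_gap_s:
        raise ValueError(
            f"non-finite gap of {longest:.2f} s exceeds repairable limit {max_gap_s} s"
        )
    if bad[0] or bad[-1]:
        raise ValueError("non-finite samples at record boundary cannot be repaired")
    idx = np.arange(samples.size)
    out = samples.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], samples[~bad])
    log.info("repaired %d non-finite samples in %d gaps", int(bad.sum()), len(starts))
    return out


def read_waveform(
    path: str | Path,
    format: Optional[str] = None,
    fs: Optional[float] = None,
    channel: Optional[str] = None,
    repair: bool = False,
    subject_id: Optional[str] = None,
) -> PPGRecord:
    """Read a raw PPG waveform from CSV or EDF.

    Parameters
    ----------
    format
        ``"csv"``, ``"edf"`` or ``"wfdb"``; inferred from the suffix when omitted.
    fs
        Required for single-column CSV; overrides the inferred rate otherwise.
    channel
        EDF channel name; defaults to the first channel.
    repair
        Interpolate non-finite samples over gaps <= 1 s instead of failing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    sid = subject_id if subject_id is not None else path.stem

    if fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] >= 2:
            t = df.iloc[:, 0].to_numpy(dtype=float)
            samples = df.iloc[:, 1].to_numpy(dtype=float)
            dt = np.diff(t)
            if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{path}: time column is not uniformly sampled")
            fs_file = 1.0 / dt[0]
            fs = fs if fs is not None else fs_file
            t0 = float(t[0])
        else:
            if fs is None:
                raise ValueError(
                    f"{path}: single-column CSV requires an explicit sampling rate"
                )
            samples = df.iloc[:, 0].to_numpy(dtype=float)
            t0 = 0.0
    elif fmt == "edf":
        import mne  # heavy import, deferred

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
        name = channel or raw.ch_names[0]
        samples = raw.get_data(picks=[name])[0]
        fs = float(raw.info["sfreq"])
        t0 = 0.0
    elif fmt == "wfdb":
        raise ValueError(
            "wfdb format requires the 'wfdb' package, which is not installed; "
            "convert the record to CSV or EDF"
        )
    else:
        raise ValueError(f"unknown waveform format {fmt!r}")

    if not np.all(np.isfinite(samples)):
        if repair:
            samples = _repair_nonfinite(np.asarray(samples, float), fs)
        else:
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"{path}: non-finite sample at index {bad} (use repair)")
    return PPGRecord(samples=samples, fs=float(fs), t0=t0, subject_id=sid)


def write_waveform(path: str | Path, record: PPGRecord) -> None:
    """Write a record as two-column ``time_s,value`` CSV."""
    df = pd.DataFrame({"time_s": record.times, "value": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def write_estimates(path: str | Path, estimates: Sequence[RREstimate]) -> None:
    """Write windowed RR estimates as CSV, one row per window, sorted by time."""
    rows = []
    for e in sorted(estimates, key=lambda e: e.t):
        by_mod = {c.modality: c for c in e.candidates}
        rows.append(
            {
                "t_s": e.t,
                "rr_fused": e.rr_fused if e.available else np.nan,
                "rr_fm": by_mod["fm"].rr_bpm if "fm" in by_mod and by_mod["fm"].valid else np.nan,
                "rr_am": by_mod["am"].rr_bpm if "am" in by_mod and by_mod["am"].valid else np.nan,
                "rr_bm": by_mod["bm"].rr_bpm if "bm" in by_mod and by_mod["bm"].valid else np.nan,
                "sqi": e.window_sqi,
                "available": e.available,
            }
        )
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing estimate columns {missing}")
    return df


def read_reference(path: str | Path) -> list[ReferenceRR]:
    """Read timestamped reference RR annotations (columns ``t_s,rr,method``)."""
    df = pd.read_csv(path)
    refs = [
        ReferenceRR(t=float(r.t_s), rr=float(r.rr), method=str(r.method))
        for r in df.itertuples()
    ]
    for method in {r.method for r in refs}:
        ts = [r.t for r in refs if r.method == method]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"{path}: timestamps not strictly increasing for {method}")
    return refs


def segment(
    record: PPGRecord, window_s: float = 120.0, hop_s: Optional[float] = None
) -> list[AnalysisWindow]:
    """Cut a record into half-open analysis windows.

    Non-overlapping by default (``hop_s = window_s``); a trailing window
    shorter than ``window_s`` is dropped, since spectral estimates on
    truncated windows are biased.
    """
    hop_s = window_s if hop_s is None else hop_s
    if window_s > record.duration:
        raise ValueError(
            f"window {window_s} s exceeds record duration {record.duration:.1f} s"
        )
    if hop_s <= 0:
        raise ValueError("hop must be positive")
    nwin = int(window_s * record.fs)
    nhop = int(hop_s * record.fs)
    windows = []
    for start in range(0, record.samples.size - nwin + 1, nhop):
        t_start = record.t0 + start / record.fs
        windows.append(
            AnalysisWindow(
                start_s=t_start,
                end_s=t_start + window_s,
                samples=record.samples[start : start + nwin],
                fs=record.fs,
            )
        )
    return windows
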