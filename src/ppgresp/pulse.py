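"""Beat detection, per-beat signal quality, and respiratory surrogates.

Detection runs on a zero-phase cardiac band-pass (0.5–8 Hz, covering 30–200
bpm). Systolic peaks must clear an adaptive threshold — 0.3 of the local
2-s peak-to-peak — and respect a 0.3 s refractory period. The preceding
local minimum is taken as the pulse foot. Fiducial *values* (amplitude,
baseline) are read off the raw waveform, because the band-pass removes the
very respiratory baseline modulation the BM surrogate needs.

The per-beat signal quality index (SQI) is the product of three sub-scores:
inter-beat-interval plausibility, amplitude plausibility against a rolling
median, and correlation with a rolling template beat. It is the package's
explicit, testable quality gate standing in for the opaque quality indices
of commercial oximeters.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .config import PipelineConfig
from .types import AnalysisWindow, BeatSeries, PPGRecord, SurrogateSignals


def _empty_beats() -> BeatSeries:
    z = np.array([])
    return BeatSeries(
        peak_times=z, trough_times=z, amplitudes=z, baselines=z, sqi=z, usable=False
    )


def _cardiac_period(xf: np.ndarray, fs: float, cfg: PipelineConfig) -> float | None:
    """Dominant beat-to-beat period from the autocorrelation, in seconds.

    The full-period lag dominates partial (dicrotic) lags because only it
    aligns whole pulses. Search is bounded by the plausible IBI range.
    """
    lo, hi = int(cfg.ibi_bounds_s[0] * fs), int(cfg.ibi_bounds_s[1] * fs)
    if xf.size < 2 * hi:
        return None
    x = xf - xf.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * x.size)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: x.size]
    if ac[0] <= 0 or hi >= ac.size:
        return None
    seg = ac[lo:hi]
    pk, _ = signal.find_peaks(seg)
    if pk.size == 0:
        lag = lo + int(np.argmax(seg))
        return lag / fs if ac[lag] > 0.1 * ac[0] else None
    # the beat period is the FIRST strong autocorrelation peak: slower
    # periodicities (respiratory modulation, multiples of the beat period)
    # can carry more energy but never precede it
    strong = pk[seg[pk] >= 0.75 * seg[pk].max()]
    lag = lo + int(strong[0])
    return lag / fs if ac[lag] > 0.1 * ac[0] else None


def detect_beats(record: PPGRecord, config: PipelineConfig | None = None) -> BeatSeries:
    """Locate systolic peaks and pulse feet in a raw PPG record.

    Fewer than ``config.min_beats`` detections yields a BeatSeries flagged
    unusable rather than an exception, so downstream windows can report
    themselves unavailable.
    """
    cfg = config or PipelineConfig()
    if record.duration < 10.0:
        raise ValueError("beat detection requires at least 10 s of signal")
    x = record.samples
    fs = record.fs

    lo, hi = cfg.cardiac_band_hz
    sos = signal.butter(3, [lo, min(hi, 0.45 * fs)], btype="band", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)

    half = max(int(cfg.adaptive_win_s * fs) // 2 * 2 + 1, 3)
    rmax = ndimage.maximum_filter1d(xf, size=half, mode="nearest")
    rmin = ndimage.minimum_filter1d(xf, size=half, mode="nearest")
    ptp = rmax - rmin
    # absolute floor keeps numerical ripple on near-flat signal from firing
    floor = 1e-6 * max(np.ptp(x), 1e-300)
    height = rmin + cfg.adaptive_frac * np.maximum(ptp, floor)

    refractory = max(int(cfg.refractory_s * fs), 1)
    peaks, _ = signal.find_peaks(xf, height=height, distance=refractory)
    peaks = peaks[ptp[peaks] > floor]
    if peaks.size < cfg.min_beats:
        return _empty_beats()

    # second pass: a period-adaptive minimum distance (0.6 x the cardiac
    # period from the autocorrelation) rejects dicrotic-notch and noise
    # peaks that clear the amplitude threshold at low heart rates
    period = _cardiac_period(xf, fs, cfg)
    if period is not None:
        dist = max(refractory, int(0.6 * period * fs))
        peaks, _ = signal.find_peaks(xf, height=height, distance=dist)
        peaks = peaks[ptp[peaks] > floor]
        if peaks.size < cfg.min_beats:
            return _empty_beats()

    # pulse foot: minimum of the filtered signal between the previous peak
    # (or one refractory-bounded lookback) and this peak
    feet = np.empty(peaks.size, dtype=int)
    lookback = int(1.5 * np.median(np.diff(peaks))) if peaks.size > 1 else int(fs)
    for j, p in enumerate(peaks):
        start = peaks[j - 1] if j > 0 else max(0, p - lookback)
        start = max(start, p - lookback)
        if start >= p:
            start = max(0, p - 1)
        feet[j] = start + int(np.argmin(xf[start:p]))

    amplitudes = x[peaks] - x[feet]
    keep = amplitudes > 0
    peaks, feet, amplitudes = peaks[keep], feet[keep], amplitudes[keep]
    if peaks.size < cfg.min_beats:
        return _empty_beats()

    beats = BeatSeries(
        peak_times=record.t0 + peaks / fs,
        trough_times=record.t0 + feet / fs,
        amplitudes=amplitudes,
        baselines=(x[peaks] + x[feet]) / 2.0,
        sqi=np.ones(peaks.size),
        usable=True,
    )
    beats.sqi = beat_quality(beats, record, cfg)
    return beats


def _rolling_median(a: np.ndarray, win: int) -> np.ndarray:
    if a.size == 0:
        return a
    import pandas as pd

    return (
        pd.Series(a).rolling(win, center=True, min_periods=1).median().to_numpy()
    )


def beat_quality(
    beats: BeatSeries, record: PPGRecord, config: PipelineConfig | None = None
) -> np.ndarray:
    """Per-beat SQI in [0, 1]: IBI x amplitude x template-correlation scores."""
    cfg = config or PipelineConfig()
    n = len(beats)
    if n == 0:
        return np.array([])

    # (i) IBI plausibility: each beat scored on its adjacent intervals
    ibi_ok = np.ones(n)
    if n > 1:
        d = np.diff(beats.peak_times)
        lo, hi = cfg.ibi_bounds_s
        edge_ok = (d >= lo) & (d <= hi)
        pre = np.concatenate(([True], edge_ok))   # interval ending at beat i
        post = np.concatenate((edge_ok, [True]))  # interval starting at beat i
        ibi_ok = (pre & post).astype(float)

    # (ii) amplitude plausibility vs rolling median, also checked against
    # the record-level median: a sustained artefact burst spans enough beats
    # to drag the rolling median along with it, and would otherwise rate its
    # own beats as plausible
    med = _rolling_median(beats.amplitudes, cfg.sqi_median_win)
    med = np.where(med > 0, med, np.inf)
    glob = float(np.median(beats.amplitudes))
    dev = np.abs(beats.amplitudes - med) / med
    if glob > 0:
        dev = np.maximum(dev, np.abs(beats.amplitudes - glob) / glob)
    amp_score = 1.0 - np.clip(dev, 0.0, 1.0)

    # (iii) correlation with the rolling template of recently accepted beats,
    # compared in beat-normalised time (segments span +-0.35 local IBI and
    # are resampled to a fixed length) so that rhythm irregularity alone —
    # which stretches the pulse but not its shape — is not penalised
    fs = record.fs
    x = record.samples
    idx = np.round((beats.peak_times - record.t0) * fs).astype(int)
    med_ibi = float(np.median(np.diff(beats.peak_times))) if n > 1 else 1.0
    if n > 1:
        d = np.diff(beats.peak_times)
        local_ibi = np.minimum(
            np.concatenate(([d[0]], d)), np.concatenate((d, [d[-1]]))
        )
        local_ibi = np.clip(local_ibi, 0.3 * med_ibi, 3.0 * med_ibi)
    else:
        local_ibi = np.full(n, med_ibi)
    n_tmpl = 32
    u = np.linspace(-0.35, 0.35, n_tmpl)
    corr_score = np.ones(n)
    accepted: list[np.ndarray] = []
    for j in range(n):
        span = local_ibi[j]
        ii = idx[j] + np.round(u * span * fs).astype(int)
        if ii[0] < 0 or ii[-1] >= x.size:
            continue
        seg = x[ii]
        seg = seg - seg.mean()
        if accepted:
            tmpl = np.mean(accepted[-cfg.sqi_median_win :], axis=0)
            denom = np.linalg.norm(seg) * np.linalg.norm(tmpl)
            r = float(seg @ tmpl / denom) if denom > 0 else 0.0
            corr_score[j] = max(r, 0.0)
        if ibi_ok[j] * amp_score[j] >= cfg.sqi_accept:
            accepted.append(seg)
    return ibi_ok * amp_score * corr_score


def _select_window(beats: BeatSeries, start_s: float, end_s: float) -> np.ndarray:
    return np.flatnonzero((beats.peak_times >= start_s) & (beats.peak_times < end_s))


def _robust_clip(x: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Winsorise at median +- k robust SDs so artefact bursts cannot swamp
    the low-frequency filters downstream."""
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return x
    return np.clip(x, med - k * mad, med + k * mad)


def _bridge_invalid(series: np.ndarray, t: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate across low-quality stretches."""
    if valid.all() or not valid.any():
        return series
    out = series.copy()
    out[~valid] = np.interp(t[~valid], t[valid], series[valid])
    return out


def extract_surrogates(
    beats: BeatSeries,
    window: AnalysisWindow,
    config: PipelineConfig | None = None,
) -> SurrogateSignals | None:
    """Derive the FM/AM/BM respiratory surrogates for one analysis window.

    FM is the beat-domain instantaneous heart rate, 60/IBI placed at the
    interval midpoint (intervals between *adjacent* accepted beats only, so
    quality-gated gaps never produce fictitious long intervals), linearly
    interpolated onto the uniform grid. AM and BM are extracted continuously
    from the waveform — AM as the Hilbert envelope of the signal band-passed
    around the cardiac fundamental, BM as the sub-cardiac low-pass baseline —
    because beat-domain sampling of amplitude and baseline aliases whenever
    the respiratory frequency exceeds half the beat rate. A zero-phase notch
    at the beat rate removes residual pulse-rate ripple when it falls near
    the respiratory band. Every series is mean-removed and linearly
    detrended; low-quality stretches (no accepted beat within ``max_gap_s``)
    are bridged by linear interpolation and flagged in ``valid_mask``.

    Returns None when fewer than ``min_beats`` accepted beats fall in the
    window (the window is then unavailable).
    """
    cfg = config or PipelineConfig()
    if not beats.usable:
        return None
    sel = _select_window(beats, window.start_s, window.end_s)
    acc = sel[beats.sqi[sel] >= cfg.sqi_accept]
    if acc.size < cfg.min_beats:
        return None

    pt = beats.peak_times[acc]
    n_grid = int(round(window.duration * cfg.fs_surr))
    t_grid = window.start_s + np.arange(n_grid) / cfg.fs_surr

    # FM support: adjacent-in-detection accepted pairs with plausible IBI
    adjacent = np.diff(acc) == 1
    ibi = np.diff(pt)
    lo, hi = cfg.ibi_bounds_s
    good = adjacent & (ibi >= lo) & (ibi <= hi)
    fm_t = (pt[:-1] + pt[1:])[good] / 2.0
    fm_v = 60.0 / ibi[good]
    if fm_t.size < 2:
        return None
    ibi_good = ibi[good]
    f_beat = 1.0 / float(np.median(ibi_good))
    ibi_cv = float(np.std(ibi_good) / np.mean(ibi_good)) if ibi_good.size >= 2 else 0.0

    # validity: a grid point is supported when its bracketing accepted
    # beats are no further than max_gap_s apart
    j = np.searchsorted(pt, t_grid)
    gap = np.empty(t_grid.size)
    inside = (j > 0) & (j < pt.size)
    gap[inside] = pt[j[inside]] - pt[j[inside] - 1]
    gap[j == 0] = pt[0] - t_grid[j == 0]
    gap[j == pt.size] = t_grid[j == pt.size] - pt[-1]
    support = gap <= cfg.max_gap_s  # beat-supported samples (coverage measure)
    # guard margin: beats at gap edges are often subtly distorted, and the
    # low-pass filters below ring past gap boundaries; widen each invalid
    # stretch so the spectral stage never sees those samples
    valid = support
    guard = int(round(cfg.edge_guard_s * cfg.fs_surr))
    if guard > 0 and not valid.all():
        valid = ndimage.binary_erosion(
            valid, structure=np.ones(2 * guard + 1), border_value=True
        )

    fm = np.interp(t_grid, fm_t, fm_v)
    fm = _bridge_invalid(fm, t_grid, valid)

    # continuous AM/BM from the raw window; low-quality stretches are
    # excised (interpolated across) before filtering so artefact energy
    # cannot ring into the neighbouring valid runs
    fs = window.fs
    x = _robust_clip(np.asarray(window.samples, dtype=float))
    if not valid.all():
        sample_valid = np.repeat(valid, int(round(fs / cfg.fs_surr)))[: x.size]
        if sample_valid.size < x.size:
            sample_valid = np.pad(sample_valid, (0, x.size - sample_valid.size), constant_values=sample_valid[-1] if sample_valid.size else True)
        if sample_valid.any() and not sample_valid.all():
            idx_all = np.arange(x.size)
            x = x.copy()
            x[~sample_valid] = np.interp(
                idx_all[~sample_valid], idx_all[sample_valid], x[sample_valid]
            )
    band_top = cfg.resp_band_bpm[1] / 60.0
    # AM: envelope of the band around the cardiac fundamental (harmonics
    # excluded, so pulse-harmonic intermodulation cannot masquerade as
    # breathing); respiratory AM appears as sidebands f_beat +- f_r
    am_lo = max(0.4 * f_beat, f_beat - 1.1 * band_top, 0.05)
    am_hi = min(f_beat + 1.1 * band_top, 0.45 * fs)
    sos_am = signal.butter(3, [am_lo, am_hi], btype="band", fs=fs, output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos_am, x)))
    sos_lp = signal.butter(4, 1.1 * band_top, btype="low", fs=fs, output="sos")
    am_c = signal.sosfiltfilt(sos_lp, env)
    # BM: sub-cardiac baseline intensity of the raw signal
    bm_c = signal.sosfiltfilt(sos_lp, x)
    if f_beat < 1.4 * band_top:  # pulse rate near the respiratory band
        bn, an = signal.iirnotch(f_beat, Q=6.0, fs=fs)
        am_c = signal.filtfilt(bn, an, am_c)
        bm_c = signal.filtfilt(bn, an, bm_c)
    idx = np.clip(((t_grid - window.start_s) * fs).astype(int), 0, x.size - 1)
    am = _bridge_invalid(am_c[idx], t_grid, valid)
    bm = _bridge_invalid(bm_c[idx], t_grid, valid)

    return SurrogateSignals(
        t=t_grid,
        fm=signal.detrend(fm),
        am=signal.detrend(am),
        bm=signal.detrend(bm),
        valid_mask=valid,
        fs_surr=cfg.fs_surr,
        ibi_cv=ibi_cv,
        f_beat=f_beat,
        coverage=float(support.mean()),
    )
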