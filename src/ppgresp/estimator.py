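"""Per-window spectral RR candidates, quality-gated fusion and smoothing.

Each surrogate series is taken to Welch's periodogram (60-s Hann segments,
50% overlap); the candidate rate is the argmax frequency inside the
4–60 breaths/min respiratory band. A candidate is trusted when the power
within one native frequency bin of the peak carries at least 20% of the
in-band power — a transparent tonality test. Fusion requires agreement:
two or more trusted candidates within 4 breaths/min are averaged; a lone
candidate passes only on a high-quality window; anything else is reported
unavailable rather than imputed. Under atrial-fibrillation-like rhythm
(window IBI coefficient of variation above 0.12) the respiratory-sinus-
arrhythmia candidate is discarded before fusion, since beat-interval
modulation is uninformative when the rhythm itself is irregular.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .io import segment
from .pulse import detect_beats, extract_surrogates
from .types import (
    BeatSeries,
    ModalityCandidate,
    PPGRecord,
    RREstimate,
    RRTrend,
)

_NFFT_FACTOR = 16  # zero-padding for sub-bin peak localisation


def _invalid(modality: str) -> ModalityCandidate:
    return ModalityCandidate(modality=modality, rr_bpm=np.nan, peak_power_ratio=0.0, valid=False)


def estimate_modality_rr(
    series: np.ndarray,
    fs_surr: float,
    valid_mask: Optional[np.ndarray] = None,
    modality: str = "am",
    config: PipelineConfig | None = None,
    coverage: Optional[float] = None,
) -> ModalityCandidate:
    """Dominant in-band frequency of one surrogate, as breaths/min.

    ``coverage`` is the beat-supported fraction of the window (defaults to
    the valid-mask mean). Insufficient coverage or a diffuse spectrum yields
    an invalid candidate, never an exception.
    """
    cfg = config or PipelineConfig()
    series = np.asarray(series, dtype=float)
    if series.size < int(cfg.welch_seg_s * fs_surr):
        return _invalid(modality)
    if valid_mask is None:
        valid_mask = np.ones(series.size, dtype=bool)
    if coverage is None:
        coverage = float(np.mean(valid_mask))
    if coverage < cfg.min_coverage:
        return _invalid(modality)

    # PSD over contiguous valid runs only, so bridged artefact stretches
    # contribute no spectral power; runs are length-weighted
    min_run = int(cfg.min_run_s * fs_surr)
    edges = np.flatnonzero(
        np.diff(np.concatenate(([0], valid_mask.view(np.int8), [0])))
    )
    runs = [
        (a, b) for a, b in zip(edges[::2], edges[1::2]) if b - a >= min_run
    ]
    if not runs:
        return _invalid(modality)
    nperseg_full = min(int(cfg.welch_seg_s * fs_surr), series.size)
    nfft = _NFFT_FACTOR * nperseg_full
    acc = None
    weight = 0
    min_nperseg = nperseg_full
    for a, b in runs:
        nperseg = min(nperseg_full, b - a)
        min_nperseg = min(min_nperseg, nperseg)
        f, p = sps.welch(
            series[a:b],
            fs=fs_surr,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            nfft=nfft,
            detrend="linear",
        )
        acc = p * (b - a) if acc is None else acc + p * (b - a)
        weight += b - a
    pxx = acc / weight
    lo, hi = cfg.resp_band_bpm[0] / 60.0, cfg.resp_band_bpm[1] / 60.0
    band = (f >= lo) & (f <= hi)
    total = float(pxx[band].sum())
    if not band.any() or total <= 0:
        return _invalid(modality)
    fb, pb = f[band], pxx[band]
    native_bin = fs_surr / min_nperseg  # resolution before zero-padding
    # the peak must be a genuine local maximum in a band extended one native
    # bin downward; otherwise a 1/f leakage tail from below the band would
    # masquerade as a slow respiratory rate at the band edge
    ext = (f >= lo - native_bin) & (f <= hi)
    loc, _ = sps.find_peaks(pxx[ext])
    f_loc = f[ext][loc]
    in_band = (f_loc >= lo) & (f_loc <= hi)
    if not in_band.any():
        return _invalid(modality)
    cand_f = f_loc[in_band]
    cand_p = pxx[ext][loc][in_band]
    f_pk = float(cand_f[np.argmax(cand_p)])
    near = np.abs(fb - f_pk) <= native_bin
    ratio = float(pb[near].sum() / total)
    return ModalityCandidate(
        modality=modality,
        rr_bpm=60.0 * f_pk,
        peak_power_ratio=ratio,
        valid=ratio >= cfg.peak_ratio_min,
    )


_IMAGE_TOL_BPM = 2.0


def fuse(
    candidates: Sequence[ModalityCandidate],
    window_sqi: float,
    ibi_cv: float = 0.0,
    f_beat: float = 0.0,
    config: PipelineConfig | None = None,
) -> Optional[float]:
    """Consensus rule over modality candidates; None when no consensus.

    Valid candidates agreeing within the spread threshold are averaged
    (the largest agreeing subset wins); a lone valid candidate passes only
    on a high-quality window. Two gates precede consensus: under
    atrial-fibrillation-like rhythm (IBI CV above the configured cutoff)
    the FM candidate is dropped; and a beat-driven candidate lying at the
    mirror frequency ``f_beat - f`` of a *disagreeing* fellow candidate is
    dropped as a sampling image (beat-interval sampling folds respiratory
    rates above half the pulse rate onto exactly that frequency).
    """
    cfg = config or PipelineConfig()
    pool = [c for c in candidates if c.valid]
    if ibi_cv > cfg.af_ibi_cv:
        pool = [c for c in pool if c.modality != "fm"]
    if f_beat > 0:
        mirror_bpm = 60.0 * f_beat
        # fm (beat-sampled) and am (envelope of the beat train) fold
        # respiratory rates above half the pulse rate onto mirror_bpm - rr;
        # the baseline surrogate is continuous and alias-free, so any fm/am
        # candidate sitting at the mirror of a valid bm candidate is
        # discarded as a sampling image
        bm = next((c for c in pool if c.modality == "bm"), None)
        if bm is not None:
            pool = [
                c
                for c in pool
                if c.modality == "bm"
                or abs((mirror_bpm - bm.rr_bpm) - c.rr_bpm) > _IMAGE_TOL_BPM
            ]
    if len(pool) >= 2:
        # largest agreeing subset; ties broken by smaller spread
        best: list = []
        best_spread = np.inf
        rates = sorted(c.rr_bpm for c in pool)
        for i in range(len(rates)):
            for k in range(len(rates), i + 1, -1):
                sub = rates[i:k]
                spread = sub[-1] - sub[0]
                if spread <= cfg.fuse_spread_bpm and (
                    len(sub) > len(best) or (len(sub) == len(best) and spread < best_spread)
                ):
                    best, best_spread = sub, spread
        if len(best) >= 2:
            return float(np.mean(best))
        return None
    if len(pool) == 1 and window_sqi >= cfg.single_sqi_min:
        return float(pool[0].rr_bpm)
    return None


def smooth(
    estimates: Sequence[RREstimate], window_s: float = 600.0
) -> RRTrend:
    """Causal moving average of available estimates over ``(t - window_s, t]``."""
    avail = [(e.t, e.rr_fused) for e in estimates if e.available]
    times, values = [], []
    for e in estimates:
        in_win = [rr for (t, rr) in avail if e.t - window_s < t <= e.t]
        if in_win:
            times.append(e.t)
            values.append(float(np.mean(in_win)))
    return RRTrend(times=np.array(times), rr_smoothed=np.array(values))


def availability(estimates: Sequence[RREstimate]) -> float:
    """Fraction of windows that fused a rate."""
    if len(estimates) == 0:
        raise ValueError("availability of an empty estimate sequence is undefined")
    return sum(e.available for e in estimates) / len(estimates)


def estimate_window(
    beats: BeatSeries, window, config: PipelineConfig
) -> RREstimate:
    surr = extract_surrogates(beats, window, config)
    sel = (beats.peak_times >= window.start_s) & (beats.peak_times < window.end_s)
    # window quality reflects the beats the estimate is actually built from;
    # beats already rejected by the per-beat gate do not drag it down
    acc = sel & (beats.sqi >= config.sqi_accept)
    if acc.any():
        window_sqi = float(beats.sqi[acc].mean())
    elif sel.any():
        window_sqi = float(beats.sqi[sel].mean())
    else:
        window_sqi = 0.0
    if surr is None:
        return RREstimate(
            t=window.end_s,
            rr_fused=None,
            candidates=[_invalid(m) for m in ("fm", "am", "bm")],
            window_sqi=window_sqi,
            available=False,
        )
    candidates = [
        estimate_modality_rr(
            getattr(surr, m),
            surr.fs_surr,
            surr.valid_mask,
            modality=m,
            config=config,
            coverage=surr.coverage,
        )
        for m in ("fm", "am", "bm")
    ]
    fused = fuse(candidates, window_sqi, surr.ibi_cv, surr.f_beat, config)
    return RREstimate(
        t=window.end_s,
        rr_fused=fused,
        candidates=candidates,
        window_sqi=window_sqi,
        available=fused is not None,
    )


def estimate_record(
    record: PPGRecord, config: PipelineConfig | None = None
) -> tuple[list[RREstimate], RRTrend, Optional[float]]:
    """Full pipeline for one record.

    Beats are detected once over the whole record (avoiding filter edge
    transients at window seams); each window then estimates and fuses from
    its own beats. Returns the per-window estimates, the smoothed trend and
    the record-level mean of available fused values (None when no window
    fused — the record is then counted unavailable, never imputed).
    """
    cfg = config or PipelineConfig()
    beats = detect_beats(record, cfg)
    windows = segment(record, cfg.window_s, cfg.hop_s)
    estimates = [estimate_window(beats, w, cfg) for w in windows]
    _drop_outlier_windows(estimates, cfg)
    trend = smooth(estimates, cfg.smooth_window_s)
    fused = [e.rr_fused for e in estimates if e.available]
    record_mean = float(np.mean(fused)) if fused else None
    return estimates, trend, record_mean


def _drop_outlier_windows(estimates: list[RREstimate], cfg: PipelineConfig) -> None:
    """Temporal-consistency pass: respiratory rate drifts slowly, so a lone
    window estimate far from the record's median is an artefact survivor and
    is demoted to unavailable (with two conflicting windows, the lower-
    quality one is demoted)."""
    avail = [e for e in estimates if e.available]
    if len(avail) >= 3:
        med = float(np.median([e.rr_fused for e in avail]))
        for e in avail:
            if abs(e.rr_fused - med) > cfg.record_outlier_bpm:
                e.rr_fused, e.available = None, False
    elif len(avail) == 2:
        a, b = avail
        if abs(a.rr_fused - b.rr_fused) > cfg.record_outlier_bpm:
            worse = a if a.window_sqi <= b.window_sqi else b
            worse.rr_fused, worse.available = None, False
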