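"""ECG-guided localization of the second heart sound (S2).

The second heart sound marks the closure of the aortic and pulmonary valves
and falls close to the T wave of a simultaneously recorded ECG.  The region
of interest for S2 is therefore taken as a window spanning 30% of the
cardiac cycle centered on the T wave; within that window the loudest point
of the phonocardiogram (by short-time energy) is designated the S2 center,
and a fixed-length snippet around it is handed to feature extraction.

R-wave detection follows the classic energy-integration recipe (band-pass,
differentiate, square, moving-window integrate, adaptive threshold with a
refractory period).  T waves are located as the maximum of the low-passed
ECG inside a physiological search window after each R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "CycleAnnotation",
    "S2SegmentSet",
    "bandpass",
    "short_time_energy",
    "detect_r_waves",
    "detect_t_waves",
    "extract_s2_segments",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs of the S2 localizer.

    s2_segment_duration : length (s) of the snippet cut around each S2
        center; 100 ms covers A2 + P2 at the widest physiological split and
        yields 9 analysis frames at the default 20 ms / 10 ms framing.
    s2_window_fraction : fraction of the RR interval forming the S2 search
        window around the T wave (0.30 -> a 0.25 s window at 72 bpm).
    """

    s2_segment_duration: float = 0.100
    s2_window_fraction: float = 0.30
    r_band: tuple[float, float] = (5.0, 25.0)
    r_integration_window: float = 0.150
    r_median_multiple: float = 4.0
    r_refractory: float = 0.200
    t_lowpass_hz: float = 10.0
    t_search_start: float = 0.120          # s after R
    t_search_end_fraction: float = 0.55    # fraction of RR after R
    pcg_band: tuple[float, float] = (25.0, 150.0)
    energy_window: float = 0.020

    def validate(self) -> None:
        if self.s2_segment_duration <= 0:
            raise ValueError("s2_segment_duration must be positive")
        if not 0 < self.s2_window_fraction < 1:
            raise ValueError("s2_window_fraction must be in (0, 1)")
        if self.r_band[0] <= 0 or self.r_band[1] <= self.r_band[0]:
            raise ValueError("r_band must be an increasing positive interval")


@dataclass(frozen=True)
class CycleAnnotation:
    """Detected landmarks of one complete cardiac cycle (times in seconds)."""

    r_time: float
    t_time: float
    cycle_length: float
    s2_window: tuple[float, float]  # half-open [start, end)
    s2_center: float


@dataclass
class S2SegmentSet:
    """Fixed-length S2 snippets of one subject, in temporal order."""

    subject_id: str
    segments: list[np.ndarray] = field(default_factory=list)
    annotations: list[CycleAnnotation] = field(default_factory=list)
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.segments}
        if len(lengths) > 1:
            raise ValueError(f"segments have mixed lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.segments)


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def lowpass(x: np.ndarray, fs: float, hi: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def short_time_energy(
    pcg: np.ndarray,
    fs: float,
    band: tuple[float, float] = (25.0, 150.0),
    window: float = 0.020,
) -> np.ndarray:
    """Loudness trace of a phonocardiogram.

    Band-passes to the S2 spectral band, squares, and smooths with a
    Hann-weighted moving average whose taper gives the trace a unique
    maximum at an isolated transient (a flat boxcar would plateau).
    """
    y = bandpass(np.asarray(pcg, dtype=float), fs, band[0], band[1])
    n = max(3, int(round(window * fs)) | 1)  # odd length keeps 'same' centered
    w = sps.windows.hann(n, sym=True)
    w /= w.sum()
    return np.convolve(y * y, w, mode="same")


def detect_r_waves(
    ecg: np.ndarray,
    sampling_rate: float,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Detect R-wave times (s) on a single-lead ECG.

    Energy-integration detector: band-pass 5-25 Hz, differentiate, square,
    150 ms moving-window integral, peak-pick above an adaptive threshold
    (multiple of the median integrated energy with a floor relative to the
    largest peak), 200 ms refractory, then refine each candidate to the
    extremum of the band-passed ECG within +/-100 ms.
    """
    cfg = config or SegmentationConfig()
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate)
    if fs < 200:
        raise ValueError(f"sampling rate {fs} Hz too low for R detection (need >= 200)")
    if len(ecg) < 2 * fs:
        raise ValueError("recording shorter than 2 s: insufficient cycles")

    y = bandpass(ecg, fs, *cfg.r_band)
    d = np.gradient(y) * fs
    e = d * d
    n_int = max(3, int(round(cfg.r_integration_window * fs)) | 1)
    w = np.ones(n_int) / n_int
    mwi = np.convolve(e, w, mode="same")

    height = max(cfg.r_median_multiple * np.median(mwi), 0.2 * mwi.max())
    if height <= 0:
        raise ValueError("insufficient cycles: no R waves detected")
    distance = max(1, int(round(cfg.r_refractory * fs)))
    peaks, _ = sps.find_peaks(mwi, height=height, distance=distance)

    # refine to the sharp deflection itself
    half = int(round(0.100 * fs))
    refined: list[int] = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(y), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(y[lo:hi]))))
    refined = sorted(set(refined))

    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < distance:
            if np.abs(y[idx]) > np.abs(y[kept[-1]]):
                kept[-1] = idx
            continue
        kept.append(idx)

    if len(kept) < 2:
        raise ValueError("insufficient cycles: fewer than 2 R waves detected")
    return np.asarray(kept, dtype=float) / fs


def detect_t_waves(
    ecg: np.ndarray,
    r_times: np.ndarray,
    sampling_rate: float,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """One T-wave time per complete RR interval (len(r_times) - 1 values).

    The T is the maximum of the 10 Hz low-passed ECG inside the window
    (R + 120 ms, R + 0.55 RR); no T is emitted for the incomplete cycle
    after the final R.
    """
    cfg = config or SegmentationConfig()
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise ValueError("need at least 2 R times to define a cardiac cycle")
    fs = float(sampling_rate)
    low = lowpass(np.asarray(ecg, dtype=float), fs, cfg.t_lowpass_hz)

    t_times = np.empty(len(r_times) - 1)
    for i in range(len(r_times) - 1):
        r, rr = r_times[i], r_times[i + 1] - r_times[i]
        a = r + cfg.t_search_start
        b = r + cfg.t_search_end_fraction * rr
        ia, ib = int(round(a * fs)), int(round(b * fs))
        ia = max(0, min(ia, len(low) - 2))
        ib = max(ia + 1, min(ib, len(low)))
        t_times[i] = (ia + int(np.argmax(low[ia:ib]))) / fs
    return t_times


def extract_s2_segments(
    recording,
    r_times: np.ndarray,
    t_times: np.ndarray,
    config: SegmentationConfig | None = None,
) -> S2SegmentSet:
    """Cut one fixed-length S2 snippet per complete cardiac cycle.

    For cycle i the search window is the interval of length
    ``s2_window_fraction * RR`` centered on the T wave (clipped to the
    recording); the S2 center is the short-time-energy argmax inside it and
    the snippet of ``s2_segment_duration`` seconds is cut around that
    center from the raw phonocardiogram.  Cycles whose snippet would overrun
    the recording are dropped (counted in a log message).
    """
    cfg = config or SegmentationConfig()
    cfg.validate()
    pcg = np.asarray(recording.pcg, dtype=float)
    fs = float(recording.sampling_rate)
    r_times = np.asarray(r_times, dtype=float)
    t_times = np.asarray(t_times, dtype=float)

    energy = short_time_energy(pcg, fs, band=cfg.pcg_band, window=cfg.energy_window)
    n_seg = int(round(cfg.s2_segment_duration * fs))
    duration = len(pcg) / fs

    segments: list[np.ndarray] = []
    annotations: list[CycleAnnotation] = []
    dropped = 0
    for i, t in enumerate(t_times):
        rr = r_times[i + 1] - r_times[i]
        half = 0.5 * cfg.s2_window_fraction * rr
        w0, w1 = max(0.0, t - half), min(duration, t + half)
        i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
        if i1 <= i0:
            dropped += 1
            continue
        center_idx = i0 + int(np.argmax(energy[i0:i1]))
        start = center_idx - n_seg // 2
        if start < 0 or start + n_seg > len(pcg):
            dropped += 1
            continue
        segments.append(pcg[start : start + n_seg].copy())
        annotations.append(
            CycleAnnotation(
                r_time=float(r_times[i]),
                t_time=float(t),
                cycle_length=float(rr),
                s2_window=(w0, w1),
                s2_center=center_idx / fs,
            )
        )

    if dropped:
        logger.info(
            "subject %s: dropped %d of %d cycles at recording edges",
            getattr(recording, "subject_id", "?"), dropped, len(t_times),
        )
    if not segments:
        raise ValueError("no S2 segments: every cycle fell outside the recording")
    return S2SegmentSet(
        subject_id=getattr(recording, "subject_id", ""),
        segments=segments,
        annotations=annotations,
        sampling_rate=fs,
    )
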