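"""Mel-frequency cepstral coefficients of S2 segments.

Each extracted S2 snippet is pre-emphasized, cut into 20 ms frames hopping
every 10 ms (50% overlap), Hamming-windowed, and mapped to the cepstral
domain: power spectrum -> triangular mel filterbank -> natural log (with a
floor) -> orthonormal type-II DCT, keeping the first 13 coefficients
(indices 0-12, the 0th being the energy-like term).  All frames of all
segments of a subject are stacked into one N x 13 matrix with per-row
provenance, the container consumed by the Gaussian-mixture classifier.

Conventions, stated so magnitudes are reproducible: mel(f) =
2595 log10(1 + f/700); the FFT length is the next power of two at or above
the frame length; power spectra are one-sided |X_k|^2 without 1/N scaling;
the DCT is orthonormal, so scaling a frame by c > 0 shifts only
coefficient 0 (by 2 ln(c) sqrt(M) for M mel filters).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

from .segmentation import S2SegmentSet

__all__ = [
    "MfccConfig",
    "MfccMatrix",
    "hz_to_mel",
    "mel_to_hz",
    "frame_signal",
    "mel_filterbank",
    "mfcc_frame",
    "subject_features",
    "concat_features",
]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MfccConfig:
    frame_length: float = 0.020      # s; body-text value (a 25 ms variant exists)
    frame_hop: float = 0.010         # s; 50% overlap
    pre_emphasis: float = 0.97
    n_mel_filters: int = 26
    n_coefficients: int = 13
    fft_length: int | None = None    # None -> next power of two >= frame samples
    mel_low: float = 0.0
    mel_high: float | None = None    # None -> sampling_rate / 2

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.frame_hop <= self.frame_length:
            raise ValueError("require 0 < frame_hop <= frame_length")
        if not 0 <= self.pre_emphasis < 1:
            raise ValueError("pre_emphasis must be in [0, 1)")
        if self.n_coefficients > self.n_mel_filters:
            raise ValueError("n_coefficients must not exceed n_mel_filters")
        high = self.mel_high if self.mel_high is not None else sampling_rate / 2
        if not 0 <= self.mel_low < high <= sampling_rate / 2:
            raise ValueError("mel range must lie within [0, sampling_rate/2]")

    def frame_samples(self, sampling_rate: float) -> int:
        return int(round(self.frame_length * sampling_rate))

    def hop_samples(self, sampling_rate: float) -> int:
        return max(1, int(round(self.frame_hop * sampling_rate)))

    def nfft(self, sampling_rate: float) -> int:
        if self.fft_length is not None:
            return self.fft_length
        n = self.frame_samples(sampling_rate)
        return 1 << (n - 1).bit_length()

    def fingerprint(self, sampling_rate: float) -> str:
        payload = {"mfcc": asdict(self), "sampling_rate": sampling_rate}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class MfccMatrix:
    """N x D feature matrix with per-row provenance.

    ``fingerprint`` identifies the extraction configuration; matrices with
    different fingerprints refuse to mix (concatenation, scoring, I/O).
    """

    values: np.ndarray
    subject_ids: np.ndarray          # per-row subject id
    segment_index: np.ndarray
    frame_index: np.ndarray
    fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.subject_ids = np.asarray(self.subject_ids)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("provenance length mismatch")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"c{i}" for i in range(self.n_coefficients)]
        )
        df.insert(0, "frame_index", self.frame_index)
        df.insert(0, "segment_index", self.segment_index)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fingerprint={self.fingerprint}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, expected_fingerprint: str | None = None) -> "MfccMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# fingerprint="):
                raise ValueError(f"{path}: missing fingerprint header")
            fp = header.split("=", 1)[1]
            if fp == "None":
                fp = None
            df = pd.read_csv(fh, sep="\t")
        if expected_fingerprint is not None and fp != expected_fingerprint:
            raise ValueError(
                f"{path}: fingerprint {fp} does not match expected {expected_fingerprint}"
            )
        cols = [c for c in df.columns if c.startswith("c")]
        return cls(
            values=df[cols].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
            segment_index=df["segment_index"].to_numpy(),
            frame_index=df["frame_index"].to_numpy(),
            fingerprint=fp,
        )


def concat_features(matrices: Sequence[MfccMatrix]) -> MfccMatrix:
    """Row-wise concatenation; refuses to mix extraction fingerprints."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    fps = {m.fingerprint for m in matrices}
    if len(fps) > 1:
        raise ValueError(f"cannot mix feature fingerprints {sorted(map(str, fps))}")
    return MfccMatrix(
        values=np.vstack([m.values for m in matrices]),
        subject_ids=np.concatenate([m.subject_ids for m in matrices]),
        segment_index=np.concatenate([m.segment_index for m in matrices]),
        frame_index=np.concatenate([m.frame_index for m in matrices]),
        fingerprint=fps.pop(),
    )


def frame_signal(
    segment: np.ndarray, sampling_rate: float, config: MfccConfig | None = None
) -> np.ndarray:
    """Pre-emphasize, frame and Hamming-window a segment.

    Returns an (n_frames, frame_samples) array; the trailing partial frame
    is dropped.  Pre-emphasis is y[n] = x[n] - alpha x[n-1] with y[0]=x[0].
    """
    cfg = config or MfccConfig()
    x = np.asarray(segment, dtype=float)
    fs = float(sampling_rate)
    cfg.validate(fs)
    n_frame = cfg.frame_samples(fs)
    hop = cfg.hop_samples(fs)
    if len(x) < n_frame:
        raise ValueError(
            f"segment of {len(x)} samples shorter than one frame ({n_frame} samples)"
        )
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - cfg.pre_emphasis * x[:-1]
    n_frames = (len(y) - n_frame) // hop + 1
    idx = np.arange(n_frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return y[idx] * np.hamming(n_frame)[None, :]


def mel_filterbank(sampling_rate: float, config: MfccConfig | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mel_filters, nfft//2 + 1).

    Centers are equally spaced on the mel scale across the configured
    range; each triangle peaks at 1 and adjacent filters cross at half
    height (in mel coordinates).
    """
    cfg = config or MfccConfig()
    fs = float(sampling_rate)
    cfg.validate(fs)
    nfft = cfg.nfft(fs)
    n_bins = nfft // 2 + 1
    if n_bins < cfg.n_mel_filters:
        raise ValueError(
            f"{cfg.n_mel_filters} mel filters need at least as many spectral "
            f"bins, got {n_bins} (fft_length {nfft})"
        )
    high = cfg.mel_high if cfg.mel_high is not None else fs / 2
    mel_edges = np.linspace(hz_to_mel(cfg.mel_low), hz_to_mel(high), cfg.n_mel_filters + 2)
    bin_mels = hz_to_mel(np.arange(n_bins) * fs / nfft)
    fb = np.zeros((cfg.n_mel_filters, n_bins))
    for k in range(cfg.n_mel_filters):
        left, center, right = mel_edges[k], mel_edges[k + 1], mel_edges[k + 2]
        up = (bin_mels - left) / (center - left)
        down = (right - bin_mels) / (right - center)
        fb[k] = np.clip(np.minimum(up, down), 0.0, None)
    if np.any(fb.sum(axis=1) == 0):
        raise ValueError("a mel filter covers no spectral bin; increase fft_length")
    return fb


def power_spectrum(frame: np.ndarray, nfft: int) -> np.ndarray:
    """One-sided magnitude-squared spectrum, no 1/N scaling."""
    spec = rfft(np.asarray(frame, dtype=float), n=nfft)
    return np.abs(spec) ** 2


def mfcc_frame(
    frame: np.ndarray,
    filterbank: np.ndarray,
    config: MfccConfig | None = None,
) -> np.ndarray:
    """First D cepstral coefficients of one already-windowed frame.

    The log floor is 1e-12 x the frame's largest filter energy (absolute
    1e-30 for silent frames), so coefficients stay finite on any input.
    """
    cfg = config or MfccConfig()
    nfft = 2 * (filterbank.shape[1] - 1)
    energies = filterbank @ power_spectrum(frame, nfft)
    floor = max(1e-12 * energies.max(initial=0.0), 1e-30)
    log_e = np.log(np.maximum(energies, floor))
    ceps = dct(log_e, type=2, norm="ortho")
    return ceps[: cfg.n_coefficients]


def subject_features(
    segments: S2SegmentSet, config: MfccConfig | None = None
) -> MfccMatrix:
    """Stack the MFCCs of every frame of every S2 segment of one subject."""
    cfg = config or MfccConfig()
    if len(segments) == 0:
        raise ValueError("no segments to featurize")
    fs = segments.sampling_rate
    fb = mel_filterbank(fs, cfg)
    rows, seg_idx, frm_idx = [], [], []
    for s, seg in enumerate(segments.segments):
        frames = frame_signal(seg, fs, cfg)
        for f, frame in enumerate(frames):
            rows.append(mfcc_frame(frame, fb, cfg))
            seg_idx.append(s)
            frm_idx.append(f)
    n = len(rows)
    return MfccMatrix(
        values=np.asarray(rows),
        subject_ids=np.repeat(segments.subject_id, n),
        segment_index=np.asarray(seg_idx),
        frame_index=np.asarray(frm_idx),
        fingerprint=cfg.fingerprint(fs),
    )
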