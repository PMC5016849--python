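"""Synthetic annotated phonocardiogram + ECG cohorts.

Pulmonary hypertension (PH, mean pulmonary artery pressure mPAp >= 25 mmHg)
changes the second heart sound: the pulmonary component P2 grows louder
relative to the aortic component A2 and the A2-P2 splitting interval
widens.  This module simulates two-channel subject recordings that carry
exactly those acoustic signatures, driven by a virtual mPAp through two
monotone maps, together with ground-truth annotations for every cardiac
cycle - so the downstream segmentation, feature-extraction and
classification stages can be exercised and measured without any clinical
recordings.

Waveform model (all components are deliberately simple):

* ECG: per cycle a sharp biphasic R deflection (narrow Gaussian spike with
  a trailing dip) and a smooth Gaussian T hump at 30% of the RR interval.
* PCG: an S1 burst shortly after R, then S2 = A2 + P2, each a
  Gaussian-enveloped damped sinusoid (A2 ~50 Hz, P2 ~45 Hz); P2 trails A2
  by ``split_map(mpap)`` and has amplitude ratio ``p2_gain_map(mpap)``.
* Cycle lengths jitter lognormally around the subject's heart rate; white
  Gaussian noise is added per channel relative to its clean peak.

Not modelled: P waves / QT dynamics, murmurs, respiration-gated splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .segmentation import short_time_energy

__all__ = [
    "SynthCohortConfig",
    "SubjectRecording",
    "CycleTruth",
    "PH_LABEL",
    "NON_PH_LABEL",
    "PH_THRESHOLD_MMHG",
    "default_split_map",
    "default_p2_gain_map",
    "generate_subject",
    "generate_cohort",
    "null_cohort",
]

PH_LABEL = "PH"
NON_PH_LABEL = "non-PH"
PH_THRESHOLD_MMHG = 25.0

# --- fixed waveform geometry (seconds / Hz / relative amplitude) ---
_FIRST_R = 0.2            # time of the first R wave
_R_SIGMA = 0.007
_R_DIP_DELAY = 0.025
_R_DIP_SIGMA = 0.008
_R_DIP_AMP = 0.25
_T_FRACTION = 0.30        # T peak at this fraction of RR after R
_T_SIGMA = 0.040
_T_AMP = 0.35
_S1_DELAY = 0.060         # S1 burst center after R
_S1_SIGMA = 0.015
_S1_FREQ = 35.0
_S1_AMP = 1.0
_A2_DELAY = 0.015         # A2 center after the T peak
_A2_FREQ = 50.0
_A2_AMP = 0.8
_P2_FREQ = 45.0
_S2_SIGMA = 0.010
_CYCLE_TAIL = 0.55        # fraction of RR that must fit before the recording end
_EDGE_MARGIN = 0.10       # extra margin so S2 snippets never overrun


def default_split_map(mpap: float) -> float:
    """A2-P2 interval in seconds: linear 20 ms at 15 mmHg -> 60 ms at 60 mmHg."""
    m = np.clip(mpap, 15.0, 60.0)
    return (20.0 + 40.0 * (m - 15.0) / 45.0) / 1000.0


def default_p2_gain_map(mpap: float) -> float:
    """P2/A2 amplitude ratio: linear 0.4 at 15 mmHg -> 1.5 at 60 mmHg."""
    m = np.clip(mpap, 15.0, 60.0)
    return 0.4 + 1.1 * (m - 15.0) / 45.0


@dataclass(frozen=True)
class SynthCohortConfig:
    """Study-condition knobs of the simulator.

    Defaults mirror the modelled study population: 20 s recordings, PH
    defined at mPAp >= 25 mmHg, class mPAp ranges centered on the cohort
    means of ~41 mmHg (PH) and ~17 mmHg (normal).
    """

    n_subjects_ph: int = 1
    n_subjects_normal: int = 1
    sampling_rate: float = 2000.0
    duration: float = 20.0
    heart_rate_mean: float = 70.0
    heart_rate_sd: float = 8.0
    mpap_range_ph: tuple[float, float] = (28.0, 55.0)
    mpap_range_normal: tuple[float, float] = (11.0, 23.0)
    split_map: Callable[[float], float] = default_split_map
    p2_gain_map: Callable[[float], float] = default_p2_gain_map
    cycle_jitter_sd: float = 0.03
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_ph < 0 or self.n_subjects_normal < 0:
            raise ValueError("subject counts must be non-negative")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        lo_ph, hi_ph = self.mpap_range_ph
        lo_nm, hi_nm = self.mpap_range_normal
        if not (lo_ph >= PH_THRESHOLD_MMHG and hi_ph >= lo_ph):
            raise ValueError("mpap_range_ph must lie at or above 25 mmHg")
        if not (hi_nm < PH_THRESHOLD_MMHG and hi_nm >= lo_nm > 0):
            raise ValueError("mpap_range_normal must lie strictly below 25 mmHg")
        grid = np.linspace(10.0, 65.0, 56)
        splits = np.array([self.split_map(m) for m in grid])
        gains = np.array([self.p2_gain_map(m) for m in grid])
        if np.any(np.diff(splits) < 0) or np.any(np.diff(gains) < 0):
            raise ValueError("split_map and p2_gain_map must be non-decreasing in mPAp")


@dataclass(frozen=True)
class CycleTruth:
    """Ground-truth landmarks of one generated cardiac cycle (seconds)."""

    r_time: float
    t_time: float
    s1_onset: float
    s2_center: float
    a2_time: float
    p2_time: float
    p2_gain: float
    cycle_length: float


@dataclass
class SubjectRecording:
    """Synchronized PCG + ECG of one subject.

    ``label`` is derived from mPAp by the 25 mmHg rule when mPAp is known;
    ``truth`` is populated only for synthetic recordings.
    """

    subject_id: str
    pcg: np.ndarray
    ecg: np.ndarray
    sampling_rate: float
    mpap: float | None = None
    label: str | None = None
    truth: list[CycleTruth] | None = None

    def __post_init__(self) -> None:
        self.pcg = np.asarray(self.pcg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.pcg.shape != self.ecg.shape:
            raise ValueError("pcg and ecg must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mpap is not None:
            derived = PH_LABEL if self.mpap >= PH_THRESHOLD_MMHG else NON_PH_LABEL
            if self.label is None:
                self.label = derived
            elif self.label != derived:
                raise ValueError(
                    f"label {self.label!r} inconsistent with mPAp {self.mpap} mmHg"
                )

    @property
    def duration(self) -> float:
        return len(self.pcg) / self.sampling_rate


def _add_bump(sig: np.ndarray, fs: float, t0: float, sigma: float, amp: float,
              freq: float | None = None) -> None:
    """Add a Gaussian bump (freq None) or Gaussian-enveloped sinusoid in place."""
    half = 5.0 * sigma
    i0 = max(0, int(np.floor((t0 - half) * fs)))
    i1 = min(len(sig), int(np.ceil((t0 + half) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs - t0
    env = amp * np.exp(-0.5 * (t / sigma) ** 2)
    if freq is not None:
        env = env * np.sin(2.0 * np.pi * freq * t)
    sig[i0:i1] += env


def generate_subject(
    config: SynthCohortConfig,
    mpap: float,
    subject_id: str,
    rng: np.random.Generator,
) -> SubjectRecording:
    """Generate one annotated two-channel recording at a given virtual mPAp.

    Deterministic given the generator state.  The truth S2-center of each
    cycle is the argmax of the short-time energy of the *clean* PCG within
    that cycle's S2 neighbourhood, i.e. the quantity the segmenter is asked
    to recover.
    """
    config.validate()
    if mpap <= 0:
        raise ValueError("mpap must be positive")
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    pcg = np.zeros(n)
    ecg = np.zeros(n)

    hr = config.heart_rate_mean + config.heart_rate_sd * rng.standard_normal()
    hr = float(np.clip(hr, 40.0, 120.0))
    base_rr = 60.0 / hr
    min_duration = _FIRST_R + _CYCLE_TAIL * base_rr + _EDGE_MARGIN
    if config.duration < min_duration:
        raise ValueError(
            f"duration {config.duration:.2f} s too short for one full cardiac "
            f"cycle at {hr:.0f} bpm; need at least {min_duration:.2f} s"
        )

    split = float(config.split_map(mpap))
    gain = float(config.p2_gain_map(mpap))

    cycles: list[dict] = []
    r = _FIRST_R
    while r < config.duration:
        rr = base_rr * float(np.exp(config.cycle_jitter_sd * rng.standard_normal()))
        if r + _CYCLE_TAIL * rr + _EDGE_MARGIN > config.duration:
            break
        t_peak = r + _T_FRACTION * rr
        a2 = t_peak + _A2_DELAY
        cycles.append({"r": r, "rr": rr, "t": t_peak, "a2": a2, "p2": a2 + split})
        r += rr

    if not cycles:
        raise ValueError(
            f"duration {config.duration:.2f} s too short for one full cardiac "
            f"cycle; need at least {min_duration:.2f} s"
        )

    for c in cycles:
        _add_bump(ecg, fs, c["r"], _R_SIGMA, 1.0)
        _add_bump(ecg, fs, c["r"] + _R_DIP_DELAY, _R_DIP_SIGMA, -_R_DIP_AMP)
        _add_bump(ecg, fs, c["t"], _T_SIGMA, _T_AMP)
        _add_bump(pcg, fs, c["r"] + _S1_DELAY, _S1_SIGMA, _S1_AMP, freq=_S1_FREQ)
        _add_bump(pcg, fs, c["a2"], _S2_SIGMA, _A2_AMP, freq=_A2_FREQ)
        _add_bump(pcg, fs, c["p2"], _S2_SIGMA, _A2_AMP * gain, freq=_P2_FREQ)

    # truth S2 centers from the clean loudness trace
    energy = short_time_energy(pcg, fs)
    truth: list[CycleTruth] = []
    for c in cycles:
        i0 = max(0, int(round((c["a2"] - 0.030) * fs)))
        i1 = min(n, int(round((c["p2"] + 0.030) * fs)))
        s2_center = (i0 + int(np.argmax(energy[i0:i1]))) / fs
        truth.append(
            CycleTruth(
                r_time=c["r"],
                t_time=c["t"],
                s1_onset=c["r"] + _S1_DELAY - 2.0 * _S1_SIGMA,
                s2_center=s2_center,
                a2_time=c["a2"],
                p2_time=c["p2"],
                p2_gain=gain,
                cycle_length=c["rr"],
            )
        )

    if config.noise_sd > 0:
        pcg = pcg + rng.normal(0.0, config.noise_sd * np.abs(pcg).max(), n)
        ecg = ecg + rng.normal(0.0, config.noise_sd * np.abs(ecg).max(), n)

    return SubjectRecording(
        subject_id=subject_id,
        pcg=pcg,
        ecg=ecg,
        sampling_rate=fs,
        mpap=float(mpap),
        truth=truth,
    )


def generate_cohort(
    config: SynthCohortConfig,
) -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Generate a labeled cohort and its metadata table.

    Each subject's mPAp is drawn uniformly from its class range; labels
    follow the 25 mmHg rule.  Per-subject child seeds are spawned from
    ``config.seed`` so cohorts are reproducible and subjects independent.
    """
    config.validate()
    n_total = config.n_subjects_ph + config.n_subjects_normal
    if n_total < 1:
        raise ValueError("cohort must contain at least one subject")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_total)
    recordings: list[SubjectRecording] = []
    rows: list[dict] = []
    for i in range(n_total):
        is_ph = i < config.n_subjects_ph
        lo, hi = config.mpap_range_ph if is_ph else config.mpap_range_normal
        rng = np.random.default_rng(children[i])
        mpap = float(rng.uniform(lo, hi))
        sid = f"{'ph' if is_ph else 'nm'}{i:03d}"
        rec = generate_subject(config, mpap, sid, rng)
        recordings.append(rec)
        rows.append(
            {"subject_id": sid, "mpap": mpap, "label": rec.label, "seed": i}
        )
    return recordings, pd.DataFrame(rows)


def null_cohort(
    n_per_arm: int,
    seed: int,
    mpap_range: tuple[float, float] = (16.0, 20.0),
    **config_kwargs,
) -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Cohort with identical acoustics in both arms (calibration control).

    Every subject's mPAp is drawn from the same range, but half the
    subjects are arbitrarily labeled PH: any classifier run on this cohort
    should perform at chance.  Labels here deliberately break the 25 mmHg
    rule, so they live in the metadata table only, not on the recordings.
    """
    base = SynthCohortConfig(seed=seed, **config_kwargs)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_arm)
    recordings, rows = [], []
    for i in range(2 * n_per_arm):
        rng = np.random.default_rng(children[i])
        mpap = float(rng.uniform(*mpap_range))
        sid = f"null{i:03d}"
        rec = generate_subject(base, mpap, sid, rng)
        rec.label = None  # label is the arm assignment, not an mPAp fact
        recordings.append(rec)
        rows.append(
            {
                "subject_id": sid,
                "mpap": mpap,
                "label": PH_LABEL if i < n_per_arm else NON_PH_LABEL,
                "seed": i,
            }
        )
    return recordings, pd.DataFrame(rows)
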