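"""On-disk formats and pipeline configuration.

Recordings travel as two-channel WAV files (channel 1 phonocardiogram,
channel 2 ECG, float32) with a cohort CSV (subject_id, mpap, label, seed)
and one JSON annotation sidecar per synthetic subject.  Fitted models are
versioned JSON.  Every derived artifact embeds the pipeline-configuration
fingerprint so artifacts from different configurations refuse to mix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .evaluation import CvResult, RocCurve, confusion_metrics
from .gmm import GmmSettings
from .mfcc import MfccConfig
from .segmentation import SegmentationConfig
from .synth import CycleTruth, SubjectRecording

__all__ = [
    "EvalSettings",
    "PipelineConfig",
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_s2_windows_tsv",
    "write_evaluation_report",
]


@dataclass(frozen=True)
class EvalSettings:
    k: int = 5
    seed: int = 0
    stratified: bool = True


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis pipeline, with a stable fingerprint."""

    sampling_rate: float = 2000.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    gmm: GmmSettings = field(default_factory=GmmSettings)
    evaluation: EvalSettings = field(default_factory=EvalSettings)

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "segmentation": asdict(self.segmentation),
            "mfcc": asdict(self.mfcc),
            "gmm": asdict(self.gmm),
            "evaluation": asdict(self.evaluation),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {"sampling_rate", "segmentation", "mfcc", "gmm", "evaluation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"PipelineConfig: unknown config keys {sorted(unknown)}")
        return cls(
            sampling_rate=data.get("sampling_rate", 2000.0),
            segmentation=_from_dict(SegmentationConfig, data.get("segmentation", {})),
            mfcc=_from_dict(MfccConfig, data.get("mfcc", {})),
            gmm=_from_dict(GmmSettings, data.get("gmm", {})),
            evaluation=_from_dict(EvalSettings, data.get("evaluation", {})),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        self.segmentation.validate()
        self.mfcc.validate(self.sampling_rate)


def write_recording(directory, recording: SubjectRecording) -> Path:
    """Write {id}.wav (2-channel float32) and, if present, truth annotations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{recording.subject_id}.wav"
    data = np.stack([recording.pcg, recording.ecg], axis=1).astype(np.float32)
    wavfile.write(path, int(round(recording.sampling_rate)), data)
    if recording.truth is not None:
        sidecar = directory / f"{recording.subject_id}.annotations.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "subject_id": recording.subject_id,
                    "mpap": recording.mpap,
                    "cycles": [asdict(c) for c in recording.truth],
                },
                fh,
                indent=1,
            )
    return path


def read_recording(
    wav_path,
    target_rate: float | None = None,
    subject_id: str | None = None,
    mpap: float | None = None,
    annotations_path=None,
) -> SubjectRecording:
    """Read a two-channel WAV (PCG + ECG); resample to target_rate if needed.

    Single-channel files are refused: S2 localization requires the
    simultaneous ECG channel.
    """
    wav_path = Path(wav_path)
    rate, raw = wavfile.read(wav_path)
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise ValueError(
            f"{wav_path}: ECG channel required - expected a two-channel WAV "
            "(phonocardiogram + simultaneous ECG)"
        )
    data = raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        data /= np.abs(data).max() or 1.0
    pcg, ecg = data[:, 0], data[:, 1]
    if target_rate is not None and rate != target_rate:
        up, down = int(round(target_rate)), int(rate)
        pcg = resample_poly(pcg, up, down)
        ecg = resample_poly(ecg, up, down)
        rate = target_rate

    truth = None
    if annotations_path is None:
        candidate = wav_path.parent / f"{wav_path.stem}.annotations.json"
        if candidate.exists():
            annotations_path = candidate
    if annotations_path is not None:
        with open(annotations_path) as fh:
            payload = json.load(fh)
        truth = [CycleTruth(**c) for c in payload["cycles"]]
        if mpap is None:
            mpap = payload.get("mpap")
    return SubjectRecording(
        subject_id=subject_id or wav_path.stem,
        pcg=pcg,
        ecg=ecg,
        sampling_rate=float(rate),
        mpap=mpap,
        truth=truth,
    )


def write_cohort(directory, recordings, metadata: pd.DataFrame) -> Path:
    """Write per-subject WAV + annotation files, then the cohort CSV.

    The CSV is written last so a failed run leaves no misleading manifest.
    """
    directory = Path(directory)
    for rec in recordings:
        write_recording(directory, rec)
    csv_path = directory / "cohort.csv"
    metadata.to_csv(csv_path, index=False)
    return csv_path


def read_cohort(directory, target_rate: float | None = None):
    """Read a simulated or recorded cohort directory (WAVs + cohort.csv)."""
    directory = Path(directory)
    csv_path = directory / "cohort.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"{csv_path} not found")
    meta = pd.read_csv(csv_path)
    recordings = []
    for row in meta.itertuples():
        mpap = None if pd.isna(getattr(row, "mpap", None)) else float(row.mpap)
        rec = read_recording(
            directory / f"{row.subject_id}.wav",
            target_rate=target_rate,
            subject_id=str(row.subject_id),
            mpap=mpap,
        )
        rec.label = str(row.label)
        recordings.append(rec)
    return recordings, meta


def write_s2_windows_tsv(path, segment_sets) -> None:
    """BED-like TSV of S2 windows for visual inspection."""
    rows = []
    for ss in segment_sets:
        for ann in ss.annotations:
            rows.append(
                {
                    "subject_id": ss.subject_id,
                    "start_s": ann.s2_window[0],
                    "end_s": ann.s2_window[1],
                    "s2_center_s": ann.s2_center,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_evaluation_report(
    out_dir,
    result: CvResult,
    roc: RocCurve,
    fingerprint: str,
    plot: bool = False,
) -> dict:
    """Write the JSON + TSV cross-validation report; return the JSON payload."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pooled = confusion_metrics(result.pooled_counts)
    macro = {
        key: float(np.mean([m[key] for m in result.fold_metrics if m[key] is not None]))
        for key in ("correct_rate", "fnr", "fpr")
    }
    report = {
        "config_fingerprint": fingerprint,
        "n_subjects": len(result.scores),
        "k": result.fold_assignment.k,
        "stratified": result.fold_assignment.stratified,
        "pooled_counts": asdict(result.pooled_counts),
        "pooled_metrics": pooled,
        "per_fold_metrics": result.fold_metrics,
        "macro_metrics": macro,
        "fold_mpap_pvalues": result.fold_mpap_pvalues,
        "auc": roc.auc,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    scores = result.scores_frame()
    scores.insert(0, "config_fingerprint", fingerprint)
    scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(out_dir / "roc.tsv", sep="\t", index=False)

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", c="gray")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"AUC = {roc.auc:.3f}")
        fig.tight_layout()
        fig.savefig(out_dir / "roc.png", dpi=120)
        plt.close(fig)
    return report
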