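"""End-to-end glue: recording -> S2 segments -> MFCC feature matrix."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .mfcc import MfccConfig, MfccMatrix, subject_features
from .segmentation import (
    SegmentationConfig,
    detect_r_waves,
    detect_t_waves,
    extract_s2_segments,
)
from .synth import SubjectRecording

logger = logging.getLogger(__name__)

__all__ = ["extract_subject_features", "cohort_features"]


def extract_subject_features(
    recording: SubjectRecording,
    seg_config: SegmentationConfig | None = None,
    mfcc_config: MfccConfig | None = None,
) -> MfccMatrix:
    """Run ECG-guided S2 extraction and MFCC computation for one subject."""
    seg_cfg = seg_config or SegmentationConfig()
    r = detect_r_waves(recording.ecg, recording.sampling_rate, seg_cfg)
    t = detect_t_waves(recording.ecg, r, recording.sampling_rate, seg_cfg)
    segments = extract_s2_segments(recording, r, t, seg_cfg)
    feats = subject_features(segments, mfcc_config or MfccConfig())
    logger.info(
        "subject %s: %d cycles -> %d segments -> %d frames",
        recording.subject_id, len(r), len(segments), feats.n_frames,
    )
    return feats


def cohort_features(
    recordings: Iterable[SubjectRecording],
    seg_config: SegmentationConfig | None = None,
    mfcc_config: MfccConfig | None = None,
) -> Mapping[str, MfccMatrix]:
    """Feature matrices for every subject of a cohort, keyed by subject id."""
    return {
        rec.subject_id: extract_subject_features(rec, seg_config, mfcc_config)
        for rec in recordings
    }
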