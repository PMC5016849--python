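"""Subject-level cross-validation, confusion metrics and ROC construction.

Evaluation is strictly subject-level: folds partition subjects, the two
class mixtures are fit on the pooled frames of training-fold subjects
only, and a structural guard asserts that no held-out subject's frames
ever reach a training matrix.  Confusion metrics treat PH as the positive
class; the ROC is swept over the NLL-ratio statistic (PH is called when
the ratio falls below the threshold) with tied scores moving atomically,
which makes the trapezoidal AUC identical to the normalized Mann-Whitney
U statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_chisquare

from .gmm import (
    NON_PH_LABEL,
    PH_LABEL,
    GmmParams,
    SubjectScore,
    classify_subject,
    fit_gmm,
)
from .mfcc import MfccMatrix, concat_features

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "ConfusionCounts",
    "RocCurve",
    "CvResult",
    "make_folds",
    "cross_validate",
    "confusion_metrics",
    "roc_curve",
    "compare_readers",
]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_subject: dict[str, int]
    seed: int
    stratified: bool

    def members(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_of_subject.items() if f == fold)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with PH as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CvResult:
    scores: list[SubjectScore]
    pooled_counts: ConfusionCounts
    fold_assignment: FoldAssignment
    fold_metrics: list[dict] = field(default_factory=list)
    fold_mpap_pvalues: list[float] = field(default_factory=list)
    train_subjects: list[list[str]] = field(default_factory=list)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.scores],
                "nll_ph": [s.nll_ph for s in self.scores],
                "nll_nonph": [s.nll_nonph for s in self.scores],
                "nll_ratio": [s.nll_ratio for s in self.scores],
                "predicted": [s.predicted for s in self.scores],
            }
        )


def make_folds(
    subject_labels: Mapping[str, str],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Randomly partition subjects into k folds, stratified by class.

    Within each class the surplus after equal division goes to the folds
    currently holding the fewest subjects, so overall fold sizes also
    differ by at most one.  Falls back to unstratified assignment (with a
    warning) when some class has fewer than k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2 so that held-out data exists")
    subjects = sorted(subject_labels)
    if len(subjects) < k:
        raise ValueError(f"cannot make {k} folds from {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    classes = sorted({subject_labels[s] for s in subjects})
    if stratified and any(
        sum(subject_labels[s] == c for s in subjects) < k for c in classes
    ):
        warnings.warn(
            f"a class has fewer than {k} members; falling back to unstratified folds",
            stacklevel=2,
        )
        stratified = False

    fold_of: dict[str, int] = {}
    if not stratified:
        order = list(subjects)
        rng.shuffle(order)
        for i, s in enumerate(order):
            fold_of[s] = i % k
    else:
        fold_sizes = np.zeros(k, dtype=int)
        for c in classes:
            members = [s for s in subjects if subject_labels[s] == c]
            rng.shuffle(members)
            base, rem = divmod(len(members), k)
            # folds with the fewest subjects so far take the surplus
            order = sorted(range(k), key=lambda f: (fold_sizes[f], f))
            counts = {f: base for f in range(k)}
            for f in order[:rem]:
                counts[f] += 1
            pos = 0
            for f in range(k):
                for s in members[pos : pos + counts[f]]:
                    fold_of[s] = f
                fold_sizes[f] += counts[f]
                pos += counts[f]
    return FoldAssignment(k=k, fold_of_subject=fold_of, seed=seed, stratified=stratified)


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Correct rate, false-negative rate, false-positive rate.

    A rate with a zero denominator is reported as None (undefined), never 0.
    """
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    cr = (counts.tp + counts.tn) / counts.total
    fnr = counts.fn / (counts.fn + counts.tp) if counts.fn + counts.tp else None
    fpr = counts.fp / (counts.fp + counts.tn) if counts.fp + counts.tn else None
    return {"correct_rate": cr, "fnr": fnr, "fpr": fpr}


def _counts_from_scores(
    scores: Sequence[SubjectScore], labels: Mapping[str, str]
) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for s in scores:
        truth_ph = labels[s.subject_id] == PH_LABEL
        pred_ph = s.predicted == PH_LABEL
        tp += truth_ph and pred_ph
        tn += (not truth_ph) and (not pred_ph)
        fp += (not truth_ph) and pred_ph
        fn += truth_ph and (not pred_ph)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def cross_validate(
    features: Mapping[str, MfccMatrix],
    labels: Mapping[str, str],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    mpap: Mapping[str, float] | None = None,
    **gmm_kwargs,
) -> CvResult:
    """k-fold subject-level cross-validation of the two-model classifier.

    Per fold: fit the PH and non-PH mixtures on the pooled frames of
    training subjects only, score every held-out subject, and pool the
    predictions.  When mPAp values are supplied, a Welch t-test between
    the training and test mPAp distributions is computed per fold and its
    p-value recorded (a balance check, not a gate).
    """
    for c in (PH_LABEL, NON_PH_LABEL):
        if sum(lbl == c for lbl in labels.values()) < 2:
            raise ValueError(f"need at least 2 subjects of class {c!r}")
    assignment = make_folds(labels, k=k, seed=seed, stratified=stratified)
    fit_seeds = np.random.SeedSequence(seed).generate_state(2 * k) % (2**31)

    scores: list[SubjectScore] = []
    fold_metrics: list[dict] = []
    fold_pvalues: list[float] = []
    train_lists: list[list[str]] = []
    for f in range(k):
        test_ids = assignment.members(f)
        train_ids = sorted(set(labels) - set(test_ids))
        train_lists.append(train_ids)
        class_models: dict[str, GmmParams] = {}
        for idx, c in enumerate((PH_LABEL, NON_PH_LABEL)):
            mats = [features[s] for s in train_ids if labels[s] == c]
            if not mats:
                raise ValueError(f"training data for fold {f} is missing class {c!r}")
            train_mat = concat_features(mats)
            # leakage guard: held-out subjects must not appear in training rows
            overlap = set(np.unique(train_mat.subject_ids)) & set(test_ids)
            assert not overlap, f"fold {f}: leaked subjects {sorted(overlap)}"
            class_models[c] = fit_gmm(
                train_mat, seed=int(fit_seeds[2 * f + idx]), **gmm_kwargs
            )
        fold_scores = [
            classify_subject(
                features[s], class_models[PH_LABEL], class_models[NON_PH_LABEL],
                subject_id=s,
            )
            for s in test_ids
        ]
        scores.extend(fold_scores)
        fold_counts = _counts_from_scores(fold_scores, labels)
        fold_metrics.append(confusion_metrics(fold_counts))
        if mpap is not None:
            p = float(
                stats.ttest_ind(
                    [mpap[s] for s in train_ids],
                    [mpap[s] for s in test_ids],
                    equal_var=False,
                ).pvalue
            )
            fold_pvalues.append(p)
            logger.info("fold %d train/test mPAp balance p = %.3f", f, p)

    return CvResult(
        scores=scores,
        pooled_counts=_counts_from_scores(scores, labels),
        fold_assignment=assignment,
        fold_metrics=fold_metrics,
        fold_mpap_pvalues=fold_pvalues,
        train_subjects=train_lists,
    )


def roc_curve(scores: Mapping[str, float], labels: Mapping[str, str]) -> RocCurve:
    """ROC of the NLL-ratio statistic (PH called when score < threshold).

    Thresholds sweep the observed score values plus the two infinite
    endpoints; equal scores move atomically, so the trapezoidal AUC equals
    the normalized Mann-Whitney U statistic.
    """
    subjects = sorted(scores)
    vals = np.array([scores[s] for s in subjects], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores must be finite")
    is_ph = np.array([labels[s] == PH_LABEL for s in subjects])
    n_pos, n_neg = int(is_ph.sum()), int((~is_ph).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    thresholds = np.concatenate(([-np.inf], np.unique(vals), [np.inf]))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred_ph = vals < thr
        tpr[i] = (pred_ph & is_ph).sum() / n_pos
        fpr[i] = (pred_ph & ~is_ph).sum() / n_neg
    # one extra point at each unique value's upper side: include <= max
    tpr[-1] = 1.0
    fpr[-1] = 1.0
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def compare_readers(
    algorithm_counts: ConfusionCounts, reader_counts: ConfusionCounts
) -> dict:
    """Compare algorithm and human-reader confusion metrics.

    Reports each rate for both, their difference (algorithm - reader) and
    a chi-squared two-proportion p-value per rate.  Rates with a zero
    denominator on either side are omitted with a warning.
    """
    if algorithm_counts.total <= 0 or reader_counts.total <= 0:
        raise ValueError("both confusion tables must be non-empty")

    def _events(c: ConfusionCounts) -> dict[str, tuple[int, int]]:
        return {
            "correct_rate": (c.tp + c.tn, c.total),
            "fnr": (c.fn, c.fn + c.tp),
            "fpr": (c.fp, c.fp + c.tn),
        }

    ev_a, ev_r = _events(algorithm_counts), _events(reader_counts)
    out: dict = {"algorithm": {}, "reader": {}, "difference": {}, "p_value": {}}
    for rate in ("correct_rate", "fnr", "fpr"):
        (xa, na), (xr, nr) = ev_a[rate], ev_r[rate]
        if na == 0 or nr == 0:
            warnings.warn(f"{rate}: zero denominator, comparison omitted", stacklevel=2)
            continue
        pa, pr = xa / na, xr / nr
        out["algorithm"][rate] = pa
        out["reader"][rate] = pr
        out["difference"][rate] = pa - pr
        if pa == pr:
            pval = 1.0
        else:
            _, pval, _ = proportions_chisquare([xa, xr], [na, nr])
        out["p_value"][rate] = float(pval)
    return out
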