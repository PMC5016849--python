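"""Tests of fold construction, cross-validation, metrics and ROC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

import phonoscreen as ps
from phonoscreen.evaluation import _counts_from_scores


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney AUC: P(PH score < non-PH score) + ties/2."""
    ph = [scores[s] for s in scores if labels[s] == ps.PH_LABEL]
    nm = [scores[s] for s in scores if labels[s] != ps.PH_LABEL]
    wins = sum((p < n) + 0.5 * (p == n) for p in ph for n in nm)
    return wins / (len(ph) * len(nm))


def enumeration_two_proportion_p(x1, n1, x2, n2):
    """Exact-enumeration p-value for a difference of two proportions.

    Under the pooled null rate, enumerate all (k1, k2) outcomes and sum
    the probability of those with at least the observed absolute
    difference of proportions.
    """
    p0 = (x1 + x2) / (n1 + n2)
    obs = abs(x1 / n1 - x2 / n2)
    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)
    prob = np.outer(binom.pmf(k1, n1, p0), binom.pmf(k2, n2, p0))
    diff = np.abs(k1[:, None] / n1 - k2[None, :] / n2)
    return float(prob[diff >= obs - 1e-12].sum())


class TestMakeFolds:
    def test_study_sized_fold_apportionment(self):
        labels = {f"p{i}": ps.PH_LABEL for i in range(86)}
        labels.update({f"n{i}": ps.NON_PH_LABEL for i in range(78)})
        folds = ps.make_folds(labels, k=5, seed=0)
        sizes = sorted(len(folds.members(f)) for f in range(5))
        assert sizes == [32, 33, 33, 33, 33]
        # stratification: per-class fold sizes differ by at most one
        for cls in (ps.PH_LABEL, ps.NON_PH_LABEL):
            per_fold = [
                sum(labels[s] == cls for s in folds.members(f)) for f in range(5)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_k1_rejected(self):
        labels = {"a": ps.PH_LABEL, "b": ps.NON_PH_LABEL}
        with pytest.raises(ValueError, match="k must be"):
            ps.make_folds(labels, k=1)

    @given(seed=st.integers(min_value=0, max_value=9999))
    def test_folds_partition_subjects(self, seed):
        labels = {f"s{i}": (ps.PH_LABEL if i % 3 else ps.NON_PH_LABEL) for i in range(23)}
        folds = ps.make_folds(labels, k=4, seed=seed)
        seen = [s for f in range(4) for s in folds.members(f)]
        assert sorted(seen) == sorted(labels)

    def test_small_class_falls_back_unstratified(self):
        labels = {f"s{i}": ps.NON_PH_LABEL for i in range(10)}
        labels["ph0"] = ps.PH_LABEL
        with pytest.warns(UserWarning, match="unstratified"):
            folds = ps.make_folds(labels, k=5, seed=0)
        assert not folds.stratified


class TestConfusionMetrics:
    def test_hand_counted_table(self):
        m = ps.confusion_metrics(ps.ConfusionCounts(tp=3, tn=4, fp=2, fn=1))
        assert m["correct_rate"] == pytest.approx(0.70)
        assert m["fnr"] == pytest.approx(0.25)
        assert m["fpr"] == pytest.approx(1 / 3)

    def test_perfect_classifier(self):
        m = ps.confusion_metrics(ps.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m["correct_rate"], m["fnr"], m["fpr"]) == (1.0, 0.0, 0.0)

    def test_empty_positive_class_is_undefined_not_zero(self):
        m = ps.confusion_metrics(ps.ConfusionCounts(tp=0, tn=7, fp=3, fn=0))
        assert m["fnr"] is None
        assert m["fpr"] == pytest.approx(0.3)

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_cr_complement_identity(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        c = ps.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        m = ps.confusion_metrics(c)
        assert m["correct_rate"] == pytest.approx(1 - (fp + fn) / c.total)


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        scores = {"a": 0.5, "b": 0.6, "c": 1.2, "d": 1.4}
        labels = {"a": ps.PH_LABEL, "b": ps.PH_LABEL,
                  "c": ps.NON_PH_LABEL, "d": ps.NON_PH_LABEL}
        roc = ps.roc_curve(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0

    def test_auc_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(17)
        vals = np.round(rng.normal(1.0, 0.15, 50), 2)  # rounding makes ties
        scores = {f"s{i}": float(v) for i, v in enumerate(vals)}
        labels = {
            f"s{i}": ps.PH_LABEL if rng.random() < 0.5 else ps.NON_PH_LABEL
            for i in range(50)
        }
        if len({labels[s] for s in labels}) < 2:
            pytest.fail("degenerate label draw")
        roc = ps.roc_curve(scores, labels)
        assert roc.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(1, 0.2, 80))}
        labels = {s: ps.PH_LABEL if rng.random() < 0.4 else ps.NON_PH_LABEL
                  for s in scores}
        roc = ps.roc_curve(scores, labels)
        y = [labels[s] == ps.PH_LABEL for s in sorted(scores)]
        x = [-scores[s] for s in sorted(scores)]  # low ratio indicates PH
        assert roc.auc == pytest.approx(sk.roc_auc_score(y, x), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(29)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(1, 0.2, 40))}
        labels = {s: ps.PH_LABEL if rng.random() < 0.5 else ps.NON_PH_LABEL
                  for s in scores}
        base = ps.roc_curve(scores, labels).auc
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            transformed = {s: float(f(v)) for s, v in scores.items()}
            assert ps.roc_curve(transformed, labels).auc == pytest.approx(base)

    def test_monotone_curve(self):
        rng = np.random.default_rng(31)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(1, 0.2, 30))}
        labels = {s: ps.PH_LABEL if rng.random() < 0.5 else ps.NON_PH_LABEL
                  for s in scores}
        roc = ps.roc_curve(scores, labels)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(37)
        aucs = []
        for _ in range(10):
            scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(1, 0.2, 200))}
            labels = {s: ps.PH_LABEL if rng.random() < 0.5 else ps.NON_PH_LABEL
                      for s in scores}
            aucs.append(ps.roc_curve(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ps.roc_curve({"a": 1.0, "b": 2.0}, {"a": ps.PH_LABEL, "b": ps.PH_LABEL})


class TestCrossValidate:
    def test_separated_cohort_classified_well(self, small_cohort_features):
        feats, labels, mpap = small_cohort_features
        res = ps.cross_validate(feats, labels, k=4, seed=0, mpap=mpap)
        m = ps.confusion_metrics(res.pooled_counts)
        assert m["correct_rate"] >= 0.8
        assert len(res.scores) == len(labels)
        assert len(res.fold_mpap_pvalues) == 4
        assert all(0 <= p <= 1 for p in res.fold_mpap_pvalues)

    def test_no_test_subject_in_training_sets(self, small_cohort_features):
        feats, labels, _ = small_cohort_features
        res = ps.cross_validate(feats, labels, k=4, seed=1)
        for f in range(4):
            test_ids = set(res.fold_assignment.members(f))
            assert test_ids.isdisjoint(res.train_subjects[f])
            assert test_ids | set(res.train_subjects[f]) == set(labels)

    def test_missing_class_in_cohort_rejected(self, small_cohort_features):
        feats, labels, _ = small_cohort_features
        only_ph = {s: ps.PH_LABEL for s in labels}
        with pytest.raises(ValueError, match="at least 2"):
            ps.cross_validate(feats, only_ph, k=2)

    def test_fold_metrics_reported_per_fold(self, small_cohort_features):
        feats, labels, _ = small_cohort_features
        res = ps.cross_validate(feats, labels, k=4, seed=2)
        assert len(res.fold_metrics) == 4
        assert all("correct_rate" in m for m in res.fold_metrics)

    def test_counts_from_scores_agrees_with_predictions(self, small_cohort_features):
        feats, labels, _ = small_cohort_features
        res = ps.cross_validate(feats, labels, k=4, seed=3)
        manual_correct = sum(
            s.predicted == labels[s.subject_id] for s in res.scores
        )
        assert res.pooled_counts.tp + res.pooled_counts.tn == manual_correct
        recomputed = _counts_from_scores(res.scores, labels)
        assert recomputed == res.pooled_counts


class TestCompareReaders:
    def test_identical_counts_no_difference(self):
        c = ps.ConfusionCounts(tp=20, tn=30, fp=10, fn=5)
        out = ps.compare_readers(c, c)
        for rate in ("correct_rate", "fnr", "fpr"):
            assert out["difference"][rate] == 0.0
            assert out["p_value"][rate] == 1.0

    def test_headline_rate_difference(self):
        """74/100 vs 56/100 correct: the published rates as toy counts."""
        alg = ps.ConfusionCounts(tp=37, tn=37, fp=13, fn=13)
        readers = ps.ConfusionCounts(tp=28, tn=28, fp=22, fn=22)
        out = ps.compare_readers(alg, readers)
        assert out["difference"]["correct_rate"] == pytest.approx(0.18)

    @pytest.mark.parametrize(
        "x1,n1,x2,n2",
        [(20, 25, 12, 25), (18, 30, 9, 30), (12, 15, 5, 12)],
    )
    def test_p_value_close_to_exact_enumeration(self, x1, n1, x2, n2):
        # the chi-squared approximation drifts further from the exact
        # enumeration only for severely unbalanced, very small tables
        alg = ps.ConfusionCounts(tp=x1, tn=0, fp=0, fn=n1 - x1)
        readers = ps.ConfusionCounts(tp=x2, tn=0, fp=0, fn=n2 - x2)
        with pytest.warns(UserWarning, match="fpr"):  # fp + tn = 0 by design
            out = ps.compare_readers(alg, readers)
        # CR for these tables is x/n; compare its chi-squared p-value with
        # the exact enumeration oracle
        exact = enumeration_two_proportion_p(x1, n1, x2, n2)
        assert out["p_value"]["correct_rate"] == pytest.approx(exact, abs=0.02)

    def test_zero_denominator_omitted_with_warning(self):
        alg = ps.ConfusionCounts(tp=0, tn=10, fp=5, fn=0)  # FNR undefined
        readers = ps.ConfusionCounts(tp=5, tn=10, fp=5, fn=5)
        with pytest.warns(UserWarning, match="fnr"):
            out = ps.compare_readers(alg, readers)
        assert "fnr" not in out["p_value"]
        assert "fpr" in out["p_value"]
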