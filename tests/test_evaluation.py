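import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rpistack.evaluation import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    cross_validate,
    metrics_from_scores,
    roc_auc,
)
from rpistack.io_formats import PairTable, ValidationError
from rpistack.model import protein_feature_frame, rna_feature_frame
from rpistack.sae import SaeConfig


def pair_counting_auc(scores, labels):
    """O(n^2) oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPointMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert (
            m.accuracy == m.sensitivity == m.specificity == m.precision == m.mcc == 1.0
        )

    def test_worked_confusion_table(self):
        m = compute_metrics(ConfusionCounts(tp=60, fp=10, tn=80, fn=20))
        assert m.accuracy == pytest.approx(140 / 170)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(80 / 90)
        assert m.precision == pytest.approx(60 / 70)
        assert m.mcc == pytest.approx(
            (60 * 80 - 10 * 20) / np.sqrt(70.0 * 80 * 90 * 100)
        )

    def test_all_positive_on_balanced_data(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=10, tn=0, fn=0))
        assert m.specificity == 0.0
        assert m.mcc == 0.0  # zero-denominator convention

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_mcc_bounds_class_swap_and_prediction_flip(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert -1.0 <= m.mcc <= 1.0
        # relabelling which class is "positive" (TP<->TN, FP<->FN) swaps
        # sensitivity<->specificity and leaves the correlation unchanged
        swapped = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert swapped.mcc == pytest.approx(m.mcc, abs=1e-12)
        assert swapped.sensitivity == pytest.approx(m.specificity)
        assert swapped.specificity == pytest.approx(m.sensitivity)
        # inverting every prediction (TP<->FN, TN<->FP) negates MCC; the
        # denominator factor multiset is unchanged, so the zero-denominator
        # convention is hit by both or neither
        flipped = compute_metrics(ConfusionCounts(tp=fn, fp=tn, tn=fp, fn=tp))
        assert flipped.mcc == pytest.approx(-m.mcc, abs=1e-12)

    def test_confusion_counting_from_vectors(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 1, 0, 1])
        c = confusion_counts(y, p)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)
        assert c.total == 5


class TestRocAuc:
    def test_scores_equal_labels(self):
        auc, *_ = roc_auc(np.array([1.0, 0, 1, 0]), np.array([1, 0, 1, 0]))
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, *_ = roc_auc(np.full(10, 0.3), np.array([0, 1] * 5))
        assert auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.random(50), 2)  # rounding forces ties
        labels = (rng.random(50) < 0.4).astype(int)
        auc, *_ = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.5).astype(int)
        auc1, *_ = roc_auc(scores, labels)
        auc2, *_ = roc_auc(np.exp(3 * scores) - 1, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_threshold_ties_count_as_positive(self):
        fold = metrics_from_scores(np.array([0.5, 0.4]), np.array([1, 0]))
        assert fold.metrics.accuracy == 1.0


@pytest.fixture(scope="module")
def features(small_dataset):
    return (
        protein_feature_frame(small_dataset.pssms),
        rna_feature_frame(small_dataset.rnas),
    )


class TestCrossValidate:
    def _cv(self, small_dataset, features, seed=0, pairs=None):
        pf, rf = features
        fast = SaeConfig(layer_sizes=(16, 8), epochs=5, batch_size=64, seed=1)
        return cross_validate(
            pairs or small_dataset.pairs,
            pf,
            rf,
            sae_config=fast,
            n_trees=30,
            folds=5,
            seed=seed,
        )

    def test_every_pair_in_exactly_one_test_fold(self, small_dataset, features):
        report = self._cv(small_dataset, features)
        assert sum(f.n for f in report.folds) == len(small_dataset.pairs)
        assert report.pooled.n == len(small_dataset.pairs)

    def test_row_order_invariance(self, small_dataset, features):
        r1 = self._cv(small_dataset, features, seed=3)
        shuffled = small_dataset.pairs.frame.sample(frac=1, random_state=0)
        r2 = self._cv(
            small_dataset, features, seed=3, pairs=PairTable(frame=shuffled)
        )
        assert r1.mean() == r2.mean()

    def test_too_few_class_members_rejected(self, small_dataset, features):
        pf, rf = features
        frame = small_dataset.pairs.frame.copy()
        frame["label"] = 0
        frame.loc[frame.index[:2], "label"] = 1  # only two positives
        with pytest.raises(ValidationError):
            cross_validate(PairTable(frame=frame), pf, rf, folds=5)

    def test_report_serializes(self, small_dataset, features):
        report = self._cv(small_dataset, features)
        d = report.to_dict()
        assert set(d) >= {"folds", "mean", "pooled"}
        assert len(d["folds"]) == 5
        for key in ("accuracy", "sensitivity", "specificity", "precision", "mcc", "auc"):
            assert 0.0 <= d["mean"][key] <= 1.0 or key == "mcc"
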