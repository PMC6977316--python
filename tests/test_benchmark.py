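"""Tanimoto similarity, 1-NN prediction, metric panel, split protocol and
Y-randomization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (accuracy_score, f1_score, matthews_corrcoef,
                             recall_score)

from ncmfp.benchmark import (ConfusionCounts, SplitProtocol, confusion,
                             confusion_metrics, label_activity,
                             one_nn_predict, run_split_protocol, tanimoto,
                             y_randomization, z_score)


def bits(s: str) -> np.ndarray:
    return np.array([int(c) for c in s], dtype=np.uint8)


class TestTanimoto:
    @pytest.mark.parametrize("a,b,expected", [
        ("1010", "1010", 1.0),
        ("1100", "0011", 0.0),
        ("1110", "0110", 2 / 3),
        ("0000", "0000", 0.0),  # convention for empty fingerprints
    ])
    def test_hand_counted(self, a, b, expected):
        assert tanimoto(bits(a), bits(b)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(bits("101"), bits("10"))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.data())
    def test_symmetry_range_and_self_similarity(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a),
                               max_size=len(a)))
        va, vb = np.array(a, dtype=np.uint8), np.array(b, dtype=np.uint8)
        s = tanimoto(va, vb)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(vb, va)
        if va.any():
            assert tanimoto(va, va) == 1.0


class TestOneNN:
    def test_exact_training_twin(self):
        train = np.array([bits("1100"), bits("0011")])
        pred = one_nn_predict(train, ["a", "b"], bits("0011"))
        assert pred[0] == "b"

    def test_single_item_training_set(self):
        pred = one_nn_predict(np.array([bits("1100")]), ["only"],
                              bits("0011"))
        assert pred[0] == "only"

    def test_tie_broken_by_input_order(self):
        train = np.array([bits("1100"), bits("0110")])
        # query equidistant from both neighbors
        pred = one_nn_predict(train, ["first", "second"], bits("1110"))
        assert pred[0] == "first"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            one_nn_predict(np.empty((0, 4)), [], bits("1010"))

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        train = rng.integers(0, 2, size=(30, 16)).astype(np.uint8)
        labels = np.array([f"c{v}" for v in rng.integers(0, 3, 30)])
        queries = rng.integers(0, 2, size=(10, 16)).astype(np.uint8)
        got = one_nn_predict(train, labels, queries)
        for qi, q in enumerate(queries):
            sims = [tanimoto(q, t) for t in train]
            assert got[qi] == labels[int(np.argmax(sims))]


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1, m.mcc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_inverted_classifier(self):
        m = confusion_metrics(ConfusionCounts(0, 10, 0, 10))
        assert m.accuracy == 0.0
        assert m.mcc == -1.0

    def test_hand_evaluated_panel(self):
        m = confusion_metrics(ConfusionCounts(tp=50, fp=10, tn=30, fn=10))
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.8333, abs=1e-4)
        assert m.f1 == pytest.approx(0.8333, abs=1e-4)
        assert m.mcc == pytest.approx(0.5833, abs=1e-4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_degenerate_ratios_flagged_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity == 0.0 and m.mcc == 0.0
        assert "sensitivity" in m.undefined_ratios

    def test_against_sklearn_on_random_tables(self):
        """1,000 random count tables agree with the textbook formulas as
        implemented independently in scikit-learn."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == pytest.approx(
                accuracy_score(y_true, y_pred))
            assert m.sensitivity == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0))
            assert m.f1 == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0))
            if len(set(y_true)) > 1 and len(set(y_pred)) > 1:
                assert m.mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestLabelActivity:
    @pytest.mark.parametrize("ic50,expected", [
        (5.0, "active"), (10.0, "inactive"), (15.0, "inactive"),
        (0.0, "active"), (9.999, "active"),
    ])
    def test_threshold_strict(self, ic50, expected):
        assert label_activity(ic50) == expected

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            label_activity(-1.0)
        with pytest.raises(ValueError):
            label_activity(float("nan"))


class TestSplitProtocol:
    def test_split_arithmetic(self, toy_benchmark):
        res = run_split_protocol(toy_benchmark["bits"],
                                 toy_benchmark["labels"],
                                 SplitProtocol(repeats=2, cv_folds=0, seed=0))
        assert len(res.external) == 2

    def test_deterministic_given_seed(self, toy_benchmark):
        proto = SplitProtocol(repeats=3, cv_folds=0, seed=4)
        r1 = run_split_protocol(toy_benchmark["bits"],
                                toy_benchmark["labels"], proto)
        r2 = run_split_protocol(toy_benchmark["bits"],
                                toy_benchmark["labels"], proto)
        assert r1.external_mean == r2.external_mean

    def test_row_order_invariance(self, toy_benchmark):
        """Shuffling dataset rows together with labels leaves the averaged
        external metrics unchanged (splits are index-free)."""
        proto = SplitProtocol(repeats=3, cv_folds=0, seed=4)
        bits_, labels = toy_benchmark["bits"], toy_benchmark["labels"]
        perm = np.random.default_rng(9).permutation(len(labels))
        r1 = run_split_protocol(bits_, labels, proto)
        r2 = run_split_protocol(bits_[perm], labels[perm], proto)
        assert r1.external_mean.accuracy == pytest.approx(
            r2.external_mean.accuracy, abs=0.05)

    def test_single_class_rejected(self, toy_benchmark):
        labels = np.array(["same"] * len(toy_benchmark["labels"]))
        with pytest.raises(ValueError):
            run_split_protocol(toy_benchmark["bits"], labels,
                               SplitProtocol())

    def test_cv_metrics_reported(self, toy_benchmark):
        res = run_split_protocol(toy_benchmark["bits"],
                                 toy_benchmark["labels"],
                                 SplitProtocol(repeats=1, cv_folds=10, seed=0))
        assert res.cv[0] is not None
        assert 0 <= res.cv[0].accuracy <= 1


class TestYRandomization:
    def test_z_score_direct_substitution(self):
        assert z_score(0.9, 0.1, 0.2) == pytest.approx(4.0)
        assert np.isnan(z_score(0.9, 0.1, 0.0))

    def test_separable_task_significant(self, toy_benchmark):
        yr = y_randomization(toy_benchmark["bits"], toy_benchmark["labels"],
                             SplitProtocol(repeats=3, cv_folds=0, seed=1),
                             rounds=20, seed=1)
        assert yr.z_mcc > 3
        assert yr.significant()

    def test_minimum_rounds_enforced(self, toy_benchmark):
        with pytest.raises(ValueError):
            y_randomization(toy_benchmark["bits"], toy_benchmark["labels"],
                            SplitProtocol(repeats=2, cv_folds=0), rounds=1)

    def test_confusion_helper(self):
        c = confusion(["a", "a", "b", "b"], ["a", "b", "b", "b"],
                      positive="a")
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 2, 0)
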