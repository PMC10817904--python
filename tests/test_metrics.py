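"""Position accuracy/error, epidermal thickness, ET accuracy, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octskin import metrics


def test_position_accuracy_tolerance_edge():
    a = np.full(50, 100)
    assert metrics.position_accuracy(a, a) == 1.0
    assert metrics.position_accuracy(a + 2, a) == 1.0   # exactly at tolerance
    assert metrics.position_accuracy(a + 3, a) == 0.0
    mixed = a.copy()
    mixed[:10] += 5
    assert metrics.position_accuracy(mixed, a) == pytest.approx(0.8)


def test_position_accuracy_symmetric_and_monotone_in_tolerance():
    rng = np.random.default_rng(0)
    a = rng.integers(50, 60, 40)
    b = a + rng.integers(-4, 5, 40)
    assert metrics.position_accuracy(a, b) == metrics.position_accuracy(b, a)
    accs = [metrics.position_accuracy(a, b, tolerance=t) for t in (4, 3, 2, 1, 0)]
    assert all(x >= y for x, y in zip(accs, accs[1:]))


def test_position_error_values():
    a = np.full(10, 7)
    assert metrics.position_error(a, a) == (0.0, 0.0)
    offs = a.copy()
    offs[::2] += 2  # |diff| alternates 2, 0 -> mean 1, sd 1
    assert metrics.position_error(offs, a) == (1.0, 1.0)
    # five-column case, checked against direct arithmetic
    pred = np.array([10, 12, 9, 15, 11])
    man = np.array([11, 12, 12, 13, 11])
    diff = np.abs(pred - man)
    mean, sd = metrics.position_error(pred, man)
    assert mean == pytest.approx(diff.mean()) and sd == pytest.approx(diff.std())


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        metrics.position_accuracy(np.arange(4), np.arange(5))
    with pytest.raises(ValueError):
        metrics.position_error(np.arange(4), np.arange(5))


def test_epidermal_thickness_conversion():
    sc = np.full(20, 100)
    dej = np.full(20, 200)
    et = metrics.epidermal_thickness(sc, dej, axial_px_um=3.25)
    assert et["mean_px"] == 100.0
    assert et["mean_um"] == pytest.approx(325.0)
    zero = metrics.epidermal_thickness(sc, sc)
    assert zero["mean_px"] == 0.0


def test_epidermal_thickness_flags_inverted_columns():
    sc = np.full(10, 100)
    dej = np.full(10, 120)
    dej[3] = 90  # impossible column
    et = metrics.epidermal_thickness(sc, dej)
    assert not et["valid"][3] and et["valid"].sum() == 9
    assert et["mean_px"] == pytest.approx(20.0)
    with pytest.raises(ValueError):
        metrics.epidermal_thickness(np.full(3, 50), np.full(3, 40))


def test_et_accuracy_counting():
    pred = [100.0, 105.0, 90.0, 100.0]
    man = [100.0, 100.0, 100.0, 98.0]
    sds = [5.0, 5.0, 5.0, 5.0]
    assert metrics.et_accuracy(pred, man, sds) == 0.75
    assert metrics.et_accuracy(man, man, sds) == 1.0
    assert metrics.et_accuracy([1.0], [2.0], [0.0]) == 0.0
    assert metrics.et_accuracy(man, man, [0.0] * 4) == 1.0  # pred == manual, any SD


def test_classification_report_perfect_predictions():
    labels = np.array([0, 1, 2] * 10)
    probs = np.zeros((30, 4))
    probs[np.arange(30), labels] = 1.0
    rep = metrics.classification_report(labels, probs)
    for cls in ("non-boundary", "SC", "DEJ"):
        assert rep[cls]["ppv"] == rep[cls]["sensitivity"] == rep[cls]["f1"] == 1.0
        assert rep[cls]["auc"] == 1.0


def test_classification_report_hand_built_confusion():
    # 6 patches: true (0,0,1,1,2,2), predicted (0,1,1,1,2,0)
    labels = np.array([0, 0, 1, 1, 2, 2])
    pred = np.array([0, 1, 1, 1, 2, 0])
    probs = np.zeros((6, 4))
    probs[np.arange(6), pred] = 1.0
    rep = metrics.classification_report(labels, probs)
    # class 0: TP=1 FP=1 FN=1 -> ppv=0.5 sens=0.5 f1=0.5
    assert rep["non-boundary"]["ppv"] == pytest.approx(0.5)
    assert rep["non-boundary"]["sensitivity"] == pytest.approx(0.5)
    # class 1: TP=2 FP=1 FN=0 -> ppv=2/3 sens=1
    assert rep["SC"]["ppv"] == pytest.approx(2 / 3)
    assert rep["SC"]["sensitivity"] == 1.0
    # class 2: TP=1 FP=0 FN=1
    assert rep["DEJ"]["ppv"] == 1.0
    assert rep["DEJ"]["sensitivity"] == pytest.approx(0.5)
    assert rep["accuracy"] == pytest.approx(4 / 6)


def test_classification_report_random_probs_auc_half():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 3, 6000)
    probs = rng.random((6000, 4))
    probs /= probs.sum(axis=1, keepdims=True)
    rep = metrics.classification_report(labels, probs)
    for cls in ("non-boundary", "SC", "DEJ"):
        assert rep[cls]["auc"] == pytest.approx(0.5, abs=0.05)


def test_classification_report_absent_class_flagged():
    labels = np.array([0, 0, 1, 1])
    probs = np.tile([0.5, 0.3, 0.1, 0.1], (4, 1))
    rep = metrics.classification_report(labels, probs)
    assert rep["DEJ"]["undefined"] and np.isnan(rep["DEJ"]["auc"])
    assert not rep["SC"]["undefined"]


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 99_999), n=st.integers(2, 60))
def test_report_fractions_bounded_property(seed, n):
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, 200, n)
    man = rng.integers(0, 200, n)
    acc = metrics.position_accuracy(pred, man)
    mean, sd = metrics.position_error(pred, man)
    assert 0.0 <= acc <= 1.0 and mean >= 0.0 and sd >= 0.0


def test_eval_report_aggregation():
    sc = np.full(30, 50)
    dej = np.full(30, 90)
    pred_pairs = [(sc, dej), (sc + 1, dej + 4)]
    manual_pairs = [(sc, dej), (sc, dej)]
    rep = metrics.EvalReport.from_traces(pred_pairs, manual_pairs)
    assert rep.per_boundary["SC"]["position_accuracy"] == 1.0
    assert rep.per_boundary["DEJ"]["position_accuracy"] == 0.5
    assert rep.overall["mean_diff"] == pytest.approx((0 + 0 + 1 + 4) / 4)
    assert rep.et_accuracy == 0.5  # second image ET off by 3 px vs SD 0
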