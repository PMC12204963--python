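"""Cascade composition, conditional second step and order calibration."""

from itertools import permutations

import numpy as np
import pytest

from ctphase import (
    Examination,
    ExtractorConfig,
    PhaseNet,
    calibrate_order,
    compose_four_dim,
    predict_one_step,
    predict_two_step,
)
from ctphase.strategies import ExamPrediction, collapse_step1
from ctphase.volumes import PhaseVolume, STEP1_CLASSES


class TestComposeFourDim:
    def test_product_rule(self):
        out = compose_four_dim([0.8, 0.1, 0.1], [0.75, 0.25])
        np.testing.assert_allclose(out, [0.6, 0.2, 0.1, 0.1])
        assert out.sum() == pytest.approx(1.0)

    def test_absent_step2_zero_ap_mass(self):
        out = compose_four_dim([0.0, 0.4, 0.6], None)
        np.testing.assert_allclose(out, [0.0, 0.0, 0.4, 0.6])

    def test_degenerate_split(self):
        out = compose_four_dim([0.5, 0.3, 0.2], [1.0, 0.0])
        assert out[0] == pytest.approx(0.5) and out[1] == 0.0

    def test_renormalize_convention(self):
        out = compose_four_dim([0.2, 0.4, 0.4], None, ap_mass="renormalize")
        np.testing.assert_allclose(out, [0.0, 0.0, 0.5, 0.5])

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            compose_four_dim([0.5, 0.5, 0.5], None)
        with pytest.raises(ValueError):
            compose_four_dim([0.8, 0.1, 0.1], [0.9, 0.2])


class _StubNet:
    """Duck-typed stand-in for PhaseNet returning scripted probabilities."""

    def __init__(self, n_classes, rows):
        self.n_classes = n_classes
        self.rows = np.asarray(rows, dtype=float)
        self.calls = 0

    def predict(self, volumes):
        self.calls += 1
        return self.rows[: volumes.shape[0]]


def _dummy_exam(n_phases, labels=None):
    phases = [PhaseVolume(np.zeros((4, 4, 4)), (1, 1, 1), "e",
                          true_phase=(labels[i] if labels else None))
              for i in range(n_phases)]
    return Examination("e", phases, order_known=False)


class TestTwoStepCascade:
    def test_second_step_skipped_without_ap(self):
        model3 = _StubNet(3, [[0.1, 0.8, 0.1], [0.1, 0.2, 0.7]])
        model2 = _StubNet(2, [[0.5, 0.5]])
        pred = predict_two_step(_dummy_exam(2), model3, model2)
        assert model2.calls == 0
        assert pred.labels_raw == ["PVP", "DP"]

    def test_second_step_invoked_once_per_ap_phase(self):
        model3 = _StubNet(3, [[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        model2 = _StubNet(2, [[0.3, 0.7]])
        pred = predict_two_step(_dummy_exam(3), model3, model2)
        assert model2.calls == 1
        assert pred.labels_raw[0] == "LAP"  # 0.9 * 0.7 in the LAP slot

    def test_assembled_vectors_sum_to_one(self):
        model3 = _StubNet(3, [[0.9, 0.05, 0.05], [0.2, 0.5, 0.3]])
        model2 = _StubNet(2, [[0.6, 0.4]])
        pred = predict_two_step(_dummy_exam(2), model3, model2)
        np.testing.assert_allclose(pred.probs4.sum(axis=1), 1.0, atol=1e-9)

    def test_wrong_head_sizes_rejected(self):
        with pytest.raises(ValueError):
            predict_two_step(_dummy_exam(1), _StubNet(4, [[0.25] * 4]),
                             _StubNet(2, [[0.5, 0.5]]))


class TestOneStep:
    def test_argmax_and_step1_collapse(self):
        model4 = _StubNet(4, [[0.7, 0.1, 0.1, 0.1], [0.05, 0.05, 0.2, 0.7]])
        pred = predict_one_step(_dummy_exam(2), model4)
        assert pred.labels_raw == ["EAP", "DP"]
        np.testing.assert_allclose(pred.step1_probs[0], [0.8, 0.1, 0.1])

    def test_uniform_tie_breaks_to_first_class(self):
        model4 = _StubNet(4, [[0.25, 0.25, 0.25, 0.25]])
        pred = predict_one_step(_dummy_exam(1), model4)
        assert pred.labels_raw == ["EAP"]


def _prediction(step1_rows, probs4=None):
    step1 = np.asarray(step1_rows, dtype=float)
    if probs4 is None:
        probs4 = np.stack([[r[0], 0.0, r[1], r[2]] for r in step1])
    labels = [("EAP", "PVP", "DP")[int(np.argmax(r))] for r in step1]
    return ExamPrediction("e", probs4, step1, labels, "two_step",
                          true_labels=[None] * len(step1))


def brute_force_assignment(step1, order_known=False):
    best, best_p = None, -1.0
    for assign in permutations(range(3), step1.shape[0]):
        if order_known and list(assign) != sorted(assign):
            continue
        p = float(np.prod([step1[i, c] for i, c in enumerate(assign)]))
        if p > best_p:
            best, best_p = assign, p
    return best, best_p


class TestCalibrateOrder:
    def test_joint_probability_example(self):
        step1 = [[0.3, 0.6, 0.1], [0.1, 0.7, 0.2], [0.0, 0.3, 0.7]]
        pred = _prediction(step1)
        assert pred.labels_raw == ["PVP", "PVP", "DP"]  # conflicting argmax
        out = calibrate_order(pred)
        assert out.labels_calibrated == ["EAP", "PVP", "DP"]
        _, best_p = brute_force_assignment(np.asarray(step1))
        assert best_p == pytest.approx(0.3 * 0.7 * 0.7)

    def test_distinct_argmax_is_noop(self):
        pred = _prediction([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        out = calibrate_order(pred)
        assert out.labels_calibrated == out.labels_raw

    def test_matches_brute_force_on_random_predictions(self, rng):
        for _ in range(50):
            step1 = rng.dirichlet(np.ones(3), size=3)
            pred = _prediction(step1)
            out = calibrate_order(pred)
            assign, _ = brute_force_assignment(step1)
            expected = [STEP1_CLASSES[c] for c in assign]
            got = [{"EAP": "AP", "LAP": "AP"}.get(l, l) for l in out.labels_calibrated]
            assert got == expected

    def test_two_phase_exam_searches_ordered_pairs(self):
        pred = _prediction([[0.5, 0.4, 0.1], [0.45, 0.45, 0.1]])
        out = calibrate_order(pred)
        got = {(l if l not in ("EAP", "LAP") else "AP") for l in out.labels_calibrated}
        assert len(got) == 2  # distinct step-1 classes

    def test_order_known_excludes_inverted_assignments(self):
        # phase 0 slightly prefers PVP, phase 1 slightly prefers AP, but the
        # listed order is the acquisition order: AP must come first
        pred = _prediction([[0.45, 0.55, 0.0], [0.55, 0.45, 0.0]])
        out = calibrate_order(pred, order_known=True)
        s1 = [{"EAP": "AP", "LAP": "AP"}.get(l, l) for l in out.labels_calibrated]
        assert s1 == ["AP", "PVP"]

    def test_relative_order_follows_canonical_timing(self):
        pred = _prediction([[0.1, 0.8, 0.1], [0.8, 0.1, 0.1], [0.1, 0.1, 0.8]])
        out = calibrate_order(pred)
        assert out.labels_calibrated == ["PVP", "EAP", "DP"]
        assert out.relative_order == [1, 0, 2]

    def test_zero_probability_falls_back_with_warning(self):
        pred = _prediction([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="falling back"):
            out = calibrate_order(pred)
        assert out.labels_calibrated == out.labels_raw


def test_collapse_step1_sums_arterial_mass():
    np.testing.assert_allclose(collapse_step1(np.array([0.3, 0.3, 0.2, 0.2])),
                               [0.6, 0.2, 0.2])


def test_strategies_agree_in_support(net16, rng):
    """Both strategies emit comparable per-phase 4-vectors on the same exam."""
    vols = [rng.random((16, 16, 16)) for _ in range(2)]
    exam = Examination("s", [PhaseVolume(v, (1, 1, 1), "s") for v in vols], False)
    model4 = PhaseNet(ExtractorConfig.desk((16, 16, 16)), 4, seed=1)
    model2 = PhaseNet(ExtractorConfig.desk((16, 16, 16)), 2, seed=2)
    p1 = predict_one_step(exam, model4)
    p2 = predict_two_step(exam, net16, model2)
    assert p1.probs4.shape == p2.probs4.shape == (2, 4)
    np.testing.assert_allclose(p1.probs4.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(p2.probs4.sum(axis=1), 1.0, atol=1e-6)
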