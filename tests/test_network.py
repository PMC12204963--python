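"""Attention fusion, shared-parameter extraction and classification heads."""

import math

import numpy as np
import pytest

from ctphase import (
    Examination,
    ExtractorConfig,
    PhaseNet,
    attention_term,
    classify_head,
    extract_features,
    forward_exam,
    fuse_features,
)
from ctphase.volumes import PhaseVolume


# --- independent loop-based oracle ----------------------------------------

def naive_attention(A, B):
    """f_att(A, B) = A · softmax(−Aᵀ B), written with explicit loops."""
    N, C = A.shape
    G = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            for n in range(N):
                G[i, j] += A[n, i] * B[n, j]
    S = np.zeros_like(G)
    for i in range(C):
        row = [math.exp(-G[i, j]) for j in range(C)]
        tot = sum(row)
        for j in range(C):
            S[i, j] = row[j] / tot
    out = np.zeros_like(A)
    for n in range(N):
        for j in range(C):
            for i in range(C):
                out[n, j] += A[n, i] * S[i, j]
    return out


def naive_fuse(mats):
    return [m + sum(naive_attention(m, o) for k, o in enumerate(mats) if k != i)
            for i, m in enumerate(mats)]


class TestAttentionTerm:
    def test_singleton_softmax_is_identity(self):
        A = np.array([[3.7]])
        np.testing.assert_allclose(attention_term(A, A), A)

    def test_identity_features_hand_values(self):
        # G = I; softmax rows of -I are [e^-1, 1]/(e^-1 + 1) permutations
        A = np.eye(2)
        out = attention_term(A, A)
        lo = math.exp(-1) / (math.exp(-1) + 1)  # 0.26894
        hi = 1.0 / (math.exp(-1) + 1)           # 0.73106
        np.testing.assert_allclose(out, [[lo, hi], [hi, lo]], atol=1e-4)
        np.testing.assert_allclose(out, naive_attention(A, A), atol=1e-12)

    def test_matches_naive_oracle_on_random_tensors(self, rng):
        for _ in range(25):
            N, C = rng.integers(1, 9, size=2)
            A, B = rng.normal(size=(N, C)), rng.normal(size=(N, C))
            np.testing.assert_allclose(attention_term(A, B),
                                       naive_attention(A, B), atol=1e-6)

    def test_softmax_rows_sum_to_one(self, rng):
        A, B = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        S = np.exp(-(A.T @ B) - np.max(-(A.T @ B), axis=1, keepdims=True))
        S /= S.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_term(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_nonfinite_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            attention_term(bad, bad)


class TestFusion:
    def test_single_phase_identity(self, rng):
        F = rng.normal(size=(4, 3))
        out = fuse_features({"PVP": F})
        np.testing.assert_array_equal(out["PVP"], F)

    def test_two_and_three_phase_match_naive_oracle(self, rng):
        for P in (2, 3):
            mats = [rng.normal(size=(6, 4)) for _ in range(P)]
            keys = ["AP", "PVP", "DP"][:P]
            out = fuse_features(dict(zip(keys, mats)))
            expected = naive_fuse(mats)
            for k, e in zip(keys, expected):
                np.testing.assert_allclose(out[k], e, atol=1e-6)

    def test_inconsistent_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_features({"AP": rng.normal(size=(4, 3)),
                           "PVP": rng.normal(size=(5, 3))})


class TestExtractor:
    def test_shared_parameters_bitwise_equal_branches(self, net16, rng):
        vol = rng.random((16, 16, 16))
        f1 = extract_features(vol, net16)
        f2 = extract_features(vol.copy(), net16)
        np.testing.assert_array_equal(f1.matrix, f2.matrix)

    def test_feature_shape_matches_config(self, net16, rng):
        f = extract_features(rng.random((16, 16, 16)), net16)
        # 16 -> stem /2 -> stage0 /2 -> stage1 /2 = 2^3 positions, 16 channels
        assert f.matrix.shape == (8, 16)

    def test_zero_input_zero_features(self, net16):
        f = extract_features(np.zeros((16, 16, 16)), net16)
        np.testing.assert_array_equal(f.matrix, 0.0)

    def test_input_shape_mismatch_rejected(self, net16):
        with pytest.raises(ValueError):
            extract_features(np.zeros((8, 8, 8)), net16)


class TestClassifyHead:
    def test_zero_logits_uniform(self):
        p = classify_head(np.zeros(5), np.zeros((4, 5)), np.zeros(4))
        np.testing.assert_allclose(p, 0.25)

    def test_sums_to_one_random(self, rng):
        p = classify_head(rng.normal(size=7), rng.normal(size=(3, 7)),
                          rng.normal(size=3))
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_logit_shift_invariance(self, rng):
        feats = rng.normal(size=4)
        W, b = rng.normal(size=(3, 4)), rng.normal(size=3)
        np.testing.assert_allclose(classify_head(feats, W, b),
                                   classify_head(feats, W, b + 5.0), atol=1e-12)


def _exam_from(vols, labels=None):
    phases = [PhaseVolume(v, (1, 1, 1), "x", true_phase=(labels[i] if labels else None))
              for i, v in enumerate(vols)]
    return Examination("x", phases, order_known=False)


class TestForwardExam:
    def test_permutation_equivariance_all_orderings(self, net16, rng):
        vols = [rng.random((16, 16, 16)) for _ in range(3)]
        base = forward_exam(_exam_from(vols), net16)
        from itertools import permutations
        for perm in permutations(range(3)):
            out = forward_exam(_exam_from([vols[i] for i in perm]), net16)
            np.testing.assert_allclose(out, base[list(perm)], atol=1e-9)

    def test_duplicate_volumes_identical_outputs(self, net16, rng):
        v = rng.random((16, 16, 16))
        out = forward_exam(_exam_from([v, v.copy()]), net16)
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_probability_conservation(self, net16, rng):
        out = forward_exam(_exam_from([rng.random((16, 16, 16))]), net16)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_single_phase_equals_plain_forward(self, net16, rng):
        """With one phase the fusion sum is empty: F' = F exactly."""
        from ctphase.nn import Tensor
        v = rng.random((16, 16, 16))
        feats = net16._front(Tensor(v[None, None]))
        fused = net16._fuse(feats)
        np.testing.assert_array_equal(fused.data, feats.data)


def test_checkpoint_roundtrip(tmp_path, net16, rng):
    vol = rng.random((3, 16, 16, 16))
    before = net16.predict(vol)
    path = tmp_path / "ckpt.npz"
    net16.save(path)
    loaded = PhaseNet.load(path)
    np.testing.assert_array_equal(loaded.predict(vol), before)
    assert loaded.cfg == net16.cfg and loaded.n_classes == net16.n_classes


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ExtractorConfig(attention_stage=2)  # last stage is not interior
    with pytest.raises(ValueError):
        PhaseNet(ExtractorConfig.desk(), n_classes=5)
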