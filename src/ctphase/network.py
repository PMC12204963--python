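"""Shared-parameter 3D residual extractor with cross-phase attention fusion.

Every phase volume of an examination passes in parallel through the *same*
feature extractor (one parameter set serves all branches).  After the
mid-level stage the per-phase feature maps are mixed by cross-phase
attention:

    f_att(A, B) = A · softmax(−Aᵀ B)        (row-wise softmax)
    F′_p = F_p + Σ_{q ≠ p} f_att(F_p, F_q)

with A, B the (N positions × C channels) flattened maps.  The affinity
Aᵀ B is a channel Gram matrix; negating it before the softmax weights each
channel of A by how *dissimilar* it is to B's channels, accentuating
inter-phase differences.  The fused maps feed the remaining stages, a
global average pool and a softmax classification head (2, 3 or 4 classes).

The fusion is symmetric and the parameters shared, so the network is
permutation-equivariant in its phase inputs: order does not matter.  With
a single phase the fusion sum is empty and the network reduces to a plain
forward pass, which is how missing phases are supported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .volumes import Examination

__all__ = [
    "ExtractorConfig", "FeatureMap", "PhaseNet", "attention_term",
    "fuse_features", "extract_features", "classify_head", "forward_exam",
]


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture of the residual feature extractor.

    ``stages`` lists ``(channels, blocks, stride)`` per stage; fusion is
    applied to the output of stage ``attention_stage`` (0-based), i.e.
    "after Layer 2" in the default four-stage, 18-layer layout.
    """

    input_shape: tuple[int, int, int] = (32, 32, 32)
    stem_channels: int = 8
    stem_stride: int = 2
    stages: tuple[tuple[int, int, int], ...] = ((8, 1, 2), (16, 1, 2), (32, 1, 1))
    attention_stage: int = 1
    scale_affinity: bool = False  # divide the Gram matrix by sqrt(N)

    def __post_init__(self) -> None:
        if not 0 <= self.attention_stage < len(self.stages) - 1:
            raise ValueError("attention_stage must be an interior stage")
        if any(c <= 0 for c, _, _ in self.stages) or self.stem_channels <= 0:
            raise ValueError("channel counts must be positive")

    @classmethod
    def desk(cls, input_shape=(32, 32, 32)) -> "ExtractorConfig":
        """Miniature preset that trains on a single CPU."""
        return cls(input_shape=tuple(input_shape))

    @classmethod
    def paper_scale(cls) -> "ExtractorConfig":
        """Full 18-layer configuration on 192-cubed inputs."""
        return cls(
            input_shape=(192, 192, 192),
            stem_channels=64,
            stem_stride=2,
            stages=((64, 2, 1), (128, 2, 2), (256, 2, 2), (512, 2, 2)),
            attention_stage=1,
        )


@dataclass
class FeatureMap:
    """Flattened mid-level features: N spatial positions × C channels."""

    matrix: np.ndarray
    phase: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or min(self.matrix.shape) < 1:
            raise ValueError("feature map must be a non-empty 2D (N, C) matrix")


def _mat(x) -> np.ndarray:
    return x.matrix if isinstance(x, FeatureMap) else np.asarray(x, dtype=np.float64)


def _stable_softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def attention_term(A, B, scale_affinity: bool = False) -> np.ndarray:
    """One cross-phase attention term: A · softmax(−Aᵀ B).

    ``A`` and ``B`` are (N, C) feature matrices of the same shape.  The
    (C × C) affinity G = Aᵀ B is negated and softmax-normalised along its
    second axis (rows sum to 1); the result re-weights A's channels.
    """
    A, B = _mat(A), _mat(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite feature values")
    G = A.T @ B
    if scale_affinity:
        G = G / np.sqrt(A.shape[0])
    S = _stable_softmax(-G, axis=1)
    return A @ S


def fuse_features(features: dict) -> dict:
    """Additive cross-phase fusion: F′_p = F_p + Σ_{q≠p} f_att(F_p, F_q).

    With a single entry the sum is empty and the input is returned
    unchanged (identity fusion).
    """
    keys = list(features)
    if not 1 <= len(keys) <= 3:
        raise ValueError("fusion expects 1-3 phase feature maps")
    mats = {k: _mat(features[k]) for k in keys}
    shapes = {m.shape for m in mats.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent feature shapes: {shapes}")
    out = {}
    for p in keys:
        fused = mats[p].copy()
        for q in keys:
            if q != p:
                fused += attention_term(mats[p], mats[q])
        out[p] = (
            FeatureMap(fused, phase=features[p].phase)
            if isinstance(features[p], FeatureMap)
            else fused
        )
    return out


# ---------------------------------------------------------------------------
# network

def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class PhaseNet:
    """Residual extractor + cross-phase fusion + softmax head.

    One parameter set serves every phase branch; the class holds the flat
    parameter dict and the architecture config, and exposes exam-level
    forward passes both as a differentiable graph (training) and as plain
    numpy probabilities (inference).
    """

    def __init__(self, cfg: ExtractorConfig, n_classes: int, seed: int = 0):
        if n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")
        self.cfg = cfg
        self.n_classes = n_classes
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        self._build(rng)

    # parameter construction --------------------------------------------
    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    def _build(self, rng: np.random.Generator) -> None:
        k = 3
        cin = 1
        self._add("stem.w", _he(rng, (self.cfg.stem_channels, cin, k, k, k), cin * k**3))
        self._add("stem.b", np.zeros(self.cfg.stem_channels))
        cin = self.cfg.stem_channels
        for si, (cout, blocks, stride) in enumerate(self.cfg.stages):
            for bi in range(blocks):
                s = stride if bi == 0 else 1
                pre = f"s{si}.b{bi}"
                self._add(f"{pre}.w1", _he(rng, (cout, cin, k, k, k), cin * k**3))
                self._add(f"{pre}.b1", np.zeros(cout))
                self._add(f"{pre}.w2", _he(rng, (cout, cout, k, k, k), cout * k**3))
                self._add(f"{pre}.b2", np.zeros(cout))
                if s != 1 or cin != cout:
                    self._add(f"{pre}.wskip", _he(rng, (cout, cin, 1, 1, 1), cin))
                cin = cout
        self._add("head.w", _he(rng, (self.n_classes, cin), cin))
        self._add("head.b", np.zeros(self.n_classes))

    # forward pieces ------------------------------------------------------
    def _block(self, x: Tensor, pre: str, stride: int) -> Tensor:
        p = self.params
        h = nn.relu(nn.conv3d(x, p[f"{pre}.w1"], p[f"{pre}.b1"], stride=stride))
        h = nn.conv3d(h, p[f"{pre}.w2"], p[f"{pre}.b2"], stride=1)
        if f"{pre}.wskip" in p:
            skip = nn.conv3d(x, p[f"{pre}.wskip"], None, stride=stride, pad=0)
        else:
            skip = x
        return nn.relu(h + skip)

    def _stages(self, x: Tensor, lo: int, hi: int) -> Tensor:
        for si in range(lo, hi):
            cout, blocks, stride = self.cfg.stages[si]
            for bi in range(blocks):
                x = self._block(x, f"s{si}.b{bi}", stride if bi == 0 else 1)
        return x

    def _front(self, x: Tensor) -> Tensor:
        """Stem + stages up to and including the attention stage."""
        p = self.params
        h = nn.relu(nn.conv3d(x, p["stem.w"], p["stem.b"], stride=self.cfg.stem_stride))
        return self._stages(h, 0, self.cfg.attention_stage + 1)

    def _fuse(self, feats: Tensor) -> Tensor:
        """Cross-phase attention over the batch (=phase) axis, in-graph."""
        P, C = feats.shape[0], feats.shape[1]
        if P == 1:
            return feats
        spatial = feats.shape[2:]
        N = int(np.prod(spatial))
        flat = [
            nn.transpose(nn.reshape(nn.index0(feats, i), (C, N)), (1, 0))
            for i in range(P)
        ]  # each (N, C)
        fused = []
        for i in range(P):
            acc = flat[i]
            for j in range(P):
                if j == i:
                    continue
                G = nn.matmul(nn.transpose(flat[i], (1, 0)), flat[j])
                if self.cfg.scale_affinity:
                    G = G * Tensor(1.0 / np.sqrt(N))
                S = nn.softmax(G * Tensor(-1.0), axis=1)
                acc = acc + nn.matmul(flat[i], S)
            fused.append(nn.reshape(nn.transpose(acc, (1, 0)), (1, C) + spatial))
        return nn.concat0(fused)

    def _back(self, feats: Tensor) -> Tensor:
        h = self._stages(feats, self.cfg.attention_stage + 1, len(self.cfg.stages))
        pooled = nn.mean_axes(h, (2, 3, 4))  # (P, C)
        logits = nn.matmul(pooled, nn.transpose(self.params["head.w"], (1, 0)))
        logits = logits + self.params["head.b"]
        return logits

    def forward_graph(self, volumes: np.ndarray) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass of one exam.

        ``volumes`` is (P, D, H, W) normalised data; returns (logits,
        probabilities), each (P, n_classes).
        """
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim != 4 or volumes.shape[0] < 1:
            raise ValueError("expected (P, D, H, W) with P >= 1")
        if tuple(volumes.shape[1:]) != tuple(self.cfg.input_shape):
            raise ValueError(
                f"input shape {volumes.shape[1:]} != configured {self.cfg.input_shape}"
            )
        x = Tensor(volumes[:, None])  # (P, 1, D, H, W)
        feats = self._fuse(self._front(x))
        logits = self._back(feats)
        return logits, nn.softmax(logits, axis=1)

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        """Per-phase class probabilities, (P, n_classes) numpy array.

        Runs without building the backward graph.
        """
        flags = {k: t.requires_grad for k, t in self.params.items()}
        try:
            for t in self.params.values():
                t.requires_grad = False
            return self.forward_graph(volumes)[1].data
        finally:
            for k, t in self.params.items():
                t.requires_grad = flags[k]

    # checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        meta = {"cfg": asdict(self.cfg), "n_classes": self.n_classes}
        arrays = {k.replace(".", "__"): t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "PhaseNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_d = meta["cfg"]
            cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
            cfg_d["stages"] = tuple(tuple(s) for s in cfg_d["stages"])
            net = cls(ExtractorConfig(**cfg_d), meta["n_classes"])
            for k in net.params:
                net.params[k].data = z[k.replace(".", "__")].astype(np.float64)
        return net


# ---------------------------------------------------------------------------
# module-level operations

def extract_features(volume: np.ndarray, net: PhaseNet,
                     phase: str | None = None) -> FeatureMap:
    """Run one volume through the shared extractor up to the fusion point.

    Returns the flattened (N, C) mid-level feature map.  Because the
    parameters are shared, identical volumes always yield identical maps,
    whichever "branch" they notionally pass through.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if tuple(volume.shape) != tuple(net.cfg.input_shape):
        raise ValueError(
            f"volume shape {volume.shape} != configured {net.cfg.input_shape}"
        )
    x = Tensor(volume[None, None])
    f = net._front(x).data[0]  # (C, d, h, w)
    C = f.shape[0]
    return FeatureMap(f.reshape(C, -1).T, phase=phase)


def classify_head(tail_features: np.ndarray, weight: np.ndarray,
                  bias: np.ndarray) -> np.ndarray:
    """Fully connected layer + softmax over pooled tail features."""
    logits = np.asarray(tail_features, float) @ np.asarray(weight, float).T + bias
    return _stable_softmax(np.atleast_2d(logits), axis=-1)[0] if logits.ndim == 1 \
        else _stable_softmax(logits, axis=-1)


def forward_exam(exam: Examination, net: PhaseNet) -> np.ndarray:
    """Per-phase probabilities for one preprocessed exam, (P, n_classes).

    Permutation-equivariant: reordering the exam's phases permutes the
    rows identically.
    """
    if not exam.phases:
        raise ValueError("empty examination")
    vols = np.stack([p.values for p in exam.phases])
    return net.predict(vols)
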