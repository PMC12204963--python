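"""HU windowing, cubic resampling, and training-time perturbations.

The model consumes volumes normalised to [0, 1] with an abdominal window
(level 50 HU, width 600 HU by default) and resampled to a cubic grid
(192³ at full scale; tests and desk presets use 32³/48³).  Training-time
perturbations mirror the acquisition variability the classifier must
tolerate: random flips (applied identically to all phases of an exam, so
co-registration is preserved), missing-phase simulation, and random phase
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import Examination, PhaseVolume


@dataclass(frozen=True)
class WindowConfig:
    """Linear display window: [WL - WW/2, WL + WW/2] maps onto [0, 1]."""

    window_level: float = 50.0
    window_width: float = 600.0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window width must be positive")


def window_normalize(values: np.ndarray | PhaseVolume,
                     cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    """Map HU onto [0, 1] through the window, clamping outside it.

    Monotone non-decreasing in HU; the window centre maps to 0.5.
    """
    arr = values.values if isinstance(values, PhaseVolume) else np.asarray(values, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite HU values")
    lo = cfg.window_level - cfg.window_width / 2.0
    out = (arr - lo) / cfg.window_width
    return np.clip(out, 0.0, 1.0)


def resample_cubic(values: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resampling onto ``target_shape``.

    The output range stays within [min, max] of the input (order-1 spline
    interpolation does not overshoot).
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    if any(n < 8 for n in target_shape):
        raise ValueError("target shape must be at least 8 per axis")
    if any(n < 2 for n in arr.shape):
        raise ValueError(
            f"cannot resample a degenerate (single-slice) axis: shape {arr.shape}"
        )
    if tuple(arr.shape) == tuple(target_shape):
        return arr.copy()
    zoom = [t / s for t, s in zip(target_shape, arr.shape)]
    out = ndimage.zoom(arr, zoom, order=1, mode="nearest", grid_mode=True)
    assert out.shape == tuple(target_shape)
    return out


def augment_flip(values: np.ndarray, rng_seed: int,
                 flip_prob: float = 0.5) -> np.ndarray:
    """Independently flip each spatial axis with probability ``flip_prob``."""
    axes = flip_axes(rng_seed, flip_prob)
    return apply_flip(values, axes)


def flip_axes(rng_seed: int, flip_prob: float = 0.5) -> tuple[int, ...]:
    """Draw the axes to flip; exposed so one draw can serve a whole exam."""
    rng = np.random.default_rng(rng_seed)
    return tuple(ax for ax in range(3) if rng.random() < flip_prob)


def apply_flip(values: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    arr = np.asarray(values)
    return np.flip(arr, axis=axes).copy() if axes else arr.copy()


def drop_phases(exam: Examination, rng_seed: int, keep_min: int = 1) -> Examination:
    """Keep a random non-empty subset of the exam's phases (labels travel)."""
    n = len(exam.phases)
    if keep_min > n:
        raise ValueError(f"keep_min={keep_min} exceeds phase count {n}")
    rng = np.random.default_rng(rng_seed)
    k = int(rng.integers(keep_min, n + 1))
    keep = sorted(rng.choice(n, size=k, replace=False).tolist())
    return Examination(
        exam_id=exam.exam_id,
        phases=[exam.phases[i] for i in keep],
        order_known=exam.order_known,
    )


def shuffle_phase_order(exam: Examination, rng_seed: int) -> Examination:
    """Permute the phases uniformly at random; order becomes unknown."""
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(exam.phases)).tolist()
    return Examination(
        exam_id=exam.exam_id,
        phases=[exam.phases[i] for i in perm],
        order_known=False,
    )


def preprocess_exam(exam: Examination, target_shape: tuple[int, int, int],
                    cfg: WindowConfig = WindowConfig()) -> Examination:
    """Window-normalise and resample every phase of an exam."""
    phases = []
    for p in exam.phases:
        vals = resample_cubic(window_normalize(p.values, cfg), target_shape)
        phases.append(replace(p, values=vals))
    return Examination(exam.exam_id, phases, exam.order_known)
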