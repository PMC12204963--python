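"""Core carriers: a single contrast-phase CT volume and an examination.

All image data is held as plain numpy arrays in Hounsfield units (HU);
spacing is millimetres per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical phase order by acquisition timing (early arterial, late
#: arterial, portal venous, delayed).
PHASES = ("EAP", "LAP", "PVP", "DP")

#: Step-1 granularity: the two arterial sub-phases collapse to "AP".
STEP1_CLASSES = ("AP", "PVP", "DP")

#: Map a 4-class label to its step-1 class.
STEP1_OF = {"EAP": "AP", "LAP": "AP", "PVP": "PVP", "DP": "DP"}

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class PhaseVolume:
    """A 3D scalar grid in HU with spacing and optional ground truth."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    exam_id: str
    true_phase: str | None = None
    acquisition_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite HU values")
        if self.true_phase is not None and self.true_phase not in PHASES:
            raise ValueError(f"unknown phase label {self.true_phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "PhaseVolume":
        return replace(self, values=self.values.copy())


@dataclass
class Examination:
    """1-3 co-registered phase volumes from one (simulated) patient.

    An examination holds at most one acquisition per step-1 class: the two
    arterial sub-phases cannot both occur in one exam.
    """

    exam_id: str
    phases: list[PhaseVolume] = field(default_factory=list)
    order_known: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.phases) <= 3:
            raise ValueError("an examination holds 1-3 phase volumes")
        labels = [p.true_phase for p in self.phases if p.true_phase is not None]
        step1 = [STEP1_OF[lbl] for lbl in labels]
        if len(step1) != len(set(step1)):
            raise ValueError(
                "at most one phase per step-1 class {AP, PVP, DP} per exam"
            )

    @property
    def true_labels(self) -> list[str | None]:
        return [p.true_phase for p in self.phases]

    def copy(self) -> "Examination":
        return Examination(
            exam_id=self.exam_id,
            phases=[p.copy() for p in self.phases],
            order_known=self.order_known,
        )
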