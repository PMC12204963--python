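"""One-step and two-step (cascade) phase classification + order calibration.

*One-step* classifies every phase directly into the four classes.  The
*two-step cascade* first classifies phases as AP / PVP / DP; a 2-class
EAP-vs-LAP model is activated **only** for phases whose first-step argmax
is AP (a conditional check guards the second step).  Both strategies
produce a 4-vector per phase so they are directly comparable.

``calibrate_order`` applies prior knowledge about examinations — one exam
holds at most one acquisition per step-1 class, acquired in the canonical
temporal order EAP/LAP < PVP < DP — by brute-force search over all
assignments of distinct step-1 classes to phases, maximising the joint
predicted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .network import PhaseNet, forward_exam
from .volumes import Examination, PHASES, STEP1_CLASSES

_CANON = {p: i for i, p in enumerate(PHASES)}


@dataclass
class ExamPrediction:
    """Per-phase probabilities and labels for one examination."""

    exam_id: str
    probs4: np.ndarray                 # (P, 4) over (EAP, LAP, PVP, DP)
    step1_probs: np.ndarray            # (P, 3) over (AP, PVP, DP)
    labels_raw: list[str]
    strategy: str                      # "one_step" | "two_step"
    labels_calibrated: list[str] | None = None
    relative_order: list[int] | None = None
    true_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs4 = np.asarray(self.probs4, dtype=np.float64)
        self.step1_probs = np.asarray(self.step1_probs, dtype=np.float64)
        if not np.allclose(self.probs4.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("4-class probability vectors must sum to 1")

    @property
    def labels(self) -> list[str]:
        """Calibrated labels when available, else raw argmax labels."""
        return self.labels_calibrated or self.labels_raw


def _argmax_label(vec: np.ndarray, classes: tuple[str, ...]) -> str:
    # np.argmax returns the first maximum: ties break to the earliest
    # class in canonical order by construction of `classes`.
    return classes[int(np.argmax(vec))]


def collapse_step1(probs4: np.ndarray) -> np.ndarray:
    """Collapse 4-class probabilities to step-1 granularity (AP, PVP, DP)."""
    p = np.asarray(probs4, dtype=np.float64)
    return np.stack([p[..., 0] + p[..., 1], p[..., 2], p[..., 3]], axis=-1)


def predict_one_step(exam: Examination, model4: PhaseNet) -> ExamPrediction:
    """Strategy A: direct 4-class prediction for every phase."""
    if model4.n_classes != 4:
        raise ValueError("one-step strategy requires a 4-class model")
    probs4 = forward_exam(exam, model4)
    labels = [_argmax_label(v, PHASES) for v in probs4]
    return ExamPrediction(
        exam_id=exam.exam_id,
        probs4=probs4,
        step1_probs=collapse_step1(probs4),
        labels_raw=labels,
        strategy="one_step",
        true_labels=list(exam.true_labels),
    )


def compose_four_dim(step1: np.ndarray, step2: np.ndarray | None,
                     ap_mass: str = "eap_slot") -> np.ndarray:
    """Assemble a 4-vector from cascade outputs by the product rule.

    ``step1`` is (AP, PVP, DP); ``step2`` the (EAP, LAP) split of the AP
    mass.  When the second step was not run (phase not called AP), the
    residual AP mass is kept with split (1, 0) — reported in the EAP slot
    purely to keep a well-formed unit-sum vector (``ap_mass='eap_slot'``),
    or renormalised away (``ap_mass='renormalize'``).
    """
    s1 = np.asarray(step1, dtype=np.float64)
    if s1.shape != (3,) or abs(s1.sum() - 1.0) > 1e-6:
        raise ValueError("step-1 vector must be a unit-sum 3-vector")
    if step2 is not None:
        s2 = np.asarray(step2, dtype=np.float64)
        if s2.shape != (2,) or abs(s2.sum() - 1.0) > 1e-6:
            raise ValueError("step-2 vector must be a unit-sum 2-vector")
    elif ap_mass == "eap_slot":
        s2 = np.array([1.0, 0.0])
    elif ap_mass == "renormalize":
        rest = s1[1] + s1[2]
        if rest <= 0:
            raise ValueError("cannot renormalise: no non-AP mass")
        return np.array([0.0, 0.0, s1[1], s1[2]]) / rest
    else:
        raise ValueError(f"unknown ap_mass convention {ap_mass!r}")
    return np.array([s1[0] * s2[0], s1[0] * s2[1], s1[1], s1[2]])


def predict_two_step(exam: Examination, model3: PhaseNet, model2: PhaseNet,
                     ap_mass: str = "eap_slot") -> ExamPrediction:
    """Strategy B: AP/PVP/DP first, then EAP-vs-LAP only for argmax-AP phases."""
    if model3.n_classes != 3 or model2.n_classes != 2:
        raise ValueError("two-step strategy requires a 3-class and a 2-class model")
    step1 = forward_exam(exam, model3)            # (P, 3) over (AP, PVP, DP)
    step1_labels = [_argmax_label(v, STEP1_CLASSES) for v in step1]

    probs4 = []
    for i, lbl in enumerate(step1_labels):
        step2 = None
        if lbl == "AP":  # conditional check: second step only on AP phases
            sub = Examination(exam.exam_id, [exam.phases[i]], exam.order_known)
            step2 = forward_exam(sub, model2)[0]  # (EAP, LAP)
        probs4.append(compose_four_dim(step1[i], step2, ap_mass=ap_mass))
    probs4 = np.stack(probs4)
    labels = [_argmax_label(v, PHASES) for v in probs4]
    return ExamPrediction(
        exam_id=exam.exam_id,
        probs4=probs4,
        step1_probs=step1,
        labels_raw=labels,
        strategy="two_step",
        true_labels=list(exam.true_labels),
    )


def _refine_ap(probs4_row: np.ndarray) -> str:
    return "EAP" if probs4_row[0] >= probs4_row[1] else "LAP"


def calibrate_order(prediction: ExamPrediction,
                    order_known: bool = False) -> ExamPrediction:
    """Relabel an exam's phases with the one-acquisition-per-class prior.

    Searches every assignment of *distinct* step-1 classes to the exam's
    phases (at most 3! = 6) and keeps the one with the largest product of
    predicted step-1 probabilities.  With ``order_known`` the phases are
    taken as listed in acquisition order and assignments violating
    AP < PVP < DP are excluded.  Phases assigned AP keep their EAP/LAP
    refinement from the 4-vector.  The relative order is the rank of each
    phase under canonical timing EAP < LAP < PVP < DP.
    """
    P = prediction.step1_probs.shape[0]
    s1 = prediction.step1_probs

    best, best_prob = None, -1.0
    for assign in permutations(range(3), P):
        if order_known and list(assign) != sorted(assign):
            continue
        prob = float(np.prod([s1[i, c] for i, c in enumerate(assign)]))
        if prob > best_prob:
            best, best_prob = assign, prob

    if best is None or best_prob <= 0.0:
        warnings.warn(
            "no feasible distinct-class assignment with nonzero probability; "
            "falling back to unconstrained argmax",
            stacklevel=2,
        )
        labels = list(prediction.labels_raw)
    else:
        labels = []
        for i, c in enumerate(best):
            cls = STEP1_CLASSES[c]
            labels.append(_refine_ap(prediction.probs4[i]) if cls == "AP" else cls)

    order = list(np.argsort(np.argsort([_CANON[lbl] for lbl in labels])))
    prediction.labels_calibrated = labels
    prediction.relative_order = [int(r) for r in order]
    return prediction
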