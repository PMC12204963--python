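"""Synthetic multi-phase abdominal CT phantoms with a rule-based labeler.

The phantom is deliberately simple geometry — an ellipsoidal liver carrying
tubular portal and hepatic veins, plus an artery (aorta / hepatic artery
blood pool) running through the volume.  What matters is not anatomical
realism but that the four contrast-phase appearances are separable under
the radiological annotation criteria:

* **EAP** — only strong enhancement of the hepatic artery; portal vein and
  hepatic vein unenhanced.
* **LAP** — artery still strong, moderate enhancement of the portal vein
  and liver parenchyma, hepatic vein unenhanced.
* **PVP** — strong enhancement of portal vein, hepatic vein and parenchyma.
* **DP** — vessels and parenchyma enhanced but less than in the PVP.

Each phase volume is built as ``unenhanced baseline + per-structure HU
deltas + Gaussian noise`` on a fixed geometry, so all phases of one exam
are co-registered by construction.  ``rule_label`` applies the annotation
ladder to measured enhancement deltas and serves as the labeling oracle
for generated data.  ``make_edge_case`` produces exams that sit near the
decision boundaries (slight portal enhancement in the arterial phase;
nearly flat PVP/DP contrast), mirroring the enhancement patterns of
clinically misidentified examinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import HU_MAX, HU_MIN, Examination, PhaseVolume

STRUCTURES = ("artery", "portal_vein", "hepatic_vein", "parenchyma")
PHANTOM_PHASES = ("unenhanced", "EAP", "LAP", "PVP", "DP")

#: Unenhanced baseline HU per tissue class (implementer-chosen defaults;
#: soft-tissue range, blood pool slightly hypodense to parenchyma).
BASELINE_HU = {
    "parenchyma": 55.0,
    "artery": 45.0,
    "portal_vein": 45.0,
    "hepatic_vein": 45.0,
    "background": 30.0,
}


@dataclass
class StructureMask:
    """A named boolean mask aligned to the phantom grid."""

    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in STRUCTURES + ("background",):
            raise ValueError(f"unknown structure {self.name!r}")
        self.voxels = np.asarray(self.voxels, dtype=bool)


@dataclass
class PhantomSpec:
    """Geometry and grid parameters of the phantom."""

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    liver_axes_frac: tuple[float, float, float] = (0.36, 0.30, 0.34)
    liver_center_frac: tuple[float, float, float] = (0.50, 0.46, 0.50)
    vessel_radius_frac: float = 0.055
    center_jitter_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if any(c + a >= 1.0 for c, a in zip(self.liver_center_frac, self.liver_axes_frac)):
            raise ValueError("liver geometry does not fit in the grid")


def _default_deltas() -> dict[str, dict[str, float]]:
    # Mean enhancement (HU over baseline) per phase and structure.  Chosen
    # to satisfy the annotation ladder with wide margins: artery peaks in
    # the arterial phases, portal/hepatic veins and parenchyma peak in the
    # PVP and wash out in the DP.
    return {
        "unenhanced": {s: 0.0 for s in STRUCTURES},
        "EAP": {"artery": 250.0, "portal_vein": 5.0, "hepatic_vein": 0.0, "parenchyma": 2.0},
        "LAP": {"artery": 220.0, "portal_vein": 45.0, "hepatic_vein": 5.0, "parenchyma": 25.0},
        "PVP": {"artery": 90.0, "portal_vein": 110.0, "hepatic_vein": 95.0, "parenchyma": 55.0},
        "DP": {"artery": 60.0, "portal_vein": 70.0, "hepatic_vein": 60.0, "parenchyma": 35.0},
    }


#: Nominal post-injection acquisition windows in seconds.
DEFAULT_TIMING = {
    "unenhanced": (0.0, 0.0),
    "EAP": (25.0, 32.0),
    "LAP": (33.0, 40.0),
    "PVP": (60.0, 75.0),
    "DP": (140.0, 155.0),
}


@dataclass
class EnhancementProfile:
    """Per-phase, per-structure enhancement deltas plus noise levels.

    ``deltas[phase][structure]`` is the mean HU added over the unenhanced
    baseline; ``jitter_sd[phase][structure]`` the SD of a per-exam random
    perturbation of that mean; ``noise_sd`` the per-voxel Gaussian noise.
    """

    deltas: dict[str, dict[str, float]] = field(default_factory=_default_deltas)
    jitter_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: {s: 3.0 for s in STRUCTURES} for p in PHANTOM_PHASES}
    )
    noise_sd: float = 5.0
    timing_s: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_TIMING))

    def __post_init__(self) -> None:
        d = self.deltas
        for s in ("portal_vein", "hepatic_vein", "parenchyma"):
            if not d["PVP"][s] > d["DP"][s]:
                raise ValueError(f"PVP delta for {s} must exceed the DP delta")
        if not d["EAP"]["portal_vein"] < d["LAP"]["portal_vein"]:
            raise ValueError("EAP portal-vein delta must be below the LAP delta")
        art = {p: d[p]["artery"] for p in ("EAP", "LAP", "PVP", "DP")}
        if max(art["PVP"], art["DP"]) >= min(art["EAP"], art["LAP"]):
            raise ValueError("artery delta must peak in the arterial phases")

    def with_delta(self, phase: str, structure: str, value: float,
                   jitter: float | None = None) -> "EnhancementProfile":
        """Return a copy with one mean delta (and optionally its jitter) replaced."""
        deltas = {p: dict(v) for p, v in self.deltas.items()}
        jit = {p: dict(v) for p, v in self.jitter_sd.items()}
        deltas[phase][structure] = value
        if jitter is not None:
            jit[phase][structure] = jitter
        return replace(self, deltas=deltas, jitter_sd=jit)


@dataclass
class LabelThresholds:
    """HU cut-offs operationalising the qualitative annotation criteria.

    The criteria are qualitative ("strong", "moderate"); these numeric
    stand-ins are config, not ground truth, and are overridable.  For the
    PVP/DP distinction a same-exam PVP reference (``pvp_reference``) takes
    precedence over the absolute cut-offs when available.
    """

    artery_strong: float = 150.0
    portal_moderate: float = 25.0
    portal_strong: float = 80.0
    hepatic_vein_unenhanced: float = 20.0
    hepatic_vein_strong: float = 80.0
    parenchyma_strong: float = 40.0
    pvp_reference: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# geometry

def _combine_seed(spec_seed: int, rng_seed: int) -> int:
    return int((spec_seed * 1_000_003 + rng_seed) % (2**31 - 1))


def build_masks(spec: PhantomSpec, rng_seed: int = 0) -> dict[str, StructureMask]:
    """Construct mutually exclusive structure masks for one phantom.

    Geometry jitter (liver centre shift) is drawn from the combined
    spec/exam seed so that every phase of one exam — and any later
    re-measurement with the same seeds — sees identical masks.
    """
    rng = np.random.default_rng([_combine_seed(spec.seed, rng_seed), 0])
    n = np.asarray(spec.shape, dtype=float)
    zz, yy, xx = np.indices(spec.shape).astype(float)

    jit = rng.normal(0.0, spec.center_jitter_frac, size=3)
    center = (np.asarray(spec.liver_center_frac) + jit) * n
    axes = np.asarray(spec.liver_axes_frac) * n
    liver = (
        ((zz - center[0]) / axes[0]) ** 2
        + ((yy - center[1]) / axes[1]) ** 2
        + ((xx - center[2]) / axes[2]) ** 2
    ) <= 1.0

    r = max(spec.vessel_radius_frac * float(n.min()), 1.2)

    # artery: blood-pool column through the volume, posterior to the liver
    ay, ax = 0.80 * n[1], 0.50 * n[2]
    artery = ((yy - ay) ** 2 + (xx - ax) ** 2) <= r**2

    # portal vein: tube along x inside the liver
    pz, py = center[0] - 0.12 * n[0], center[1]
    portal = (((zz - pz) ** 2 + (yy - py) ** 2) <= r**2) & liver

    # hepatic vein: tube along x in a different slab of the liver
    hz, hy = center[0] + 0.16 * n[0], center[1] + 0.05 * n[1]
    hepatic = (((zz - hz) ** 2 + (yy - hy) ** 2) <= r**2) & liver

    # enforce exclusivity by priority: artery > portal > hepatic > parenchyma
    portal &= ~artery
    hepatic &= ~(artery | portal)
    parenchyma = liver & ~(artery | portal | hepatic)

    masks = {
        "artery": StructureMask("artery", artery),
        "portal_vein": StructureMask("portal_vein", portal),
        "hepatic_vein": StructureMask("hepatic_vein", hepatic),
        "parenchyma": StructureMask("parenchyma", parenchyma),
        "background": StructureMask(
            "background", ~(artery | portal | hepatic | parenchyma)
        ),
    }
    for name in STRUCTURES:
        if not masks[name].voxels.any():
            raise ValueError(f"degenerate geometry: empty mask for {name}")
    return masks


def baseline_volume(spec: PhantomSpec, masks: dict[str, StructureMask],
                    exam_id: str = "baseline") -> PhaseVolume:
    """Noise-free unenhanced volume for the given geometry."""
    vals = np.full(spec.shape, BASELINE_HU["background"], dtype=np.float64)
    for name in STRUCTURES:
        vals[masks[name].voxels] = BASELINE_HU[name]
    return PhaseVolume(vals, spec.spacing, exam_id=exam_id, true_phase=None)


# ---------------------------------------------------------------------------
# exam generation

def make_phantom_exam(
    spec: PhantomSpec,
    profile: EnhancementProfile,
    phase_labels: set[str] | list[str],
    rng_seed: int,
    exam_id: str | None = None,
) -> Examination:
    """Generate one co-registered multi-phase examination.

    Phases appear in canonical acquisition order (EAP/LAP < PVP < DP) with
    ``acquisition_index`` set accordingly.  Randomness (geometry jitter,
    per-exam delta jitter, voxel noise) is fully determined by
    ``(spec.seed, rng_seed)``; each phase draws from its own child stream
    so adding or removing phases does not change the others.
    """
    labels = sorted(set(phase_labels), key=("EAP", "LAP", "PVP", "DP").index)
    if not labels:
        raise ValueError("phase_labels must be non-empty")
    if any(lbl not in ("EAP", "LAP", "PVP", "DP") for lbl in labels):
        raise ValueError(f"unknown phase label in {phase_labels!r}")
    if "EAP" in labels and "LAP" in labels:
        raise ValueError("an exam has a single arterial acquisition: EAP or LAP, not both")
    if len(labels) > 3:
        raise ValueError("an examination holds at most 3 phases")

    base_seed = _combine_seed(spec.seed, rng_seed)
    if exam_id is None:
        exam_id = f"phantom-{rng_seed}"
    masks = build_masks(spec, rng_seed)
    base = baseline_volume(spec, masks).values

    phases = []
    for idx, phase in enumerate(labels):
        # child stream per phase: (base_seed, 1 + canonical phase index)
        rng = np.random.default_rng([base_seed, 1 + ("EAP", "LAP", "PVP", "DP").index(phase)])
        vals = base.copy()
        for s in STRUCTURES:
            delta = profile.deltas[phase][s] + rng.normal(0.0, profile.jitter_sd[phase][s])
            vals[masks[s].voxels] += delta
        vals += rng.normal(0.0, profile.noise_sd, size=spec.shape)
        np.clip(vals, HU_MIN, HU_MAX, out=vals)
        phases.append(
            PhaseVolume(vals, spec.spacing, exam_id=exam_id,
                        true_phase=phase, acquisition_index=idx)
        )
    return Examination(exam_id=exam_id, phases=phases, order_known=True)


# ---------------------------------------------------------------------------
# measurement + rule-based labeling

def measure_enhancement(
    volume: PhaseVolume,
    baseline: PhaseVolume,
    masks: dict[str, StructureMask],
) -> dict[str, float]:
    """Mean HU enhancement over baseline inside each structure mask."""
    if volume.shape != baseline.shape:
        raise ValueError(
            f"volume shape {volume.shape} != baseline shape {baseline.shape}"
        )
    out: dict[str, float] = {}
    for name in STRUCTURES:
        m = masks[name].voxels
        if not m.any():
            raise ValueError(f"empty mask for {name}")
        out[name] = float(volume.values[m].mean() - baseline.values[m].mean())
    return out


def rule_label(deltas: dict[str, float], thresholds: LabelThresholds | None = None) -> str:
    """Apply the annotation decision ladder to measured enhancement deltas.

    Ladder: strong artery with unenhanced hepatic vein → arterial phase,
    split EAP/LAP on the portal vein reaching the moderate band; otherwise
    PVP if portal vein, hepatic vein and parenchyma are all strongly
    enhanced (or match a same-exam PVP reference), else DP.
    """
    t = thresholds or LabelThresholds()
    missing = [s for s in STRUCTURES if s not in deltas]
    if missing:
        raise ValueError(f"missing structure deltas: {missing}")
    art, por = deltas["artery"], deltas["portal_vein"]
    hep, par = deltas["hepatic_vein"], deltas["parenchyma"]

    if art >= t.artery_strong and hep < t.hepatic_vein_unenhanced:
        return "EAP" if por < t.portal_moderate else "LAP"

    if t.pvp_reference is not None:
        ref = t.pvp_reference
        washed_out = (
            por < ref["portal_vein"]
            and hep < ref["hepatic_vein"]
            and par < ref["parenchyma"]
        )
        if washed_out:
            return "DP"
        return "PVP"

    if (
        por >= t.portal_strong
        and hep >= t.hepatic_vein_strong
        and par >= t.parenchyma_strong
    ):
        return "PVP"
    return "DP"


# ---------------------------------------------------------------------------
# edge cases near the decision boundaries

EDGE_CASE_KINDS = ("eap_portal_flash", "lap_low_portal", "pvp_dp_flat")


def hard_arterial_profile() -> EnhancementProfile:
    """Profile whose EAP and LAP differ mainly in portal-vein enhancement.

    The two arterial appearances are made identical in every structure
    except the portal vein, whose deltas are pulled toward the moderate
    cut-off (EAP ~12 HU, LAP ~30 HU).  The arterial sub-phases are then
    genuinely hard to separate — the regime where the two-step cascade is
    expected to pay off.
    """
    p = EnhancementProfile()
    p = p.with_delta("EAP", "portal_vein", 12.0, jitter=2.0)
    p = p.with_delta("LAP", "portal_vein", 30.0, jitter=2.0)
    for phase in ("EAP", "LAP"):
        p = p.with_delta(phase, "artery", 235.0)
        p = p.with_delta(phase, "hepatic_vein", 2.0)
        p = p.with_delta(phase, "parenchyma", 8.0)
    return p


def simulate_dataset(
    n_exams: int,
    spec: PhantomSpec | None = None,
    profile: EnhancementProfile | None = None,
    seed: int = 0,
    edge_case_fraction: float = 0.0,
) -> list[Examination]:
    """Generate a labelled cohort of three-phase phantom examinations.

    The arterial acquisition alternates between EAP and LAP so both
    sub-phases are represented; a fraction of exams is replaced by
    boundary edge cases (cycling through the known kinds).  Exam-level
    randomness derives from ``seed`` and the exam index only, so cohorts
    are reproducible and extendable.
    """
    spec = spec or PhantomSpec()
    profile = profile or EnhancementProfile()
    rng = np.random.default_rng(seed)
    n_edge = int(round(edge_case_fraction * n_exams))
    exams = []
    for i in range(n_exams):
        exam_seed = int(rng.integers(2**31 - 1))
        if i < n_edge:
            kind = EDGE_CASE_KINDS[i % len(EDGE_CASE_KINDS)]
            exam = make_edge_case(kind, spec, seed=exam_seed, profile=profile)
            exam.exam_id = f"exam-{i:04d}-{kind}"
            for p in exam.phases:
                p.exam_id = exam.exam_id
        else:
            arterial = "EAP" if i % 2 == 0 else "LAP"
            exam = make_phantom_exam(spec, profile, {arterial, "PVP", "DP"},
                                     rng_seed=exam_seed, exam_id=f"exam-{i:04d}")
        exams.append(exam)
    return exams


def make_edge_case(case_kind: str, spec: PhantomSpec, seed: int,
                   profile: EnhancementProfile | None = None) -> Examination:
    """Generate an exam whose deltas sit near the labeling boundaries.

    * ``eap_portal_flash`` — EAP with a slightly enhancing portal vein
      (~12 HU), the pattern behind most arterial-phase misidentifications.
    * ``lap_low_portal`` — LAP with portal enhancement just above the
      moderate cut-off.
    * ``pvp_dp_flat`` — PVP/DP pair whose portal-vein difference is ~34 HU
      and hepatic-vein difference ~9 HU, a nearly flat washout.
    """
    base = profile or EnhancementProfile()
    if case_kind == "eap_portal_flash":
        prof = base.with_delta("EAP", "portal_vein", 12.0, jitter=1.0)
        labels = {"EAP", "PVP", "DP"}
    elif case_kind == "lap_low_portal":
        prof = base.with_delta("LAP", "portal_vein", 28.0, jitter=1.0)
        labels = {"LAP", "PVP", "DP"}
    elif case_kind == "pvp_dp_flat":
        prof = base.with_delta("PVP", "portal_vein", 100.0, jitter=1.0)
        prof = prof.with_delta("PVP", "hepatic_vein", 90.0, jitter=1.0)
        prof = prof.with_delta("DP", "portal_vein", 66.0, jitter=1.0)
        prof = prof.with_delta("DP", "hepatic_vein", 81.0, jitter=1.0)
        labels = {"PVP", "DP"}
    else:
        raise ValueError(f"unknown edge case kind {case_kind!r}")
    return make_phantom_exam(spec, prof, labels, rng_seed=seed,
                             exam_id=f"edge-{case_kind}-{seed}")
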