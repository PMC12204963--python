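"""NIfTI volume I/O and CSV manifests / prediction tables.

Volumes travel as NIfTI-1 (spacing in the affine); an exam manifest is a
CSV with columns ``exam_id, phase_file, true_phase, acquisition_index``
(one row per phase).  Deliberately no DICOM: phase identity is inferred
from image content, never from acquisition metadata.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .strategies import ExamPrediction
from .volumes import Examination, PhaseVolume, STEP1_OF

MANIFEST_COLUMNS = ["exam_id", "phase_file", "true_phase", "acquisition_index"]


def save_volume(vol: PhaseVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def load_volume(path: str | Path, exam_id: str = "", true_phase: str | None = None,
                acquisition_index: int | None = None) -> PhaseVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhaseVolume(np.asarray(img.dataobj, dtype=np.float64), spacing,
                       exam_id=exam_id, true_phase=true_phase,
                       acquisition_index=acquisition_index)


def save_exams(exams: list[Examination], out_dir: str | Path,
               manifest_name: str = "manifest.csv") -> Path:
    """Write all volumes as .nii.gz plus a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in exams:
        for i, p in enumerate(exam.phases):
            fname = f"{exam.exam_id}_phase{i}.nii.gz"
            save_volume(p, out / fname)
            rows.append({
                "exam_id": exam.exam_id,
                "phase_file": fname,
                "true_phase": p.true_phase if p.true_phase else "",
                "acquisition_index": p.acquisition_index
                if (exam.order_known and p.acquisition_index is not None) else "",
            })
    mpath = out / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(mpath, index=False)
    return mpath


def read_manifest(path: str | Path, load_volumes: bool = True) -> list[Examination]:
    """Read a manifest into Examinations, validating the exam structure.

    Rejects exams with more than 3 phases or duplicate step-1 truth
    classes, naming the offending row.  ``order_known`` is true when every
    phase of the exam has an acquisition index.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"exam_id": str, "phase_file": str})
    missing_cols = [c for c in ("exam_id", "phase_file") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {missing_cols}")
    base = path.parent
    exams: list[Examination] = []
    for exam_id, grp in df.groupby("exam_id", sort=False):
        if len(grp) > 3:
            raise ValueError(
                f"exam {exam_id!r} has {len(grp)} phases (max 3), "
                f"rows {list(grp.index + 2)}"
            )
        phases, step1_seen = [], set()
        order_known = True
        for row_i, row in grp.iterrows():
            fpath = base / str(row["phase_file"])
            if load_volumes and not os.path.exists(fpath):
                raise FileNotFoundError(
                    f"manifest row {row_i + 2}: phase file not found: {fpath}"
                )
            phase = row.get("true_phase")
            phase = None if (pd.isna(phase) or phase == "") else str(phase)
            if phase is not None:
                s1 = STEP1_OF.get(phase)
                if s1 is None:
                    raise ValueError(f"manifest row {row_i + 2}: unknown phase {phase!r}")
                if s1 in step1_seen:
                    raise ValueError(
                        f"manifest row {row_i + 2}: duplicate step-1 class {s1} "
                        f"in exam {exam_id!r}"
                    )
                step1_seen.add(s1)
            acq = row.get("acquisition_index")
            acq = None if (acq is None or pd.isna(acq) or acq == "") else int(acq)
            if acq is None:
                order_known = False
            if load_volumes:
                phases.append(load_volume(fpath, exam_id=str(exam_id),
                                          true_phase=phase, acquisition_index=acq))
            else:
                phases.append(PhaseVolume(np.zeros((2, 2, 2)), (1, 1, 1),
                                          exam_id=str(exam_id), true_phase=phase,
                                          acquisition_index=acq))
        exams.append(Examination(str(exam_id), phases, order_known=order_known))
    return exams


def write_predictions(preds: list[ExamPrediction], path: str | Path) -> None:
    rows = []
    for p in preds:
        for i in range(p.probs4.shape[0]):
            rows.append({
                "exam_id": p.exam_id,
                "phase_index": i,
                "p_EAP": p.probs4[i, 0], "p_LAP": p.probs4[i, 1],
                "p_PVP": p.probs4[i, 2], "p_DP": p.probs4[i, 3],
                "label_raw": p.labels_raw[i],
                "label_calibrated": (p.labels_calibrated[i]
                                     if p.labels_calibrated else ""),
                "relative_order": (p.relative_order[i]
                                   if p.relative_order else ""),
                "strategy": p.strategy,
                "true_phase": p.true_labels[i] if p.true_labels else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
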