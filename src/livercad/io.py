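"""NIfTI study loading, CSV marker tables, NIfTI phantom export."""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError, SchemaError
from .study import GRADES, PHASE_NAMES, MarkerVector, TumorStudy


def _read_nifti(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_study(
    phase_paths: Dict[str, "os.PathLike"],
    mask_path,
    phase_times: Optional[Sequence[float]] = None,
    study_id: Optional[str] = None,
    grade: Optional[str] = None,
) -> TumorStudy:
    """Load four co-registered phase volumes and a mask from NIfTI files.

    ``phase_paths`` maps the phase names (pre/arterial/venous/delayed) to
    file paths; voxel spacing is read from the mask header.
    """
    missing = [k for k in PHASE_NAMES if k not in phase_paths]
    if missing:
        raise ValueError(f"missing phase paths: {missing}")
    phases = {}
    spacings = {}
    for name in PHASE_NAMES:
        phases[name], spacings[name] = _read_nifti(phase_paths[name])
    mask, mask_spacing = _read_nifti(mask_path)
    shapes = {n: v.shape for n, v in phases.items()}
    if len(set(shapes.values()) | {mask.shape}) != 1:
        raise GridMismatchError(f"grid mismatch: phases {shapes}, mask {mask.shape}")
    kwargs = {}
    if phase_times is not None:
        kwargs["phase_times"] = tuple(phase_times)
    return TumorStudy(
        study_id=study_id or os.path.basename(os.fspath(mask_path)).split(".")[0],
        phases=phases,
        mask=mask,
        spacing=mask_spacing,
        grade=grade,
        **kwargs,
    )


def save_study(study: TumorStudy, out_dir) -> Dict[str, str]:
    """Write a study's phases and mask as uncompressed NIfTI files."""
    os.makedirs(out_dir, exist_ok=True)
    affine = np.diag(list(study.spacing) + [1.0])
    paths = {}
    for name in PHASE_NAMES:
        p = os.path.join(os.fspath(out_dir), f"{study.study_id}_{name}.nii")
        nib.save(nib.Nifti1Image(study.phases[name].astype(np.float32), affine), p)
        paths[name] = p
    p = os.path.join(os.fspath(out_dir), f"{study.study_id}_mask.nii")
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), affine), p)
    paths["mask"] = p
    return paths


def write_marker_table(
    records: Sequence[MarkerVector],
    path,
    grades: Optional[Dict[str, Optional[str]]] = None,
) -> pd.DataFrame:
    """One CSV row per study: study_id, grade (may be empty), then markers."""
    if not records:
        raise ValueError("no records")
    schema = records[0].names
    for r in records[1:]:
        if r.names != schema:
            raise SchemaError("inconsistent marker schema")
    rows = []
    for r in records:
        grade = (grades or {}).get(r.study_id)
        rows.append({"study_id": r.study_id, "grade": grade, **r.values})
    df = pd.DataFrame(rows, columns=["study_id", "grade", *schema])
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_marker_table(path) -> Tuple[pd.DataFrame, pd.Series]:
    """Returns (marker matrix indexed by study_id, grade series)."""
    df = pd.read_csv(path, dtype={"study_id": str}, float_precision="round_trip")
    grades = df.set_index("study_id")["grade"]
    grades = grades.where(grades.isin(GRADES), None)
    x = df.set_index("study_id").drop(columns=["grade"])
    return x, grades


def markers_to_records(df: pd.DataFrame) -> List[MarkerVector]:
    return [
        MarkerVector(study_id=str(idx), values=row.to_dict())
        for idx, row in df.iterrows()
    ]
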