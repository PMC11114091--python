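"""NIfTI helpers and input validation for the analysis pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_SUBJECT_COLUMNS = (
    "subject_id", "timepoint", "days_since_stroke", "age", "sex", "lesion_volume_ml",
)
CLINICAL_COLUMNS = ("nihss", "uefm", "nhp", "grip_rel")
KNOWN_TIMEPOINTS = ("TP1", "TP2", "TP3", "TP4")


def affine_for(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
               voxel_size_mm: float = 2.0) -> None:
    if affine is None:
        affine = affine_for(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, path, affine: np.ndarray | None = None,
              voxel_size_mm: float = 2.0) -> None:
    if affine is None:
        affine = affine_for(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


@dataclass
class ValidationReport:
    """Input checks split into hard failures and warnings."""

    failures: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def fail(self, msg: str) -> None:
        self.failures.append(msg)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        log.warning("%s", msg)


def validate_inputs(
    dwi: np.ndarray,
    dwi_affine: np.ndarray,
    masks: dict,
    subject_table: pd.DataFrame | None = None,
    affine_tol: float = 1e-4,
) -> ValidationReport:
    """Check grid/affine agreement, mask binarity and table schema.

    ``masks`` maps names to ``(array, affine)`` pairs. Affine disagreement
    beyond ``affine_tol`` and non-binary masks are hard failures; missing
    clinical columns are warnings.
    """
    report = ValidationReport()
    if dwi.ndim != 4:
        report.fail(f"DWI must be 4-D, got {dwi.ndim}-D")
    grid = dwi.shape[:3]
    for name, (arr, aff) in masks.items():
        if arr.shape != grid:
            report.fail(f"mask {name!r} grid {arr.shape} != DWI grid {grid}")
        if np.max(np.abs(np.asarray(aff) - np.asarray(dwi_affine))) > affine_tol:
            report.fail(f"mask {name!r} affine disagrees with DWI beyond {affine_tol}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            report.fail(f"non-binary mask {name!r} (values {vals[:5]})")
    if subject_table is not None:
        for col in REQUIRED_SUBJECT_COLUMNS:
            if col not in subject_table.columns:
                report.fail(f"subject table missing column '{col}'")
        for col in CLINICAL_COLUMNS:
            if col not in subject_table.columns:
                report.warn(f"subject table lacks clinical column '{col}'")
        if "timepoint" in subject_table.columns:
            unknown = set(subject_table["timepoint"].astype(str)) - set(KNOWN_TIMEPOINTS)
            if unknown:
                report.fail(f"unknown timepoint labels: {sorted(unknown)}")
    return report
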