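"""Study-level data model: four-phase volumes, mask, grades, marker records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import DEFAULT_PHASE_TIMES
from .errors import (
    BadPhaseTimesError,
    EmptyMaskError,
    GridMismatchError,
    SchemaError,
)

PHASE_NAMES: Tuple[str, ...] = ("pre", "arterial", "venous", "delayed")
GRADES: Tuple[str, ...] = ("LR1", "LR2", "LR3", "LR4", "LR5")
GROUPS3: Tuple[str, ...] = ("benign", "intermediate", "malignant")

#: LR grade -> coarse 3-class group used by the first classification stage
GRADE_TO_GROUP: Dict[str, str] = {
    "LR1": "benign",
    "LR2": "benign",
    "LR3": "intermediate",
    "LR4": "malignant",
    "LR5": "malignant",
}

MARKER_GROUPS: Tuple[str, ...] = (
    "morphological",
    "first_order",
    "glcm",
    "glrlm",
    "functional",
)


@dataclass
class TumorStudy:
    """One tumor: four co-registered gray-scale phase volumes plus a mask.

    Voxel indices are 0-based; world coordinates are ``index * spacing``
    in millimetres; the mask foreground is any value > 0.
    """

    study_id: str
    phases: Dict[str, np.ndarray]
    mask: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_times: Tuple[float, ...] = DEFAULT_PHASE_TIMES
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if tuple(self.phases.keys()) != PHASE_NAMES:
            self.phases = {k: self.phases[k] for k in PHASE_NAMES}
        self.mask = np.asarray(self.mask) > 0
        self.spacing = tuple(float(s) for s in self.spacing)
        self.phase_times = tuple(float(t) for t in self.phase_times)
        self.validate()

    def validate(self) -> None:
        shape = self.mask.shape
        for name in PHASE_NAMES:
            vol = self.phases[name]
            if vol.ndim != 3 or vol.shape != shape:
                raise GridMismatchError(
                    f"grid mismatch: phase '{name}' has shape {vol.shape}, "
                    f"mask has shape {shape}"
                )
        if not self.mask.any():
            raise EmptyMaskError("empty mask")
        _, n_comp = ndimage.label(self.mask, structure=np.ones((3, 3, 3)))
        if n_comp != 1:
            raise GridMismatchError(
                f"mask must be a single 26-connected component, found {n_comp}"
            )
        if len(self.phase_times) != 4 or np.any(np.diff(self.phase_times) <= 0):
            raise BadPhaseTimesError(f"bad phase times {self.phase_times}")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def phase_stack(self) -> np.ndarray:
        return np.stack([self.phases[k] for k in PHASE_NAMES])


@dataclass
class MarkerVector:
    """Named marker record for one study (fixed 249-name schema by default)."""

    study_id: str
    values: Dict[str, float]
    group: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise SchemaError(f"non-finite marker values: {bad[:5]}")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.values.keys())

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GradePrediction:
    """Routing-consistent two-stage prediction for one study."""

    study_id: str
    stage1: str
    final: str

    def __post_init__(self) -> None:
        if self.stage1 not in GROUPS3:
            raise ValueError(f"unknown stage-1 group {self.stage1!r}")
        if self.final not in GRADES:
            raise ValueError(f"unknown grade {self.final!r}")
        if GRADE_TO_GROUP[self.final] != self.stage1:
            raise ValueError(
                f"inconsistent prediction: stage1={self.stage1} final={self.final}"
            )
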