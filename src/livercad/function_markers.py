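"""Wash-in / wash-out slope markers from the four-phase enhancement curve."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .config import Config
from .errors import EmptyMaskError
from .study import PHASE_NAMES, TumorStudy

FUNCTIONAL_NAMES = ["slope_washin", "slope_pv", "slope_del"]


@dataclass(frozen=True)
class EnhancementCurve:
    """Mean mask intensity per phase at the acquisition times."""

    intensities: Tuple[float, float, float, float]
    times: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.intensities) != 4 or len(self.times) != 4:
            raise ValueError("curve needs exactly 4 phases")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"bad phase times {self.times}")

    def slopes(self) -> Tuple[float, float, float]:
        i = np.asarray(self.intensities, dtype=float)
        t = np.asarray(self.times, dtype=float)
        s = np.diff(i) / np.diff(t)
        return (float(s[0]), float(s[1]), float(s[2]))


def enhancement_curve(
    study: TumorStudy, times: Optional[Tuple[float, ...]] = None, relative: bool = False
) -> EnhancementCurve:
    """Mean raw (unquantized) mask intensity across the four phases."""
    if not study.mask.any():
        raise EmptyMaskError("empty mask")
    means = [float(study.phases[p][study.mask].mean()) for p in PHASE_NAMES]
    if relative:
        base = means[0]
        if base == 0:
            raise ValueError("relative enhancement undefined: zero baseline")
        means = [(m - base) / base for m in means]
    return EnhancementCurve(tuple(means), tuple(times or study.phase_times))


def enhancement_slopes(study: TumorStudy, cfg: Optional[Config] = None) -> Dict[str, float]:
    """Three slopes in intensity/s: wash-in (pre -> arterial), portal-venous
    wash-out (arterial -> venous) and delayed wash-out (venous -> delayed)."""
    relative = cfg.func.relative if cfg is not None else False
    curve = enhancement_curve(study, times=study.phase_times, relative=relative)
    s = curve.slopes()
    return dict(zip(FUNCTIONAL_NAMES, s))
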