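"""Configuration objects for the extraction pipeline.

Defaults reproduce the published operating point (70 harmonic degrees,
256 gray levels, phase times 0/35/50/180 s).  ``Config.test_scale()``
returns a reduced operating point for fast desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

DEFAULT_PHASE_TIMES = (0.0, 35.0, 50.0, 180.0)


@dataclass(frozen=True)
class ARConfig:
    """Attraction-repulsion spherical parameterization constants.

    The source method leaves these unspecified; the defaults were tuned
    for stable convergence on icosphere fixtures and are all exposed.
    """

    ca1: float = 0.003
    ca2: float = 0.3
    cr: float = 1.0
    threshold: float = 1e-4
    max_iters: int = 300
    #: recompute repulsion displacements from pre-attraction positions
    literal_alpha: bool = False

    def __post_init__(self) -> None:
        if min(self.ca1, self.ca2, self.cr, self.threshold) <= 0:
            raise ValueError("attraction/repulsion constants must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass(frozen=True)
class SmoothConfig:
    iters: int = 10
    factor: float = 0.5


@dataclass(frozen=True)
class MorphConfig:
    l_max: int = 70
    ar: ARConfig = field(default_factory=ARConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    #: divide per-degree errors by node count (off = raw distance sums)
    normalize_errors: bool = False


@dataclass(frozen=True)
class TextureConfig:
    levels: int = 256


@dataclass(frozen=True)
class FuncConfig:
    times: tuple = DEFAULT_PHASE_TIMES
    relative: bool = False


@dataclass(frozen=True)
class Config:
    morph: MorphConfig = field(default_factory=MorphConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    func: FuncConfig = field(default_factory=FuncConfig)

    @classmethod
    def default(cls) -> "Config":
        return cls()

    @classmethod
    def test_scale(cls, l_max: int = 25, max_iters: int = 60) -> "Config":
        """Reduced settings for fast runs (< 10 s per study)."""
        return cls(
            morph=MorphConfig(
                l_max=l_max,
                ar=ARConfig(threshold=5e-4, max_iters=max_iters),
                smooth=SmoothConfig(iters=5, factor=0.5),
            )
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        morph = d.get("morph", {})
        ar = ARConfig(**morph.pop("ar", {})) if "ar" in morph else ARConfig()
        smooth = (
            SmoothConfig(**morph.pop("smooth", {}))
            if "smooth" in morph
            else SmoothConfig()
        )
        func = dict(d.get("func", {}))
        if "times" in func:
            func["times"] = tuple(func["times"])
        return cls(
            morph=MorphConfig(ar=ar, smooth=smooth, **morph),
            texture=TextureConfig(**d.get("texture", {})),
            func=FuncConfig(**func),
        )

    @classmethod
    def from_json(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_times(self, times) -> "Config":
        return replace(self, func=replace(self.func, times=tuple(times)))
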