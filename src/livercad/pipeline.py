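"""End-to-end marker extraction and study-level diagnosis orchestration."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .config import Config
from .errors import LiverCADError
from .function_markers import FUNCTIONAL_NAMES, enhancement_slopes
from .morphology import morphological_marker_names, morphological_markers
from .study import MarkerVector, TumorStudy
from .texture import textural_marker_names, textural_markers


def marker_schema(cfg: Optional[Config] = None) -> List[Tuple[str, str]]:
    """Fixed (name, group) schema: 70 + 104 + 24 + 48 + 3 = 249 by default."""
    if cfg is None:
        cfg = Config.default()
    schema: List[Tuple[str, str]] = [
        (n, "morphological") for n in morphological_marker_names(cfg.morph.l_max)
    ]
    for name in textural_marker_names():
        if "_fo_" in name:
            schema.append((name, "first_order"))
        elif "_glcm_" in name:
            schema.append((name, "glcm"))
        else:
            schema.append((name, "glrlm"))
    schema += [(n, "functional") for n in FUNCTIONAL_NAMES]
    return schema


def marker_group_map(names: Iterable[str]) -> Dict[str, str]:
    """Infer the marker group from the schema naming convention."""
    out = {}
    for n in names:
        if n.startswith("SH_err_"):
            out[n] = "morphological"
        elif "_fo_" in n:
            out[n] = "first_order"
        elif "_glcm_" in n:
            out[n] = "glcm"
        elif "_glrlm_" in n:
            out[n] = "glrlm"
        elif n in FUNCTIONAL_NAMES:
            out[n] = "functional"
        else:
            raise KeyError(f"marker {n!r} not in schema")
    return out


def _run(module: str, fn, *args):
    try:
        return fn(*args)
    except LiverCADError as e:
        raise type(e)(f"{module}: {e}") from e


def extract_all_markers(study: TumorStudy, cfg: Optional[Config] = None) -> MarkerVector:
    """All morphological, textural and functional markers for one study.

    Deterministic given (study, cfg); no partial output is produced when a
    module fails — the error propagates with the module name attached.
    """
    if cfg is None:
        cfg = Config.default()
    morph = _run("morphology", morphological_markers, study, cfg)
    tex = _run("texture", textural_markers, study, cfg)
    func = _run("function_markers", enhancement_slopes, study, cfg)
    values = {**morph, **tex, **func}
    schema = marker_schema(cfg)
    ordered = {name: values[name] for name, _ in schema}
    return MarkerVector(
        study_id=study.study_id, values=ordered, group=dict(schema)
    )


def extract_cohort(
    studies: Iterable[TumorStudy], cfg: Optional[Config] = None
) -> Tuple[pd.DataFrame, pd.Series]:
    """Marker matrix (rows = studies) and grade labels for a cohort."""
    studies = list(studies)
    records = [extract_all_markers(s, cfg) for s in studies]
    x = pd.DataFrame(
        [r.values for r in records], index=[r.study_id for r in records]
    )
    grades = pd.Series(
        {s.study_id: s.grade for s in studies}, name="grade"
    ).reindex(x.index)
    return x, grades
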