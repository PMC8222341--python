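"""Marker-subset selection: forward / stepwise wrappers and Gini importance.

The wrapper methods grow an ordinary-least-squares model of an ordinal
class code and admit the candidate with the smallest partial-F p-value; the
stepwise variant additionally drops included markers whose p-value rises
above the removal threshold.  Gini selection ranks markers by random-forest
mean impurity decrease and keeps those above the mean importance, either
over all markers jointly or within each marker group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .errors import SingleClassError
from .pipeline import marker_group_map

RF_PARAMS = dict(
    class_weight="balanced",
    criterion="gini",
    max_depth=30,
    min_samples_leaf=5,
    min_samples_split=2,
    n_estimators=100,
)


@dataclass
class SelectionResult:
    selected: List[str]
    method: str
    thresholds: Dict[str, float] = field(default_factory=dict)
    trace: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate markers in selection")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected": self.selected,
                    "method": self.method,
                    "thresholds": self.thresholds,
                    "trace": self.trace,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected=list(d["selected"]),
            method=d.get("method", "unknown"),
            thresholds=d.get("thresholds", {}),
            trace=d.get("trace", {}),
        )


def _class_code(y: Sequence) -> np.ndarray:
    classes = sorted(set(y))
    if len(classes) < 2:
        raise SingleClassError("single class")
    code = {c: i for i, c in enumerate(classes)}
    return np.array([code[v] for v in y], dtype=float)


def _usable_columns(x: pd.DataFrame) -> List[str]:
    usable = []
    constant = []
    for c in x.columns:
        if np.ptp(x[c].to_numpy()) == 0:
            constant.append(c)
        else:
            usable.append(c)
    if constant:
        warnings.warn(
            f"skipping {len(constant)} constant marker column(s)", stacklevel=3
        )
    return usable


def _candidate_pvalue(xs: np.ndarray, cand: np.ndarray, y: np.ndarray) -> float:
    """Partial-F p-value of one candidate added to the current OLS model.

    For a single added regressor this equals the p-value of its t-test.
    """
    design = sm.add_constant(np.column_stack([xs, cand]) if xs.size else cand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, design).fit()
    p = res.pvalues[-1]
    return float(p) if np.isfinite(p) else 1.0


def _model_pvalues(xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = sm.add_constant(xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, design).fit()
    p = np.asarray(res.pvalues)[1:]
    return np.where(np.isfinite(p), p, 1.0)


def forward_select(x: pd.DataFrame, y: Sequence, st: float = 0.05) -> SelectionResult:
    """Greedy growth: admit the lowest-p candidate while its p-value < st."""
    yc = _class_code(y)
    candidates = _usable_columns(x)
    selected: List[str] = []
    trace: Dict[str, float] = {}
    while candidates:
        xs = x[selected].to_numpy() if selected else np.empty((len(yc), 0))
        pvals = [_candidate_pvalue(xs, x[c].to_numpy(), yc) for c in candidates]
        best = int(np.argmin(pvals))  # ties broken by schema order
        if pvals[best] >= st:
            break
        name = candidates.pop(best)
        selected.append(name)
        trace[name] = pvals[best]
    return SelectionResult(selected, "forward", {"st": st}, trace)


def stepwise_select(
    x: pd.DataFrame, y: Sequence, st_enter: float = 0.05, st_remove: float = 0.05
) -> SelectionResult:
    """Bi-directional elimination: forward entry then backward pruning."""
    yc = _class_code(y)
    candidates = _usable_columns(x)
    selected: List[str] = []
    trace: Dict[str, float] = {}
    seen = set()
    while True:
        remaining = [c for c in candidates if c not in selected]
        entered = False
        if remaining:
            xs = x[selected].to_numpy() if selected else np.empty((len(yc), 0))
            pvals = [_candidate_pvalue(xs, x[c].to_numpy(), yc) for c in remaining]
            best = int(np.argmin(pvals))
            if pvals[best] < st_enter:
                selected.append(remaining[best])
                trace[remaining[best]] = pvals[best]
                entered = True
        # backward check of already-included markers
        while len(selected) > 1:
            p = _model_pvalues(x[selected].to_numpy(), yc)
            worst = int(np.argmax(p))
            if p[worst] < st_remove:
                break
            trace[selected[worst]] = float(p[worst])
            del selected[worst]
        state = frozenset(selected)
        if not entered or state in seen:
            break
        seen.add(state)
    return SelectionResult(
        selected, "stepwise", {"st_enter": st_enter, "st_remove": st_remove}, trace
    )


def gini_select(
    x: pd.DataFrame,
    y: Sequence,
    mode: str = "combined",
    seed: int = 0,
    groups: Optional[Dict[str, str]] = None,
) -> SelectionResult:
    """Keep markers whose forest impurity importance exceeds the mean.

    ``mode='combined'`` ranks all markers jointly; ``mode='separate'``
    applies the rule within each marker group and unions the survivors.
    """
    if mode not in ("combined", "separate"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(set(y)) < 2:
        raise SingleClassError("single class")
    y = np.asarray(y)

    def _fit_importances(cols: List[str]) -> np.ndarray:
        rf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
        rf.fit(x[cols].to_numpy(), y)
        return rf.feature_importances_

    trace: Dict[str, float] = {}
    selected: List[str] = []
    if mode == "combined":
        cols = list(x.columns)
        imp = _fit_importances(cols)
        trace = dict(zip(cols, imp.astype(float)))
        cutoff = imp.mean()
        selected = [c for c, v in zip(cols, imp) if v > cutoff]
    else:
        if groups is None:
            groups = marker_group_map(x.columns)
        order = {c: i for i, c in enumerate(x.columns)}
        by_group: Dict[str, List[str]] = {}
        for c in x.columns:
            by_group.setdefault(groups[c], []).append(c)
        keep = set()
        for cols in by_group.values():
            imp = _fit_importances(cols)
            for c, v in zip(cols, imp):
                trace[c] = float(v)
            cutoff = imp.mean()
            keep.update(c for c, v in zip(cols, imp) if v > cutoff)
        selected = sorted(keep, key=order.get)
    return SelectionResult(selected, f"gini_{mode}", {}, trace)
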