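"""Two-stage grading, alternative classifiers, cross-validation, metrics.

Stage 1 separates benign (LR1-2) / intermediate (LR3) / malignant (LR4-5);
stage 2 grades within the benign and malignant groups.  Sensitivity,
specificity and F1 use the group-level TP/TN/FP/FN definitions: TP =
malignant predicted malignant, TN = benign predicted benign, FP = benign or
intermediate predicted malignant, FN = malignant or intermediate predicted
benign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import (
    SchemaError,
    TooManyFoldsError,
    UnknownClassifierError,
    UnlabeledSubjectError,
)
from .selection import RF_PARAMS, SelectionResult
from .study import GRADES, GRADE_TO_GROUP, GradePrediction, MarkerVector

FAMILIES = ("rf", "knn", "svm-cubic", "svm-quad", "nb", "lda")


def make_classifier(family: str, seed: Optional[int] = 0):
    """Classifier with the published grid-search hyper-parameters."""
    if family == "rf":
        return RandomForestClassifier(random_state=seed, **RF_PARAMS)
    if family == "knn":
        return KNeighborsClassifier(
            n_neighbors=5, weights="uniform", metric="minkowski", p=2, leaf_size=30
        )
    if family in ("svm-cubic", "svm-quad"):
        degree = 3 if family == "svm-cubic" else 2
        return SVC(
            C=1.0,
            kernel="poly",
            degree=degree,
            gamma=0.001,
            tol=0.001,
            break_ties=False,
            cache_size=200,
            decision_function_shape="ovr",
            random_state=seed,
        )
    if family == "nb":
        return BernoulliNB(alpha=0.5, binarize=0.0, fit_prior=True, class_prior=None)
    if family == "lda":
        return LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=0.52, n_components=None, tol=1e-4
        )
    raise UnknownClassifierError(f"unknown classifier {family!r}")


# ---------------------------------------------------------------------------
# two-stage model
# ---------------------------------------------------------------------------


@dataclass
class TwoStageModel:
    stage1: object
    stage2_benign: object
    stage2_malignant: object
    markers: List[str]
    family: str = "rf"

    def predict(self, x: pd.DataFrame) -> List[GradePrediction]:
        return predict_two_stage(self, x)


def _check_labels(y: Sequence) -> List[str]:
    labels = list(y)
    for v in labels:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v not in GRADES:
            raise UnlabeledSubjectError(f"unlabeled subject: grade {v!r}")
    return labels


def train_two_stage(
    x: pd.DataFrame,
    y: Sequence,
    family: str = "rf",
    seed: int = 0,
    markers: Optional[List[str]] = None,
    _cache: Optional[dict] = None,
) -> TwoStageModel:
    """Fit stage-1 on collapsed 3-group labels and the two stage-2 binary
    classifiers on the ground-truth benign and malignant subsets.

    ``_cache`` (used by cross-validation) memoizes stage-2 fits keyed by
    their exact training rows; in LOSO most folds leave the stage-2
    subsets untouched.
    """
    labels = _check_labels(y)
    if markers is not None:
        missing = [m for m in markers if m not in x.columns]
        if missing:
            raise SchemaError(f"marker schema mismatch: missing {missing[:5]}")
        x = x[markers]
    markers = list(x.columns)
    groups = np.array([GRADE_TO_GROUP[v] for v in labels])
    labels = np.array(labels)

    for side, pair in (("benign", ("LR1", "LR2")), ("malignant", ("LR4", "LR5"))):
        present = set(labels[groups == side])
        if not set(pair) <= present:
            missing_grades = sorted(set(pair) - present)
            raise UnlabeledSubjectError(
                f"unlabeled subject class missing for stage2_{side}: {missing_grades}"
            )

    xa = x.to_numpy()
    stage1 = make_classifier(family, seed)
    stage1.fit(xa, groups)

    def _fit_stage2(side: str, offset: int):
        sel = groups == side
        sub_seed = None if seed is None else seed + offset
        key = None
        if _cache is not None:
            key = (side, family, sub_seed, tuple(markers), tuple(x.index[sel]))
            if key in _cache:
                return _cache[key]
        clf = make_classifier(family, sub_seed)
        clf.fit(xa[sel], labels[sel])
        if key is not None:
            _cache[key] = clf
        return clf

    s2b = _fit_stage2("benign", 1)
    s2m = _fit_stage2("malignant", 2)
    return TwoStageModel(stage1, s2b, s2m, markers, family)


def _as_frame(x, markers: List[str]) -> pd.DataFrame:
    if isinstance(x, MarkerVector):
        x = pd.DataFrame([x.values], index=[x.study_id])
    elif isinstance(x, pd.Series):
        x = x.to_frame().T
    missing = [m for m in markers if m not in x.columns]
    if missing:
        raise SchemaError(f"marker schema mismatch: missing {missing[:5]}")
    return x[markers]


def predict_two_stage(
    model: TwoStageModel, x: Union[pd.DataFrame, pd.Series, MarkerVector]
) -> List[GradePrediction]:
    """Stage-1 routing then within-group grading; LR3 for intermediates."""
    frame = _as_frame(x, model.markers)
    xa = frame.to_numpy()
    stage1 = model.stage1.predict(xa)
    final = np.empty(len(xa), dtype=object)
    final[stage1 == "intermediate"] = "LR3"
    for side, clf in (("benign", model.stage2_benign), ("malignant", model.stage2_malignant)):
        sel = stage1 == side
        if sel.any():
            final[sel] = clf.predict(xa[sel])
    return [
        GradePrediction(study_id=str(idx), stage1=s1, final=f)
        for idx, s1, f in zip(frame.index, stage1, final)
    ]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionSummary:
    matrix: np.ndarray  # (5, 5), rows = truth LR1..LR5
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    f1: float
    per_grade_accuracy: Dict[str, float]
    overall_accuracy: float


def compute_metrics(
    truth: Sequence[str], pred: Sequence[Union[GradePrediction, str]]
) -> ConfusionSummary:
    """Confusion matrix over the five grades plus the group-level metrics."""
    if len(truth) == 0:
        raise ValueError("no subjects")
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    truth = list(truth)
    final = [p.final if isinstance(p, GradePrediction) else p for p in pred]
    gi = {g: k for k, g in enumerate(GRADES)}
    matrix = np.zeros((5, 5), dtype=int)
    for t, f in zip(truth, final):
        matrix[gi[t], gi[f]] += 1

    tgroup = np.array([GRADE_TO_GROUP[t] for t in truth])
    pgroup = np.array([GRADE_TO_GROUP[f] for f in final])
    tp = int(np.sum((tgroup == "malignant") & (pgroup == "malignant")))
    tn = int(np.sum((tgroup == "benign") & (pgroup == "benign")))
    fp = int(np.sum((tgroup != "malignant") & (pgroup == "malignant")))
    fn = int(np.sum((tgroup != "benign") & (pgroup == "benign")))

    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    per_grade = {}
    for g, k in gi.items():
        n_g = matrix[k].sum()
        per_grade[g] = float(matrix[k, k] / n_g) if n_g else float("nan")
    overall = float(np.trace(matrix) / matrix.sum())
    return ConfusionSummary(matrix, tp, tn, fp, fn, sens, spec, f1, per_grade, overall)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

Selector = Callable[[pd.DataFrame, Sequence], SelectionResult]


@dataclass
class EvalReport:
    scheme: str
    repeats: int
    metrics: Dict[str, Tuple[float, float]]  # name -> (mean, std)
    pooled: ConfusionSummary
    per_repeat: List[ConfusionSummary] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "repeats": self.repeats,
            "seed": self.seed,
            "metrics": {k: {"mean": m, "std": s} for k, (m, s) in self.metrics.items()},
            "confusion_matrix": self.pooled.matrix.tolist(),
            "grades": list(GRADES),
        }


def _folds(scheme: str, groups: np.ndarray, n: int, rng_seed: int):
    if scheme == "loso":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    k = {"k10": 10, "k5": 5}.get(scheme)
    if k is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    if k > n:
        raise TooManyFoldsError(f"too many folds: {k} > {n}")
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return list(skf.split(np.zeros(n), groups))


def _one_pass(
    x: pd.DataFrame,
    labels: np.ndarray,
    folds,
    family: str,
    seed: int,
    selector: Optional[Union[Selector, SelectionResult]],
    trainer,
) -> ConfusionSummary:
    preds: Dict[int, str] = {}
    cache: dict = {}
    for tr, te in folds:
        x_tr, y_tr = x.iloc[tr], labels[tr]
        markers = None
        if isinstance(selector, SelectionResult):
            markers = selector.selected
        elif selector is not None:
            markers = selector(x_tr, y_tr).selected
        if markers is not None and len(markers) == 0:
            markers = None  # empty selection: fall back to the full schema
        kwargs = {"_cache": cache} if trainer is train_two_stage else {}
        model = trainer(x_tr, y_tr, family=family, seed=seed, markers=markers, **kwargs)
        for idx, p in zip(te, model.predict(x.iloc[te])):
            preds[int(idx)] = p.final if isinstance(p, GradePrediction) else p
    ordered = [preds[i] for i in range(len(labels))]
    return compute_metrics(list(labels), ordered)


def _aggregate(scheme, repeats, summaries, seed) -> EvalReport:
    names = ["sensitivity", "specificity", "f1", "overall_accuracy"]
    metrics = {}
    for name in names:
        vals = np.array([getattr(s, name) for s in summaries])
        metrics[name] = (float(vals.mean()), float(vals.std()))
    for g in GRADES:
        vals = np.array([s.per_grade_accuracy[g] for s in summaries])
        metrics[f"accuracy_{g}"] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    pooled_matrix = np.sum([s.matrix for s in summaries], axis=0)
    # rebuild pooled summary from the summed confusion matrix
    truth, pred = [], []
    for i, g in enumerate(GRADES):
        for j, h in enumerate(GRADES):
            truth += [g] * pooled_matrix[i, j]
            pred += [h] * pooled_matrix[i, j]
    pooled = compute_metrics(truth, pred)
    return EvalReport(scheme, repeats, metrics, pooled, list(summaries), seed)


class _OneStageModel:
    """Single 5-class classifier exposing the two-stage predict contract."""

    def __init__(self, clf, markers):
        self.clf = clf
        self.markers = markers

    def predict(self, x: pd.DataFrame):
        frame = _as_frame(x, self.markers)
        final = self.clf.predict(frame.to_numpy())
        return [
            GradePrediction(str(i), GRADE_TO_GROUP[f], f)
            for i, f in zip(frame.index, final)
        ]


def _train_one_stage(x, y, family="rf", seed=0, markers=None):
    labels = np.array(_check_labels(y))
    if markers is not None:
        x = x[markers]
    clf = make_classifier(family, seed)
    clf.fit(x.to_numpy(), labels)
    return _OneStageModel(clf, list(x.columns))


def cross_validate(
    x: pd.DataFrame,
    y: Sequence,
    scheme: str = "loso",
    repeats: int = 10,
    family: str = "rf",
    selector: Optional[Union[Selector, SelectionResult]] = None,
    seed: int = 0,
    stages: int = 2,
) -> EvalReport:
    """LOSO or repeated stratified k-fold evaluation of the grading model.

    Stratification uses the 3-group label so each fold preserves the
    benign/intermediate/malignant proportions.  Any selection callable is
    re-run inside each training fold (no test-fold leakage); LOSO folds are
    fixed by definition so repeats only vary the classifier seed.
    """
    labels = np.array(_check_labels(y))
    groups = np.array([GRADE_TO_GROUP[v] for v in labels])
    n = len(labels)
    trainer = train_two_stage if stages == 2 else _train_one_stage
    summaries = []
    for rep in range(repeats):
        folds = _folds(scheme, groups, n, rng_seed=seed + rep)
        summaries.append(
            _one_pass(x, labels, folds, family, seed + 1000 * rep, selector, trainer)
        )
    return _aggregate(scheme, repeats, summaries, seed)


def one_stage_baseline(
    x: pd.DataFrame,
    y: Sequence,
    scheme: str = "loso",
    repeats: int = 10,
    family: str = "rf",
    seed: int = 0,
) -> EvalReport:
    """Single 5-class forest with the same hyper-parameters and metrics."""
    return cross_validate(
        x, y, scheme=scheme, repeats=repeats, family=family, seed=seed, stages=1
    )


def compare_stages(
    x: pd.DataFrame,
    y: Sequence,
    scheme: str = "loso",
    repeats: int = 10,
    family: str = "rf",
    seed: int = 0,
) -> Dict[str, EvalReport]:
    """Two-stage vs one-stage side-by-side evaluation harness."""
    return {
        "two_stage": cross_validate(
            x, y, scheme=scheme, repeats=repeats, family=family, seed=seed, stages=2
        ),
        "one_stage": one_stage_baseline(
            x, y, scheme=scheme, repeats=repeats, family=family, seed=seed
        ),
    }
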