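"""Interval-probability majority-vote classifier over discretized features.

Training tabulates, per statistic ``s``, the count matrix ``Cm[c, i, s]``
(windows of class ``c`` whose value of ``s`` falls in interval ``i``) and
derives the likelihood matrix

    AIm[c,i,s] = Cm[c,i,s]/total[c,s] * 1/(l-1) * sum_{j!=c} (1 - Cm[j,i,s]/total[j,s])

whose entries lie in [0, 1]: the first factor is the within-class interval
probability, the second the average absence of the other classes from the
interval.  Prediction sums, over all statistics, the AIm entry of the
interval containing the query value and returns the class with the
largest vote mass (``mpa``); every statistic carries equal weight, ties
break toward the smaller rating.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discretize import FeatureScheme, discretize
from .errors import ParameterError, SchemaMismatchError, ValidationError
from .features import FEATURE_SCHEMA_VERSION, FeatureMatrix


@dataclass
class Prediction:
    """Predicted rating plus the per-class vote sums behind it."""

    mpa: int
    scores: dict[int, float]


@dataclass
class AmevaModel:
    """Discretization scheme + Cm + AIm for every feature, serializable."""

    classes: list[int]
    feature_names: list[str]
    cuts: list[np.ndarray]           # per feature
    cm: list[np.ndarray]             # per feature, (l, k_f) counts
    aim: list[np.ndarray]            # per feature, (l, k_f) likelihoods
    variant: str = "original"
    schema_version: str = FEATURE_SCHEMA_VERSION
    config_hash: str = ""
    degenerate: bool = False
    missing_classes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        l = len(self.classes)
        f = len(self.feature_names)
        if not (len(self.cuts) == len(self.cm) == len(self.aim) == f):
            raise ValidationError("per-feature arrays inconsistent with feature names")
        for s in range(f):
            k = len(self.cuts[s]) + 1
            if self.cm[s].shape != (l, k) or self.aim[s].shape != (l, k):
                raise ValidationError(f"matrix shapes inconsistent for feature {s}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classes": self.classes,
            "variant": self.variant,
            "schema_version": self.schema_version,
            "config_hash": self.config_hash,
            "degenerate": self.degenerate,
            "missing_classes": self.missing_classes,
            "features": [
                {
                    "name": self.feature_names[s],
                    "cuts": np.asarray(self.cuts[s]).tolist(),
                    "cm": np.asarray(self.cm[s]).tolist(),
                    "aim": np.asarray(self.aim[s]).tolist(),
                }
                for s in range(len(self.feature_names))
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "AmevaModel":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            classes=[int(c) for c in doc["classes"]],
            feature_names=[f["name"] for f in doc["features"]],
            cuts=[np.asarray(f["cuts"], dtype=float) for f in doc["features"]],
            cm=[np.asarray(f["cm"], dtype=float) for f in doc["features"]],
            aim=[np.asarray(f["aim"], dtype=float) for f in doc["features"]],
            variant=doc.get("variant", "original"),
            schema_version=doc.get("schema_version", FEATURE_SCHEMA_VERSION),
            config_hash=doc.get("config_hash", ""),
            degenerate=doc.get("degenerate", False),
            missing_classes=[int(c) for c in doc.get("missing_classes", [])],
        )


def aim_from_counts(cm: np.ndarray) -> np.ndarray:
    """AIm likelihoods from a (classes x intervals) count matrix.

    Classes with zero total contribute probability 0 everywhere.  With a
    single represented class the averaging factor is undefined and the
    within-class probability alone is returned (model flagged degenerate
    by the caller).
    """
    cm = np.asarray(cm, dtype=float)
    totals = cm.sum(axis=1)
    present = totals > 0
    p = np.zeros_like(cm)
    p[present] = cm[present] / totals[present, None]
    l = int(present.sum())
    if l < 2:
        return p
    s = p.sum(axis=0)  # per-interval sum over classes
    # sum_{j != c} (1 - p_j) = (l - 1) - (s - p_c); absent classes add 1 - 0
    # but are excluded from l, matching their exclusion from the class set
    other = ((l - 1) - (s[None, :] - p)) / (l - 1)
    aim = p * other
    aim[~present] = 0.0
    return aim


def fit(features: FeatureMatrix, variant: str = "original") -> AmevaModel:
    """Learn a discretization scheme per feature and tabulate Cm and AIm."""
    if features.labels is None:
        raise ParameterError("fit requires a labeled feature matrix")
    labels = features.labels
    if not np.all(np.isin(labels, [1, 2, 3, 4, 5])):
        raise ParameterError("labels must be ratings in 1..5")
    classes = [1, 2, 3, 4, 5]
    present = sorted(set(int(c) for c in np.unique(labels)))
    missing = [c for c in classes if c not in present]
    degenerate = len(present) < 2
    if degenerate:
        warnings.warn("training data holds a single class; model is degenerate", stacklevel=2)
    if missing and not degenerate:
        warnings.warn(
            f"classes {missing} absent from training; they can never be predicted",
            stacklevel=2,
        )

    codes = np.searchsorted(np.asarray(classes), labels)
    l = len(classes)
    cuts_list, cm_list, aim_list = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-feature single-interval warnings
        for s in range(features.n_features):
            col = features.X[:, s]
            if degenerate:
                scheme = FeatureScheme(np.empty(0))
            else:
                scheme, _ = discretize(col, labels, variant=variant)
            iv = scheme.interval_of(col)
            cm = np.zeros((l, scheme.k))
            np.add.at(cm, (codes, iv), 1)
            cuts_list.append(scheme.cuts)
            cm_list.append(cm)
            aim_list.append(aim_from_counts(cm))

    return AmevaModel(
        classes=classes,
        feature_names=list(features.names),
        cuts=cuts_list,
        cm=cm_list,
        aim=aim_list,
        variant=variant,
        schema_version=features.schema_version,
        config_hash=features.config_hash,
        degenerate=degenerate,
        missing_classes=missing,
    )


def _check_schema(model: AmevaModel, features: FeatureMatrix) -> None:
    if model.schema_version != features.schema_version:
        raise SchemaMismatchError(
            f"model schema {model.schema_version!r} != feature schema "
            f"{features.schema_version!r}"
        )
    if model.feature_names != list(features.names):
        missing = [n for n in model.feature_names if n not in features.names]
        raise SchemaMismatchError(
            f"feature names differ from the model's; missing {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )


def predict_scores(model: AmevaModel, X: np.ndarray) -> np.ndarray:
    """Per-class vote sums for each row of ``X`` (n_windows x l)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if X.shape[1] != len(model.feature_names):
        raise SchemaMismatchError(
            f"{X.shape[1]} features supplied, model expects {len(model.feature_names)}"
        )
    scores = np.zeros((n, len(model.classes)))
    for s in range(X.shape[1]):
        iv = np.searchsorted(model.cuts[s], X[:, s], side="left")
        scores += model.aim[s][:, iv].T
    return scores


def predict(model: AmevaModel, x: np.ndarray, features: FeatureMatrix | None = None) -> Prediction:
    """Predict the rating of one feature vector (Eq.-style vote sum)."""
    scores = predict_scores(model, np.asarray(x, dtype=float)[None, :])[0]
    mpa = model.classes[int(np.argmax(scores))]  # first max -> smaller rating
    return Prediction(mpa=mpa, scores=dict(zip(model.classes, scores.tolist())))


def predict_batch(model: AmevaModel, features: FeatureMatrix) -> np.ndarray:
    """Predicted ratings for every window of a feature matrix."""
    _check_schema(model, features)
    scores = predict_scores(model, features.X)
    return np.asarray(model.classes)[np.argmax(scores, axis=1)]


def majority_rating(window_ratings: np.ndarray) -> int:
    """Per-video rating: majority over window votes, ties to the smaller."""
    vals, counts = np.unique(np.asarray(window_ratings, dtype=int), return_counts=True)
    return int(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------

@dataclass
class ClassResult:
    success: int = 0
    error: int = 0

    @property
    def total(self) -> int:
        return self.success + self.error

    @property
    def accuracy(self) -> float:
        return self.success / self.total if self.total else float("nan")


@dataclass
class CVReport:
    """Aggregated per-class and overall accuracy over the repetitions."""

    per_class: dict[int, ClassResult]
    repetitions: int
    seed: int
    variant: str
    unsplittable: list[int] = field(default_factory=list)

    @property
    def overall_accuracy(self) -> float:
        succ = sum(r.success for r in self.per_class.values())
        tot = sum(r.total for r in self.per_class.values())
        return succ / tot if tot else float("nan")

    def to_text(self) -> str:
        lines = [
            f"Stratified random subsampling: {self.repetitions} repetitions of "
            f"70/15/15 train/validation/test (seed={self.seed}, variant={self.variant})",
            f"{'class':>5} {'success':>8} {'error':>6} {'accuracy':>9}",
        ]
        for c in sorted(self.per_class):
            r = self.per_class[c]
            lines.append(f"{c:>5} {r.success:>8} {r.error:>6} {100 * r.accuracy:>8.1f}%")
        lines.append(f"overall accuracy: {100 * self.overall_accuracy:.1f}%")
        if self.unsplittable:
            lines.append(f"unsplittable classes (too few instances): {self.unsplittable}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {"class": c, "success": r.success, "error": r.error, "accuracy": r.accuracy}
            for c, r in sorted(self.per_class.items())
        ]
        rows.append({
            "class": "overall",
            "success": sum(r.success for r in self.per_class.values()),
            "error": sum(r.error for r in self.per_class.values()),
            "accuracy": self.overall_accuracy,
        })
        pd.DataFrame(rows).to_csv(path, index=False)


def stratified_split(
    labels: np.ndarray,
    rng: np.random.Generator,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    min_per_class: int = 7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """One stratified random train/validation/test split.

    Classes with fewer than ``min_per_class`` instances cannot give every
    part at least one instance under 70/15/15 and are excluded (reported
    as unsplittable).
    """
    train, val, test, unsplittable = [], [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < min_per_class:
            unsplittable.append(int(c))
            continue
        idx = rng.permutation(idx)
        n_tr = int(round(fractions[0] * idx.size))
        n_va = max(1, int(round(fractions[1] * idx.size)))
        n_tr = min(n_tr, idx.size - n_va - 1)
        train.append(idx[:n_tr])
        val.append(idx[n_tr:n_tr + n_va])
        test.append(idx[n_tr + n_va:])
    cat = lambda parts: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=int)
    return cat(train), cat(val), cat(test), unsplittable


def cross_validate(
    features: FeatureMatrix,
    repetitions: int = 10,
    seed: int = 0,
    variant: str = "original",
    merge_validation: bool = True,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> CVReport:
    """Repeated stratified random 70/15/15 subsampling evaluation.

    The protocol runs ``repetitions`` independent stratified random
    splits.  The validation part is merged into training unless a caller
    wants it held out for variant selection (``merge_validation=False``
    keeps it unused).  Success/error counts accumulate over repetitions.
    """
    if features.labels is None:
        raise ParameterError("cross_validate requires labels")
    rng = np.random.default_rng(seed)
    per_class: dict[int, ClassResult] = {}
    unsplittable: list[int] = []
    for _ in range(repetitions):
        tr, va, te, uns = stratified_split(features.labels, rng, fractions)
        unsplittable = sorted(set(unsplittable) | set(uns))
        fit_idx = np.sort(np.concatenate([tr, va])) if merge_validation else tr
        model = fit(features.subset(fit_idx), variant=variant)
        pred = predict_batch(model, features.subset(te))
        truth = features.labels[te]
        for c in np.unique(truth):
            r = per_class.setdefault(int(c), ClassResult())
            sel = truth == c
            r.success += int(np.sum(pred[sel] == c))
            r.error += int(np.sum(pred[sel] != c))
    return CVReport(
        per_class=per_class,
        repetitions=repetitions,
        seed=seed,
        variant=variant,
        unsplittable=unsplittable,
    )
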