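"""Detection scoring, frame metrics, and cross-validation harnesses.

Two cross-validation schemes evaluate generalization:

* **LOSOCV** (leave one subject out) — one fold per subject; the model
  never sees any data from the held-out subject.
* **LOTOCV** (leave one task out) — one fold per (subject, task); the
  training set includes the same subject's other tasks, so subject-
  specific appearance can be exploited.  Held-out no-interaction
  (hand-waving) tasks contribute accuracy but no F1 (they contain no true
  positives); no-interaction tasks that are not held out stay in the
  training set of every fold.

Within each fold the HOG→PCA shape projection is fitted on the training
rows only, one forest is trained on instances pooled from both hands, and
both the prediction track and the ground-truth track of every held-out
(task, hand) are passed through the identical temporal post-processing
before confusion counts are accumulated.  Fold metrics pool frames within
the fold; scheme-level summaries are fold means ± standard deviations.
Every fold is checked for train/test leakage before any training happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import ForestConfig, ScoreTrack, train as train_forest
from .data_model import BoundingBox, Dataset, Side, TaskSequence
from .region_features import (
    FeatureConfig,
    RawInstanceFeatures,
    ShapeProjection,
    extract_task_features,
    feature_schema,
    fit_shape_projection,
    schema_hash,
)
from .temporal_postprocess import PostprocessConfig, postprocess_track

__all__ = [
    "LeakageError",
    "ConfusionCounts",
    "MetricSet",
    "PipelineConfig",
    "Fold",
    "FoldResult",
    "CVResult",
    "iou",
    "match_detections",
    "frame_metrics",
    "make_loso_folds",
    "make_loto_folds",
    "verify_fold",
    "build_feature_cache",
    "run_cv",
    "run_losocv",
    "run_lotocv",
    "interaction_percentage",
    "interaction_percentages",
    "f1_vs_percentage_correlation",
    "always_positive_f1",
    "majority_accuracy",
]

logger = logging.getLogger(__name__)

SeqKey = tuple[str, str]  # (subject_id, task_id)

SIDE_KEYS = [Side.MORE_AFFECTED.value, Side.LESS_AFFECTED.value, "overall"]


class LeakageError(RuntimeError):
    """A fold's training set contains held-out test rows."""


# ---------------------------------------------------------------------------
# detection scoring


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two boxes (half-open)."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_truth_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_truth_negative(self) -> int:
        return self.fp + self.tn


def match_detections(
    pred: Mapping[tuple[int, Side], BoundingBox | Sequence[BoundingBox]],
    truth: Mapping[tuple[int, Side], BoundingBox],
    iou_threshold: float = 0.15,
    units: Optional[Iterable[tuple[int, Side]]] = None,
) -> ConfusionCounts:
    """IoU-match predicted hand boxes against ground truth.

    A predicted box is a true positive when its IoU with the same-frame,
    same-side truth box is strictly above ``iou_threshold`` (at exactly
    the threshold it is a false positive).  With several predictions for
    one unit, the highest-IoU prediction is matched first and the rest
    count as false positives.  Truth boxes left unmatched are false
    negatives; units (frame, side) with neither prediction nor truth are
    true negatives.  ``units`` defaults to the union of the two key sets.
    """
    counts = ConfusionCounts()
    if units is None:
        units = set(pred) | set(truth)
    for unit in units:
        p = pred.get(unit)
        boxes: list[BoundingBox] = [] if p is None else ([p] if isinstance(p, BoundingBox) else list(p))
        t = truth.get(unit)
        if t is None:
            if boxes:
                counts.fp += len(boxes)
            else:
                counts.tn += 1
            continue
        if not boxes:
            counts.fn += 1
            continue
        ious = sorted((iou(b, t) for b in boxes), reverse=True)
        if ious[0] > iou_threshold:
            counts.tp += 1
            counts.fp += len(ious) - 1
        else:
            counts.fp += len(ious)
            counts.fn += 1
    return counts


# ---------------------------------------------------------------------------
# frame metrics


@dataclass
class MetricSet:
    """F1 / precision / recall / accuracy with undefined values as None.

    Precision (and hence F1) is undefined when there are no predicted
    positives; recall (and F1) when there are no true positives — the
    no-interaction-task rule.  Undefined metrics are excluded from
    averages rather than counted as zero.
    """

    f1: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    accuracy: Optional[float]

    @classmethod
    def from_confusion(cls, c: ConfusionCounts) -> "MetricSet":
        precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
        recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
        if precision is None or recall is None or (precision + recall) == 0:
            f1 = None if precision is None or recall is None else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
        return cls(f1=f1, precision=precision, recall=recall, accuracy=accuracy)


def frame_metrics(pred: np.ndarray, truth: np.ndarray) -> MetricSet:
    """Standard binary classification metrics over aligned label vectors."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors must align")
    c = ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )
    return MetricSet.from_confusion(c)


def _confusion_from_vectors(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class Fold:
    fold_id: str
    train_keys: tuple[SeqKey, ...]
    test_keys: tuple[SeqKey, ...]


def make_loso_folds(dataset: Dataset) -> list[Fold]:
    """One fold per subject; all of the subject's tasks are held out."""
    subjects = dataset.subject_ids
    if len(subjects) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    keys = [(s.subject_id, s.task_id) for s in dataset.sequences]
    folds = []
    for subject in subjects:
        test = tuple(k for k in keys if k[0] == subject)
        folds.append(
            Fold(
                fold_id=f"loso:{subject}",
                train_keys=tuple(k for k in keys if k[0] != subject),
                test_keys=test,
            )
        )
    return folds


def make_loto_folds(dataset: Dataset) -> list[Fold]:
    """One fold per (subject, task); every other task is in training."""
    keys = [(s.subject_id, s.task_id) for s in dataset.sequences]
    if len(keys) < 2:
        raise ValueError("LOTOCV needs at least 2 tasks")
    return [
        Fold(
            fold_id=f"loto:{subject}:{task}",
            train_keys=tuple(k for k in keys if k != (subject, task)),
            test_keys=((subject, task),),
        )
        for subject, task in keys
    ]


def verify_fold(fold: Fold) -> None:
    """Raise :class:`LeakageError` if test rows leak into training."""
    overlap = set(fold.train_keys) & set(fold.test_keys)
    if overlap:
        raise LeakageError(
            f"fold {fold.fold_id}: test sequences {sorted(overlap)} appear in training"
        )


# ---------------------------------------------------------------------------
# pipeline configuration and the feature cache


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with the printed defaults."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)
    families: Optional[list[str]] = None  # None = every family of the stage
    iou_threshold: float = 0.15


FeatureCache = dict[SeqKey, dict[Side, RawInstanceFeatures]]


def build_feature_cache(
    dataset: Dataset, config: FeatureConfig = FeatureConfig()
) -> FeatureCache:
    """Extract raw (pre-PCA) features for every sequence once."""
    cache: FeatureCache = {}
    for seq in dataset.sequences:
        cache[(seq.subject_id, seq.task_id)] = extract_task_features(seq, config)
        logger.info("extracted features for %s/%s", seq.subject_id, seq.task_id)
    return cache


def _stage_selection(raw: RawInstanceFeatures, stage: str) -> tuple[np.ndarray, np.ndarray]:
    """(row mask, labels) of the labeled rows for a stage."""
    if stage == "interaction":
        sel = raw.interacting >= 0
        return sel, raw.interacting[sel]
    if stage == "role":
        sel = raw.role >= 0
        return sel, raw.role[sel]
    raise ValueError(f"unknown stage {stage!r}")


def _assemble_rows(
    raw: RawInstanceFeatures,
    sel: np.ndarray,
    stage: str,
    projection: Optional[ShapeProjection],
    config: PipelineConfig,
) -> np.ndarray:
    blocks = {
        "colour": raw.colour,
        "motion": raw.motion,
        "size_change": raw.size_change,
    }
    parts = []
    for name, _ in feature_schema(stage, config.features):
        if config.families is not None and name not in config.families:
            continue
        if name == "shape":
            parts.append(projection.apply(raw.hog_raw[sel]))
        else:
            parts.append(blocks[name][sel])
    if not parts:
        raise ValueError(f"no feature families selected from {config.families!r}")
    return np.concatenate(parts, axis=1)


def _bilateral_keys(cache: FeatureCache) -> set[SeqKey]:
    """Tasks in which both hands carry role labels (bimanual tasks)."""
    out = set()
    for key, sides in cache.items():
        if all(np.any(sides[side].role >= 0) for side in Side):
            out.add(key)
    return out


# ---------------------------------------------------------------------------
# cross-validation results


@dataclass
class FoldResult:
    fold_id: str
    test_subject: str
    test_task: Optional[str]
    is_no_interaction_holdout: bool
    confusions: dict[str, ConfusionCounts]
    metrics: dict[str, MetricSet]
    constant_truth_tracks: int
    n_train_rows: int
    train_keys: tuple[SeqKey, ...]
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class CVResult:
    scheme: str
    stage: str
    folds: list[FoldResult]
    interaction_percentages: dict[tuple[str, str], float]
    schema: str

    def _defined(self, metric: str, side: str) -> list[float]:
        values = []
        for fr in self.folds:
            if fr.skipped:
                continue
            v = getattr(fr.metrics[side], metric)
            if v is not None:
                values.append(v)
        return values

    def mean_metric(self, metric: str, side: str = "overall") -> tuple[float, float]:
        """Mean ± standard deviation of a metric across folds (defined only)."""
        values = self._defined(metric, side)
        if not values:
            return float("nan"), float("nan")
        return float(np.mean(values)), float(np.std(values))

    def mean_f1(self, side: str = "overall") -> float:
        return self.mean_metric("f1", side)[0]

    def mean_accuracy(self, side: str = "overall") -> float:
        return self.mean_metric("accuracy", side)[0]

    def pooled_confusion(self, side: str = "overall") -> ConfusionCounts:
        total = ConfusionCounts()
        for fr in self.folds:
            if not fr.skipped:
                total = total + fr.confusions[side]
        return total

    def subject_confusion(self, subject: str, side: str = "overall") -> ConfusionCounts:
        total = ConfusionCounts()
        for fr in self.folds:
            if not fr.skipped and fr.test_subject == subject:
                total = total + fr.confusions[side]
        return total

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for fr in self.folds:
            if fr.test_subject not in out:
                out.append(fr.test_subject)
        return out

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for side in SIDE_KEYS:
            for metric in ("f1", "precision", "recall", "accuracy"):
                mean, std = self.mean_metric(metric, side)
                rows.append(
                    {
                        "scheme": self.scheme,
                        "stage": self.stage,
                        "side": side,
                        "metric": metric,
                        "mean": mean,
                        "std": std,
                        "n_folds": len(self._defined(metric, side)),
                    }
                )
        return pd.DataFrame(rows)

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            for side in SIDE_KEYS:
                m = fr.metrics.get(side) if not fr.skipped else None
                rows.append(
                    {
                        "fold_id": fr.fold_id,
                        "subject": fr.test_subject,
                        "task": fr.test_task,
                        "side": side,
                        "no_interaction_holdout": fr.is_no_interaction_holdout,
                        "skipped": fr.skipped,
                        "f1": None if m is None else m.f1,
                        "precision": None if m is None else m.precision,
                        "recall": None if m is None else m.recall,
                        "accuracy": None if m is None else m.accuracy,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the harness


def run_cv(
    dataset: Dataset,
    folds: list[Fold],
    stage: str = "interaction",
    config: PipelineConfig = None,
    cache: Optional[FeatureCache] = None,
) -> CVResult:
    """Run the full pipeline over a list of folds.

    Every fold is leakage-checked before training.  Folds whose training
    labels collapse to a single class are skipped with a logged reason.
    """
    if config is None:
        config = PipelineConfig()
    if cache is None:
        cache = build_feature_cache(dataset, config.features)
    schema = schema_hash(stage, config.features)
    seq_by_key = {(s.subject_id, s.task_id): s for s in dataset.sequences}

    fold_results: list[FoldResult] = []
    for fold in folds:
        verify_fold(fold)

        train_X_parts, train_y_parts, train_hogs = [], [], []
        raw_sel = {}
        for key in fold.train_keys:
            for side in Side:
                raw = cache[key][side]
                sel, labels = _stage_selection(raw, stage)
                if sel.any():
                    raw_sel[(key, side)] = (raw, sel, labels)
                    train_hogs.append(raw.hog_raw[sel])
                    train_y_parts.append(labels)

        test_subject = fold.test_keys[0][0]
        test_task = fold.test_keys[0][1] if len(fold.test_keys) == 1 else None
        is_noint_holdout = all(
            seq_by_key[k].is_no_interaction_task for k in fold.test_keys
        )
        y_all = np.concatenate(train_y_parts) if train_y_parts else np.array([])
        if y_all.size == 0 or np.unique(y_all).size < 2:
            logger.warning("fold %s skipped: single-class training labels", fold.fold_id)
            fold_results.append(
                FoldResult(
                    fold_id=fold.fold_id,
                    test_subject=test_subject,
                    test_task=test_task,
                    is_no_interaction_holdout=is_noint_holdout,
                    confusions={},
                    metrics={},
                    constant_truth_tracks=0,
                    n_train_rows=int(y_all.size),
                    train_keys=fold.train_keys,
                    skipped=True,
                    skip_reason="single-class training labels",
                )
            )
            continue

        needs_shape = config.families is None or "shape" in config.families
        projection = None
        if needs_shape:
            projection = fit_shape_projection(
                np.concatenate(train_hogs), config.features.pca_components
            )

        X_train = np.concatenate(
            [
                _assemble_rows(raw, sel, stage, projection, config)
                for (key, side), (raw, sel, labels) in raw_sel.items()
            ]
        )
        model = train_forest(
            X_train,
            y_all,
            schema=schema,
            task=stage,
            config=config.forest,
            trained_on=fold.fold_id,
        )

        confusions = {k: ConfusionCounts() for k in SIDE_KEYS}
        constant_tracks = 0
        for key in fold.test_keys:
            for side in Side:
                raw = cache[key][side]
                sel, labels = _stage_selection(raw, stage)
                if not sel.any():
                    continue
                X_test = _assemble_rows(raw, sel, stage, projection, config)
                scores = model.predict_scores(X_test, schema)
                pred_bin, _ = postprocess_track(scores, config.post)
                truth_bin, truth_const = postprocess_track(
                    labels.astype(float), config.post
                )
                if truth_const:
                    constant_tracks += 1
                c = _confusion_from_vectors(pred_bin, truth_bin)
                confusions[side.value] = confusions[side.value] + c
                confusions["overall"] = confusions["overall"] + c

        fold_results.append(
            FoldResult(
                fold_id=fold.fold_id,
                test_subject=test_subject,
                test_task=test_task,
                is_no_interaction_holdout=is_noint_holdout,
                confusions=confusions,
                metrics={k: MetricSet.from_confusion(v) for k, v in confusions.items()},
                constant_truth_tracks=constant_tracks,
                n_train_rows=int(y_all.size),
                train_keys=fold.train_keys,
            )
        )
        logger.info(
            "fold %s: overall F1=%s", fold.fold_id, fold_results[-1].metrics["overall"].f1
        )

    scheme = "LOSOCV" if folds and folds[0].fold_id.startswith("loso") else "LOTOCV"
    return CVResult(
        scheme=scheme,
        stage=stage,
        folds=fold_results,
        interaction_percentages=interaction_percentages(dataset),
        schema=schema,
    )


def _stage_dataset(
    dataset: Dataset, stage: str, cache: FeatureCache
) -> Dataset:
    """Restrict to bilateral, non-waving tasks for the role stage."""
    if stage != "role":
        return dataset
    bilateral = _bilateral_keys(cache)
    seqs = [s for s in dataset.sequences if (s.subject_id, s.task_id) in bilateral]
    if not seqs:
        raise ValueError("role stage: no bilateral tasks with role labels")
    return Dataset(sequences=seqs, subjects=dataset.subjects)


def run_losocv(
    dataset: Dataset,
    stage: str = "interaction",
    config: PipelineConfig = None,
    cache: Optional[FeatureCache] = None,
) -> CVResult:
    """Leave-one-subject-out cross-validation over the full pipeline."""
    if config is None:
        config = PipelineConfig()
    if cache is None:
        cache = build_feature_cache(dataset, config.features)
    staged = _stage_dataset(dataset, stage, cache)
    return run_cv(staged, make_loso_folds(staged), stage, config, cache)


def run_lotocv(
    dataset: Dataset,
    stage: str = "interaction",
    config: PipelineConfig = None,
    cache: Optional[FeatureCache] = None,
) -> CVResult:
    """Leave-one-task-out cross-validation over the full pipeline."""
    if config is None:
        config = PipelineConfig()
    if cache is None:
        cache = build_feature_cache(dataset, config.features)
    staged = _stage_dataset(dataset, stage, cache)
    return run_cv(staged, make_loto_folds(staged), stage, config, cache)


# ---------------------------------------------------------------------------
# interaction percentages and the F1 correlation


def interaction_percentage(sequences: Iterable[TaskSequence], side: Side) -> Optional[float]:
    """100 × interacting instances / labeled instances for one subject+side.

    Returns None (undefined) when no labeled instances exist.
    """
    n_labeled = 0
    n_interacting = 0
    for seq in sequences:
        for obs in seq.iter_side(side):
            if obs.interacting is not None:
                n_labeled += 1
                if obs.interacting:
                    n_interacting += 1
    if n_labeled == 0:
        return None
    return 100.0 * n_interacting / n_labeled


def interaction_percentages(dataset: Dataset) -> dict[tuple[str, str], float]:
    """Ground-truth interaction percentage per (subject, side) and overall."""
    out: dict[tuple[str, str], float] = {}
    for subject in dataset.subject_ids:
        seqs = dataset.by_subject(subject)
        n_lab, n_pos = 0, 0
        for side in Side:
            pct = interaction_percentage(seqs, side)
            if pct is not None:
                out[(subject, side.value)] = pct
            for seq in seqs:
                for obs in seq.iter_side(side):
                    if obs.interacting is not None:
                        n_lab += 1
                        n_pos += int(obs.interacting)
        if n_lab:
            out[(subject, "overall")] = 100.0 * n_pos / n_lab
    return out


def f1_vs_percentage_correlation(cv: CVResult) -> dict[str, tuple[float, float]]:
    """Pearson correlation of per-subject F1 against interaction percentage.

    Per-subject F1 pools the confusion counts of the subject's test folds.
    Returns ``{side: (r, p)}`` for each hand side and "overall"; a side
    with fewer than 3 subjects carrying a defined F1 yields (nan, nan).
    """
    out: dict[str, tuple[float, float]] = {}
    for side in SIDE_KEYS:
        f1s, pcts = [], []
        for subject in cv.subjects:
            c = cv.subject_confusion(subject, side)
            m = MetricSet.from_confusion(c)
            pct = cv.interaction_percentages.get((subject, side))
            if m.f1 is not None and pct is not None:
                f1s.append(m.f1)
                pcts.append(pct)
        if len(f1s) < 3 or np.std(f1s) == 0 or np.std(pcts) == 0:
            out[side] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(f1s, pcts)
        out[side] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# trivial baselines


def always_positive_f1(cv: CVResult, side: str = "overall") -> float:
    """F1 of predicting every frame positive, on the post-processed truth."""
    c = cv.pooled_confusion(side)
    pos, neg = c.n_truth_positive, c.n_truth_negative
    if pos + neg == 0:
        return float("nan")
    return 2 * pos / (2 * pos + neg)


def majority_accuracy(cv: CVResult, side: str = "overall") -> float:
    """Accuracy of always predicting the majority class of the truth."""
    c = cv.pooled_confusion(side)
    if c.total == 0:
        return float("nan")
    return max(c.n_truth_positive, c.n_truth_negative) / c.total
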