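"""Recording-level evaluation: chunk inference, max pooling, and metrics.

Recordings are scored in 3-second chunks; per class, the recording score is
the maximum over its chunks ("the highest detection score for each species
across all chunks"). Metrics: single-label F1 (macro default), per-class
average precision and mAP, macro AUROC, micro precision/recall at a fixed
threshold, regime-stratified AP, and the foreground/background recall
contrast on two-species recordings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .audio import AudioClip
from .frontend import chunk_recording, compute_mel
from .labels import ClassVocabulary, RecordingAnnotation, data_regime
from .models import ClassifierModel

__all__ = [
    "RecordingPrediction", "MetricsReport", "max_pool_recording",
    "predict_recording", "single_label_f1", "average_precision",
    "mean_average_precision", "auroc", "macro_auroc", "thresholded_pr",
    "foreground_background_recall", "stratified_ap", "multi_label_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecordingPrediction:
    """Per-class scores in [0, 1] after max pooling over a recording's chunks."""

    recording_id: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))


def max_pool_recording(chunk_scores: np.ndarray,
                       recording_id: str = "") -> RecordingPrediction:
    """Elementwise maximum over chunks; ``chunk_scores`` is (chunks, classes)."""
    chunk_scores = np.asarray(chunk_scores, dtype=np.float64)
    if chunk_scores.ndim != 2 or chunk_scores.shape[0] == 0:
        raise ValueError(f"need a non-empty (chunks, classes) matrix, "
                         f"got shape {chunk_scores.shape}")
    return RecordingPrediction(recording_id, chunk_scores.max(axis=0))


def predict_recording(model: ClassifierModel, recording: AudioClip,
                      recording_id: str = "", chunk_seconds: float = 3.0,
                      standardize: bool = True) -> RecordingPrediction:
    """Chunk a recording, score every chunk, and max-pool per class."""
    chunks = chunk_recording(recording, chunk_seconds)
    xs = []
    for chunk in chunks:
        mel = compute_mel(chunk, model.mel_config)
        xs.append(mel.standardized() if standardize else mel.values)
    logits = model.forward_batch(np.stack(xs)).data
    return max_pool_recording(model.activate(logits), recording_id)


# ---------------------------------------------------------------------------
# metrics


def single_label_f1(predictions: list[RecordingPrediction], truths: list[int],
                    averaging: str = "macro") -> float:
    """F1 of argmax predictions; ties go to the lowest class index."""
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be macro or micro, got {averaging!r}")
    n_classes = len(predictions[0].scores)
    pred_labels = np.array([int(np.argmax(p.scores)) for p in predictions])
    truths = np.asarray(truths, dtype=int)
    if averaging == "micro":
        # for single-label top-1 prediction micro-F1 equals accuracy
        return float(np.mean(pred_labels == truths))
    f1s = []
    for c in range(n_classes):
        tp = int(np.sum((pred_labels == c) & (truths == c)))
        fp = int(np.sum((pred_labels == c) & (truths != c)))
        fn = int(np.sum((pred_labels != c) & (truths == c)))
        if tp + fp + fn == 0:
            continue
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


def average_precision(scores, truths) -> float:
    """Area under the precision-recall step curve for one class."""
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truths[order]
    tp_cum = np.cumsum(sorted_truth)
    precision = tp_cum / np.arange(1, len(scores) + 1)
    return float(np.sum(precision * sorted_truth) / n_pos)


def mean_average_precision(score_matrix: np.ndarray,
                           truth_matrix: np.ndarray) -> tuple[float, dict[int, float]]:
    """Unweighted mean AP over classes with >= 1 positive; returns (mAP, per-class)."""
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    truth_matrix = np.asarray(truth_matrix, dtype=int)
    per_class: dict[int, float] = {}
    for c in range(truth_matrix.shape[1]):
        if truth_matrix[:, c].sum() == 0:
            logger.info("class %d has no positives; excluded from mAP", c)
            continue
        per_class[c] = average_precision(score_matrix[:, c], truth_matrix[:, c])
    if not per_class:
        raise ValueError("no class has positives; mAP undefined")
    return float(np.mean(list(per_class.values()))), per_class


def auroc(scores, truths) -> float:
    """Rank-statistic AUROC; ties between scores count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    n_neg = len(truths) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[truths == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def macro_auroc(score_matrix: np.ndarray, truth_matrix: np.ndarray) -> float:
    """Mean AUROC over classes with both positives and negatives."""
    truth_matrix = np.asarray(truth_matrix, dtype=int)
    values = []
    for c in range(truth_matrix.shape[1]):
        col = truth_matrix[:, c]
        if col.sum() == 0 or col.sum() == len(col):
            logger.info("class %d is degenerate; excluded from macro AUROC", c)
            continue
        values.append(auroc(np.asarray(score_matrix)[:, c], col))
    if not values:
        raise ValueError("all classes degenerate; macro AUROC undefined")
    return float(np.mean(values))


def thresholded_pr(score_matrix: np.ndarray, truth_matrix: np.ndarray,
                   threshold: float = 0.2,
                   averaging: str = "micro") -> tuple[float, float]:
    """Precision and recall at a fixed decision threshold (inclusive >=)."""
    if not 0.0 <= threshold <= 1.0 + 1e-12:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(score_matrix, dtype=np.float64)
    truths = np.asarray(truth_matrix, dtype=int)
    decided = scores >= threshold
    if averaging == "micro":
        tp = int(np.sum(decided & (truths == 1)))
        fp = int(np.sum(decided & (truths == 0)))
        fn = int(np.sum(~decided & (truths == 1)))
        if tp + fp == 0:
            logger.warning("no predictions above threshold %.3g; precision "
                           "reported as 0", threshold)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        return float(precision), float(recall)
    if averaging != "macro":
        raise ValueError(f"averaging must be micro or macro, got {averaging!r}")
    precisions, recalls = [], []
    for c in range(truths.shape[1]):
        if truths[:, c].sum() == 0:
            continue
        tp = int(np.sum(decided[:, c] & (truths[:, c] == 1)))
        fp = int(np.sum(decided[:, c] & (truths[:, c] == 0)))
        fn = int(np.sum(~decided[:, c] & (truths[:, c] == 1)))
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn))
    return float(np.mean(precisions)), float(np.mean(recalls))


def foreground_background_recall(
    predictions: dict[str, RecordingPrediction],
    annotations: list[RecordingAnnotation],
    vocab: ClassVocabulary,
    target_species: list[str],
    threshold: float = 0.2,
) -> dict[str, dict[str, float]]:
    """Recall per species, split by foreground vs background instances.

    Restricted to recordings with exactly two labelled species. For each
    target species, recall is measured over recordings where it is the
    primary (foreground) and, separately, where it is the secondary
    (background). Species with no qualifying instances on a side are
    omitted from that side (logged).
    """
    out: dict[str, dict[str, float]] = {}
    for species in target_species:
        idx = vocab.index(species)
        fg_hits, fg_total, bg_hits, bg_total = 0, 0, 0, 0
        for ann in annotations:
            if len(ann.all_species) != 2 or species not in ann.all_species:
                continue
            pred = predictions.get(ann.recording_id)
            if pred is None:
                continue
            detected = pred.scores[idx] >= threshold
            if ann.primary_species == species:
                fg_total += 1
                fg_hits += int(detected)
            else:
                bg_total += 1
                bg_hits += int(detected)
        entry = {}
        if fg_total:
            entry["foreground_recall"] = fg_hits / fg_total
            entry["n_foreground"] = fg_total
        else:
            logger.info("species %s has no foreground instances", species)
        if bg_total:
            entry["background_recall"] = bg_hits / bg_total
            entry["n_background"] = bg_total
        else:
            logger.info("species %s has no background instances", species)
        if entry:
            out[species] = entry
    return out


def stratified_ap(per_class_ap: dict[str, float],
                  per_class_counts: dict[str, int]) -> dict[str, dict]:
    """Group per-class AP by data regime; report median and quartiles."""
    groups: dict[str, list[float]] = {"low": [], "medium": [], "high": []}
    for cls, ap in per_class_ap.items():
        if cls not in per_class_counts:
            raise KeyError(f"no recording count for class {cls!r}")
        groups[data_regime(per_class_counts[cls])].append(ap)
    out = {}
    for regime, aps in groups.items():
        if aps:
            q1, med, q3 = np.percentile(aps, [25, 50, 75])
            out[regime] = {"n": len(aps), "median": float(med),
                           "q1": float(q1), "q3": float(q3), "aps": aps}
        else:
            out[regime] = {"n": 0, "median": None, "q1": None, "q3": None,
                           "aps": []}
    return out


@dataclass
class MetricsReport:
    """Bundle of evaluation results; serializes to JSON/CSV."""

    f1_macro: float | None = None
    f1_micro: float | None = None
    map: float | None = None
    auroc_macro: float | None = None
    per_class_ap: dict[str, float] = field(default_factory=dict)
    precision_at_threshold: float | None = None
    recall_at_threshold: float | None = None
    threshold: float | None = None
    stratified: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def multi_label_report(score_matrix: np.ndarray, truth_matrix: np.ndarray,
                       vocab: ClassVocabulary, threshold: float = 0.2,
                       per_class_counts: dict[str, int] | None = None
                       ) -> MetricsReport:
    """Full multi-label evaluation: mAP, macro AUROC, thresholded P/R."""
    map_value, per_class = mean_average_precision(score_matrix, truth_matrix)
    named_ap = {vocab.classes[c]: ap for c, ap in per_class.items()}
    precision, recall = thresholded_pr(score_matrix, truth_matrix, threshold)
    report = MetricsReport(
        map=map_value,
        auroc_macro=macro_auroc(score_matrix, truth_matrix),
        per_class_ap=named_ap,
        precision_at_threshold=precision,
        recall_at_threshold=recall,
        threshold=threshold,
    )
    if per_class_counts is not None:
        report.stratified = stratified_ap(
            named_ap, {c: per_class_counts.get(c, 0) for c in named_ap})
    return report
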