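"""Event-level evaluation: onset–annotation matching, confusion metrics,
and recording-grouped cross-validation.

Evaluation is at event level.  An annotated interval counts as detected when
at least one onset falls inside it (multiple onsets collapse to one hit);
onsets inside no interval are false alarms of the gate.  For the classifier,
sensitivity is the fraction of cough candidates classified cough and
specificity the fraction of non-cough candidates classified non-cough.

Cross-validation folds are assigned per *recording*, never per segment, so
segments cut from one recording can never straddle the train/validation
boundary — performance estimates then reflect unseen recording conditions
rather than memorised room acoustics.

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .classifier import (
    ClassifierConfig,
    LabeledExample,
    build_model,
    train as train_classifier,
)

__all__ = [
    "AnnotatedInterval",
    "ConfusionCounts",
    "EvalResult",
    "FoldAssignment",
    "match_onsets",
    "detection_rate",
    "confusion_metrics",
    "make_grouped_folds",
    "cross_validate",
]


def round_half_up_1(x: float) -> float:
    """Round to one decimal with ties away from zero, as results are printed."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnnotatedInterval:
    """A labeled ground-truth time span within one recording."""

    recording_id: str
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise ValueError(f"need start_s < end_s, got [{self.start_s}, {self.end_s})")

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts plus the derived percentages (None where undefined)."""

    counts: ConfusionCounts
    sensitivity_pct: float | None
    specificity_pct: float | None
    detection_rate_pct: float | None = None


@dataclass(frozen=True)
class FoldAssignment:
    """recording_id -> fold index; every recording in exactly one fold."""

    mapping: dict[str, int]
    k: int

    def fold_ids(self, fold: int) -> set[str]:
        return {rid for rid, f in self.mapping.items() if f == fold}

    def train_ids(self, fold: int) -> set[str]:
        return {rid for rid, f in self.mapping.items() if f != fold}


def _merge_intervals(intervals: list[AnnotatedInterval]) -> list[AnnotatedInterval]:
    """Merge overlapping same-label intervals (annotations imply disjoint events)."""
    out: list[AnnotatedInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.label, v.start_s)):
        if out and out[-1].label == iv.label and iv.start_s < out[-1].end_s:
            prev = out.pop()
            iv = AnnotatedInterval(
                recording_id=iv.recording_id,
                start_s=prev.start_s,
                end_s=max(prev.end_s, iv.end_s),
                label=iv.label,
            )
        out.append(iv)
    out.sort(key=lambda v: v.start_s)
    return out


def match_onsets(detected, truth: list[AnnotatedInterval]) -> tuple[int, int, int]:
    """Count (detected intervals, missed intervals, onsets outside any interval).

    An interval is detected iff >= 1 onset lies within ``[start_s, end_s)``;
    extra onsets in the same interval do not count it again.

    ``detected`` is a list of onset events or plain times (seconds).

    Raises
    ------
    ValueError
        If the truth intervals span more than one recording.
    """
    if len({iv.recording_id for iv in truth}) > 1:
        raise ValueError("match_onsets operates on a single recording at a time")
    times = [getattr(o, "time_s", o) for o in detected]
    merged = _merge_intervals(list(truth))
    hit = [False] * len(merged)
    outside = 0
    for t in times:
        inside = False
        for j, iv in enumerate(merged):
            if iv.contains(t):
                hit[j] = True
                inside = True
                break
        if not inside:
            outside += 1
    n_hit = sum(hit)
    return n_hit, len(merged) - n_hit, outside


def detection_rate(detected_positive: int, total_positive: int) -> float:
    """Percentage of annotated events detected, rounded half-up to one decimal."""
    if total_positive <= 0:
        raise ValueError("total_positive must be > 0")
    return round_half_up_1(100.0 * detected_positive / total_positive)


def confusion_metrics(counts: ConfusionCounts) -> EvalResult:
    """Sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp).

    A metric with a zero denominator is reported as ``None`` (missing), never
    silently as 0 or 100.
    """
    sens = (
        round_half_up_1(100.0 * counts.tp / (counts.tp + counts.fn))
        if counts.tp + counts.fn > 0
        else None
    )
    spec = (
        round_half_up_1(100.0 * counts.tn / (counts.tn + counts.fp))
        if counts.tn + counts.fp > 0
        else None
    )
    return EvalResult(counts=counts, sensitivity_pct=sens, specificity_pct=spec)


def make_grouped_folds(recording_ids: list[str], k: int, seed: int) -> FoldAssignment:
    """Deterministic seeded shuffle then round-robin assignment of recordings.

    Fold sizes differ by at most one, and grouping holds by construction.

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of distinct recordings.
    """
    distinct = sorted(set(recording_ids))
    if k < 1 or k > len(distinct):
        raise ValueError(f"need 1 <= k <= {len(distinct)} distinct recordings, got k={k}")
    rng = np.random.default_rng(seed)
    order = list(distinct)
    rng.shuffle(order)
    return FoldAssignment(mapping={rid: i % k for i, rid in enumerate(order)}, k=k)


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def average_results(fold_results: list[EvalResult]) -> EvalResult:
    """Arithmetic mean of per-fold percentages (missing values excluded)."""
    sens = [r.sensitivity_pct for r in fold_results if r.sensitivity_pct is not None]
    spec = [r.specificity_pct for r in fold_results if r.specificity_pct is not None]
    total = ConfusionCounts(
        tp=sum(r.counts.tp for r in fold_results),
        fn=sum(r.counts.fn for r in fold_results),
        fp=sum(r.counts.fp for r in fold_results),
        tn=sum(r.counts.tn for r in fold_results),
    )
    return EvalResult(
        counts=total,
        sensitivity_pct=round_half_up_1(float(np.mean(sens))) if sens else None,
        specificity_pct=round_half_up_1(float(np.mean(spec))) if spec else None,
    )


def cross_validate(
    examples: list[LabeledExample],
    k: int,
    config: ClassifierConfig,
    threshold: float = 0.5,
    seed: int | None = None,
) -> tuple[list[EvalResult], EvalResult, FoldAssignment]:
    """Recording-grouped k-fold cross-validation of the classifier.

    A fresh model is trained per fold with a fold-specific child seed; the
    averaged result is the arithmetic mean of per-fold sensitivity and
    specificity.

    Raises
    ------
    ValueError
        If any fold's validation set contains a single class (re-seed or
        enlarge the corpus).
    """
    seed = config.seed if seed is None else seed
    folds = make_grouped_folds([ex.recording_id for ex in examples], k, seed)
    y = np.array([1 if ex.label == "cough" else 0 for ex in examples])
    rec = np.array([ex.recording_id for ex in examples])

    for fold in range(k):
        val_ids = folds.fold_ids(fold)
        y_val = y[np.isin(rec, sorted(val_ids))]
        if len(np.unique(y_val)) < 2:
            raise ValueError(
                f"validation fold {fold} contains a single class; "
                "re-seed the fold assignment or enlarge the corpus"
            )

    fold_results: list[EvalResult] = []
    for fold in range(k):
        val_ids = folds.fold_ids(fold)
        in_val = np.isin(rec, sorted(val_ids))
        assert not (set(rec[in_val]) & set(rec[~in_val])), "recording leakage across folds"
        train_ex = [ex for ex, v in zip(examples, in_val) if not v]
        val_ex = [ex for ex, v in zip(examples, in_val) if v]
        fold_cfg = ClassifierConfig(
            lstm_layers=config.lstm_layers,
            lstm_units=config.lstm_units,
            fc_units=config.fc_units,
            dropout_p=config.dropout_p,
            n_classes=config.n_classes,
            train_params=config.train_params,
            seed=int(np.random.default_rng([seed, fold]).integers(0, 2**31)),
        )
        model = build_model(fold_cfg, train_ex[0].spectrogram.params)
        train_classifier(model, train_ex, fold_cfg)
        p = model.predict_proba([ex.spectrogram for ex in val_ex])
        y_pred = (p >= threshold).astype(int)
        y_val = y[in_val]
        fold_results.append(confusion_metrics(_counts_from_predictions(y_val, y_pred)))
    return fold_results, average_results(fold_results), folds
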