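"""Leave-one-subject-out evaluation: folds, metrics, reports, comparisons.

The evaluation contract mirrors subject-independent affective-computing
practice: every subject is held out exactly once, models train on all other
subjects' windows (optionally including time-shift augmented copies), and
the held-out subject is scored on base (non-augmented) windows only.  The
cohort-level figure is the unweighted mean of the per-fold window accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import DataError, ValidationError
from .estimators import (
    MODALITY_ORDER,
    CNNClassifier,
    EarlyFusionCNN,
    LateFusionCNN,
    MidFusionCNN,
)
from .models import FusionWeights, TrainConfig
from .preprocess import (
    AugmentationConfig,
    SegmentationConfig,
    augment,
    preprocess_recording,
    segment,
)
from .synthetic import LEVELS

__all__ = [
    "TaskSpec",
    "FoldSplit",
    "MetricReport",
    "FoldResult",
    "ExperimentReport",
    "PairedComparison",
    "loso_splits",
    "confusion",
    "binary_metrics",
    "multiclass_metrics",
    "run_experiment",
    "summarize_fusion_weights",
    "paired_comparison",
]

MODEL_CHOICES = ("eda", "emg", "ecg", "early_fusion", "mid_fusion", "late_fusion")


@dataclass(frozen=True)
class TaskSpec:
    """A classification task: a binary level pair or the full 5-class problem."""

    kind: str  # "binary" | "multiclass"
    levels: tuple[str, ...]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if len(self.levels) != 2:
                raise ValidationError("binary task requires exactly 2 levels")
        elif self.kind == "multiclass":
            if tuple(self.levels) != LEVELS:
                raise ValidationError("multiclass task requires all five levels")
        else:
            raise ValidationError(f"unknown task kind {self.kind!r}")
        if self.positive_class is not None and self.positive_class not in self.levels:
            raise ValidationError("positive_class must be one of the task levels")

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    @property
    def positive_index(self) -> int:
        if self.kind != "binary":
            raise ValidationError("positive_index is defined for binary tasks only")
        pos = self.positive_class if self.positive_class is not None else self.levels[-1]
        return self.levels.index(pos)

    @classmethod
    def binary(cls, low: str = "T0", high: str = "T4") -> "TaskSpec":
        return cls(kind="binary", levels=(low, high), positive_class=high)

    @classmethod
    def multiclass(cls) -> "TaskSpec":
        return cls(kind="multiclass", levels=LEVELS)


@dataclass(frozen=True)
class FoldSplit:
    test_subject: str
    train_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.test_subject in self.train_subjects:
            raise ValidationError("test subject must not appear in train subjects")


def loso_splits(subject_ids: Sequence[str]) -> list[FoldSplit]:
    """One fold per subject, each subject held out exactly once (sorted order)."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids")
    if len(ids) < 2:
        raise ValidationError("leave-one-subject-out requires >= 2 subjects")
    ids = sorted(ids)
    return [
        FoldSplit(test_subject=sid, train_subjects=tuple(s for s in ids if s != sid))
        for sid in ids
    ]


def confusion(y_true, y_pred, c: int) -> np.ndarray:
    """c x c count matrix, rows = truth, columns = prediction (integer labels)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.shape} truth vs {y_pred.shape} predictions"
        )
    if len(y_true) == 0:
        return np.zeros((c, c), dtype=int)
    return _sk_confusion(y_true, y_pred, labels=np.arange(c))


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.per_class is not None:
            d["per_class"] = self.per_class
        return d


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def binary_metrics(cm: np.ndarray, positive: int = 1) -> MetricReport:
    """Accuracy, precision, recall and F1 from a 2x2 count matrix."""
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise ValidationError(f"binary metrics need a 2x2 matrix, got {cm.shape}")
    p = positive
    tp = cm[p, p]
    fn = cm[p].sum() - tp
    fp = cm[:, p].sum() - tp
    tn = cm.sum() - tp - fn - fp
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    return MetricReport(
        accuracy=_safe_div(tp + tn, cm.sum(), "accuracy"),
        precision=precision,
        recall=recall,
        f1=_safe_div(2 * precision * recall, precision + recall, "F1"),
    )


def multiclass_metrics(cm: np.ndarray) -> MetricReport:
    """Class-averaged one-vs-rest accuracy/precision/recall and macro F1."""
    cm = np.asarray(cm)
    c = cm.shape[0]
    if cm.shape != (c, c) or c < 2:
        raise ValidationError(f"need a square confusion matrix, got {cm.shape}")
    n = cm.sum()
    accs, precs, recs, f1s = [], [], [], []
    per_class = {}
    for i in range(c):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        acc_i = _safe_div(tp + tn, n, f"class-{i} accuracy")
        prec_i = _safe_div(tp, tp + fp, f"class-{i} precision")
        rec_i = _safe_div(tp, tp + fn, f"class-{i} recall")
        f1_i = _safe_div(2 * prec_i * rec_i, prec_i + rec_i, f"class-{i} F1")
        accs.append(acc_i)
        precs.append(prec_i)
        recs.append(rec_i)
        f1s.append(f1_i)
        per_class[i] = {
            "accuracy": acc_i,
            "precision": prec_i,
            "recall": rec_i,
            "f1": f1_i,
        }
    return MetricReport(
        accuracy=float(np.mean(accs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        per_class=per_class,
    )


@dataclass
class FoldResult:
    split: FoldSplit
    metrics: MetricReport
    confusion: np.ndarray
    fusion_weights: FusionWeights | None = None


@dataclass
class ExperimentReport:
    """Per-fold and aggregated LOSO results for one task/model pair."""

    task: TaskSpec
    model_choice: str
    per_fold: list[FoldResult]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.metrics.accuracy for f in self.per_fold])

    def total_confusion(self) -> np.ndarray:
        return np.sum([f.confusion for f in self.per_fold], axis=0)

    def as_dict(self) -> dict:
        return {
            "task": {
                "kind": self.task.kind,
                "levels": list(self.task.levels),
                "positive_class": self.task.positive_class,
            },
            "model": self.model_choice,
            "mean": self.mean,
            "sd": self.sd,
            "per_fold": [
                {
                    "test_subject": f.split.test_subject,
                    "metrics": f.metrics.as_dict(),
                    "confusion": f.confusion.tolist(),
                    "fusion_weights": (
                        list(f.fusion_weights.alpha) if f.fusion_weights else None
                    ),
                }
                for f in self.per_fold
            ],
        }


def _aggregate(per_fold: list[FoldResult]) -> tuple[dict, dict]:
    names = ("accuracy", "precision", "recall", "f1")
    mean = {}
    sd = {}
    for name in names:
        vals = np.array([getattr(f.metrics, name) for f in per_fold], dtype=float)
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def _build_model(model_choice: str, cfg: TrainConfig, fold_seed: int):
    kwargs = dict(
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        dropout_rate=cfg.dropout_rate,
        random_state=fold_seed,
    )
    if model_choice == "eda":
        return CNNClassifier(architecture="eda", **kwargs)
    if model_choice in ("emg", "ecg"):
        return CNNClassifier(architecture="emg_ecg", **kwargs)
    if model_choice == "early_fusion":
        return EarlyFusionCNN(**kwargs)
    if model_choice == "mid_fusion":
        return MidFusionCNN(**kwargs)
    if model_choice == "late_fusion":
        return LateFusionCNN(**kwargs)
    raise ValidationError(
        f"unknown model_choice {model_choice!r}; expected one of {MODEL_CHOICES}"
    )


def _prepare_subject(
    rec,
    labels,
    task: TaskSpec,
    seg_cfg: SegmentationConfig,
    aug_cfg: AugmentationConfig | None,
):
    task_labels = [l for l in labels if l.level in task.levels]
    if not task_labels:
        raise DataError(
            f"subject {rec.subject_id} has no trials for levels {task.levels}"
        )
    if abs(rec.fs_hz - seg_cfg.fs_hz) > 1e-6:
        rec = preprocess_recording(rec, target_fs_hz=seg_cfg.fs_hz)
    if aug_cfg is None:
        segs = segment(rec, task_labels, seg_cfg)
    else:
        segs = augment(rec, task_labels, seg_cfg, aug_cfg)
    # stack (n, 3, L) in the fixed (EDA, EMG, ECG) modality order
    ref = segs[MODALITY_ORDER[0]]
    X = np.stack([segs[m].data[:, :, 0] for m in MODALITY_ORDER], axis=1)
    return {
        "X": X,
        "y": ref.labels,
        "is_augmented": ref.is_augmented,
        "subject_ids": ref.subject_ids,
    }


def _resolve_cohort(cohort):
    from . import io as pio

    if isinstance(cohort, (str, Path)):
        cohort = pio.read_manifest(Path(cohort))
    if isinstance(cohort, pio.DatasetManifest):
        loaded = []
        for sid, rec_file, label_file in cohort.subjects:
            rec = pio.read_recording(cohort.root / rec_file, subject_id=sid)
            labels = pio.read_labels(cohort.root / label_file)
            loaded.append((rec, labels))
        return loaded
    return list(cohort)


def run_experiment(
    cohort,
    task: TaskSpec,
    model_choice: str = "late_fusion",
    train_cfg: TrainConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> ExperimentReport:
    """LOSO cross-validation of one model on one task.

    ``cohort`` is a manifest (path or object) or an in-memory list of
    ``(recording, labels)`` pairs.  Each fold trains on all other subjects'
    windows (augmented copies included when ``aug_cfg`` is given) and
    evaluates on the held-out subject's base windows only; augmented windows
    never enter evaluation, and no window of the test subject ever enters
    training (asserted by a subject-id audit).
    """
    train_cfg = train_cfg or TrainConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    pairs = _resolve_cohort(cohort)
    prepared = {}
    for rec, labels in pairs:
        prepared[rec.subject_id] = _prepare_subject(rec, labels, task, seg_cfg, aug_cfg)
    folds = loso_splits(list(prepared))
    level_to_idx = {lev: i for i, lev in enumerate(task.levels)}
    modality_idx = (
        MODALITY_ORDER.index(model_choice) if model_choice in MODALITY_ORDER else None
    )
    per_fold: list[FoldResult] = []
    for k, split in enumerate(folds):
        train_parts = [prepared[s] for s in split.train_subjects]
        X_train = np.concatenate([p["X"] for p in train_parts])
        y_train = np.concatenate([p["y"] for p in train_parts])
        train_sids = np.concatenate([p["subject_ids"] for p in train_parts])
        if np.any(train_sids == split.test_subject):  # LOSO integrity audit
            raise ValidationError(
                f"fold {k}: test subject {split.test_subject} leaked into training"
            )
        test_part = prepared[split.test_subject]
        keep = ~test_part["is_augmented"]
        X_test = test_part["X"][keep]
        y_test = test_part["y"][keep]
        missing = [lev for lev in task.levels if lev not in set(y_train)]
        if missing:
            raise DataError(f"fold {k}: training data lacks level(s) {missing}")
        if modality_idx is not None:
            X_train_in, X_test_in = X_train[:, modality_idx], X_test[:, modality_idx]
        else:
            X_train_in, X_test_in = X_train, X_test
        model = _build_model(model_choice, train_cfg, train_cfg.seed + k)
        model.fit(X_train_in, y_train)
        y_pred = model.predict(X_test_in)
        cm = confusion(
            [level_to_idx[l] for l in y_test],
            [level_to_idx[l] for l in y_pred],
            task.n_classes,
        )
        if task.kind == "binary":
            metrics = binary_metrics(cm, positive=task.positive_index)
        else:
            metrics = multiclass_metrics(cm)
        weights = getattr(model, "fusion_weights_", None)
        per_fold.append(
            FoldResult(split=split, metrics=metrics, confusion=cm, fusion_weights=weights)
        )
    mean, sd = _aggregate(per_fold)
    return ExperimentReport(
        task=task, model_choice=model_choice, per_fold=per_fold, mean=mean, sd=sd
    )


def summarize_fusion_weights(report: ExperimentReport) -> dict[str, dict[str, float]]:
    """Mean/median/quartiles of the learned alpha per modality over folds."""
    if any(f.fusion_weights is None for f in report.per_fold):
        raise TypeError(
            "fusion-weight summary requires a late-fusion report "
            f"(got model {report.model_choice!r})"
        )
    alphas = np.array([f.fusion_weights.alpha for f in report.per_fold])  # (folds, 3)
    out = {}
    for i, mod in enumerate(MODALITY_ORDER):
        col = alphas[:, i]
        out[mod] = {
            "mean": float(col.mean()),
            "median": float(np.median(col)),
            "q25": float(np.percentile(col, 25)),
            "q75": float(np.percentile(col, 75)),
        }
    return out


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-fold accuracies."""

    statistic: float
    p_value: float
    n_nonzero: int
    significant: bool
    insufficient_n: bool


def paired_comparison(
    report_a: ExperimentReport, report_b: ExperimentReport, alpha: float = 0.05
) -> PairedComparison:
    """Compare two LOSO reports on identical folds (zero differences excluded;
    exact null for small n, normal approximation otherwise)."""
    subjects_a = [f.split.test_subject for f in report_a.per_fold]
    subjects_b = [f.split.test_subject for f in report_b.per_fold]
    if subjects_a != subjects_b:
        raise ValidationError("reports cover different folds; cannot pair them")
    diffs = report_a.fold_accuracies() - report_b.fold_accuracies()
    n_nonzero = int(np.count_nonzero(diffs))
    # two-sided exact signed-rank needs >= 6 non-zero pairs to ever reach p < 0.05
    insufficient = n_nonzero < 6
    if n_nonzero == 0:
        return PairedComparison(0.0, 1.0, 0, False, insufficient)
    res = _stats.wilcoxon(
        report_a.fold_accuracies(),
        report_b.fold_accuracies(),
        zero_method="wilcox",
        alternative="two-sided",
        method="auto",
    )
    return PairedComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_nonzero=n_nonzero,
        significant=bool(res.pvalue < alpha) and not insufficient,
        insufficient_n=insufficient,
    )
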