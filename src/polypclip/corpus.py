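"""Data model, metadata I/O, patient-level fold construction, and metrics.

An endoscopy corpus is a flat image folder plus a tab-separated metadata table
(columns ``filename``, ``label``, ``patient_id``, optional ``text``). All
evaluation splits are made at the patient level: every image of a patient lands
on exactly one side of a split, which prevents identity leakage between train
and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

__all__ = [
    "CLASSES",
    "ImageSample",
    "SplitPlan",
    "ConfusionMatrix",
    "Metrics",
    "load_dataset",
    "patient_level_folds",
    "compute_metrics",
]

#: The three polyp subtype classes, in canonical order.
CLASSES = ("adenoma", "hyperplasia", "normal")


@dataclass
class ImageSample:
    """One endoscopy frame with its class label and patient identity."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    label: str
    patient_id: str
    text: str | None = None
    source_path: Path | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got shape {self.image.shape}")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class SplitPlan:
    """Patient-level cross-validation folds: (train-patients, test-patients) pairs."""

    folds: list[tuple[set[str], set[str]]]
    seed: int

    def __post_init__(self):
        all_test: set[str] = set()
        for train, test in self.folds:
            if train & test:
                raise ValueError("train and test patient sets overlap within a fold")
            if all_test & test:
                raise ValueError("a patient appears in more than one test set")
            all_test |= test

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "folds": [
                {"train": sorted(tr), "test": sorted(te)} for tr, te in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            folds=[(set(f["train"]), set(f["test"])) for f in payload["folds"]],
            seed=payload["seed"],
        )


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Metrics:
    """Accuracy plus per-class and macro precision/recall/F1 (one-vs-rest)."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                }
                for c in self.confusion.classes
            },
            "confusion": self.confusion.counts.tolist(),
        }


def load_dataset(
    image_root: str | Path,
    metadata: str | Path,
    classes: tuple[str, ...] = CLASSES,
) -> list[ImageSample]:
    """Read a TSV metadata table and its images into a list of samples.

    The table must have columns ``filename``, ``label``, ``patient_id`` and may
    have a free-text ``text`` column. Images are decoded as RGB and rescaled to
    [0, 1]. Row order is preserved.
    """
    image_root = Path(image_root)
    df = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
    required = {"filename", "label", "patient_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    samples: list[ImageSample] = []
    for idx, row in df.iterrows():
        if row["label"] not in classes:
            raise ValueError(
                f"row {idx}: unrecognized label {row['label']!r}; "
                f"allowed labels are {list(classes)}"
            )
        if not row["patient_id"]:
            raise ValueError(f"row {idx}: missing or empty patient_id")
        path = image_root / row["filename"]
        if not path.is_file():
            raise FileNotFoundError(f"row {idx}: image file not found: {path}")
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        samples.append(
            ImageSample(
                image=arr,
                label=row["label"],
                patient_id=row["patient_id"],
                text=row.get("text") or None,
                source_path=path,
            )
        )
    return samples


def patient_level_folds(
    samples: list[ImageSample], k: int, seed: int
) -> SplitPlan:
    """Partition patients into ``k`` class-stratified, balanced folds.

    Each patient is stratified by their (single) majority class; within every
    class stratum the fold sizes differ by at most one. Images never split
    across folds because assignment is per patient.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    # majority class per patient
    by_patient: dict[str, list[str]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s.label)
    patients = sorted(by_patient)
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for p in patients:
        labels = by_patient[p]
        majority = max(sorted(set(labels)), key=labels.count)
        strata.setdefault(majority, []).append(p)

    fold_sets: list[set[str]] = [set() for _ in range(k)]
    pointer = 0  # continuous round-robin across strata keeps totals balanced
    for cls in sorted(strata):
        members = list(strata[cls])
        rng.shuffle(members)
        for p in members:
            fold_sets[pointer % k].add(p)
            pointer += 1

    all_patients = set(patients)
    folds = [(all_patients - test, test) for test in fold_sets]
    return SplitPlan(folds=folds, seed=seed)


def compute_metrics(
    y_true: list[str], y_pred: list[str], classes: tuple[str, ...] = CLASSES
) -> Metrics:
    """Confusion matrix, accuracy, and one-vs-rest precision/recall/F1.

    Macro values are unweighted means over classes. Zero denominators yield 0
    (a class never predicted has precision 0; F1 is 0 when P + R = 0).
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    unknown = set(y_true) | set(y_pred) - set(classes)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    cm = _sk_confusion(y_true, y_pred, labels=list(classes))
    prec, rec, f1, _ = _sk_prfs(
        y_true, y_pred, labels=list(classes), zero_division=0, average=None
    )
    confusion = ConfusionMatrix(counts=cm, classes=tuple(classes))
    accuracy = float(np.trace(cm)) / max(confusion.total, 1)
    return Metrics(
        accuracy=accuracy,
        precision={c: float(p) for c, p in zip(classes, prec)},
        recall={c: float(r) for c, r in zip(classes, rec)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        confusion=confusion,
    )
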