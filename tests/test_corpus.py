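"""Corpus I/O, patient-level folds, and classification metrics."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

import polypclip as pc
from polypclip.corpus import CLASSES, compute_metrics, load_dataset, patient_level_folds


def _write_corpus(tmp_path, rows):
    img_dir = tmp_path / "images"
    img_dir.mkdir()
    rng = np.random.default_rng(0)
    for r in rows:
        arr = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        Image.fromarray(arr).save(img_dir / r["filename"])
    meta = tmp_path / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    return img_dir, meta


def test_load_dataset_reads_rows_in_order(tmp_path):
    rows = [
        {"filename": "a.png", "label": "adenoma", "patient_id": "P1", "text": "t1"},
        {"filename": "b.png", "label": "hyperplasia", "patient_id": "P2", "text": ""},
        {"filename": "c.png", "label": "normal", "patient_id": "P1", "text": "t3"},
    ]
    img_dir, meta = _write_corpus(tmp_path, rows)
    samples = load_dataset(img_dir, meta)
    assert [s.label for s in samples] == ["adenoma", "hyperplasia", "normal"]
    assert [s.patient_id for s in samples] == ["P1", "P2", "P1"]
    assert samples[1].text is None  # empty text column becomes None
    assert all(0 <= s.image.min() and s.image.max() <= 1 for s in samples)


def test_load_dataset_rejects_unknown_label(tmp_path):
    rows = [{"filename": "a.png", "label": "adenocarcinoma", "patient_id": "P1"}]
    img_dir, meta = _write_corpus(tmp_path, rows)
    with pytest.raises(ValueError, match="adenoma"):
        load_dataset(img_dir, meta)


def test_load_dataset_rejects_missing_patient_and_file(tmp_path):
    rows = [{"filename": "a.png", "label": "normal", "patient_id": ""}]
    img_dir, meta = _write_corpus(tmp_path, rows)
    with pytest.raises(ValueError, match="patient_id"):
        load_dataset(img_dir, meta)
    rows = [{"filename": "ghost.png", "label": "normal", "patient_id": "P1"}]
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    with pytest.raises(FileNotFoundError, match="row 0"):
        load_dataset(img_dir, meta)


def _fake_samples(patient_labels):
    img = np.zeros((1, 1, 3))
    return [
        pc.ImageSample(image=img, label=lbl, patient_id=pid)
        for pid, lbl in patient_labels
    ]


def test_five_patients_five_folds_each_test_is_one_patient():
    samples = _fake_samples([(f"P{i}", "adenoma") for i in range(5)])
    plan = patient_level_folds(samples, k=5, seed=0)
    assert sorted(len(te) for _, te in plan.folds) == [1] * 5


def test_study_shaped_patient_counts_balance():
    # 39/36/16 patients per class, five folds -> test sizes {19,18,18,18,18}
    labels = ["adenoma"] * 39 + ["hyperplasia"] * 36 + ["normal"] * 16
    samples = _fake_samples([(f"P{i:03d}", l) for i, l in enumerate(labels)])
    plan = patient_level_folds(samples, k=5, seed=3)
    sizes = sorted((len(te) for _, te in plan.folds), reverse=True)
    assert sizes == [19, 18, 18, 18, 18]
    # within-class stratum sizes differ by at most one across folds
    for cls, total in (("adenoma", 39), ("hyperplasia", 36), ("normal", 16)):
        members = {s.patient_id for s in samples if s.label == cls}
        per_fold = [len(te & members) for _, te in plan.folds]
        assert max(per_fold) - min(per_fold) <= 1 and sum(per_fold) == total


def test_fold_disjointness_over_many_random_corpora():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(5, 40))
        labels = rng.choice(CLASSES, size=n)
        samples = _fake_samples(
            [(f"P{i}", labels[i]) for i in range(n)]
        )
        k = int(rng.integers(2, min(6, n + 1)))
        plan = patient_level_folds(samples, k=k, seed=int(rng.integers(1 << 30)))
        all_patients = {s.patient_id for s in samples}
        seen = set()
        for train, test in plan.folds:
            assert not train & test
            assert not seen & test
            seen |= test
        assert seen == all_patients


def test_too_few_patients_raises():
    samples = _fake_samples([("P1", "normal"), ("P2", "normal")])
    with pytest.raises(ValueError, match="at least"):
        patient_level_folds(samples, k=3, seed=0)


def test_metrics_match_hand_computed_confusion_matrix():
    # confusion rows (true x pred) for A,B,N:
    #   A: [1,1,0], B: [0,2,0], N: [1,0,1]
    y_true = ["adenoma", "adenoma", "hyperplasia", "hyperplasia", "normal", "normal"]
    y_pred = ["adenoma", "hyperplasia", "hyperplasia", "hyperplasia", "normal", "adenoma"]
    m = compute_metrics(y_true, y_pred)
    assert np.array_equal(m.confusion.counts, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])
    assert m.accuracy == pytest.approx(4 / 6)
    assert m.precision["adenoma"] == pytest.approx(0.5)
    assert m.recall["adenoma"] == pytest.approx(0.5)
    assert m.f1["hyperplasia"] == pytest.approx(0.8)
    assert m.f1["normal"] == pytest.approx(2 / 3)
    assert m.macro_precision == pytest.approx((0.5 + 2 / 3 + 1.0) / 3)
    assert m.macro_recall == pytest.approx((0.5 + 1.0 + 0.5) / 3)
    assert m.macro_f1 == pytest.approx((0.5 + 0.8 + 2 / 3) / 3)


def _brute_force_metrics(y_true, y_pred, classes):
    per = {}
    for c in classes:
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[c] = (prec, rec, f1)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    return acc, per


def test_metrics_match_brute_force_counter_on_random_labels():
    rng = np.random.default_rng(5)
    for _ in range(500):
        n = int(rng.integers(1, 201))
        y_true = list(rng.choice(CLASSES, size=n))
        y_pred = list(rng.choice(CLASSES, size=n))
        m = compute_metrics(y_true, y_pred)
        acc, per = _brute_force_metrics(y_true, y_pred, CLASSES)
        assert m.accuracy == pytest.approx(acc)
        for c in CLASSES:
            assert m.precision[c] == pytest.approx(per[c][0])
            assert m.recall[c] == pytest.approx(per[c][1])
            assert m.f1[c] == pytest.approx(per[c][2])
        # accuracy always equals trace / total
        assert m.accuracy == pytest.approx(
            np.trace(m.confusion.counts) / m.confusion.total
        )


def test_class_absent_from_predictions_gets_zero_precision():
    y_true = ["adenoma", "hyperplasia", "normal"]
    y_pred = ["adenoma", "adenoma", "adenoma"]
    m = compute_metrics(y_true, y_pred)
    assert m.precision["normal"] == 0.0
    assert m.f1["normal"] == 0.0


def test_metrics_validate_inputs():
    with pytest.raises(ValueError, match="length"):
        compute_metrics(["adenoma"], [])
    with pytest.raises(ValueError, match="unknown"):
        compute_metrics(["adenoma"], ["polyp"])
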