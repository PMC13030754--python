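"""Shared fixtures: corpora and a trained model reused by expensive tests."""

from __future__ import annotations

import numpy as np
import pytest

import polypclip as pc
from polypclip.trainer import holdout_split

CORPUS_SEED = 11
RUN_SEED = 1


@pytest.fixture(scope="session")
def default_corpus():
    """The default desk-scale corpus: 3 classes, 30 patients/class, 5 images."""
    samples, meta = pc.generate_dataset(pc.SyntheticConfig(seed=CORPUS_SEED))
    return samples, meta


@pytest.fixture(scope="session")
def tiny_corpus():
    """A very small corpus for fast trainer unit tests."""
    cfg = pc.SyntheticConfig(
        patients_per_class=(4, 4, 4), images_per_patient=2, image_size=32,
        seed=CORPUS_SEED,
    )
    samples, meta = pc.generate_dataset(cfg)
    return samples, meta


@pytest.fixture
def tiny_run_config():
    return pc.RunConfig(seed=RUN_SEED, epochs=2, image_size=32, embed_dim=8,
                        hidden_dim=12, track_epoch_metrics=False)


@pytest.fixture(scope="session")
def trained_default_model(default_corpus):
    """One full default training run on a patient-level holdout split.

    Session-scoped so the end-to-end recovery, embedding-geometry, and
    evaluation-consistency tests share a single ~20 s fit.
    """
    samples, _ = default_corpus
    config = pc.RunConfig(seed=RUN_SEED)
    train, test = holdout_split(samples, config)
    model, history = pc.fit(train, config)
    metrics = pc.evaluate(
        model, test, train_patients={s.patient_id for s in train}
    )
    return {
        "model": model,
        "history": history,
        "train": train,
        "test": test,
        "metrics": metrics,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
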