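"""Shared fixtures: a small synthetic corpus and a classifier trained on it.

Everything is generated at test time from fixed seeds; no audio files ship
with the repository.
"""

from __future__ import annotations

import pytest

from coughwatch import (
    ClassifierConfig,
    CorpusRecipe,
    TrainParams,
    build_model,
    make_corpus,
    train,
)
from coughwatch.pipeline import build_labeled_examples

SMALL_RECIPE = CorpusRecipe(n_coughs=3, n_distractors=3, duration_s=10.0)

FAST_TRAIN = TrainParams(max_epochs=12, patience=3)


@pytest.fixture(scope="session")
def small_corpus():
    """8 annotated 10 s scenes, 3 coughs + 3 distractors each, dry, SNR 20-30 dB."""
    return make_corpus(8, SMALL_RECIPE, seed=1)


@pytest.fixture(scope="session")
def small_examples(small_corpus):
    """Gated + labeled segments from the small corpus."""
    examples = []
    for rec, truth in small_corpus:
        examples += build_labeled_examples(rec, list(truth.intervals))
    return examples


@pytest.fixture(scope="session")
def trained_model(small_examples):
    """One classifier trained on the small corpus (full 2x256 architecture)."""
    config = ClassifierConfig(train_params=FAST_TRAIN, seed=11)
    model = build_model(config)
    train(model, small_examples, config)
    return model
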