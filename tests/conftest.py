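import numpy as np
import pytest

from gosummary import (
    FixtureSpec,
    TinySeq2Seq,
    TrainingConfig,
    make_proteins,
    make_vocabulary,
    train,
)
from gosummary.dataset import assemble_section, split_dataset
from gosummary.scoring import default_embedder_panel

# training profile of the tiny from-scratch backend (the full-scale recipe in
# TrainingConfig's defaults applies to fine-tuning a large pretrained model;
# a small model trained from random init needs a larger step size)
TINY_TRAIN = dict(epochs=40, learning_rate=3e-3, batch_size=4, early_stopping_patience=8, seed=0)


@pytest.fixture(scope="session")
def small_world():
    """60-protein synthetic world with three engineered redundancy groups."""
    spec = FixtureSpec(n_proteins=60, seed=11, redundancy_groups=[(4, 0.9), (4, 0.9), (4, 0.9)])
    vocab = make_vocabulary(spec)
    anns, refs = make_proteins(spec, vocab)
    return spec, vocab, anns, refs


@pytest.fixture(scope="session")
def trained_setup():
    """400-protein Function dataset, a fitted tiny backend, and its untrained clone."""
    spec = FixtureSpec(n_proteins=400, seed=2)
    vocab = make_vocabulary(spec)
    anns, refs = make_proteins(spec, vocab)
    records = assemble_section(anns, vocab, refs, "Function")
    split = split_dataset(records, seed=0)
    corpus = [r.document.text for r in split.train] + [r.reference for r in split.train]
    backend = TinySeq2Seq(corpus, seed=0)
    untrained = backend.clone()
    trace = train(backend, split.train, split.validation, TrainingConfig(**TINY_TRAIN))
    return {
        "vocab": vocab,
        "split": split,
        "backend": backend,
        "untrained": untrained,
        "trace": trace,
        "embedders": default_embedder_panel(0),
    }
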