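import pytest

from chemner import (
    FeatureConfig,
    FixtureConfig,
    PipelineConfig,
    TaggerPipeline,
    generate_corpus,
)

# Table-8-shaped reference data used across test modules: the 13-token
# segmentation of "[C(8)mim][PF(6)]" and its per-token label marginals.
FORMULA_EXCERPT = "[C(8)mim][PF(6)]"
FORMULA_TOKENS = ["[", "C", "(", "8", ")", "mim", "]",
                  "[", "PF", "(", "6", ")", "]"]
FORMULA_LABELS = ["B"] + ["I"] * 11 + ["E"]
FORMULA_MARGINALS = [
    0.994456, 0.997241, 0.999912, 0.999914, 0.999853, 0.997244, 0.996372,
    0.996110, 0.995940, 0.996733, 0.996693, 0.825782, 0.731261,
]


@pytest.fixture(scope="session")
def small_corpus():
    """60 training + 20 held-out synthetic documents."""
    train = generate_corpus(FixtureConfig(n_documents=60, seed=11))
    test = generate_corpus(FixtureConfig(n_documents=20, seed=99))
    return train, test


@pytest.fixture(scope="session")
def trained_pipeline(small_corpus):
    """A pipeline with Brown features fitted on the small training corpus
    (shared across tests; treat as read-only)."""
    (train_docs, train_gold), _ = small_corpus
    config = PipelineConfig(
        features=FeatureConfig(brown=True, n_clusters=32), c=2.0)
    return TaggerPipeline(config).fit(train_docs, train_gold)
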