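"""Shared fixtures.

The session-scoped ``study`` fixture trains both classifiers once under the
package's standard synthetic study conditions (2,000 documents per class, 30
class-specific terms per class, 5x boost) and is shared by the acceptance
tests and the heavier model tests to keep the suite fast.
"""

from types import SimpleNamespace

import pytest

import chemtriage as ct

# the two worked-example titles (PubMed 17994679 / 17886339)
CHEMBL_TITLE = (
    "Discovery of biaryl anthranilides as full agonists for the high affinity "
    "niacin receptor."
)
MEDLINE_TITLE = "Automatic prediction of protein interactions with large scale motion."

STUDY_SEED = 7


@pytest.fixture()
def example_docs():
    return [
        ct.Document("17994679", CHEMBL_TITLE),
        ct.Document("17886339", MEDLINE_TITLE),
    ]


@pytest.fixture()
def pipeline():
    return ct.PipelineConfig()


@pytest.fixture(scope="session")
def study():
    """Standard study corpus with trained NB and RF models and an 80/20 split."""
    corpus = ct.generate_corpus(ct.SynthConfig(seed=STUDY_SEED))
    config = ct.PipelineConfig()
    tokenized = ct.tokenize_corpus(corpus.documents, config)
    vocab = ct.build_vocabulary(tokenized)
    matrix = ct.vectorize(
        tokenized, vocab, labels=[d.label for d in corpus.documents]
    )
    train_idx, test_idx = ct.stratified_split(matrix.labels, 0.2, seed=STUDY_SEED)
    train = matrix.subset(train_idx)
    test = matrix.subset(test_idx)
    nb = ct.train_nb(train)
    rf = ct.train_rf(train, n_trees=100, seed=STUDY_SEED)
    return SimpleNamespace(
        corpus=corpus,
        config=config,
        tokenized=tokenized,
        vocab=vocab,
        matrix=matrix,
        train=train,
        test=test,
        nb=nb,
        rf=rf,
    )


@pytest.fixture(scope="session")
def small_labeled_corpus():
    """Smaller separable corpus for cheap end-to-end tests."""
    cfg = ct.SynthConfig(
        n_pos=150,
        n_neg=150,
        vocab_size_shared=300,
        vocab_size_pos_only=12,
        vocab_size_neg_only=12,
        abstract_length_mean=60.0,
        seed=11,
    )
    return ct.generate_corpus(cfg)
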