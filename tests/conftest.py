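"""Shared fixtures: a hand-written article + lexicon, and a small trained reader."""

import pytest
from hypothesis import settings

from biocloze import build_corpus, assign_ids, split_corpus
from biocloze.corpus_io import Article
from biocloze.lexicon import Lexicon, LexiconEntry
from biocloze.reader import ReaderConfig, train
from biocloze.synth import SynthConfig, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mini_lexicon() -> Lexicon:
    """A lexicon around a breast-cancer coactivator abstract."""
    return Lexicon([
        LexiconEntry("breast cancer", "E_BC", "Disease"),
        LexiconEntry("breast tumors", "E_BC", "Disease"),
        LexiconEntry("NCOA1", "E_NCOA1", "Gene"),
        LexiconEntry("SRC-1", "E_NCOA1", "Gene"),
        LexiconEntry("AP-1", "E_AP1", "Transcription Factor"),
        LexiconEntry("CSF1", "E_CSF1", "Gene"),
        LexiconEntry("M-CSF1", "E_CSF1", "Gene"),
        LexiconEntry("c-Fos", "E_FOS", "Gene"),
        LexiconEntry("mice", "E_MICE", "Organisms [B]"),
        LexiconEntry("disease recurrence", "E_REC", "Phenomena and Processes [G]"),
        LexiconEntry("metastasis", "E_MET", "Phenomena and Processes [G]"),
        LexiconEntry("human", "E_HUM", "Organisms [B]"),
    ])


@pytest.fixture(scope="session")
def coactivator_article() -> Article:
    """A condensed abstract whose title and last sentence both name entities."""
    abstract = (
        "In breast cancer , overexpression of the nuclear coactivator NCOA1 "
        "( SRC-1 ) is associated with disease recurrence . To examine the "
        "impact of NCOA1 overexpression we generated transgenic mice . "
        "NCOA1 upregulates CSF1 expression through c-Fos and AP-1 binding "
        "sites . In a cohort of 453 human breast tumors , NCOA1 and CSF1 "
        "levels correlated positively with disease recurrence . Together , "
        "our results define an NCOA1/AP-1/CSF1 regulatory axis that promotes "
        "breast cancer metastasis , offering a novel therapeutic avenue ."
    )
    return Article(
        article_id="PM0001",
        title="NCOA1 directly targets M-CSF1 expression to promote breast cancer metastasis",
        abstract=abstract,
        year=2014)


@pytest.fixture(scope="session")
def cue_splits():
    """A small planted-cue corpus, LS variant, local IDs, split three ways."""
    config = SynthConfig(n_articles=400, vocab_size=300, n_entities=80,
                         tokens_per_doc_mean=60.0, tokens_per_doc_sd=6.0,
                         cue_strength=1.0, seed=7)
    articles, entries, _ = generate_corpus(config)
    instances, rejections = build_corpus(articles, Lexicon(entries), "LS")
    assert not rejections
    instances, _ = assign_ids(instances, "local", seed=7)
    return split_corpus(instances, (0.7, 0.15, 0.15), seed=7)


@pytest.fixture(scope="session")
def small_config() -> ReaderConfig:
    return ReaderConfig(word_dim=16, type_dim=0, hidden_size=16,
                        batch_size=16, max_epochs=8, patience=8, seed=5)


@pytest.fixture(scope="session")
def trained_small(cue_splits, small_config):
    """One reader trained on the planted-cue corpus (shared across tests)."""
    train_set, valid_set, _ = cue_splits
    return train(train_set, valid_set, small_config)
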