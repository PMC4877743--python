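import pytest

from mirlink.corpus_io import DocumentRecord
from mirlink.entities import (
    detect_disease_mentions,
    detect_gene_mentions,
    detect_mir_mentions,
    resolve_overlaps,
)
from mirlink.lexicon import load_default_lexicon
from mirlink.preprocess import ChunkedSentence, chunk, default_tagger


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def tagger(lexicon):
    return default_tagger()


@pytest.fixture(scope="session")
def make_sentence(lexicon, tagger):
    """Factory: one chunked sentence with mentions detected, as the pipeline
    would prepare it."""

    def build(text: str) -> ChunkedSentence:
        record = DocumentRecord(pmid="T", title=text, abstract="")
        mentions = resolve_overlaps(
            detect_mir_mentions(record.text)
            + detect_disease_mentions(record, lexicon)
            + detect_gene_mentions(record, lexicon)
        )
        sent = ChunkedSentence(index=0, start=0, end=len(text), text=text)
        sent.mentions = mentions
        return chunk(sent, tagger)

    return build
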