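import pytest

from medline_dq.synth import SyntheticCorpusConfig, generate_corpus_bytes
from medline_dq.xml_io import XmlRecordSlice, split_records


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-record synthetic corpus shared across read-only tests."""
    config = SyntheticCorpusConfig(n_records=300, seed=11)
    files, manifest = generate_corpus_bytes(config)
    return config, files, manifest


@pytest.fixture(scope="session")
def small_corpus_slices(small_corpus):
    _, files, _ = small_corpus
    return [s for i, f in enumerate(files) for s in split_records(f, f"base{i}")]


def article_slice(body: str, pmid: int = 1, status: str = "MEDLINE") -> XmlRecordSlice:
    """Wrap a MedlineCitation/PubmedData body fragment into an article slice."""
    xml = (
        f'<PubmedArticle><MedlineCitation Status="{status}">'
        f'<PMID Version="1">{pmid}</PMID>{body}</MedlineCitation></PubmedArticle>'
    )
    return XmlRecordSlice(
        pmid=pmid, version=1, kind="article", raw_xml=xml,
        source_file="fixture", source_index=0,
    )


def full_slice(xml: str, pmid: int, kind: str = "article") -> XmlRecordSlice:
    return XmlRecordSlice(
        pmid=pmid, version=1, kind=kind, raw_xml=xml,
        source_file="fixture", source_index=0,
    )
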