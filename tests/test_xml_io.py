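"""Streaming split, record parsing, author extraction, reference flattening,
and text sanitization."""

import gzip

import pytest
from lxml import etree

from medline_dq.xml_io import (
    RecordParseError,
    XmlParseError,
    extract_authors,
    flatten_references,
    parse_article,
    sanitize_text,
    serialize_articles,
    split_records,
)

from conftest import article_slice, full_slice


def wrap(children: str) -> bytes:
    return f"<PubmedArticleSet>{children}</PubmedArticleSet>".encode()


def minimal_article(pmid: int, title: str = "T") -> str:
    return (
        f'<PubmedArticle><MedlineCitation Status="MEDLINE"><PMID Version="1">{pmid}</PMID>'
        f"<Article><ArticleTitle>{title}</ArticleTitle></Article>"
        f"</MedlineCitation></PubmedArticle>"
    )


class TestSplitRecords:
    def test_three_articles_yield_three_slices(self):
        xml = wrap("".join(minimal_article(i) for i in (1, 2, 3)))
        slices = list(split_records(xml, "f"))
        assert [s.pmid for s in slices] == [1, 2, 3]
        assert all(s.kind == "article" for s in slices)
        assert [s.source_index for s in slices] == [0, 1, 2]

    def test_delete_citation_yields_one_slice_per_pmid(self):
        xml = wrap(
            minimal_article(1)
            + minimal_article(2)
            + "<DeleteCitation><PMID>10</PMID><PMID>11</PMID></DeleteCitation>"
        )
        slices = list(split_records(xml, "f"))
        kinds = [s.kind for s in slices]
        assert kinds == ["article", "article", "delete_citation", "delete_citation"]
        assert [s.pmid for s in slices[2:]] == [10, 11]

    def test_book_article_slices_are_tagged(self):
        xml = wrap(
            '<PubmedBookArticle><BookDocument><PMID Version="1">5</PMID>'
            "</BookDocument></PubmedBookArticle>" + minimal_article(6)
        )
        kinds = [s.kind for s in split_records(xml, "f")]
        assert kinds == ["book_article", "article"]

    def test_gzip_transport_is_transparent(self):
        xml = wrap(minimal_article(1))
        slices = list(split_records(gzip.compress(xml), "f.gz"))
        assert [s.pmid for s in slices] == [1]

    def test_missing_pmid_reported_and_skipped(self):
        xml = wrap(
            "<PubmedArticle><MedlineCitation><Article/></MedlineCitation></PubmedArticle>"
            + minimal_article(2)
        )
        errors = []
        slices = list(split_records(xml, "f", on_error=errors.append))
        assert [s.pmid for s in slices] == [2]
        assert len(errors) == 1 and errors[0].source_index == 0

    def test_malformed_xml_raises_with_position(self):
        with pytest.raises(XmlParseError, match="line"):
            list(split_records(b"<PubmedArticleSet><PubmedArticle>", "f"))

    def test_synthetic_corpus_slice_count_matches_manifest(self, small_corpus, small_corpus_slices):
        _, _, manifest = small_corpus
        assert len(small_corpus_slices) == manifest.n_records

    def test_raw_xml_is_well_formed(self, small_corpus_slices):
        for s in small_corpus_slices[:20]:
            etree.fromstring(s.raw_xml.encode())


class TestParseArticle:
    def test_minimal_fields(self):
        rec = parse_article(article_slice("<Article><ArticleTitle>T</ArticleTitle></Article>"))
        assert rec.pmid == 1 and rec.title == "T"
        assert rec.abstract is None and rec.doi is None
        assert rec.medline_date is None and rec.pub_year_structured is None

    def test_doi_from_back_matter(self):
        xml = (
            '<PubmedArticle><MedlineCitation Status="MEDLINE"><PMID>1</PMID>'
            "<Article><ArticleTitle>T</ArticleTitle></Article></MedlineCitation>"
            '<PubmedData><ArticleIdList><ArticleId IdType="pubmed">1</ArticleId>'
            '<ArticleId IdType="doi">10.1093/nar/gkaa1234</ArticleId>'
            "</ArticleIdList></PubmedData></PubmedArticle>"
        )
        rec = parse_article(full_slice(xml, 1))
        assert rec.doi == "10.1093/nar/gkaa1234"

    def test_medline_date_fallback(self):
        body = (
            "<Article><Journal><JournalIssue><PubDate>"
            "<MedlineDate>1946 May–June</MedlineDate>"
            "</PubDate></JournalIssue></Journal></Article>"
        )
        rec = parse_article(article_slice(body))
        assert rec.pub_year_structured is None
        assert rec.medline_date == "1946 May–June"

    def test_structured_abstract_sections_concatenated(self):
        body = (
            "<Article><Abstract>"
            '<AbstractText Label="BACKGROUND">First part.</AbstractText>'
            '<AbstractText Label="METHODS">Second part.</AbstractText>'
            "</Abstract></Article>"
        )
        rec = parse_article(article_slice(body))
        assert rec.abstract == "First part. Second part."

    def test_inline_markup_flattened(self):
        body = "<Article><ArticleTitle>The <i>BRCA1</i> gene<sub>2</sub></ArticleTitle></Article>"
        rec = parse_article(article_slice(body))
        assert rec.title == "The BRCA1 gene2"

    def test_missing_citation_is_structural_error(self):
        with pytest.raises(RecordParseError):
            parse_article(full_slice("<PubmedArticle><PubmedData/></PubmedArticle>", 1))

    def test_incomplete_date_revised_is_error(self):
        body = "<DateRevised><Year>2021</Year></DateRevised><Article/>"
        with pytest.raises(RecordParseError):
            parse_article(article_slice(body))

    def test_empty_title_maps_to_absent(self):
        rec = parse_article(article_slice("<Article><ArticleTitle>  </ArticleTitle></Article>"))
        assert rec.title is None


AUTHOR_BODY = """<Article><AuthorList>
<Author ValidYN="Y"><LastName>Wang</LastName><ForeName>Wei</ForeName></Author>
<Author ValidYN="N"><LastName>Bad</LastName></Author>
<Author ValidYN="Y"><LastName>Li</LastName><ForeName>Jing</ForeName></Author>
</AuthorList></Article>"""


class TestExtractAuthors:
    def test_validyn_n_excluded(self):
        authors = extract_authors(article_slice(AUTHOR_BODY))
        assert [a.last_name for a in authors] == ["Wang", "Li"]
        assert [a.position for a in authors] == [1, 2]

    def test_interleaved_collective_groups_repeat_member(self):
        # The consortium pattern: the same person listed under 12 groups.
        entries = "".join(
            f'<Author ValidYN="Y"><CollectiveName>Group {g}</CollectiveName></Author>'
            f'<Author ValidYN="Y"><LastName>Appels</LastName><ForeName>Rudi</ForeName></Author>'
            for g in range(12)
        )
        authors = extract_authors(article_slice(f"<Article><AuthorList>{entries}</AuthorList></Article>"))
        personal = [a for a in authors if a.collective_name is None]
        collective = [a for a in authors if a.collective_name is not None]
        assert len(personal) == 12 and len(collective) == 12
        assert {(a.last_name, a.fore_name) for a in personal} == {("Appels", "Rudi")}
        # document order preserved: alternating collective, personal
        assert [a.collective_name is not None for a in authors] == [True, False] * 12

    def test_first_affiliation_rule(self):
        body = (
            '<Article><AuthorList><Author ValidYN="Y"><LastName>Kim</LastName>'
            "<AffiliationInfo><Affiliation>First University.</Affiliation></AffiliationInfo>"
            "<AffiliationInfo><Affiliation>Second.</Affiliation></AffiliationInfo>"
            "<AffiliationInfo><Affiliation>Third.</Affiliation></AffiliationInfo>"
            "</Author></AuthorList></Article>"
        )
        (author,) = extract_authors(article_slice(body))
        assert author.affiliation_first == "First University."
        assert author.affiliation_count == 3

    def test_orcid_and_affiliation_identifiers(self):
        body = (
            '<Article><AuthorList><Author ValidYN="Y"><LastName>Eker</LastName>'
            '<Identifier Source="ORCID">0000-0002-5696-5368</Identifier>'
            "<AffiliationInfo><Affiliation>Uni.</Affiliation>"
            '<Identifier Source="ISNI">000000012096021X</Identifier>'
            '<Identifier Source="GRID">grid.1234.0a</Identifier>'
            "</AffiliationInfo></Author></AuthorList></Article>"
        )
        (author,) = extract_authors(article_slice(body))
        assert author.orcid_raw == "0000-0002-5696-5368"
        assert ("ISNI", "000000012096021X") in author.affiliation_identifiers
        assert ("GRID", "grid.1234.0a") in author.affiliation_identifiers

    def test_investigators_never_read(self):
        body = (
            "<InvestigatorList><Investigator ValidYN=\"Y\"><LastName>X</LastName>"
            "</Investigator></InvestigatorList>" + AUTHOR_BODY
        )
        authors = extract_authors(article_slice(body))
        assert len(authors) == 2

    def test_author_count_matches_xpath_oracle(self, small_corpus_slices):
        for s in small_corpus_slices:
            root = etree.fromstring(s.raw_xml.encode())
            expected = len(
                root.xpath('MedlineCitation/Article/AuthorList/Author[not(@ValidYN="N")]')
            )
            assert len(extract_authors(s)) == expected


def refs_xml(back: str) -> str:
    return (
        '<PubmedArticle><MedlineCitation Status="MEDLINE"><PMID>1</PMID><Article/>'
        f"</MedlineCitation><PubmedData>{back}</PubmedData></PubmedArticle>"
    )


class TestFlattenReferences:
    def test_one_list_many_refs(self):
        back = "<ReferenceList>" + "".join(
            f"<Reference><Citation>R{i}</Citation></Reference>" for i in range(5)
        ) + "</ReferenceList>"
        entries = flatten_references(full_slice(refs_xml(back), 1))
        assert [e.citation_text for e in entries] == [f"R{i}" for i in range(5)]
        assert all(e.nesting_depth == 0 for e in entries)

    def test_many_singleton_lists(self):
        back = "".join(
            f"<ReferenceList><Reference><Citation>R{i}</Citation></Reference></ReferenceList>"
            for i in range(5)
        )
        entries = flatten_references(full_slice(refs_xml(back), 1))
        assert [e.citation_text for e in entries] == [f"R{i}" for i in range(5)]

    def test_both_encodings_flatten_identically(self):
        one_list = "<ReferenceList>" + "".join(
            f"<Reference><Citation>R{i}</Citation></Reference>" for i in range(5)
        ) + "</ReferenceList>"
        many_lists = "".join(
            f"<ReferenceList><Reference><Citation>R{i}</Citation></Reference></ReferenceList>"
            for i in range(5)
        )
        a = flatten_references(full_slice(refs_xml(one_list), 1))
        b = flatten_references(full_slice(refs_xml(many_lists), 1))
        assert [e.citation_text for e in a] == [e.citation_text for e in b]

    def test_nested_depth_recorded(self):
        back = (
            "<ReferenceList><ReferenceList><ReferenceList><ReferenceList>"
            "<Reference><Citation>Deep</Citation></Reference>"
            "</ReferenceList></ReferenceList></ReferenceList></ReferenceList>"
        )
        entries = flatten_references(full_slice(refs_xml(back), 1))
        assert len(entries) == 1 and entries[0].nesting_depth == 3


class TestSanitizeText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("a\r\nb", "a b"),
            ("İstanbul", "İstanbul"),
            ('say "hi"\\', 'say "hi"\\'),
            ("a\tb  c", "a b c"),
            ("  padded  ", "padded"),
            ("éclair", "éclair"),  # combining accent folds to NFC
        ],
    )
    def test_rules(self, raw, expected):
        assert sanitize_text(raw) == expected


class TestRoundTrip:
    def test_parse_serialize_identity_on_synthetic_corpus(self, small_corpus_slices):
        records = [parse_article(s) for s in small_corpus_slices]
        blob = serialize_articles(records)
        reparsed = [parse_article(s) for s in split_records(blob, "roundtrip")]
        assert len(reparsed) == len(records)
        for a, b in zip(records, reparsed):
            assert a == b
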