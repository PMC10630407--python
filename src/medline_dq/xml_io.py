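"""Streaming PubMed XML input/output.

PubMed distributes its corpus as gzipped XML files whose root element,
``PubmedArticleSet``, holds up to 30 000 ``PubmedArticle`` (or
``PubmedBookArticle``) children; daily update files may additionally carry a
``DeleteCitation`` element listing PMIDs to remove.  This module splits such
files into per-record slices with bounded memory, parses each record into
typed dataclasses, and handles the structural quirks the format is known
for: interleaved ``CollectiveName``/``Author`` entries, arbitrarily nested
``ReferenceList`` elements, and control/extended characters embedded in text
fields.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from typing import BinaryIO, Callable, Iterable, Iterator, Optional, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "XmlRecordSlice",
    "ArticleRecord",
    "AuthorRecord",
    "ReferenceEntry",
    "RecordError",
    "XmlParseError",
    "RecordParseError",
    "split_records",
    "parse_article",
    "extract_authors",
    "flatten_references",
    "sanitize_text",
    "serialize_articles",
]


class XmlParseError(Exception):
    """The XML stream itself is malformed (names the position if known)."""


class RecordParseError(Exception):
    """A single record is structurally unusable (e.g. no MedlineCitation)."""


@dataclass(frozen=True)
class RecordError:
    """A record-level problem encountered while splitting; parsing continues."""

    source_file: str
    source_index: int
    message: str


@dataclass(frozen=True)
class XmlRecordSlice:
    """One record cut out of a PubmedArticleSet file.

    ``raw_xml`` is a self-contained, well-formed element (a PubmedArticle,
    PubmedBookArticle, or a synthesized ``<DeleteCitation>`` holding a single
    PMID).  ``source_index`` is the record's 0-based position within the file,
    which together with ``source_file`` gives a total provenance order.
    """

    pmid: int
    version: int
    kind: str  # "article" | "book_article" | "delete_citation"
    raw_xml: str
    source_file: str
    source_index: int


@dataclass
class AuthorRecord:
    """One author entry: either a personal name or a collective name.

    Only entries with ``ValidYN="Y"`` are extracted; Investigator elements are
    never read.  Of an author's affiliations only the first string is kept
    (``affiliation_first``) alongside the total count.
    """

    position: int
    last_name: Optional[str] = None
    fore_name: Optional[str] = None
    initials: Optional[str] = None
    suffix: Optional[str] = None
    collective_name: Optional[str] = None
    valid_yn: str = "Y"
    affiliation_first: Optional[str] = None
    affiliation_count: int = 0
    orcid_raw: Optional[str] = None
    affiliation_identifiers: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ReferenceEntry:
    citation_text: Optional[str] = None
    article_ids: list[tuple[str, str]] = field(default_factory=list)
    nesting_depth: int = 0


@dataclass
class ArticleRecord:
    """A parsed PubmedArticle: the bibliographic front matter plus the DOI
    and references from the back matter."""

    pmid: int
    status: str = ""
    date_revised: Optional[date] = None
    title: Optional[str] = None
    abstract: Optional[str] = None
    copyright_info: Optional[str] = None
    language_raw: list[str] = field(default_factory=list)
    pub_year_structured: Optional[int] = None
    medline_date: Optional[str] = None
    doi: Optional[str] = None
    journal_nlm_id: Optional[str] = None
    publication_types: list[str] = field(default_factory=list)
    authors: list[AuthorRecord] = field(default_factory=list)
    references: list[ReferenceEntry] = field(default_factory=list)


_WS_RUN = re.compile(r" {2,}")


def sanitize_text(raw: str) -> str:
    """Normalize a text field for in-memory use.

    Carriage returns, line feeds and tabs each become a single space, runs of
    spaces collapse to one, and leading/trailing whitespace is trimmed.
    Backslashes and quotes are preserved (escaping is a serializer concern),
    and non-ASCII characters are preserved under Unicode NFC — "İstanbul"
    remains distinct from "Istanbul".
    """
    t = raw.replace("\r", " ").replace("\n", " ").replace("\t", " ")
    t = _WS_RUN.sub(" ", t).strip()
    return unicodedata.normalize("NFC", t)


def _open_stream(xml_source: Union[str, bytes, BinaryIO]) -> BinaryIO:
    if isinstance(xml_source, bytes):
        xml_source = io.BytesIO(xml_source)
    elif isinstance(xml_source, str):
        xml_source = open(xml_source, "rb")
    head = xml_source.read(2)
    xml_source.seek(0)
    if head == b"\x1f\x8b":
        return gzip.open(xml_source, "rb")  # type: ignore[return-value]
    return xml_source


def _element_text(elem: Optional[etree._Element]) -> Optional[str]:
    """Flattened, sanitized text content of an element, or None if the element
    is absent or empty after sanitization (inline markup is dropped)."""
    if elem is None:
        return None
    text = sanitize_text("".join(elem.itertext()))
    return text or None


def split_records(
    xml_source: Union[str, bytes, BinaryIO],
    source_name: str,
    on_error: Optional[Callable[[RecordError], None]] = None,
) -> Iterator[XmlRecordSlice]:
    """Stream one :class:`XmlRecordSlice` per record of a PubmedArticleSet.

    Accepts a path, raw bytes, or a binary stream; gzip is detected from the
    magic bytes.  Memory stays bounded regardless of file size: each record
    subtree is discarded once yielded.  A record lacking a PMID is reported
    through ``on_error`` (default: a warning log) and skipped; malformed XML
    raises :class:`XmlParseError` naming the offending position.
    """

    def report(index: int, message: str) -> None:
        err = RecordError(source_name, index, message)
        if on_error is not None:
            on_error(err)
        else:
            logger.warning("%s[%d]: %s", source_name, index, message)

    stream = _open_stream(xml_source)
    index = 0
    try:
        context = etree.iterparse(
            stream,
            events=("end",),
            tag=("PubmedArticle", "PubmedBookArticle", "DeleteCitation"),
            recover=False,
        )
        for _, elem in context:
            # Skip nested matches (DeleteCitation is always a direct child of
            # the root, as are the article elements).
            parent = elem.getparent()
            if parent is not None and parent.tag != "PubmedArticleSet":
                continue
            if elem.tag == "DeleteCitation":
                for pmid_el in elem.findall("PMID"):
                    text = (pmid_el.text or "").strip()
                    if not text.isdigit():
                        report(index, f"DeleteCitation PMID not numeric: {text!r}")
                    else:
                        version = int(pmid_el.get("Version", "1"))
                        yield XmlRecordSlice(
                            pmid=int(text),
                            version=version,
                            kind="delete_citation",
                            raw_xml=f'<DeleteCitation><PMID Version="{version}">{text}</PMID></DeleteCitation>',
                            source_file=source_name,
                            source_index=index,
                        )
                    index += 1
            else:
                kind = "article" if elem.tag == "PubmedArticle" else "book_article"
                pmid_el = elem.find("MedlineCitation/PMID")
                if pmid_el is None:
                    pmid_el = elem.find("BookDocument/PMID")
                text = (pmid_el.text or "").strip() if pmid_el is not None else ""
                if not text.isdigit():
                    report(index, f"record has no usable PMID (tag {elem.tag})")
                else:
                    yield XmlRecordSlice(
                        pmid=int(text),
                        version=int(pmid_el.get("Version", "1")),
                        kind=kind,
                        raw_xml=etree.tostring(elem, encoding="unicode"),
                        source_file=source_name,
                        source_index=index,
                    )
                index += 1
            # Free the processed subtree and any preceding siblings.
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(
            f"{source_name}: malformed XML at line {exc.lineno}, column {exc.offset}: {exc.msg}"
        ) from exc
    finally:
        stream.close()


def _parse_date_revised(citation: etree._Element) -> Optional[date]:
    el = citation.find("DateRevised")
    if el is None:
        return None
    parts = {}
    for name in ("Year", "Month", "Day"):
        child = el.find(name)
        text = (child.text or "").strip() if child is not None else ""
        if not text.isdigit():
            raise RecordParseError(f"DateRevised has incomplete component {name!r}")
        parts[name] = int(text)
    return date(parts["Year"], parts["Month"], parts["Day"])


def parse_article(slice_: XmlRecordSlice) -> ArticleRecord:
    """Parse an article slice into an :class:`ArticleRecord`.

    Front-matter fields come from MedlineCitation; the DOI is taken from the
    back-matter ArticleIdList when present.  Absent elements map to ``None``,
    never to an empty string.  Unknown children are ignored (debug-logged).
    """
    if slice_.kind != "article":
        raise ValueError(f"parse_article expects kind='article', got {slice_.kind!r}")
    root = etree.fromstring(slice_.raw_xml.encode("utf-8"))
    citation = root.find("MedlineCitation")
    if citation is None:
        raise RecordParseError(f"PMID {slice_.pmid}: record lacks MedlineCitation")

    art = citation.find("Article")
    record = ArticleRecord(pmid=slice_.pmid)
    record.status = citation.get("Status", "")
    record.date_revised = _parse_date_revised(citation)
    record.journal_nlm_id = _element_text(citation.find("MedlineJournalInfo/NlmUniqueID"))

    if art is not None:
        record.title = _element_text(art.find("ArticleTitle"))
        abstract_el = art.find("Abstract")
        if abstract_el is not None:
            sections = [
                sanitize_text("".join(t.itertext()))
                for t in abstract_el.findall("AbstractText")
            ]
            joined = " ".join(s for s in sections if s)
            record.abstract = joined or None
            record.copyright_info = _element_text(abstract_el.find("CopyrightInformation"))
        record.language_raw = [
            (lang.text or "").strip()
            for lang in art.findall("Language")
            if (lang.text or "").strip()
        ]
        pubdate = art.find("Journal/JournalIssue/PubDate")
        if pubdate is not None:
            year_el = pubdate.find("Year")
            if year_el is not None and (year_el.text or "").strip().isdigit():
                record.pub_year_structured = int(year_el.text.strip())
            md = pubdate.find("MedlineDate")
            if md is not None and md.text is not None:
                record.medline_date = sanitize_text(md.text) or None
        record.publication_types = [
            t for t in (_element_text(pt) for pt in art.findall("PublicationTypeList/PublicationType")) if t
        ]
    else:
        logger.debug("PMID %d: MedlineCitation has no Article element", slice_.pmid)

    doi_el = root.find('PubmedData/ArticleIdList/ArticleId[@IdType="doi"]')
    if doi_el is not None and doi_el.text is not None:
        record.doi = sanitize_text(doi_el.text) or None

    record.authors = extract_authors(slice_)
    record.references = flatten_references(slice_)
    return record


def extract_authors(slice_: XmlRecordSlice) -> list[AuthorRecord]:
    """Extract the author list of an article slice in document order.

    Entries with ``ValidYN="N"`` are dropped; ``CollectiveName`` children
    yield records with ``collective_name`` set and the personal name parts
    absent.  Only the first Affiliation string is stored, with the total
    Affiliation element count alongside.  ``Identifier Source="ORCID"`` on
    the author populates ``orcid_raw``; ISNI/GRID identifiers attached to
    AffiliationInfo populate ``affiliation_identifiers``.
    """
    if slice_.kind != "article":
        raise ValueError(f"extract_authors expects kind='article', got {slice_.kind!r}")
    root = etree.fromstring(slice_.raw_xml.encode("utf-8"))
    authors: list[AuthorRecord] = []
    position = 0
    for author_el in root.findall("MedlineCitation/Article/AuthorList/Author"):
        if author_el.get("ValidYN", "Y") != "Y":
            continue
        position += 1
        rec = AuthorRecord(position=position, valid_yn="Y")
        rec.last_name = _element_text(author_el.find("LastName"))
        rec.fore_name = _element_text(author_el.find("ForeName"))
        rec.initials = _element_text(author_el.find("Initials"))
        rec.suffix = _element_text(author_el.find("Suffix"))
        rec.collective_name = _element_text(author_el.find("CollectiveName"))
        for ident in author_el.findall("Identifier"):
            if ident.get("Source", "").upper() == "ORCID" and ident.text:
                rec.orcid_raw = sanitize_text(ident.text) or None
        # Affiliations appear either under AffiliationInfo (2015+ DTD) or as
        # direct Affiliation children (older exports); handle both.
        affiliations: list[str] = []
        for aff_info in author_el.findall("AffiliationInfo"):
            text = _element_text(aff_info.find("Affiliation"))
            if text:
                affiliations.append(text)
            for ident in aff_info.findall("Identifier"):
                source = ident.get("Source", "")
                scheme = source.upper() if source.upper() in ("ISNI", "GRID") else "other"
                if ident.text:
                    rec.affiliation_identifiers.append((scheme, sanitize_text(ident.text)))
        for aff in author_el.findall("Affiliation"):
            text = _element_text(aff)
            if text:
                affiliations.append(text)
        if affiliations:
            rec.affiliation_first = affiliations[0]
        rec.affiliation_count = len(affiliations)
        authors.append(rec)
    return authors


def _walk_reference_lists(el: etree._Element, depth: int, out: list[ReferenceEntry]) -> None:
    for child in el:
        if child.tag == "Reference":
            entry = ReferenceEntry(nesting_depth=depth)
            entry.citation_text = _element_text(child.find("Citation"))
            for aid in child.findall("ArticleIdList/ArticleId"):
                if aid.text:
                    entry.article_ids.append((aid.get("IdType", ""), sanitize_text(aid.text)))
            out.append(entry)
        elif child.tag == "ReferenceList":
            _walk_reference_lists(child, depth + 1, out)


def flatten_references(slice_: XmlRecordSlice) -> list[ReferenceEntry]:
    """Flatten the back matter's ReferenceList forest into document order.

    The DTD allows both one list with many references and many singleton
    lists — and lists nested to arbitrary depth; every Reference appears
    exactly once with its nesting depth recorded (0 = inside a top-level
    ReferenceList).
    """
    if slice_.kind != "article":
        raise ValueError(f"flatten_references expects kind='article', got {slice_.kind!r}")
    root = etree.fromstring(slice_.raw_xml.encode("utf-8"))
    out: list[ReferenceEntry] = []
    pubmed_data = root.find("PubmedData")
    if pubmed_data is not None:
        for ref_list in pubmed_data.findall("ReferenceList"):
            _walk_reference_lists(ref_list, 0, out)
    return out


# ---------------------------------------------------------------------------
# Serialization (round-trip support for the corpus store and the generator)

def _sub(parent: etree._Element, tag: str, text: Optional[str] = None, **attrs: str) -> etree._Element:
    el = etree.SubElement(parent, tag, attrs)
    if text is not None:
        el.text = text
    return el


def article_to_element(record: ArticleRecord) -> etree._Element:
    """Render an :class:`ArticleRecord` back to a PubmedArticle element."""
    pa = etree.Element("PubmedArticle")
    citation = _sub(pa, "MedlineCitation", Status=record.status or "MEDLINE")
    _sub(citation, "PMID", str(record.pmid), Version="1")
    if record.date_revised is not None:
        dr = _sub(citation, "DateRevised")
        _sub(dr, "Year", f"{record.date_revised.year:04d}")
        _sub(dr, "Month", f"{record.date_revised.month:02d}")
        _sub(dr, "Day", f"{record.date_revised.day:02d}")
    art = _sub(citation, "Article")
    journal = _sub(art, "Journal")
    issue = _sub(journal, "JournalIssue")
    pubdate = _sub(issue, "PubDate")
    if record.pub_year_structured is not None:
        _sub(pubdate, "Year", str(record.pub_year_structured))
    elif record.medline_date is not None:
        _sub(pubdate, "MedlineDate", record.medline_date)
    if record.title is not None:
        _sub(art, "ArticleTitle", record.title)
    if record.abstract is not None or record.copyright_info is not None:
        abstract = _sub(art, "Abstract")
        if record.abstract is not None:
            _sub(abstract, "AbstractText", record.abstract)
        if record.copyright_info is not None:
            _sub(abstract, "CopyrightInformation", record.copyright_info)
    if record.authors:
        alist = _sub(art, "AuthorList", CompleteYN="Y")
        for author in record.authors:
            a_el = _sub(alist, "Author", ValidYN=author.valid_yn)
            if author.collective_name is not None:
                _sub(a_el, "CollectiveName", author.collective_name)
            if author.last_name is not None:
                _sub(a_el, "LastName", author.last_name)
            if author.fore_name is not None:
                _sub(a_el, "ForeName", author.fore_name)
            if author.initials is not None:
                _sub(a_el, "Initials", author.initials)
            if author.suffix is not None:
                _sub(a_el, "Suffix", author.suffix)
            if author.orcid_raw is not None:
                _sub(a_el, "Identifier", author.orcid_raw, Source="ORCID")
            n_affs = author.affiliation_count
            for k in range(n_affs):
                info = _sub(a_el, "AffiliationInfo")
                text = author.affiliation_first if k == 0 else f"Affiliation {k + 1}"
                _sub(info, "Affiliation", text or "")
                if k == 0:
                    for scheme, value in author.affiliation_identifiers:
                        _sub(info, "Identifier", value, Source=scheme)
    for lang in record.language_raw:
        _sub(art, "Language", lang)
    if record.publication_types:
        ptl = _sub(art, "PublicationTypeList")
        for pt in record.publication_types:
            _sub(ptl, "PublicationType", pt)
    mji = _sub(citation, "MedlineJournalInfo")
    if record.journal_nlm_id is not None:
        _sub(mji, "NlmUniqueID", record.journal_nlm_id)
    pubmed_data = _sub(pa, "PubmedData")
    id_list = _sub(pubmed_data, "ArticleIdList")
    _sub(id_list, "ArticleId", str(record.pmid), IdType="pubmed")
    if record.doi is not None:
        _sub(id_list, "ArticleId", record.doi, IdType="doi")
    if record.references:
        # Re-serialize the flattened forest: one top-level list per depth run.
        ref_list = _sub(pubmed_data, "ReferenceList")
        for entry in record.references:
            target = ref_list
            for _ in range(entry.nesting_depth):
                nested = target.find("ReferenceList")
                if nested is None:
                    nested = _sub(target, "ReferenceList")
                target = nested
            ref = _sub(target, "Reference")
            if entry.citation_text is not None:
                _sub(ref, "Citation", entry.citation_text)
            if entry.article_ids:
                aids = _sub(ref, "ArticleIdList")
                for id_type, value in entry.article_ids:
                    _sub(aids, "ArticleId", value, IdType=id_type)
    return pa


def serialize_articles(records: Iterable[ArticleRecord], deleted_pmids: Iterable[int] = ()) -> bytes:
    """Serialize records (and an optional DeleteCitation block) to XML bytes."""
    root = etree.Element("PubmedArticleSet")
    for record in records:
        root.append(article_to_element(record))
    deleted = list(deleted_pmids)
    if deleted:
        dc = _sub(root, "DeleteCitation")
        for pmid in deleted:
            _sub(dc, "PMID", str(pmid), Version="1")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
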