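"""Corpus assembly: baseline + updates + deletions, then study-record selection.

The analysis corpus is built by ingesting the annual baseline files first and
then the daily update files.  For each PMID only the record with the newest
``DateRevised`` is retained; ties break toward the later (file, index)
position, and records with no DateRevised sort as oldest.  Update files may
also carry a DeleteCitation block whose PMIDs become tombstones.

Selection then keeps only MEDLINE-status records that have a title and are
not news items, with a fixed exclusion precedence (status → news → title) so
the per-reason counts are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

from .xml_io import ArticleRecord, AuthorRecord, ReferenceEntry, XmlRecordSlice, parse_article

logger = logging.getLogger(__name__)

#: Publication types treated as journalism and excluded from the study set.
DEFAULT_NEWS_TYPES = frozenset({"News", "Newspaper Article"})

STORE_SCHEMA_VERSION = 1


@dataclass
class Corpus:
    """The assembled record set keyed by PMID, with provenance and tombstones."""

    records: dict[int, ArticleRecord] = field(default_factory=dict)
    provenance: dict[int, tuple[str, int]] = field(default_factory=dict)
    tombstones: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SelectionReport:
    """Per-reason exclusion counts for one selection run."""

    n_input: int = 0
    n_status_excluded: int = 0
    n_news_excluded: int = 0
    n_untitled_excluded: int = 0
    n_selected: int = 0

    def check(self) -> None:
        total = (
            self.n_selected
            + self.n_status_excluded
            + self.n_news_excluded
            + self.n_untitled_excluded
        )
        if total != self.n_input:
            raise AssertionError(
                f"selection counts do not add up: {total} != {self.n_input}"
            )


def _revision_key(record: ArticleRecord, prov: tuple[str, int]) -> tuple[date, str, int]:
    # No DateRevised sorts as oldest; ties on the date break toward the later
    # (file, index) provenance, i.e. the later export wins.
    return (record.date_revised or date.min, prov[0], prov[1])


def apply_updates(corpus: Corpus, updates: Iterable[XmlRecordSlice]) -> Corpus:
    """Fold article slices into the corpus, keeping the newest per PMID.

    The retained record for a PMID is the one with the newest DateRevised
    across everything seen so far; an unseen PMID is inserted.  A slice that
    fails to parse is logged and leaves the corpus unchanged for that PMID.
    An update for a tombstoned PMID re-inserts it (deletion is not final
    against later exports).
    """
    for slice_ in updates:
        if slice_.kind != "article":
            continue
        try:
            record = parse_article(slice_)
        except Exception as exc:  # parse failures are data, not fatal
            logger.warning(
                "%s[%d] PMID %s: update not applied: %s",
                slice_.source_file, slice_.source_index, slice_.pmid, exc,
            )
            continue
        prov = (slice_.source_file, slice_.source_index)
        existing = corpus.records.get(record.pmid)
        if existing is None or _revision_key(record, prov) >= _revision_key(
            existing, corpus.provenance[record.pmid]
        ):
            corpus.records[record.pmid] = record
            corpus.provenance[record.pmid] = prov
            corpus.tombstones.discard(record.pmid)
    return corpus


def apply_deletions(corpus: Corpus, deletions: Iterable[XmlRecordSlice]) -> Corpus:
    """Remove the listed PMIDs, recording them as tombstones."""
    for slice_ in deletions:
        if slice_.kind != "delete_citation":
            continue
        if slice_.pmid in corpus.records:
            del corpus.records[slice_.pmid]
            corpus.provenance.pop(slice_.pmid, None)
        else:
            logger.warning(
                "%s[%d]: deletion of absent PMID %d is a no-op",
                slice_.source_file, slice_.source_index, slice_.pmid,
            )
        corpus.tombstones.add(slice_.pmid)
    return corpus


def apply_file(corpus: Corpus, slices: Iterable[XmlRecordSlice]) -> Corpus:
    """Apply one file's slices in document order: articles, then deletions.

    In the distributed format the DeleteCitation block sits at the end of the
    file, so processing slices in source order gives update-then-delete
    semantics within a file.
    """
    slices = list(slices)
    apply_updates(corpus, (s for s in slices if s.kind == "article"))
    apply_deletions(corpus, (s for s in slices if s.kind == "delete_citation"))
    return corpus


def select_study_records(
    corpus: Corpus,
    news_types: frozenset[str] = DEFAULT_NEWS_TYPES,
) -> tuple[Corpus, SelectionReport]:
    """Apply the study's record-selection filters.

    Retains records with Status="MEDLINE", no news publication type, and a
    non-empty title.  Each excluded record is counted under the first
    matching reason in the order status → news → title.
    """
    report = SelectionReport(n_input=len(corpus.records))
    selected = Corpus(tombstones=set(corpus.tombstones))
    for pmid, record in corpus.records.items():
        if record.status != "MEDLINE":
            report.n_status_excluded += 1
        elif news_types.intersection(record.publication_types):
            report.n_news_excluded += 1
        elif record.title is None:
            report.n_untitled_excluded += 1
        else:
            selected.records[pmid] = record
            selected.provenance[pmid] = corpus.provenance.get(pmid, ("", 0))
            report.n_selected += 1
    report.check()
    return selected, report


# ---------------------------------------------------------------------------
# Corpus store: newline-delimited JSON records + a tombstone list.

def _record_to_dict(record: ArticleRecord) -> dict:
    d = dataclasses.asdict(record)
    if record.date_revised is not None:
        d["date_revised"] = record.date_revised.isoformat()
    return d


def _record_from_dict(d: dict) -> ArticleRecord:
    d = dict(d)
    if d.get("date_revised"):
        d["date_revised"] = date.fromisoformat(d["date_revised"])
    d["authors"] = [
        AuthorRecord(**{**a, "affiliation_identifiers": [tuple(x) for x in a["affiliation_identifiers"]]})
        for a in d["authors"]
    ]
    d["references"] = [
        ReferenceEntry(**{**r, "article_ids": [tuple(x) for x in r["article_ids"]]})
        for r in d["references"]
    ]
    return ArticleRecord(**d)


def save_corpus(corpus: Corpus, path: Union[str, Path]) -> None:
    """Write the corpus store: one JSON object per line.

    Line 1 is a schema header; record lines hold the record plus provenance;
    the final line lists the tombstoned PMIDs.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema": "medline-dq-corpus", "version": STORE_SCHEMA_VERSION}) + "\n")
        for pmid in sorted(corpus.records):
            fh.write(
                json.dumps(
                    {
                        "record": _record_to_dict(corpus.records[pmid]),
                        "provenance": list(corpus.provenance.get(pmid, ("", 0))),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
        fh.write(json.dumps({"tombstones": sorted(corpus.tombstones)}) + "\n")


def load_corpus(path: Union[str, Path]) -> Corpus:
    path = Path(path)
    corpus = Corpus()
    with path.open("r", encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("schema") != "medline-dq-corpus":
            raise ValueError(f"{path}: not a corpus store")
        for line in fh:
            obj = json.loads(line)
            if "tombstones" in obj:
                corpus.tombstones.update(obj["tombstones"])
            else:
                record = _record_from_dict(obj["record"])
                corpus.records[record.pmid] = record
                corpus.provenance[record.pmid] = tuple(obj["provenance"])  # type: ignore[assignment]
    return corpus
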