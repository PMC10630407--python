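"""Per-field interpretation rules for MEDLINE records.

Covers the semantics that sit between raw parsed fields and quality metrics:

* regex validation of persistent identifiers (DOI, ORCID, ISNI, GRID) — by
  pattern only, no checksum verification, with the all-zero ORCID placeholder
  explicitly rejected;
* MARC language-code parsing, including concatenated codes such as
  ``fregerita`` (French + German + Italian) and the rule that a solitary
  ``und``/``mul`` value is invalid;
* publication-year extraction with a structured-Year fast path and a
  free-text MedlineDate fallback scanned for four-digit runs under both
  reluctant (first match) and greedy (last match) semantics — the two can
  disagree when the string embeds page numbers;
* trailing e-mail extraction from affiliation strings;
* author-name anomaly flags (single-character surnames, collective names
  polluting personal-name fields, oversized forenames/suffixes/initials);
* duplicate-ORCID detection within one article and abstract-truncation
  sentinels.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .xml_io import ArticleRecord, AuthorRecord

__all__ = [
    "IdentifierPattern",
    "ValidationResult",
    "YearExtraction",
    "LanguageParse",
    "EmailExtraction",
    "ALL_ZERO_ORCID",
    "PLACEHOLDER_EMAIL",
    "load_identifier_patterns",
    "load_language_table",
    "load_truncation_sentinels",
    "validate_identifier",
    "validate_isni_any",
    "parse_language_field",
    "extract_publication_year",
    "extract_email_from_affiliation",
    "flag_author_anomalies",
    "detect_duplicate_orcid",
    "detect_truncated_abstract",
]

ALL_ZERO_ORCID = "0000-0000-0000-0000"
PLACEHOLDER_EMAIL = "user@example.com"

#: Publication years outside this window are treated as non-viable.
YEAR_WINDOW = (1800, datetime.date.today().year + 2)


@dataclass(frozen=True)
class IdentifierPattern:
    scheme: str
    pattern: str
    match_mode: str  # "full_match" | "search"

    def matches(self, value: str) -> bool:
        compiled = re.compile(self.pattern)
        if self.match_mode == "full_match":
            return compiled.fullmatch(value) is not None
        return compiled.search(value) is not None


@dataclass(frozen=True)
class ValidationResult:
    scheme: str
    present: bool
    valid: bool
    reason: str  # "ok" | "pattern_fail" | "all_zero_orcid" | "blank"


@dataclass(frozen=True)
class YearExtraction:
    source: str  # "structured" | "medline_date"
    year_reluctant: Optional[int]
    year_greedy: Optional[int]
    span_years: Optional[int]
    viable: bool
    greedy_viable: bool = False


@dataclass(frozen=True)
class LanguageParse:
    raw: str
    codes: tuple[str, ...]
    solitary_undetermined: bool
    ok: bool


@dataclass(frozen=True)
class EmailExtraction:
    email: Optional[str]
    placeholder: bool


def _data_text(name: str) -> str:
    return resources.files("medline_dq.data").joinpath(name).read_text(encoding="utf-8")


def load_identifier_patterns(text: Optional[str] = None) -> dict[str, IdentifierPattern]:
    """Load the shipped identifier patterns (or parse an alternative config)."""
    if text is None:
        text = _data_text("identifier_patterns.txt")
    patterns: dict[str, IdentifierPattern] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        scheme, pattern, match_mode = line.split("\t")
        re.compile(pattern)  # must compile; fail loudly at load time
        patterns[scheme] = IdentifierPattern(scheme, pattern, match_mode)
    return patterns


def load_language_table(text: Optional[str] = None) -> dict[str, str]:
    """MARC language code → name, from the shipped two-column TSV."""
    if text is None:
        text = _data_text("marc_languages.tsv")
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        code, name = line.split("\t")
        table[code] = name
    return table


def load_truncation_sentinels(text: Optional[str] = None) -> tuple[str, ...]:
    if text is None:
        text = _data_text("truncation_sentinels.txt")
    return tuple(
        line for line in text.splitlines() if line and not line.startswith("#")
    )


_PATTERNS = load_identifier_patterns()
_LANGUAGES = load_language_table()
_SENTINELS = load_truncation_sentinels()


def validate_identifier(
    scheme: str,
    value: Optional[str],
    patterns: Optional[dict[str, IdentifierPattern]] = None,
) -> ValidationResult:
    """Validate one identifier value against its scheme's pattern.

    Absent or blank values are "not present" (and therefore not valid).  An
    ORCID equal to the all-zero placeholder is present but invalid.  Only the
    ASCII hyphen-minus is accepted in ORCIDs.
    """
    patterns = patterns if patterns is not None else _PATTERNS
    if scheme not in patterns:
        raise KeyError(f"unknown identifier scheme {scheme!r}")
    if value is None or not value.strip():
        return ValidationResult(scheme, present=False, valid=False, reason="blank")
    if scheme == "ORCID" and value == ALL_ZERO_ORCID:
        return ValidationResult(scheme, present=True, valid=False, reason="all_zero_orcid")
    if patterns[scheme].matches(value):
        return ValidationResult(scheme, present=True, valid=True, reason="ok")
    return ValidationResult(scheme, present=True, valid=False, reason="pattern_fail")


def validate_isni_any(value: Optional[str]) -> ValidationResult:
    """ISNI validity in either the presentation (spaced) or compact form."""
    res = validate_identifier("ISNI_presentation", value)
    if res.valid or not res.present:
        return ValidationResult("ISNI", res.present, res.valid, res.reason)
    res = validate_identifier("ISNI_compact", value)
    return ValidationResult("ISNI", res.present, res.valid, res.reason)


def parse_language_field(
    raw: str, table: Optional[dict[str, str]] = None
) -> LanguageParse:
    """Split a Language value into consecutive 3-letter MARC codes.

    ``"fregerita"`` parses to ``("fre", "ger", "ita")``.  A length not
    divisible by 3, or any chunk absent from the code table, marks the parse
    failed with the raw value preserved.  ``solitary_undetermined`` is true
    exactly when the parse yields a single ``und`` or ``mul``; the flag never
    fires when other codes accompany them.
    """
    table = table if table is not None else _LANGUAGES
    if not raw:
        raise ValueError("parse_language_field requires a non-empty value")
    if len(raw) % 3 != 0:
        return LanguageParse(raw=raw, codes=(), solitary_undetermined=False, ok=False)
    codes = tuple(raw[i : i + 3] for i in range(0, len(raw), 3))
    if any(code not in table for code in codes):
        return LanguageParse(raw=raw, codes=(), solitary_undetermined=False, ok=False)
    solitary = codes in (("und",), ("mul",))
    return LanguageParse(raw=raw, codes=codes, solitary_undetermined=solitary, ok=True)


_FOUR_DIGITS = re.compile(r"\d{4}")
_LAST_FOUR_DIGITS = re.compile(r".*(\d{4})", re.DOTALL)


def _viable(year: Optional[int], window: tuple[int, int]) -> bool:
    return year is not None and window[0] <= year <= window[1]


def extract_publication_year(
    record: ArticleRecord, window: tuple[int, int] = YEAR_WINDOW
) -> YearExtraction:
    """Extract a publication year, preferring the structured Year element.

    When only a free-text MedlineDate is available, the string is scanned for
    four-digit substrings: the reluctant (shortest-match) extraction takes
    the first and the greedy (longest-match) extraction takes the last.  For
    span dates such as "1946 May–June" the two agree; for strings that embed
    page ranges (e.g. "1975 part 2): 1125–1132, Dec") the greedy value lands
    on a page number and is flagged non-viable by the plausibility window.
    """
    if record.pub_year_structured is not None:
        year = record.pub_year_structured
        return YearExtraction(
            source="structured",
            year_reluctant=year,
            year_greedy=year,
            span_years=0,
            viable=_viable(year, window),
            greedy_viable=_viable(year, window),
        )
    text = record.medline_date or ""
    first = _FOUR_DIGITS.search(text)
    if first is None:
        return YearExtraction(
            source="medline_date",
            year_reluctant=None,
            year_greedy=None,
            span_years=None,
            viable=False,
        )
    last = _LAST_FOUR_DIGITS.match(text)
    year_reluctant = int(first.group(0))
    year_greedy = int(last.group(1))  # type: ignore[union-attr]
    return YearExtraction(
        source="medline_date",
        year_reluctant=year_reluctant,
        year_greedy=year_greedy,
        span_years=year_greedy - year_reluctant,
        viable=_viable(year_reluctant, window),
        greedy_viable=_viable(year_greedy, window),
    )


# Conservative: a trailing local@domain.tld token, optionally ending with a
# period.  E-mail is only a cautionary discriminator here, so no RFC 5322
# ambition.
_TRAILING_EMAIL = re.compile(
    r"(?:^|\s)([A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,})\.?$"
)


def extract_email_from_affiliation(affiliation: str) -> EmailExtraction:
    """Extract the e-mail address historically appended to the first
    affiliation string, if present; flags the ``user@example.com``
    placeholder."""
    m = _TRAILING_EMAIL.search(affiliation.strip())
    if m is None:
        return EmailExtraction(email=None, placeholder=False)
    email = m.group(1)
    return EmailExtraction(email=email, placeholder=email.lower() == PLACEHOLDER_EMAIL)


@dataclass(frozen=True)
class AnomalyThresholds:
    collective_word_count: int = 8
    forename_concat_length: int = 100
    suffix_length: int = 20
    initials_length: int = 4


def flag_author_anomalies(
    author: AuthorRecord, thresholds: AnomalyThresholds = AnomalyThresholds()
) -> set[str]:
    """Flag name-field pathologies on one author entry.

    The flags cover the recurring pollution patterns: one-character surnames
    (transposition errors), collective names entered into personal-name
    fields, forenames that carry a concatenated affiliation, and oversized
    suffix/initials values.
    """
    flags: set[str] = set()
    if author.last_name is not None and len(author.last_name) == 1:
        flags.add("single_char_last_name")
    for name in (author.last_name, author.fore_name):
        if name is not None and len(name.split(" ")) >= thresholds.collective_word_count:
            flags.add("suspected_collective_in_personal_field")
    if (
        author.fore_name is not None
        and len(author.fore_name) >= thresholds.forename_concat_length
    ):
        flags.add("forename_equals_affiliation_concat")
    if author.suffix is not None and len(author.suffix) >= thresholds.suffix_length:
        flags.add("suffix_pollution")
    if author.initials is not None and len(author.initials) > thresholds.initials_length:
        flags.add("initials_overlong")
    return flags


def detect_duplicate_orcid(article: ArticleRecord) -> list[tuple[str, list[int]]]:
    """Group valid ORCIDs shared by two or more author positions of one
    article — the "same ORCID allocated to multiple authors" error."""
    by_orcid: dict[str, list[int]] = {}
    for author in article.authors:
        if author.orcid_raw is None:
            continue
        if validate_identifier("ORCID", author.orcid_raw).valid:
            by_orcid.setdefault(author.orcid_raw, []).append(author.position)
    return [
        (orcid, positions)
        for orcid, positions in sorted(by_orcid.items())
        if len(set(positions)) >= 2
    ]


def detect_truncated_abstract(
    abstract: str, sentinels: Optional[Sequence[str]] = None
) -> bool:
    """True iff the abstract ends with an NLM truncation sentinel phrase."""
    sentinels = sentinels if sentinels is not None else _SENTINELS
    stripped = abstract.rstrip()
    return any(stripped.endswith(s) for s in sentinels)
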