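"""Seeded synthetic PubMed corpus generator with fault injection.

Generates DTD-shaped ``PubmedArticleSet`` XML (baseline files, update files
with deletions, and a matching journal reference list) together with a
ground-truth :class:`PathologyManifest`, so the whole assessment pipeline can
be exercised end to end without downloading anything.

Every known data pathology of the real corpus is modelled as an independent
Bernoulli event per eligible record or author at a configurable rate:
collective names polluting personal-name fields, interleaved collective
groups (including the repeated-member pattern), one-character surnames,
affiliation text concatenated into forenames, oversized suffixes, duplicate
and all-zero ORCIDs, placeholder e-mails, narrative and punctuation-only
affiliations, span-type and erroneous MedlineDate values, concatenated
language codes, solitary und/mul languages, nested and singleton-sibling
reference lists, control/extended characters, truncation sentinels,
placeholder abstracts and titles, missing titles, news publication types,
non-MEDLINE statuses, invalid (ValidYN="N") author entries and dangling
journal identifiers.  Each applied injection is logged in the manifest,
which downstream tests treat as the oracle.

Same seed ⇒ bit-identical corpus and manifest: each record draws from its
own deterministic random stream keyed by ``(seed, record index)``, so
injection decisions are independent of record order.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .xml_io import sanitize_text

__all__ = [
    "PATHOLOGY_REGISTRY",
    "PATHOLOGY_DETECTORS",
    "SyntheticCorpusConfig",
    "PathologyManifest",
    "GenerationError",
    "generate_corpus",
    "generate_corpus_bytes",
    "generate_update_batch",
    "generate_journal_reference",
]


class GenerationError(ValueError):
    """Raised for impossible generator configurations."""


#: Pathology name -> (default rate, scope).  Scope "record" draws once per
#: record, "author" once per personal author entry.
PATHOLOGY_REGISTRY: dict[str, tuple[float, str]] = {
    "narrative_affiliation": (0.01, "author"),
    "punctuation_only_affiliation": (0.01, "author"),
    "collective_in_lastname": (0.005, "author"),
    "interleaved_collective_groups": (0.002, "record"),
    "repeated_author_via_groups": (0.001, "record"),
    "single_char_last_name": (0.005, "author"),
    "forename_affiliation_concat": (0.001, "author"),
    "suffix_pollution": (0.002, "author"),
    "duplicate_orcid_in_article": (0.002, "record"),
    "all_zero_orcid": (0.0005, "author"),
    "placeholder_email": (0.002, "author"),
    "invalid_author_validyn": (0.002, "author"),
    "medline_date_span": (0.01, "record"),
    "medline_date_erroneous": (0.002, "record"),
    "concatenated_language_codes": (0.005, "record"),
    "solitary_und_mul": (0.002, "record"),
    "nested_reference_list": (0.05, "record"),
    "many_singleton_reference_lists": (0.05, "record"),
    "escape_characters": (0.02, "record"),
    "extended_characters": (0.05, "record"),
    "truncated_abstract_sentinel": (0.004, "record"),
    "placeholder_abstract": (0.002, "record"),
    "short_placeholder_title": (0.002, "record"),
    "missing_title": (0.0003, "record"),
    "news_publication_type": (0.001, "record"),
    "non_medline_status": (0.05, "record"),
    "dangling_journal": (0.005, "record"),
}

#: Which downstream operation or metric recovers each pathology (enforced by
#: a registry-completeness test).
PATHOLOGY_DETECTORS: dict[str, str] = {
    "narrative_affiliation": "profiling.extreme_values on affiliation_first (longest)",
    "punctuation_only_affiliation": "profiling.profile_string_field top table under 20 chars",
    "collective_in_lastname": "semantics.flag_author_anomalies: suspected_collective_in_personal_field",
    "interleaved_collective_groups": "xml_io.extract_authors preserves collective entries in order",
    "repeated_author_via_groups": "xml_io.extract_authors yields repeated identical name parts",
    "single_char_last_name": "semantics.flag_author_anomalies: single_char_last_name",
    "forename_affiliation_concat": "semantics.flag_author_anomalies: forename_equals_affiliation_concat",
    "suffix_pollution": "semantics.flag_author_anomalies: suffix_pollution",
    "duplicate_orcid_in_article": "semantics.detect_duplicate_orcid",
    "all_zero_orcid": "semantics.validate_identifier reason=all_zero_orcid",
    "placeholder_email": "semantics.extract_email_from_affiliation placeholder flag",
    "invalid_author_validyn": "xml_io.extract_authors excludes ValidYN=N (count = elements - parsed)",
    "medline_date_span": "semantics.extract_publication_year span_years > 0",
    "medline_date_erroneous": "semantics.extract_publication_year viable/greedy_viable flags",
    "concatenated_language_codes": "semantics.parse_language_field multi-code parse",
    "solitary_und_mul": "semantics.parse_language_field solitary_undetermined",
    "nested_reference_list": "xml_io.flatten_references nesting_depth > 0",
    "many_singleton_reference_lists": "xml_io.flatten_references yields one entry per singleton list",
    "escape_characters": "xml_io.sanitize_text collapses control characters",
    "extended_characters": "xml_io.sanitize_text preserves non-ASCII under NFC",
    "truncated_abstract_sentinel": "semantics.detect_truncated_abstract",
    "placeholder_abstract": "profiling.profile_string_field top table under 20 chars",
    "short_placeholder_title": "profiling.profile_string_field top table under 20 chars",
    "missing_title": "corpus.select_study_records n_untitled_excluded",
    "news_publication_type": "corpus.select_study_records n_news_excluded",
    "non_medline_status": "corpus.select_study_records n_status_excluded",
    "dangling_journal": "metrics.referential_integrity dangling_keys / n_affected",
}

_FILLER = (
    "analysis assay binding cardiac cell clinical cohort control disease dna "
    "effect enzyme expression factor function gene growth human immune kinase "
    "level liver mechanism model mouse outcome pathway patient plasma protein "
    "receptor response risk serum signal study therapy tissue treatment tumor"
).split()

_LAST_NAMES = (
    "Wang Li Zhang Chen Liu Lee Kim Yang Wu Huang Smith Jones Garcia Müller "
    "Rossi Tanaka Singh Kumar Ivanov Novak Silva Santos Park Choi Nguyen"
).split()

_FORE_NAMES = (
    "Wei Jing Yan Hui Min James Mary Robert Linda David Maria Anna Hiroshi "
    "Yuki Priya Arjun Olga Ivan Ana Carlos Sofia Jan Eva Marie Pierre"
).split()

_COLLECTIVES = (
    "Neonatal Screening Group Specialist Committee For Prevention And Control Of Birth Defects",
    "The Group Of Minimally Invasive Spinal Surgery And Enhanced Recovery Professional Committee",
    "Expert Committee Of The Inter-Laboratory Quality Assessment Of Prenatal Screening",
    "International Wheat Genome Sequencing Consortium Working Group Three",
    "Consensus Group Of Experts On Application Of Metagenomic Next Generation Sequencing",
)

_EXTENDED_WORDS = ("İstanbul", "Müller", "Søren", "Ramírez", "Dvořák", "Çelik")

_LANG_WEIGHTED = (
    ["eng"] * 50 + ["ger", "fre", "rus", "jpn", "spa", "chi", "ita", "pol"]
)

_SENTINELS = (
    "(ABSTRACT TRUNCATED)",
    "(ABSTRACT TRUNCATED AT 250 WORDS)",
    "(ABSTRACT TRUNCATED AT 400 WORDS)",
)

_ERRONEOUS_MEDLINE_DATES = (
    # Forms modelled on the observed erroneous values: pagination ranges
    # trailing the year, and a bare junk token with no year at all.
    "{y} part 2): 1125-1132, Dec",
    "{y} Suppl): 1035-15 August 1041",
    "1",
)


@dataclass
class SyntheticCorpusConfig:
    """Study conditions for one synthetic corpus.

    Identifier presence rates echo the observed orders of magnitude: DOIs on
    most articles, ORCIDs on a few percent of authors, institutional
    identifiers (ISNI/GRID) far rarer, affiliation strings a bit under half.
    """

    n_records: int = 10_000
    seed: int = 0
    records_per_file: int = 30_000
    base_pmid: int = 10_000_001
    year_range: tuple[int, int] = (1960, 2022)
    doi_rate: float = 0.7
    #: Optional (rate_at_min_year, rate_at_max_year) linear ramp; overrides doi_rate.
    doi_rate_by_year: Optional[tuple[float, float]] = None
    doi_invalid_rate: float = 0.006
    orcid_rate: float = 0.03
    orcid_invalid_rate: float = 0.001
    isni_rate: float = 0.002
    grid_rate: float = 0.002
    affiliation_rate: float = 0.45
    multi_affiliation_rate: float = 0.05
    abstract_rate: float = 0.67
    copyright_rate: float = 0.22
    email_rate: float = 0.01
    reference_rate: float = 0.6
    decoy_rate: float = 0.1  # InvestigatorList/ChemicalList decoys the parser must ignore
    n_journals: int = 50
    n_dangling_journals: int = 5
    author_count_weights: tuple[int, ...] = (5, 10, 15, 20, 15, 10, 5, 2)  # 1..8 authors
    pathology_rates: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in PATHOLOGY_REGISTRY.items()}
    )

    def validate(self) -> None:
        if self.n_records < 1:
            raise GenerationError("n_records must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise GenerationError("year_range min > max")
        for name, rate in self.pathology_rates.items():
            if name not in PATHOLOGY_REGISTRY:
                raise GenerationError(f"unknown pathology {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"rate for {name} out of [0,1]: {rate}")
        for a, b in (("missing_title", "short_placeholder_title"),
                     ("solitary_und_mul", "concatenated_language_codes"),
                     ("medline_date_erroneous", "medline_date_span")):
            if self.pathology_rates.get(a, 0) + self.pathology_rates.get(b, 0) > 1.0:
                raise GenerationError(
                    f"conflicting rates: {a} + {b} exceed 1.0 within one exclusive group"
                )

    def rate(self, name: str) -> float:
        return self.pathology_rates.get(name, 0.0)

    def journal_pool(self) -> list[str]:
        return [str(8_000_000 + i) for i in range(self.n_journals)]

    def dangling_pool(self) -> list[str]:
        return [str(8_100_000 + i) for i in range(self.n_dangling_journals)]

    def doi_rate_for_year(self, year: int) -> float:
        if self.doi_rate_by_year is None:
            return self.doi_rate
        lo, hi = self.year_range
        start, end = self.doi_rate_by_year
        if hi == lo:
            return end
        frac = (year - lo) / (hi - lo)
        return start + (end - start) * frac


@dataclass
class PathologyManifest:
    """Ground truth for one generated corpus: per-record facts and injections,
    plus global counts and per-year identifier tallies."""

    seed: int
    n_records: int
    records: list[dict] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)
    per_year: dict[int, dict[str, int]] = field(default_factory=dict)
    journal_usage: Counter = field(default_factory=Counter)

    def add_record(self, facts: dict) -> None:
        self.records.append(facts)
        for p in facts["pathologies"]:
            self.counts[p["name"]] += 1
        if facts["year_viable"]:
            slot = self.per_year.setdefault(
                facts["year_reluctant"],
                {"articles": 0, "valid_doi": 0, "authors": 0, "valid_orcid": 0},
            )
            slot["articles"] += 1
            slot["valid_doi"] += int(facts["doi_valid"])
            slot["authors"] += facts["n_parsed_authors"]
            slot["valid_orcid"] += facts["n_valid_orcid_authors"]
        self.journal_usage[facts["journal_nlm_id"]] += 1

    def to_json_lines(self) -> str:
        head = json.dumps(
            {"schema": "medline-dq-manifest", "seed": self.seed, "n_records": self.n_records},
            sort_keys=True,
        )
        body = "\n".join(
            json.dumps(rec, sort_keys=True, ensure_ascii=False) for rec in self.records
        )
        tail = json.dumps({"counts": dict(sorted(self.counts.items()))}, ensure_ascii=False)
        return head + "\n" + body + "\n" + tail + "\n"


def _sub(parent: etree._Element, tag: str, text: Optional[str] = None, **attrs: str) -> etree._Element:
    el = etree.SubElement(parent, tag, attrs)
    if text is not None:
        el.text = text
    return el


def _sentence(rng: random.Random, n_words: int) -> str:
    words = [rng.choice(_FILLER) for _ in range(n_words)]
    return " ".join(words).capitalize() + "."


def _valid_orcid(rng: random.Random) -> str:
    parts = [rng.randint(0, 9999) for _ in range(3)]
    last = rng.randint(1, 9999)  # never all-zero
    return f"0000-{parts[1]:04d}-{parts[2]:04d}-{last:04d}"


def _build_record(config: SyntheticCorpusConfig, index: int) -> tuple[etree._Element, dict]:
    """Build one PubmedArticle element plus its manifest facts."""
    rng = random.Random(f"{config.seed}:{index}")
    pmid = config.base_pmid + index
    pathologies: list[dict] = []

    def draw(name: str) -> bool:
        return rng.random() < config.rate(name)

    def inject(name: str, **params) -> None:
        pathologies.append({"name": name, **params})

    year = rng.randint(*config.year_range)

    # --- record-scope draws (always consumed in a fixed order so streams
    # stay aligned across configurations) -----------------------------------
    p_non_medline = draw("non_medline_status")
    p_news = draw("news_publication_type")
    p_missing_title = draw("missing_title")
    p_placeholder_title = draw("short_placeholder_title")
    p_escape = draw("escape_characters")
    p_extended = draw("extended_characters")
    p_md_err = draw("medline_date_erroneous")
    p_md_span = draw("medline_date_span")
    p_solitary = draw("solitary_und_mul")
    p_concat_lang = draw("concatenated_language_codes")
    p_placeholder_abs = draw("placeholder_abstract")
    p_truncated = draw("truncated_abstract_sentinel")
    p_nested_refs = draw("nested_reference_list")
    p_singleton_refs = draw("many_singleton_reference_lists")
    p_interleaved = draw("interleaved_collective_groups")
    p_repeated = draw("repeated_author_via_groups")
    p_dup_orcid = draw("duplicate_orcid_in_article")
    p_dangling = draw("dangling_journal")

    status = "MEDLINE"
    if p_non_medline:
        status = rng.choice(["In-Process", "PubMed-not-MEDLINE", "Publisher"])
        inject("non_medline_status", status=status)

    pub_types = ["Journal Article"]
    if p_news:
        pub_types.append("News")
        inject("news_publication_type")

    # Title (precedence: missing > placeholder > normal)
    title: Optional[str] = _sentence(rng, rng.randint(5, 12))
    if p_missing_title:
        title = None
        inject("missing_title")
    elif p_placeholder_title:
        title = "[Not Available]."
        inject("short_placeholder_title")
    if title is not None and p_extended:
        title = title[:-1] + " in " + rng.choice(_EXTENDED_WORDS) + "."
        inject("extended_characters")
    raw_title = title
    if title is not None and p_escape:
        # Control characters and escapes the sanitizer must neutralize while
        # preserving backslashes and quotes.
        raw_title = title[:-1] + ' \\ "quoted"\r\n\ttail.'
        title = sanitize_text(raw_title)
        inject("escape_characters")

    # Publication date (precedence: erroneous > span > structured)
    pub_year_structured: Optional[int] = year
    medline_date: Optional[str] = None
    if p_md_err:
        form = rng.choice(_ERRONEOUS_MEDLINE_DATES)
        medline_date = form.format(y=year)
        pub_year_structured = None
        inject("medline_date_erroneous", value=medline_date)
    elif p_md_span:
        span = rng.randint(1, 3)
        medline_date = f"{year} Nov-{year + span} Jan"
        pub_year_structured = None
        inject("medline_date_span", span=span)

    # Expected year extraction facts
    import re as _re

    if pub_year_structured is not None:
        year_reluctant: Optional[int] = pub_year_structured
        year_greedy: Optional[int] = pub_year_structured
    else:
        runs = _re.findall(r"\d{4}", medline_date or "")
        year_reluctant = int(runs[0]) if runs else None
        m = _re.match(r".*(\d{4})", medline_date or "", _re.DOTALL)
        year_greedy = int(m.group(1)) if m else None
    year_viable = year_reluctant is not None and 1800 <= year_reluctant <= 2100

    # Languages (precedence: solitary > concatenated > single weighted code)
    if p_solitary:
        languages = [rng.choice(["und", "mul"])]
        inject("solitary_und_mul", value=languages[0])
    elif p_concat_lang:
        n_codes = rng.randint(2, 3)
        codes = rng.sample(["fre", "ger", "ita", "spa", "rus", "eng"], n_codes)
        languages = ["".join(codes)]
        inject("concatenated_language_codes", value=languages[0])
    else:
        languages = [rng.choice(_LANG_WEIGHTED)]

    # Abstract
    abstract: Optional[str] = None
    truncated = False
    if rng.random() < config.abstract_rate:
        if p_placeholder_abs:
            abstract = "[Figure: see text]."
            inject("placeholder_abstract")
        else:
            abstract = _sentence(rng, rng.randint(30, 80))
            if p_truncated:
                abstract = abstract + " " + rng.choice(_SENTINELS)
                truncated = True
                inject("truncated_abstract_sentinel")
    copyright_info: Optional[str] = None
    if abstract is not None and rng.random() < config.copyright_rate:
        copyright_info = rng.choice(
            [
                f"Copyright © {year} Elsevier Inc. All rights reserved.",
                f"© {year}. The Author(s).",
                f"©{year} AACR.",
            ]
        )

    # Journal
    if p_dangling:
        journal_nlm_id = rng.choice(config.dangling_pool())
        inject("dangling_journal", nlm_id=journal_nlm_id)
    else:
        journal_nlm_id = rng.choice(config.journal_pool())

    # DOI
    doi: Optional[str] = None
    doi_valid = False
    if rng.random() < config.doi_rate_for_year(year):
        if rng.random() < config.doi_invalid_rate:
            doi = f"doi:10.1/{pmid}"
        else:
            doi = f"10.{1000 + rng.randint(0, 8999)}/synth.{pmid}"
            doi_valid = True

    # --- authors ------------------------------------------------------------
    n_personal = rng.choices(range(1, len(config.author_count_weights) + 1),
                             weights=config.author_count_weights)[0]
    authors: list[dict] = []  # plan entries; "kind": personal|collective
    for a in range(n_personal):
        plan: dict = {"kind": "personal", "valid_yn": "Y"}
        last = rng.choice(_LAST_NAMES)
        fore = rng.choice(_FORE_NAMES)
        if draw("invalid_author_validyn"):
            plan["valid_yn"] = "N"
            inject("invalid_author_validyn", author_index=a)
        if draw("collective_in_lastname"):
            last = rng.choice(_COLLECTIVES)
            inject("collective_in_lastname", author_index=a)
        elif draw("single_char_last_name"):
            last = last[0]
            inject("single_char_last_name", author_index=a)
        if draw("forename_affiliation_concat"):
            fore = (
                fore
                + " Department Of Radiology University Hospital College Of Medicine "
                + "The University Of The Republic Seoul Republic Of Korea Smart Imaging Center"
            )
            inject("forename_affiliation_concat", author_index=a)
        suffix: Optional[str] = None
        if draw("suffix_pollution"):
            suffix = "(Conceptualization; Review and editing; Approved final version)"
            inject("suffix_pollution", author_index=a)
        elif rng.random() < 0.02:
            suffix = rng.choice(["Jr", "3rd", "2nd", "Sr"])
        plan.update(
            last_name=last,
            fore_name=fore,
            initials="".join(w[0] for w in fore.split(" ")[:2]).upper()[:2],
            suffix=suffix,
        )

        # ORCID
        orcid: Optional[str] = None
        orcid_valid = False
        all_zero = False
        if draw("all_zero_orcid"):
            orcid = "0000-0000-0000-0000"
            all_zero = True
            inject("all_zero_orcid", author_index=a)
        elif rng.random() < config.orcid_rate:
            if rng.random() < config.orcid_invalid_rate:
                orcid = f"0000-0002-{rng.randint(0, 999):03d}"  # malformed
            else:
                orcid = _valid_orcid(rng)
                orcid_valid = True
        plan.update(orcid=orcid, orcid_valid=orcid_valid, orcid_all_zero=all_zero)

        # Affiliation (precedence: narrative > punctuation-only > normal)
        affiliation: Optional[str] = None
        extra_affiliations = 0
        p_narrative = draw("narrative_affiliation")
        p_punct = draw("punctuation_only_affiliation")
        p_email = draw("placeholder_email")
        if rng.random() < config.affiliation_rate or p_narrative or p_punct or p_email:
            if p_narrative:
                depts = "; ".join(
                    f"Department of {rng.choice(_FILLER).capitalize()}, University of "
                    f"{rng.choice(_FILLER).capitalize()}"
                    for _ in range(12)
                )
                affiliation = (
                    "The authors are affiliated as follows: " + depts + ", and collaborating centres."
                )
                inject("narrative_affiliation", author_index=a)
            elif p_punct:
                affiliation = rng.choice([".", ",."])
                inject("punctuation_only_affiliation", author_index=a)
            else:
                affiliation = (
                    f"Department of {rng.choice(_FILLER).capitalize()}, "
                    f"University of {rng.choice(_FILLER).capitalize()}, "
                    f"{rng.choice(['London, UK', 'Paris, France', 'Seoul, Republic of Korea', 'Boston, MA, USA'])}."
                )
                if p_extended and rng.random() < 0.5:
                    affiliation = affiliation[:-1] + f", {rng.choice(_EXTENDED_WORDS)}."
            if p_email:
                affiliation = affiliation + " user@example.com."
                inject("placeholder_email", author_index=a)
            elif rng.random() < config.email_rate and not p_punct:
                affiliation = affiliation + f" {fore.split(' ')[0].lower()}.{last.split(' ')[0].lower()}@example.org."
            if rng.random() < config.multi_affiliation_rate:
                extra_affiliations = rng.randint(1, 2)
        plan.update(affiliation=affiliation, extra_affiliations=extra_affiliations)

        # Institutional identifiers ride on the first affiliation
        isni: Optional[str] = None
        grid: Optional[str] = None
        if affiliation is not None:
            if rng.random() < config.isni_rate:
                digits = [str(rng.randint(0, 9)) for _ in range(15)]
                check = rng.choice("0123456789X")
                if rng.random() < 0.5:
                    compact = "".join(digits) + check
                    isni = compact
                else:
                    d = "".join(digits) + check
                    isni = f"{d[0:4]} {d[4:8]} {d[8:12]} {d[12:16]}"
            if rng.random() < config.grid_rate:
                grid = f"grid.{rng.randint(1000, 999999)}.{rng.choice('0123456789abcdef')}"
        plan.update(isni=isni, grid=grid)
        authors.append(plan)

    # Duplicate ORCID within the article (needs >= 2 ValidYN=Y personal
    # authors; all-zero carriers are left alone so their injection stays true)
    valid_idx = [
        i
        for i, p in enumerate(authors)
        if p["valid_yn"] == "Y" and not p.get("orcid_all_zero")
    ]
    if p_dup_orcid and len(valid_idx) >= 2:
        i1, i2 = rng.sample(valid_idx, 2)
        shared = _valid_orcid(rng)
        for i in (i1, i2):
            authors[i].update(orcid=shared, orcid_valid=True, orcid_all_zero=False)
        inject("duplicate_orcid_in_article", author_indices=sorted([i1, i2]), orcid=shared)

    # Interleaved collective groups, optionally with a repeated member
    if p_interleaved or p_repeated:
        n_groups = rng.randint(2, 4) if not p_repeated else rng.randint(2, 3)
        entries: list[dict] = []
        repeated_member: Optional[dict] = None
        if p_repeated:
            repeated_member = {
                "kind": "personal",
                "valid_yn": "Y",
                "last_name": rng.choice(_LAST_NAMES),
                "fore_name": rng.choice(_FORE_NAMES),
                "initials": "X",
                "suffix": None,
                "orcid": None,
                "orcid_valid": False,
                "orcid_all_zero": False,
                "affiliation": None,
                "extra_affiliations": 0,
                "isni": None,
                "grid": None,
            }
        for g in range(n_groups):
            entries.append({"kind": "collective", "valid_yn": "Y",
                            "collective_name": f"{rng.choice(_COLLECTIVES)} Subgroup {g + 1}"})
            if repeated_member is not None:
                entries.append(dict(repeated_member))
        authors.extend(entries)
        if p_interleaved:
            inject("interleaved_collective_groups", n_groups=n_groups)
        if p_repeated:
            inject(
                "repeated_author_via_groups",
                n_groups=n_groups,
                last_name=repeated_member["last_name"],  # type: ignore[index]
            )

    # --- references ----------------------------------------------------------
    ref_texts: list[tuple[str, int]] = []  # (citation, depth)
    if rng.random() < config.reference_rate or p_nested_refs or p_singleton_refs:
        n_refs = rng.randint(1, 5)
        for r in range(n_refs):
            ref_texts.append((_sentence(rng, 6), 0))
    nested_depth = 0
    if p_nested_refs:
        nested_depth = rng.randint(1, 3)
        ref_texts.append((_sentence(rng, 6), nested_depth))
        inject("nested_reference_list", depth=nested_depth)
    n_singletons = 0
    if p_singleton_refs:
        n_singletons = rng.randint(2, 5)
        inject("many_singleton_reference_lists", n_lists=n_singletons)

    date_revised = (
        rng.randint(2015, 2021),
        rng.randint(1, 12),
        rng.randint(1, 28),
    )

    # --- build the XML element ----------------------------------------------
    pa = etree.Element("PubmedArticle")
    citation = _sub(pa, "MedlineCitation", Status=status, Owner="NLM")
    _sub(citation, "PMID", str(pmid), Version="1")
    dr = _sub(citation, "DateRevised")
    _sub(dr, "Year", f"{date_revised[0]:04d}")
    _sub(dr, "Month", f"{date_revised[1]:02d}")
    _sub(dr, "Day", f"{date_revised[2]:02d}")
    art = _sub(citation, "Article", PubModel="Print")
    journal = _sub(art, "Journal")
    issue = _sub(journal, "JournalIssue", CitedMedium="Print")
    pubdate = _sub(issue, "PubDate")
    if pub_year_structured is not None:
        _sub(pubdate, "Year", str(pub_year_structured))
    else:
        _sub(pubdate, "MedlineDate", medline_date)
    _sub(journal, "Title", f"Synthetic Journal {journal_nlm_id}")
    if raw_title is not None:
        _sub(art, "ArticleTitle", raw_title)
    if abstract is not None:
        abs_el = _sub(art, "Abstract")
        _sub(abs_el, "AbstractText", abstract)
        if copyright_info is not None:
            _sub(abs_el, "CopyrightInformation", copyright_info)
    alist = _sub(art, "AuthorList", CompleteYN="Y")
    for plan in authors:
        a_el = _sub(alist, "Author", ValidYN=plan["valid_yn"])
        if plan["kind"] == "collective":
            _sub(a_el, "CollectiveName", plan["collective_name"])
            continue
        _sub(a_el, "LastName", plan["last_name"])
        _sub(a_el, "ForeName", plan["fore_name"])
        _sub(a_el, "Initials", plan["initials"])
        if plan["suffix"] is not None:
            _sub(a_el, "Suffix", plan["suffix"])
        if plan["orcid"] is not None:
            _sub(a_el, "Identifier", plan["orcid"], Source="ORCID")
        if plan["affiliation"] is not None:
            info = _sub(a_el, "AffiliationInfo")
            _sub(info, "Affiliation", plan["affiliation"])
            if plan["isni"] is not None:
                _sub(info, "Identifier", plan["isni"], Source="ISNI")
            if plan["grid"] is not None:
                _sub(info, "Identifier", plan["grid"], Source="GRID")
            for k in range(plan["extra_affiliations"]):
                info = _sub(a_el, "AffiliationInfo")
                _sub(info, "Affiliation", f"Secondary Department {k + 1}, University of Elsewhere.")
    for lang in languages:
        _sub(art, "Language", lang)
    ptl = _sub(art, "PublicationTypeList")
    for pt in pub_types:
        _sub(ptl, "PublicationType", pt, UI="")
    if rng.random() < config.decoy_rate:
        # Decoy content the extractor must ignore.
        ilist = _sub(citation, "InvestigatorList")
        inv = _sub(ilist, "Investigator", ValidYN="Y")
        _sub(inv, "LastName", rng.choice(_LAST_NAMES))
        _sub(inv, "ForeName", rng.choice(_FORE_NAMES))
        chem = _sub(citation, "ChemicalList")
        c = _sub(chem, "Chemical")
        _sub(c, "NameOfSubstance", rng.choice(_FILLER), UI="D000000")
    mji = _sub(citation, "MedlineJournalInfo")
    _sub(mji, "Country", "England")
    _sub(mji, "NlmUniqueID", journal_nlm_id)
    pubmed_data = _sub(pa, "PubmedData")
    id_list = _sub(pubmed_data, "ArticleIdList")
    _sub(id_list, "ArticleId", str(pmid), IdType="pubmed")
    if doi is not None:
        _sub(id_list, "ArticleId", doi, IdType="doi")
    base_refs = [(t, d) for t, d in ref_texts if d == 0]
    deep_refs = [(t, d) for t, d in ref_texts if d > 0]
    if base_refs or deep_refs:
        rl = _sub(pubmed_data, "ReferenceList")
        _sub(rl, "Title", "References")
        for text, _ in base_refs:
            ref = _sub(rl, "Reference")
            _sub(ref, "Citation", text)
        for text, depth in deep_refs:
            target = rl
            for _ in range(depth):
                target = _sub(target, "ReferenceList")
            ref = _sub(target, "Reference")
            _sub(ref, "Citation", text)
    for s in range(n_singletons):
        rl = _sub(pubmed_data, "ReferenceList")
        ref = _sub(rl, "Reference")
        _sub(ref, "Citation", _sentence(rng, 6))
        ref_texts.append(("singleton", 0))

    # --- manifest facts -------------------------------------------------------
    n_parsed_authors = sum(1 for p in authors if p["valid_yn"] == "Y")
    n_valid_orcid = sum(
        1
        for p in authors
        if p["valid_yn"] == "Y" and p["kind"] == "personal" and p.get("orcid_valid")
    )
    facts = {
        "pmid": pmid,
        "status": status,
        "is_news": p_news,
        "has_title": title is not None,
        "title": title,
        "year": year,
        "pub_year_structured": pub_year_structured,
        "medline_date": medline_date,
        "year_reluctant": year_reluctant,
        "year_greedy": year_greedy,
        "year_viable": year_viable,
        "languages": languages,
        "solitary_und_mul": bool(p_solitary),
        "journal_nlm_id": journal_nlm_id,
        "journal_dangling": bool(p_dangling),
        "doi": doi,
        "doi_valid": doi_valid,
        "has_abstract": abstract is not None,
        "truncated_abstract": truncated,
        "n_author_elements": len(authors),
        "n_parsed_authors": n_parsed_authors,
        "n_validyn_n": sum(1 for p in authors if p["valid_yn"] == "N"),
        "n_collective_entries": sum(
            1 for p in authors if p["kind"] == "collective" and p["valid_yn"] == "Y"
        ),
        "n_all_zero_orcid": sum(
            1 for p in authors if p["valid_yn"] == "Y" and p.get("orcid_all_zero")
        ),
        "n_valid_orcid_authors": n_valid_orcid,
        "has_duplicate_orcid": any(
            p["name"] == "duplicate_orcid_in_article" for p in pathologies
        ),
        "n_with_affiliation": sum(
            1
            for p in authors
            if p["valid_yn"] == "Y" and p["kind"] == "personal" and p.get("affiliation")
        ),
        "n_references": len(ref_texts),
        "max_reference_depth": nested_depth,
        "pathologies": pathologies,
    }
    return pa, facts


def generate_corpus_bytes(
    config: SyntheticCorpusConfig,
) -> tuple[list[bytes], PathologyManifest]:
    """Generate the corpus as in-memory XML byte strings (one per file)."""
    config.validate()
    manifest = PathologyManifest(seed=config.seed, n_records=config.n_records)
    files: list[bytes] = []
    root: Optional[etree._Element] = None
    for index in range(config.n_records):
        if index % config.records_per_file == 0:
            if root is not None:
                files.append(
                    etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
                )
            root = etree.Element("PubmedArticleSet")
        element, facts = _build_record(config, index)
        root.append(element)  # type: ignore[union-attr]
        manifest.add_record(facts)
    if root is not None:
        files.append(
            etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
        )
    return files, manifest


def generate_corpus(
    config: SyntheticCorpusConfig, out_dir: Union[str, Path], compress: bool = True
) -> tuple[list[Path], PathologyManifest]:
    """Generate baseline XML files plus the manifest under ``out_dir``.

    Files are gzipped with a zeroed mtime so the same seed produces
    byte-identical output.  The manifest is written alongside as
    newline-delimited JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blobs, manifest = generate_corpus_bytes(config)
    paths: list[Path] = []
    for i, blob in enumerate(blobs):
        if compress:
            path = out_dir / f"synthetic_baseline_{i + 1:04d}.xml.gz"
            with open(path, "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                    gz.write(blob)
        else:
            path = out_dir / f"synthetic_baseline_{i + 1:04d}.xml"
            path.write_bytes(blob)
        paths.append(path)
    (out_dir / "manifest.ndjson").write_text(manifest.to_json_lines(), encoding="utf-8")
    return paths, manifest


@dataclass
class UpdateDelta:
    """Expected post-merge state after applying one update batch."""

    revised_pmids: list[int]
    added: list[dict]  # facts of brand-new records
    deleted_pmids: list[int]
    revised_facts: dict[int, dict] = field(default_factory=dict)

    def expected_pmids(self, baseline_pmids: set[int]) -> set[int]:
        out = set(baseline_pmids)
        out.update(f["pmid"] for f in self.added)
        out.difference_update(self.deleted_pmids)
        return out


def generate_update_batch(
    config: SyntheticCorpusConfig,
    manifest: PathologyManifest,
    n_revise: int = 5,
    n_add: int = 3,
    n_delete: int = 2,
) -> tuple[bytes, UpdateDelta]:
    """Generate one daily-update file: revised records (newer DateRevised),
    brand-new records, and a trailing DeleteCitation block.

    Revised and deleted PMID sets are disjoint.  The delta records the
    expected post-merge corpus so replays can be checked exactly.
    """
    if n_revise + n_delete > manifest.n_records:
        raise GenerationError("revise + delete exceeds corpus size")
    rng = random.Random(f"{config.seed}:update")
    pmids = [config.base_pmid + i for i in range(manifest.n_records)]
    chosen = rng.sample(pmids, n_revise + n_delete)
    revise_pmids = sorted(chosen[:n_revise])
    delete_pmids = sorted(chosen[n_revise:])

    root = etree.Element("PubmedArticleSet")
    delta = UpdateDelta(revised_pmids=revise_pmids, added=[], deleted_pmids=delete_pmids)

    # Revised records: regenerate from a fresh stream, keep the PMID, and
    # stamp a DateRevised strictly newer than any baseline date (2022+).
    rev_config = dataclasses.replace(config, seed=config.seed + 1_000_003)
    for pmid in revise_pmids:
        index = pmid - config.base_pmid
        element, facts = _build_record(rev_config, index)
        dr = element.find("MedlineCitation/DateRevised")
        for tag, value in (("Year", "2022"), ("Month", "06"), ("Day", "15")):
            dr.find(tag).text = value  # type: ignore[union-attr]
        facts["pmid"] = pmid
        root.append(element)
        delta.revised_facts[pmid] = facts

    add_config = dataclasses.replace(
        config,
        seed=config.seed + 2_000_003,
        base_pmid=config.base_pmid + manifest.n_records,
    )
    for j in range(n_add):
        element, facts = _build_record(add_config, j)
        root.append(element)
        delta.added.append(facts)

    if delete_pmids:
        dc = _sub(root, "DeleteCitation")
        for pmid in delete_pmids:
            _sub(dc, "PMID", str(pmid), Version="1")

    blob = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return blob, delta


def generate_journal_reference(
    config: SyntheticCorpusConfig,
    manifest: PathologyManifest,
    path: Union[str, Path],
    omit_nlm_ids: Optional[set[str]] = None,
) -> tuple[Path, list[str]]:
    """Write a J_MEDLINE-style journal reference file for the corpus.

    By default every main-pool NlmId used in the corpus is listed and the
    dangling-pool identifiers are omitted; an explicit ``omit_nlm_ids`` set
    overrides that.  Returns the path and the sorted omitted identifiers
    that actually occur in the corpus.
    """
    path = Path(path)
    used = set(manifest.journal_usage)
    if omit_nlm_ids is None:
        omit_nlm_ids = set(config.dangling_pool())
    listed = sorted(used - omit_nlm_ids)
    omitted = sorted(used & omit_nlm_ids)
    lines: list[str] = []
    for jr_id, nlm_id in enumerate(listed, start=1):
        lines.append("-" * 56)
        lines.append(f"JrId: {jr_id}")
        lines.append(f"JournalTitle: Synthetic Journal {nlm_id}")
        lines.append(f"MedAbbr: Synth J {nlm_id[-3:]}")
        lines.append("ISSN (Print): 0000-0000")
        lines.append(f"NlmId: {nlm_id}")
    lines.append("-" * 56)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path, omitted
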