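"""Identifier validation, language parsing, year extraction, e-mail
extraction, anomaly flags, duplicate ORCIDs, truncation sentinels."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from medline_dq.semantics import (
    AnomalyThresholds,
    detect_duplicate_orcid,
    detect_truncated_abstract,
    extract_email_from_affiliation,
    extract_publication_year,
    flag_author_anomalies,
    load_identifier_patterns,
    load_language_table,
    parse_language_field,
    validate_identifier,
    validate_isni_any,
)
from medline_dq.xml_io import ArticleRecord, AuthorRecord

PATTERNS = load_identifier_patterns()
LANGUAGES = load_language_table()


class TestValidateIdentifier:
    # (scheme, value, expect_valid)
    TABLE = [
        ("DOI", "10.1093/nar/gkaa1234", True),
        ("DOI", "10.1000/xyz:123(45);a-b_c.d/e", True),
        ("DOI", "doi:10.1", False),
        ("DOI", "10.123/short-prefix", False),  # fewer than 4 registrant digits
        ("DOI", "11.1093/nar/gkaa1234", False),
        ("ORCID", "0000-0002-5696-5368", True),
        ("ORCID", "0000-0002-1825-009X", True),  # X check digit form
        ("ORCID", "0000-0002-18253787", False),
        ("ORCID", "0000–0002–5696–5368", False),  # en dashes are typography, not data
        ("ISNI_presentation", "0000 0001 2096 021X", True),
        ("ISNI_presentation", "0000000120960218", False),
        ("ISNI_compact", "000000012096021X", True),
        ("ISNI_compact", "0000 0001 2096 0218", False),
        ("GRID", "grid.1234.0a", True),
        ("GRID", "grid.426106.7", True),
        ("GRID", "grid.12.3", False),
        ("GRID", "grid.1234567.0", False),
    ]

    @pytest.mark.parametrize("scheme,value,expect_valid", TABLE)
    def test_table(self, scheme, value, expect_valid):
        result = validate_identifier(scheme, value)
        assert result.present and result.valid is expect_valid

    def test_blank_is_not_present(self):
        for value in (None, "", "   "):
            result = validate_identifier("DOI", value)
            assert not result.present and not result.valid and result.reason == "blank"

    def test_all_zero_orcid_detected(self):
        result = validate_identifier("ORCID", "0000-0000-0000-0000")
        assert result.present and not result.valid and result.reason == "all_zero_orcid"

    def test_unknown_scheme_is_config_error(self):
        with pytest.raises(KeyError):
            validate_identifier("ROR", "ror.04abc")

    def test_isni_either_form(self):
        assert validate_isni_any("000000012096021X").valid
        assert validate_isni_any("0000 0001 2096 021X").valid
        assert not validate_isni_any("junk").valid

    def test_shipped_patterns_compile_and_cover_five_schemes(self):
        assert set(PATTERNS) == {
            "DOI", "ORCID", "ISNI_presentation", "ISNI_compact", "GRID",
        }
        for p in PATTERNS.values():
            re.compile(p.pattern)


class TestParseLanguage:
    def test_concatenated_codes(self):
        parse = parse_language_field("fregerita")
        assert parse.codes == ("fre", "ger", "ita")
        assert parse.ok and not parse.solitary_undetermined

    def test_single_code(self):
        parse = parse_language_field("eng")
        assert parse.codes == ("eng",) and not parse.solitary_undetermined

    @pytest.mark.parametrize("raw", ["und", "mul"])
    def test_solitary_undetermined(self, raw):
        parse = parse_language_field(raw)
        assert parse.solitary_undetermined

    def test_undetermined_with_company_is_not_solitary(self):
        parse = parse_language_field("undeng")
        assert parse.ok and not parse.solitary_undetermined

    @pytest.mark.parametrize("raw", ["en", "engl", "zzz", "engzzz"])
    def test_unparseable_marked_failed(self, raw):
        parse = parse_language_field(raw)
        assert not parse.ok and parse.raw == raw and parse.codes == ()

    @given(st.lists(st.sampled_from(sorted(LANGUAGES)), min_size=1, max_size=4))
    @settings(derandomize=True, max_examples=50)
    def test_reconcatenation_is_identity(self, codes):
        raw = "".join(codes)
        parse = parse_language_field(raw)
        assert parse.ok and "".join(parse.codes) == raw


def md_record(medline_date):
    return ArticleRecord(pmid=1, medline_date=medline_date)


class TestYearExtraction:
    def test_structured_year_preferred(self):
        yx = extract_publication_year(ArticleRecord(pmid=1, pub_year_structured=1999))
        assert yx.source == "structured"
        assert (yx.year_reluctant, yx.year_greedy, yx.span_years) == (1999, 1999, 0)
        assert yx.viable

    def test_time_span_value(self):
        yx = extract_publication_year(md_record("1946 May–June"))
        assert yx.year_reluctant == 1946 and yx.year_greedy == 1946
        assert yx.span_years == 0 and yx.viable

    def test_pagination_confuses_greedy_only(self):
        yx = extract_publication_year(md_record("1975 part 2): 1125–1132, Dec"))
        assert yx.year_reluctant == 1975 and yx.year_greedy == 1132
        assert yx.viable and not yx.greedy_viable

    def test_split_pagination(self):
        yx = extract_publication_year(md_record("1980 Suppl): 1035–15 August 1041"))
        assert yx.year_reluctant == 1980 and yx.year_greedy == 1041

    def test_no_four_digit_run(self):
        yx = extract_publication_year(md_record("1"))
        assert yx.year_reluctant is None and yx.year_greedy is None
        assert not yx.viable and yx.span_years is None

    def test_genuine_span(self):
        yx = extract_publication_year(md_record("1974-2002"))
        assert yx.span_years == 28  # largest span observed in the wild

    @given(st.text(alphabet="0123456789 -abcXYZ):", max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_extracted_years_are_four_digit_substrings(self, text):
        yx = extract_publication_year(md_record(text))
        for year in (yx.year_reluctant, yx.year_greedy):
            if year is not None:
                assert f"{year:04d}" in text


class TestEmailExtraction:
    def test_trailing_email_extracted(self):
        result = extract_email_from_affiliation("Dept X, Uni Y. jane.doe@uni.edu.")
        assert result.email == "jane.doe@uni.edu" and not result.placeholder

    def test_no_email(self):
        assert extract_email_from_affiliation("London, UK.").email is None

    def test_placeholder_flagged(self):
        result = extract_email_from_affiliation("Somewhere. user@example.com.")
        assert result.email == "user@example.com" and result.placeholder

    def test_embedded_address_not_extracted(self):
        result = extract_email_from_affiliation("a@b.com was the contact, London.")
        assert result.email is None


def author(**kwargs):
    return AuthorRecord(position=1, **kwargs)


class TestAuthorAnomalies:
    def test_single_char_last_name(self):
        assert flag_author_anomalies(author(last_name="S")) == {"single_char_last_name"}

    def test_long_forename_is_affiliation_concat(self):
        fore = "Moon Hyung " + "Department Of Radiology " * 12  # >= 100 chars, >= 8 words
        flags = flag_author_anomalies(author(fore_name=fore.strip()))
        assert "forename_equals_affiliation_concat" in flags
        assert "suspected_collective_in_personal_field" in flags

    def test_clean_author_unflagged(self):
        assert flag_author_anomalies(author(last_name="Wang", fore_name="Wei")) == set()

    def test_suffix_and_initials_flags(self):
        flags = flag_author_anomalies(
            author(suffix="(Conceptualization; Review and editing)", initials="ABCDE")
        )
        assert flags == {"suffix_pollution", "initials_overlong"}

    def test_flags_monotone_in_thresholds(self):
        subject = author(
            last_name="A B C D E F G H",
            fore_name="x" * 120,
            suffix="y" * 30,
            initials="ZZZZZ",
        )
        loose = AnomalyThresholds(
            collective_word_count=20,
            forename_concat_length=500,
            suffix_length=100,
            initials_length=10,
        )
        assert flag_author_anomalies(subject, loose) < flag_author_anomalies(subject)


class TestDuplicateOrcid:
    def brute_force(self, article):
        found = {}
        for i, a in enumerate(article.authors):
            for b in article.authors[i + 1:]:
                if (
                    a.orcid_raw
                    and a.orcid_raw == b.orcid_raw
                    and validate_identifier("ORCID", a.orcid_raw).valid
                ):
                    found.setdefault(a.orcid_raw, set()).update({a.position, b.position})
        return {k: sorted(v) for k, v in found.items()}

    def make(self, orcids):
        return ArticleRecord(
            pmid=1,
            authors=[
                AuthorRecord(position=i + 1, orcid_raw=o) for i, o in enumerate(orcids)
            ],
        )

    def test_shared_pair(self):
        article = self.make(["0000-0002-5696-5368", "0000-0002-5696-5368", None])
        [(orcid, positions)] = detect_duplicate_orcid(article)
        assert orcid == "0000-0002-5696-5368" and positions == [1, 2]

    def test_distinct_orcids_clean(self):
        article = self.make(["0000-0002-5696-5368", "0000-0002-1825-009X"])
        assert detect_duplicate_orcid(article) == []

    def test_three_way_matches_pairwise_oracle(self):
        article = self.make(["0000-0002-5696-5368"] * 3 + ["0000-0002-1825-009X"])
        result = {o: p for o, p in detect_duplicate_orcid(article)}
        assert result == self.brute_force(article)
        assert result["0000-0002-5696-5368"] == [1, 2, 3]

    def test_all_zero_never_counts(self):
        article = self.make(["0000-0000-0000-0000"] * 2)
        assert detect_duplicate_orcid(article) == []


class TestTruncationSentinels:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Long text. (ABSTRACT TRUNCATED AT 250 WORDS)", True),
            ("Long text. (ABSTRACT TRUNCATED)", True),
            ("Long text. (ABSTRACT TRUNCATED AT 400 WORDS)", True),
            ("Short abstract.", False),
            ("(ABSTRACT TRUNCATED) but then more text.", False),
        ],
    )
    def test_sentinels(self, text, expected):
        assert detect_truncated_abstract(text) is expected
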