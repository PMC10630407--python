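"""String-field profiling: length distributions, five-number summaries,
top-N frequency tables, extreme values, and per-year identifier prevalence.

Lengths are measured in Unicode code points and in words, where a word is a
token obtained by splitting on the space character (U+0020) with empty
tokens dropped — upstream sanitization has already collapsed all other
whitespace to single spaces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .semantics import (
    extract_publication_year,
    validate_identifier,
    validate_isni_any,
)

__all__ = [
    "FiveNumberSummary",
    "FieldProfile",
    "YearPoint",
    "YearSeries",
    "char_length",
    "word_count",
    "five_number_summary",
    "profile_string_field",
    "extreme_values",
    "identifier_prevalence_by_year",
]


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


@dataclass
class FieldProfile:
    field_name: str
    n: int
    char_len_summary: Optional[FiveNumberSummary]
    word_count_summary: Optional[FiveNumberSummary]
    top_values: list[tuple[str, int]] = field(default_factory=list)
    longest: list[tuple[str, int]] = field(default_factory=list)
    shortest: list[tuple[str, int]] = field(default_factory=list)


@dataclass(frozen=True)
class YearPoint:
    year: int
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


@dataclass
class YearSeries:
    metric_name: str
    points: list[YearPoint] = field(default_factory=list)
    n_excluded: int = 0  # records without a viable publication year


def char_length(value: str) -> int:
    return len(value)


def word_count(value: str) -> int:
    """Tokens after splitting on U+0020, empty tokens dropped."""
    return len([t for t in value.split(" ") if t])


def five_number_summary(
    values: Sequence[float], mode: str = "exact", error: float = 1e-4
) -> Optional[FiveNumberSummary]:
    """Min, Q1, median, Q3, max of a numeric sample.

    Exact mode interpolates linearly between closest ranks.  Approximate mode
    evaluates quantiles on a stride subsample of the sorted data with stride
    ``max(1, floor(error·n))``, guaranteeing a rank error of at most
    ``error·n``; min and max are always exact.  Empty input yields None.
    """
    if len(values) == 0:
        return None
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if mode == "exact":
        q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
        return FiveNumberSummary(*map(float, q))
    if mode != "approximate":
        raise ValueError(f"unknown mode {mode!r}")
    stride = max(1, int(error * n))
    out = []
    for q in (0.0, 0.25, 0.5, 0.75, 1.0):
        exact_rank = q * (n - 1)
        rank = int(round(exact_rank / stride)) * stride
        out.append(float(arr[min(rank, n - 1)]))
    return FiveNumberSummary(*out)


def profile_string_field(
    values: Iterable[str],
    field_name: str = "",
    top_n: int = 15,
    length_filter: Optional[Callable[[str], bool]] = None,
    k_extremes: int = 10,
    summary_mode: str = "exact",
) -> FieldProfile:
    """Profile one sanitized string field.

    Length summaries cover all values; the top-N table is computed after
    applying ``length_filter`` when given (e.g. "under 20 characters", as
    used for affiliation/abstract/title placeholder hunting).  Ties in
    counts break lexicographically.
    """
    values = list(values)
    n = len(values)
    if n == 0:
        return FieldProfile(field_name, 0, None, None)
    char_lens = [char_length(v) for v in values]
    word_counts = [word_count(v) for v in values]
    filtered = values if length_filter is None else [v for v in values if length_filter(v)]
    counts = Counter(filtered)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return FieldProfile(
        field_name=field_name,
        n=n,
        char_len_summary=five_number_summary(char_lens, mode=summary_mode),
        word_count_summary=five_number_summary(word_counts, mode=summary_mode),
        top_values=top,
        longest=extreme_values(values, k_extremes, "longest"),
        shortest=extreme_values(values, k_extremes, "shortest"),
    )


def extreme_values(
    values: Iterable[str], k: int, direction: str = "longest"
) -> list[tuple[str, int]]:
    """Top-k values by character length; ties break lexicographically."""
    values = list(values)
    if direction == "longest":
        ordered = sorted(values, key=lambda v: (-len(v), v))
    elif direction == "shortest":
        ordered = sorted(values, key=lambda v: (len(v), v))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return [(v, len(v)) for v in ordered[:k]]


def identifier_prevalence_by_year(corpus, scheme: str, window=None) -> YearSeries:
    """Per-publication-year fraction of entities carrying a valid identifier.

    The entity is the article for DOI and the author for ORCID/ISNI/GRID and
    for the affiliation string (where "valid" means present).  The year is
    the reluctant extraction; records without a viable year are excluded and
    counted in ``n_excluded``.
    """
    from .semantics import YEAR_WINDOW

    window = window or YEAR_WINDOW
    num: Counter[int] = Counter()
    den: Counter[int] = Counter()
    n_excluded = 0
    for record in corpus.records.values():
        yx = extract_publication_year(record, window)
        if not yx.viable:
            n_excluded += 1
            continue
        year = yx.year_reluctant
        assert year is not None
        if scheme == "DOI":
            den[year] += 1
            if validate_identifier("DOI", record.doi).valid:
                num[year] += 1
            continue
        for author in record.authors:
            den[year] += 1
            if scheme == "ORCID":
                ok = validate_identifier("ORCID", author.orcid_raw).valid
            elif scheme == "ISNI":
                vals = [v for s, v in author.affiliation_identifiers if s == "ISNI"]
                ok = any(validate_isni_any(v).valid for v in vals)
            elif scheme == "GRID":
                vals = [v for s, v in author.affiliation_identifiers if s == "GRID"]
                ok = any(validate_identifier("GRID", v).valid for v in vals)
            elif scheme == "affiliation":
                ok = author.affiliation_first is not None
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            if ok:
                num[year] += 1
    points = [YearPoint(y, num[y], den[y]) for y in sorted(den)]
    return YearSeries(metric_name=f"{scheme}_prevalence", points=points, n_excluded=n_excluded)
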