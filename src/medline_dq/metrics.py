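"""Data-quality metrics: completeness, validity, uniqueness, and referential
integrity.

For a field over N records with M missing values, P = N − M are present,
D counts distinct present values and V counts present values whose format
validates.  The three derived ratios are

    completeness = P / N,   validity = V / P,   uniqueness = D / P,

with validity and uniqueness undefined when nothing is present.  Distinct
counts are exact (no sketching).  Referential integrity checks a key column
(journal NLM identifiers) against a reference key set and reports both the
distinct dangling keys and the number of affected articles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

from .semantics import ValidationResult
from .xml_io import sanitize_text

__all__ = [
    "QualityMetrics",
    "ReferentialIntegrityResult",
    "compute_quality_metrics",
    "referential_integrity",
    "round_metric",
    "read_journal_reference",
    "NOT_AVAILABLE",
]

#: Rendering used for undefined ratios; never 0.
NOT_AVAILABLE = "N/A"


@dataclass
class QualityMetrics:
    """The N/M/P/D/V counts and derived ratios for one field."""

    n_records: int
    n_missing: int
    n_present: int
    n_distinct: int
    n_valid: Optional[int]  # None when no validator applies to the field

    @property
    def completeness(self) -> Optional[float]:
        return self.n_present / self.n_records if self.n_records else None

    @property
    def validity(self) -> Optional[float]:
        if self.n_valid is None or self.n_present == 0:
            return None
        return self.n_valid / self.n_present

    @property
    def uniqueness(self) -> Optional[float]:
        return self.n_distinct / self.n_present if self.n_present else None

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_missing": self.n_missing,
            "n_present": self.n_present,
            "n_distinct": self.n_distinct,
            "n_valid": self.n_valid,
            "completeness": self.completeness,
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "completeness_pct": round_metric(self.completeness),
            "validity_pct": round_metric(self.validity),
            "uniqueness_pct": round_metric(self.uniqueness),
        }


@dataclass
class ReferentialIntegrityResult:
    n_with_key: int
    n_matched: int
    dangling_keys: list[str] = field(default_factory=list)
    n_affected: int = 0

    @property
    def integrity(self) -> Optional[float]:
        return self.n_matched / self.n_with_key if self.n_with_key else None


def compute_quality_metrics(
    values: Iterable[Optional[str]],
    validator: Optional[Callable[[Optional[str]], ValidationResult]] = None,
    sanitize: bool = True,
    casefold_distinct: bool = False,
) -> QualityMetrics:
    """Compute N/M/P/D/V and the derived ratios over one pass of the values.

    A value that is None or blank after sanitization counts as missing.
    Distinctness is exact and case-sensitive by default; ``casefold_distinct``
    switches to case-insensitive comparison (appropriate for DOIs, which are
    case-insensitive by definition).  When ``validator`` is None the field
    has no validity notion and V is reported as None, not 0.
    """
    n_records = 0
    n_present = 0
    n_valid: Optional[int] = 0 if validator is not None else None
    distinct: set[str] = set()
    for value in values:
        n_records += 1
        if value is not None and sanitize:
            value = sanitize_text(value)
        if value is None or value == "":
            continue
        n_present += 1
        distinct.add(value.casefold() if casefold_distinct else value)
        if validator is not None and validator(value).valid:
            n_valid += 1  # type: ignore[operator]
    return QualityMetrics(
        n_records=n_records,
        n_missing=n_records - n_present,
        n_present=n_present,
        n_distinct=len(distinct),
        n_valid=n_valid,
    )


def referential_integrity(
    keys: Iterable[Optional[str]], reference_keys: set[str]
) -> ReferentialIntegrityResult:
    """Match per-article keys against a reference key set.

    ``keys`` is one entry per article (None when the article carries no key).
    ``dangling_keys`` lists the distinct unmatched identifiers and
    ``n_affected`` the number of articles carrying one of them.  An empty
    reference set is a configuration error — distinguishable from 0%
    integrity.
    """
    if not reference_keys:
        raise ValueError("empty journal reference set (configuration error)")
    n_with_key = 0
    n_matched = 0
    n_affected = 0
    dangling: set[str] = set()
    for key in keys:
        if key is None or key == "":
            continue
        n_with_key += 1
        if key in reference_keys:
            n_matched += 1
        else:
            dangling.add(key)
            n_affected += 1
    return ReferentialIntegrityResult(
        n_with_key=n_with_key,
        n_matched=n_matched,
        dangling_keys=sorted(dangling),
        n_affected=n_affected,
    )


def round_metric(x: Optional[float], places: int = 3) -> str:
    """Render a ratio as a percentage string with fixed decimals, half-up.

    ``0.713734`` renders as ``"71.373"`` and ``1.0`` as ``"100.000"``.
    Undefined ratios render as the not-available marker.
    """
    if x is None:
        return NOT_AVAILABLE
    quantum = Decimal(1).scaleb(-places)
    return str((Decimal(repr(x)) * 100).quantize(quantum, rounding=ROUND_HALF_UP))


_DASHED_LINE = re.compile(r"^-{4,}\s*$")


def read_journal_reference(source: Union[str, Path, Iterable[str]]) -> dict[str, dict[str, str]]:
    """Read an NLM journal list (J_MEDLINE format) into NlmId-keyed records.

    The format is blocks of ``Key: value`` lines separated by dashed lines;
    each block describes one journal and must carry an ``NlmId`` key.
    Returns ``{nlm_id: {key: value, ...}}``; use ``set(result)`` as the
    reference key set for :func:`referential_integrity`.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = list(source)
    journals: dict[str, dict[str, str]] = {}
    block: dict[str, str] = {}

    def flush() -> None:
        nonlocal block
        if block:
            nlm_id = block.get("NlmId", "").strip()
            if nlm_id:
                journals[nlm_id] = block
            block = {}

    for line in lines:
        if _DASHED_LINE.match(line):
            flush()
        elif ":" in line:
            key, _, value = line.partition(":")
            block[key.strip()] = value.strip()
    flush()
    return journals
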