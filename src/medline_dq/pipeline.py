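"""End-to-end assessment pipeline: split → parse → merge → select → assess →
profile, producing a machine-readable report.

The pipeline is a single-machine streaming re-architecture of what is
usually run on a cluster: time is O(records) and memory is bounded by the
retained corpus, so full-scale runs remain possible but are not required.
Partial failures of individual records never abort a run — they are logged,
tallied, and surfaced in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .corpus import (
    Corpus,
    DEFAULT_NEWS_TYPES,
    SelectionReport,
    apply_file,
    select_study_records,
)
from .metrics import (
    compute_quality_metrics,
    read_journal_reference,
    referential_integrity,
    round_metric,
)
from .profiling import identifier_prevalence_by_year, profile_string_field
from .semantics import (
    detect_duplicate_orcid,
    detect_truncated_abstract,
    flag_author_anomalies,
    parse_language_field,
    validate_identifier,
    validate_isni_any,
)
from .xml_io import RecordError, split_records

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """Fatal pipeline failure (unreadable input, empty input set)."""


@dataclass
class PipelineConfig:
    baseline_files: list[Union[str, Path]] = field(default_factory=list)
    update_files: list[Union[str, Path]] = field(default_factory=list)
    journal_ref: Optional[Union[str, Path]] = None
    news_types: frozenset[str] = DEFAULT_NEWS_TYPES
    top_n: int = 15
    k_extremes: int = 10
    short_value_limit: int = 20  # "under 20 characters" placeholder tables

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "baseline_files": [str(p) for p in self.baseline_files],
                "update_files": [str(p) for p in self.update_files],
                "journal_ref": str(self.journal_ref) if self.journal_ref else None,
                "news_types": sorted(self.news_types),
                "top_n": self.top_n,
                "k_extremes": self.k_extremes,
                "short_value_limit": self.short_value_limit,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def build_corpus(config: PipelineConfig) -> tuple[Corpus, list[RecordError]]:
    """Ingest baseline files then update files into one corpus."""
    if not config.baseline_files:
        raise PipelineError("no baseline input files")
    errors: list[RecordError] = []
    corpus = Corpus()
    for path in list(config.baseline_files) + list(config.update_files):
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        slices = split_records(str(path), path.name, on_error=errors.append)
        apply_file(corpus, slices)
    return corpus, errors


def _profile_dict(profile) -> dict:
    def summary(s):
        return None if s is None else list(s.as_tuple())

    return {
        "field_name": profile.field_name,
        "n": profile.n,
        "char_len_summary": summary(profile.char_len_summary),
        "word_count_summary": summary(profile.word_count_summary),
        "top_values": [[v, c] for v, c in profile.top_values],
        "longest": [[v, l] for v, l in profile.longest],
        "shortest": [[v, l] for v, l in profile.shortest],
    }


def _year_series_dict(series) -> dict:
    return {
        "metric_name": series.metric_name,
        "n_excluded": series.n_excluded,
        "points": [
            [p.year, p.numerator, p.denominator, p.fraction] for p in series.points
        ],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full assessment and return the report as a plain dict.

    The report is deterministic for fixed inputs and configuration except
    for the ``generated_at`` stamp.
    """
    corpus, record_errors = build_corpus(config)
    selected, selection = select_study_records(corpus, config.news_types)
    records = list(selected.records.values())

    # --- per-field quality metrics -----------------------------------------
    metrics: dict[str, dict] = {}
    metrics["DOI"] = compute_quality_metrics(
        (r.doi for r in records),
        validator=lambda v: validate_identifier("DOI", v),
        casefold_distinct=True,
    ).as_dict()
    metrics["title"] = compute_quality_metrics((r.title for r in records)).as_dict()
    metrics["abstract"] = compute_quality_metrics((r.abstract for r in records)).as_dict()

    def language_validator(value):
        parse = parse_language_field(value)
        from .semantics import ValidationResult

        ok = parse.ok and not parse.solitary_undetermined
        return ValidationResult("language", True, ok, "ok" if ok else "pattern_fail")

    metrics["language"] = compute_quality_metrics(
        (" ".join(r.language_raw) if r.language_raw else None for r in records),
        validator=lambda v: language_validator(v.replace(" ", "")),
    ).as_dict()

    authors = [a for r in records for a in r.authors]
    personal = [a for a in authors if a.collective_name is None]
    metrics["forename"] = compute_quality_metrics((a.fore_name for a in personal)).as_dict()
    metrics["initials"] = compute_quality_metrics((a.initials for a in personal)).as_dict()
    metrics["ORCID"] = compute_quality_metrics(
        (a.orcid_raw for a in authors),
        validator=lambda v: validate_identifier("ORCID", v),
    ).as_dict()

    def first_ident(author, scheme):
        vals = [v for s, v in author.affiliation_identifiers if s == scheme]
        return vals[0] if vals else None

    metrics["ISNI"] = compute_quality_metrics(
        (first_ident(a, "ISNI") for a in authors), validator=validate_isni_any
    ).as_dict()
    metrics["GRID"] = compute_quality_metrics(
        (first_ident(a, "GRID") for a in authors),
        validator=lambda v: validate_identifier("GRID", v),
    ).as_dict()
    metrics["Affiliation"] = compute_quality_metrics(
        (a.affiliation_first for a in authors)
    ).as_dict()

    # --- referential integrity ---------------------------------------------
    if config.journal_ref is not None:
        journals = read_journal_reference(config.journal_ref)
        ri = referential_integrity(
            (r.journal_nlm_id for r in records), set(journals)
        )
        ri_dict = {
            "skipped": False,
            "n_with_key": ri.n_with_key,
            "n_matched": ri.n_matched,
            "n_affected": ri.n_affected,
            "dangling_keys": ri.dangling_keys,
            "integrity": ri.integrity,
            "integrity_pct": round_metric(ri.integrity),
        }
    else:
        ri_dict = {"skipped": True}

    # --- profiles ------------------------------------------------------------
    short = lambda v: len(v) < config.short_value_limit  # noqa: E731
    profiles = {}
    for name, values, length_filter in (
        ("title", [r.title for r in records if r.title], short),
        ("abstract", [r.abstract for r in records if r.abstract], short),
        ("copyright", [r.copyright_info for r in records if r.copyright_info], short),
        ("last_name", [a.last_name for a in personal if a.last_name], None),
        ("fore_name", [a.fore_name for a in personal if a.fore_name], None),
        ("suffix", [a.suffix for a in personal if a.suffix], None),
        ("affiliation", [a.affiliation_first for a in authors if a.affiliation_first], short),
    ):
        profiles[name] = _profile_dict(
            profile_string_field(
                values,
                field_name=name,
                top_n=config.top_n,
                length_filter=length_filter,
                k_extremes=config.k_extremes,
            )
        )

    # --- year series ---------------------------------------------------------
    year_series = {
        "DOI": _year_series_dict(identifier_prevalence_by_year(selected, "DOI")),
        "ORCID": _year_series_dict(identifier_prevalence_by_year(selected, "ORCID")),
    }

    # --- anomaly tallies ------------------------------------------------------
    anomaly_counts: dict[str, int] = {}
    for author in personal:
        for flag in flag_author_anomalies(author):
            anomaly_counts[flag] = anomaly_counts.get(flag, 0) + 1
    n_all_zero = sum(
        1
        for a in authors
        if a.orcid_raw is not None
        and validate_identifier("ORCID", a.orcid_raw).reason == "all_zero_orcid"
    )
    n_dup_orcid_articles = sum(1 for r in records if detect_duplicate_orcid(r))
    n_solitary = 0
    for r in records:
        raw = "".join(r.language_raw)
        if raw:
            parse = parse_language_field(raw)
            if parse.solitary_undetermined:
                n_solitary += 1
    n_truncated = sum(
        1 for r in records if r.abstract and detect_truncated_abstract(r.abstract)
    )
    anomalies = {
        "author_flags": anomaly_counts,
        "all_zero_orcid": n_all_zero,
        "duplicate_orcid_articles": n_dup_orcid_articles,
        "solitary_und_mul_records": n_solitary,
        "truncated_abstracts": n_truncated,
    }

    report = {
        "tool": "medline-dq",
        "version": __version__,
        "config_hash": config.config_hash(),
        "input_files": [str(p) for p in list(config.baseline_files) + list(config.update_files)],
        "generated_at": pd.Timestamp.now().isoformat(),
        "n_record_errors": len(record_errors),
        "corpus": {
            "n_records": len(corpus.records),
            "n_tombstones": len(corpus.tombstones),
        },
        "selection": dataclasses.asdict(selection),
        "metrics": metrics,
        "referential_integrity": ri_dict,
        "profiles": profiles,
        "year_series": year_series,
        "anomalies": anomalies,
    }
    return report


# ---------------------------------------------------------------------------
# Rendering

def render_report(report: dict, fmt: str, out_dir: Union[str, Path]) -> list[Path]:
    """Render a report dict to files; returns the paths written.

    ``json`` is lossless; ``csv_bundle`` writes one CSV per populated table;
    ``markdown`` mirrors the familiar identifier-metric and top-N layouts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(report, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
        return [path]
    if fmt == "csv_bundle":
        paths = []
        rows = [
            {"field": name, **{k: v for k, v in m.items()}}
            for name, m in report["metrics"].items()
        ]
        path = out_dir / "metrics.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths.append(path)
        for name, profile in report["profiles"].items():
            if profile["top_values"]:
                path = out_dir / f"top_{name}.csv"
                pd.DataFrame(profile["top_values"], columns=["value", "count"]).to_csv(
                    path, index=False
                )
                paths.append(path)
            if profile["longest"]:
                path = out_dir / f"longest_{name}.csv"
                pd.DataFrame(profile["longest"], columns=["value", "length"]).to_csv(
                    path, index=False
                )
                paths.append(path)
        for scheme, series in report["year_series"].items():
            path = out_dir / f"by_year_{scheme}.csv"
            pd.DataFrame(
                series["points"], columns=["year", "numerator", "denominator", "fraction"]
            ).to_csv(path, index=False)
            paths.append(path)
        if not report["referential_integrity"].get("skipped", False):
            path = out_dir / "referential_integrity.csv"
            ri = report["referential_integrity"]
            pd.DataFrame(
                [{k: v for k, v in ri.items() if k != "dangling_keys"}]
            ).to_csv(path, index=False)
            paths.append(path)
        return paths
    if fmt == "markdown":
        lines = [
            f"# MEDLINE data-quality report ({report['version']})",
            "",
            "## Identifier metrics",
            "",
            "| Identifier | Completeness (%) | Validity (%) | Uniqueness (%) |",
            "| --- | --- | --- | --- |",
        ]
        for name, m in report["metrics"].items():
            lines.append(
                f"| {name} | {m['completeness_pct']} | {m['validity_pct']} | {m['uniqueness_pct']} |"
            )
        lines += ["", "## Selection", ""]
        for key, value in report["selection"].items():
            lines.append(f"- {key}: {value}")
        for name, profile in report["profiles"].items():
            if not profile["top_values"]:
                continue
            lines += ["", f"## Top {name} values", "", "| Value | Occurrences |", "| --- | --- |"]
            for value, count in profile["top_values"]:
                lines.append(f"| {value} | {count} |")
        path = out_dir / "report.md"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return [path]
    raise ValueError(f"unknown report format {fmt!r}")


def markdown_metric_row(completeness: float, validity: float, uniqueness: float) -> str:
    """One identifier-table row in the markdown rendering convention."""
    return " | ".join(round_metric(x) for x in (completeness, validity, uniqueness))


# ---------------------------------------------------------------------------
# Minimal structural schema validation for the report JSON.

def validate_report(report: dict, schema: Optional[dict] = None) -> list[str]:
    """Check the report against the shipped structural schema.

    Returns a list of problems (empty = valid).  Supports the subset of JSON
    Schema the shipped document uses: type, required, properties.
    """
    if schema is None:
        from importlib import resources

        schema = json.loads(
            resources.files("medline_dq.data").joinpath("report_schema.json").read_text()
        )
    problems: list[str] = []

    types = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }

    def walk(node: dict, value, path: str) -> None:
        expected = node.get("type")
        if expected is not None:
            py = types[expected]
            if not isinstance(value, py) or (expected == "integer" and isinstance(value, bool)):
                problems.append(f"{path}: expected {expected}, got {type(value).__name__}")
                return
        for key in node.get("required", []):
            if key not in value:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in node.get("properties", {}).items():
            if isinstance(value, dict) and key in value:
                walk(sub, value[key], f"{path}.{key}")

    walk(schema, report, "$")
    return problems
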