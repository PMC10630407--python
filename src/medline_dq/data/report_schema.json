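{
  "type": "object",
  "required": [
    "tool",
    "version",
    "config_hash",
    "input_files",
    "generated_at",
    "n_record_errors",
    "corpus",
    "selection",
    "metrics",
    "referential_integrity",
    "profiles",
    "year_series",
    "anomalies"
  ],
  "properties": {
    "tool": {"type": "string"},
    "version": {"type": "string"},
    "config_hash": {"type": "string"},
    "input_files": {"type": "array"},
    "generated_at": {"type": "string"},
    "n_record_errors": {"type": "integer"},
    "corpus": {
      "type": "object",
      "required": ["n_records", "n_tombstones"],
      "properties": {
        "n_records": {"type": "integer"},
        "n_tombstones": {"type": "integer"}
      }
    },
    "selection": {
      "type": "object",
      "required": [
        "n_input",
        "n_status_excluded",
        "n_news_excluded",
        "n_untitled_excluded",
        "n_selected"
      ]
    },
    "metrics": {
      "type": "object",
      "required": [
        "DOI",
        "ORCID",
        "ISNI",
        "GRID",
        "Affiliation",
        "title",
        "abstract",
        "language",
        "forename",
        "initials"
      ]
    },
    "referential_integrity": {"type": "object", "required": ["skipped"]},
    "profiles": {"type": "object"},
    "year_series": {
      "type": "object",
      "required": ["DOI", "ORCID"]
    },
    "anomalies": {
      "type": "object",
      "required": [
        "author_flags",
        "all_zero_orcid",
        "duplicate_orcid_articles",
        "solitary_und_mul_records",
        "truncated_abstracts"
      ]
    }
  }
}
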