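# Identifier validation patterns, one per line: scheme <TAB> regex <TAB> match_mode
# Patterns are kept verbatim; match_mode is full_match or search.
DOI	^10.\d{4,9}/[-._;()/:a-zA-Z0-9]+$	full_match
ORCID	^\d{4}-\d{4}-\d{4}-(\d{3}X|\d{4})	full_match
ISNI_presentation	[0-9]{4} [0-9]{4} [0-9]{4} [0-9]{3}[0-9X]	full_match
ISNI_compact	[0-9]{15}[0-9X]	full_match
GRID	grid\.\d{4,6}\.[0-9a-f]{1,2}	full_match
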