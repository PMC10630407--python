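# Methods

This note documents the procedures `medline-dq` implements, the parameters
that matter, what the synthetic generator does and does not emulate, and the
numerical/design choices made where the design was genuinely open.

## Corpus assembly

PubMed's distribution model is an annual baseline plus daily update files
that carry revised records, new records, and a `DeleteCitation` block.
`medline_dq.corpus` folds these into one record set keyed by PMID:

- For each PMID the retained record is the one with the newest
  `DateRevised`. The PMID `Version` attribute is parsed and stored but never
  used as a merge key (it is populated meaningfully by only one publisher).
- **Tie rule.** Records with equal `DateRevised` resolve toward the later
  (file, index) position — later files are later exports. Records with no
  `DateRevised` sort as oldest. These rules are this package's choice; the
  distribution format does not specify one.
- **Tombstones.** Deleted PMIDs are remembered; deleting an absent PMID is a
  logged no-op. An update arriving after a deletion re-inserts the record:
  update files are processed in order, so a later export legitimately
  supersedes an earlier deletion.
- **Selection.** The study set keeps records with `Status="MEDLINE"`, no
  news publication type, and a non-empty title. "News" is operationalized
  as a configurable publication-type set, default {`News`, `Newspaper
  Article`} — the NLM types that describe journalism. Exclusions are counted
  under the first matching reason in the fixed order status → news → title,
  which makes the per-reason counts deterministic.

## Parsing rules

- Only `Author` entries with `ValidYN="Y"` are extracted (the default when
  the attribute is absent); `Investigator` elements are never read.
  `CollectiveName` entries become author records with the personal name
  parts absent, preserving document order — the interleaved
  collective/personal pattern some consortia use survives parsing intact.
- Only the first `Affiliation` string per author is stored, together with
  the total affiliation count. Both the 2015+ `AffiliationInfo` nesting and
  the older direct `Affiliation` child are accepted. Affiliation text under
  `CollectiveName`-only entries is read the same way as for personal
  entries.
- Reference lists are flattened recursively: the DTD permits one list with
  many references, many singleton lists, and arbitrary nesting; every
  `Reference` appears exactly once, in document order, with its nesting
  depth recorded.
- Multi-section structured abstracts are concatenated in order with a
  single space, labels dropped: downstream profiling treats the abstract as
  one string, so a join rule was needed and this is the least surprising
  one. Inline markup in titles/abstracts is flattened to its text content.
- Text sanitization replaces CR/LF/TAB with spaces, collapses space runs,
  trims, and applies Unicode NFC. Backslashes and quotes are preserved in
  memory — escaping is a serializer concern. Non-ASCII is preserved
  (İstanbul stays distinct from Istanbul). Undecodable bytes are a
  record-level error, not a silent replacement.
- A present-but-incomplete `DateRevised` is a record error; a wholly absent
  one is allowed.
- `PubmedBookArticle` records are sliced and tagged but not parsed into the
  corpus; the pipeline covers journal citation records only.

## Identifier validation

The five shipped patterns (DOI; ORCID; ISNI presentation and compact; GRID)
live in `data/identifier_patterns.txt` and are applied in **full-match**
mode by default. The DOI pattern is anchored at both ends and ORCID at the
start as written; ISNI and GRID carry no anchors of their own, and
full-match mode keeps validity from passing on embedded garbage. A `search`
mode is available per pattern for dialect experiments. Checksums are
deliberately not verified — a well-formed but wrong ORCID passes — except
that the all-zero ORCID placeholder is explicitly invalid with its own
reason code. Only the ASCII hyphen-minus is accepted in ORCIDs. Distinct
counts are exact, case-sensitive after sanitization, with an optional
casefold for DOIs (case-insensitive by definition).

## Year extraction

Structured `Year` wins when present. Otherwise the free-text `MedlineDate`
is scanned for four-digit substrings: the reluctant extraction takes the
first (shortest-match quantifier semantics), the greedy extraction the last
(longest-match). For genuine spans ("1946 May–June") the two agree; for
strings that embed pagination ("1975 part 2): 1125–1132, Dec") the greedy
value lands on a page number. Viability is a plausibility window of
[1800, current year + 2]; a reluctant year inside the window counts, and
per-year series exclude (and count) records without a viable year.

## Metrics and rounding

completeness = P/N, validity = V/P, uniqueness = D/P; V and the two
P-denominated ratios are undefined (rendered `N/A`, never 0) when nothing
is present, and a field with no validity notion reports V as undefined
rather than 0. Percentages render with exactly three decimals using
**half-up** rounding via decimal arithmetic (the rounding mode had to be
chosen; half-up matches how the reference tables read). Referential
integrity reports matched/with-key plus the distinct dangling keys and the
affected-article count; an empty reference set is a configuration error,
distinguishable from 0% integrity.

## Profiling

Character length is the Unicode code-point count; word count splits on
U+0020 only, dropping empty tokens (other whitespace has already been
collapsed by sanitization). Five-number summaries use linear interpolation
between closest ranks in exact mode; the approximate mode evaluates
quantiles on a deterministic stride subsample of the sorted data with
stride ≤ error·n, guaranteeing rank error at most error·n (default error
1e-4) with exact min/max. Ties in top-N counts and in extreme-value lengths
break lexicographically so outputs are stable. Plots are out of scope: the
per-year series are emitted as tidy (year, numerator, denominator,
fraction) tables from which the usual prevalence figures can be drawn.

## Synthetic corpus generator

The generator emulates the *shape* of PubMed XML (only the elements the
pipeline reads, plus decoy elements it must ignore, such as
`InvestigatorList` and `ChemicalList`) and the *catalog* of known
pathologies, each as an independent Bernoulli event per eligible record or
author. Default rates are chosen to echo the observed prevalence ranks —
DOIs on ~70% of articles, ORCIDs on ~3% of authors, institutional
identifiers two orders rarer, affiliations a bit under half — without
claiming exact real-corpus values; the registry defaults live in
`PATHOLOGY_REGISTRY` and every entry has a downstream detector
(`PATHOLOGY_DETECTORS`, enforced by a test). Filler text comes from a small
embedded word list.

Randomness: one seed, stream-split per record index
(`random.Random(f"{seed}:{index}")`), so injection decisions are
independent of record order and the same seed yields bit-identical files
(gzip mtime zeroed) and manifest across processes.

What the generator does **not** emulate: realistic name/language/journal
frequency distributions beyond rank order, the full DTD, MeSH/chemical
semantics, and real-world correlations between defects (injections are
independent). Passing the manifest-recovery tests therefore demonstrates
that the pipeline's detectors and counts are correct against known ground
truth at realistic rates — not that the shipped default rates equal the
real corpus's rates.

Mutually exclusive injections (missing vs placeholder title; solitary
und/mul vs concatenated languages; erroneous vs span MedlineDate) are drawn
independently and applied by fixed precedence; only the applied injection
is logged, and a configuration whose exclusive-group rates exceed 1.0 is
rejected with an error naming the conflicting rates.

Update batches stamp revised records with a `DateRevised` (2022-06-15)
strictly newer than any baseline date (baseline revision dates are drawn
from 2015–2021), choose revised and deleted PMID sets disjointly, and
record the expected post-merge state so replays can be checked exactly.
The journal reference writer emits the J_MEDLINE block format
(`Key: value` lines between dashed separators, keyed by `NlmId`) for all
used journals except the dangling pool.

## Problem sizes

The test suite exercises the full pipeline at 300–600 records and the
manifest-recovery acceptance check at 10 000 records with the default
registry rates; oracle-equivalence checks run on randomized inputs up to
10 000 values. These sizes give every pathology a nonzero expected count
while keeping the suite fast; the streaming parser itself is
O(records) in time with bounded memory, so full-scale corpora are a matter
of wall clock, not design.

## Known limitations

- Validity is regex-shape only; checksum-valid-looking but wrong
  identifiers pass, exactly as documented.
- Truncation detection relies on sentinel phrases (configurable in
  `data/truncation_sentinels.txt`); silently truncated abstracts without a
  sentinel are not detectable from the record alone.
- The e-mail extractor is deliberately conservative (trailing token only);
  it is a cautionary discriminator, not an address parser.
- The shipped MARC language table is a curated subset covering common
  MEDLINE languages; unknown codes mark a parse failed rather than guessing.
- Outlier detection by length highlights many data issues but cannot catch
  all of them; flags are heuristics with configurable thresholds
  (collective-in-personal-name ≥ 8 words, forename-affiliation concat ≥ 100
  chars, suffix ≥ 20 chars, initials > 4 chars).
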