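# Methods

## The data model

The unit of exchange is the site-local **study record**: eleven core data
elements (identifiers; acronym; contact details; participating site; title;
description; conditions; demographic inclusion criteria; recruitment status;
further-information URLs; keywords) plus provenance — the exporting site and
its local id, whose pair is globally unique. Titles and descriptions are
modeled as language-tagged texts (German/English, at most one per language),
because the audit treats the two languages as separate fields. Recruitment
status uses the FHIR R4 `ResearchStudy.status` value set verbatim (all eleven
codes), which keeps the FHIR mapping lossless; site registries using other
vocabularies must map before ingestion.

Trial identifiers are `(source, system URI, value)` triples. Equality and
hashing use only the normalized `(system, value)` pair — the source label is
derived from the system URI and can never disambiguate further. The canonical
system URIs are:

| source | system URI | public link template |
|---|---|---|
| NCT | `http://clinicaltrials.gov` | `https://clinicaltrials.gov/ct2/show/{value}` |
| DRKS | `http://www.drks.de` | `https://www.drks.de/drks_web/navigate.do?navigationId=trial.HTML&TRIAL_ID={value}` |
| EudraCT | `http://www.clinicaltrialsregister.eu` | `https://www.clinicaltrialsregister.eu/ctr-search/search?query=eudract_number:{value}` |
| UTN | `http://www.who.int/ictrp/unambiguous_identification/utn` | none (no public lookup) |
| local | `https://fhir.{site}/studienregister/NamingSystem/id` | configurable per site |

Record-level invariants (a LOCAL identifier must exist, non-LOCAL systems
must match the table, ages must be ordered, URLs absolute, ...) are *reported*
by `validate_record` rather than enforced at construction, so malformed
exports can be loaded and inspected; validation is total and returns
violations as data.

## FHIR mapping

`to_research_study` emits one `ResearchStudy` plus one `Location` per site
(referenced by `ResearchStudy.site`) and one `Group` for the eligibility
criteria (referenced by `ResearchStudy.enrollment`); a config switch emits
them as `contained` resources instead. Gender is a coded characteristic and
age a value range in years on the Group. The profile extensions — acronym,
per-site recruitment status, per-site contacts — live at configurable URLs
because the canonical profile is published externally; the defaults are
stable placeholder URIs under the registry's canonical namespace.

Design choices where the base resource leaves room:

- **Localized titles/descriptions.** `ResearchStudy.title` is a single
  string. All language variants are carried in a translation-style complex
  extension (`language` code + `content` string); the bare `title` /
  `description` elements hold the English text when present, else the German,
  purely as a display value. Reconstructing from the extension alone makes
  the round trip unambiguous — if only the preferred language were mirrored
  into `title`, a record with only a German title could not be distinguished
  from an English-only one on ingestion.
- **relatedArtifact.** Besides the record's own links, one `relatedArtifact`
  is derived per identifier from the link templates above (UTNs and local ids
  without a template yield none). On ingestion, entries that exactly equal a
  derivable link are dropped again, so derived links never accumulate.
- **Deterministic ids.** Resource ids are slugs of the stable business keys
  (site id; exporting site + local id; first identifier for masters) plus a
  short hash, and bundle `fullUrl`s are UUIDv5 values of `type/id` — identical
  input therefore serializes byte-identically. All JSON is written with
  sorted keys and compact separators.
- **Provenance.** The exporting site is encoded in the LOCAL identifier's
  per-site system URI (template above) and parsed back on ingestion; a master
  record's `member_refs` are recovered the same way from the member LOCAL
  identifiers it retains.

`validate_profile` checks base structural rules (resource type, status code
membership, identifiers with system+value, relatedArtifact shape) plus the
profile rules (extension payload shapes, site-status codes in the value set,
master-tag code). Unknown extensions are ignored but logged.

## Merging

Identifier values from real exports carry trailing whitespace and case noise
that silently breaks linkage, so normalization precedes everything: trim,
remove internal whitespace, uppercase NCT/DRKS values, infer the source from
the system URI (unknown systems are site-local).

The identifier graph has one vertex per record and an edge wherever two
records share a normalized *primary* identifier. The primary set defaults to
{NCT, DRKS, EudraCT}; the UTN is recognized but not used as a merge key
unless enabled, since it plays no role in the merging procedure. Connected
components are found by breadth-first search from each unvisited vertex
(an independent union-find implementation serves as test oracle). Every
component — including singletons and records with no primary identifier at
all — yields one master record, so unicentric studies get masters too.

Determinism is imposed wherever the procedure would otherwise be arbitrary:
members are ordered by `(exporting_site, local_id)`, clusters by their
smallest member, identifier unions sorted with non-local identifiers first.
"First study wins" conflict resolution for scalar fields (acronym, title and
description per language, eligibility) uses that member order. The master's
single overall status is `active` if any site is recruiting, otherwise the
first match in a fixed precedence list (temporarily-closed variants, then
approved, in-review, closed-to-accrual variants, administratively-completed,
completed, disapproved, withdrawn) — the merged record should look active to
a registry reader whenever any site still recruits.

`merge_all` recomputes all masters from scratch and diffs against the
previous master set (full-recompute batch semantics, matching a daily run; an
incremental variant keyed on the updated record's identifiers is a documented
future optimization). A new master that shares any identifier with an
existing master becomes a conditional *update* keyed on that shared
identifier plus the master tag; otherwise a *create* keyed on its first
identifier. Existing masters matching no new master — and surplus masters
when previously separate clusters coalesce — are scheduled as conditional
*deletes*. Re-running on unchanged input yields content-identical updates and
no deletes.

Site-export bundles key each record's conditional update on its LOCAL
identifier **and** a `_tag:not` exclusion of the master tag: masters retain
their members' LOCAL identifiers, so without the exclusion a site's
conditional update would match two resources on the server.

## Discrepancy audit

Within each multicentric cluster (members from ≥ 2 distinct exporting sites)
the audit counts, per field (acronym, title and description per language),
whether the set of normalized non-missing values has ≥ 2 elements. Unset
values are excluded before counting — a missing value is incomplete data, not
a conflict. Normalization collapses runs of Unicode whitespace (registry
exports contain non-breaking spaces) to single spaces, strips ends, and
case-folds (locale-independent, so German ß/umlauts fold consistently);
punctuation is deliberately left intact, since a punctuation change can be a
content change. Percentages are printed with two decimals below 10% and one
decimal above, the convention used in consortium audit reports.

## Synthetic registry generator

The generator emulates the consortium setting: `n_studies` true studies, each
carrying well-formed NCT ("NCT" + 8 digits), DRKS ("DRKS" + 8 digits) and
EudraCT ("YYYY-NNNNNN-CC", check characters not validated) identifiers; a
`multicentric_fraction` of them exported by 2–4 sampled sites, each export
with its own 12-letter local id, per-site status and contacts. Defaults —
10 sites, 500 studies, 30% multicentric, identifier dropout probability 0.2
per identifier per export — reflect a mid-size university-hospital
consortium. Dropout is constrained so each true study's records stay
connected through shared identifiers (a repair loop restores the fewest
dropped identifiers needed); `allow_fragmentation` disables the constraint to
study the failure mode. Unicentric exports may lose all primary identifiers,
which is harmless: they form singleton components.

Textual discrepancies are injected per multicentric study and field with
per-field probabilities defaulting to rates observed in a real consortium
corpus (acronym 12.5%, German title 4.42%, English title 13.7%, German
description 0.65%, English description 6.63%). A content-level edit inserts a
single word (or appends a letter to the acronym) — the mechanism seen in
practice, where a study-protocol title differs from the registry title by one
added word; cosmetic case/whitespace edits are injected at the same rates and
must never be counted. The ground-truth object records the true record→study
assignment and the injected content edits, so cluster recovery and audit
counts can be checked exactly. One seeded RNG drives everything; identical
configs produce byte-identical NDJSON.

What the generator does **not** emulate: realistic clinical vocabularies or
title semantics (titles are drawn from a word pool), identifier typos,
cross-study identifier collisions from data-entry errors, text-encoding
corruption, and site-specific export quirks. Passing tests therefore
demonstrate the correctness of the mapping/merging/audit machinery under the
stated noise model, not robustness to arbitrarily dirty real-world exports —
identifier *typos* in particular would fragment clusters by design, since
merging is exact-match on normalized identifiers.

## Numerical and degenerate-input choices

- Empty record list: empty graph, zero masters, empty plan; empty cluster:
  error. A zero-entry transaction bundle is valid.
- Percent formatting with zero multicentric clusters prints `0.00`.
- Python `round`-style float formatting is used for percentages; the reported
  audit counts themselves are integers, so no tolerance questions arise.
- NDJSON parse errors carry the 1-based line number; validation failures exit
  with status 2 and list every violation.

## Problem sizes

The default test and demo corpora are 10 sites × 500 studies (≈ 790 records),
which exercises every code path including coalescing and deletion plans; the
component-search oracle check runs 1,000 random graphs of up to 200 vertices.
These sizes were chosen as the package's own test conditions; the algorithms
are linear in records + identifier pairs and handle corpora orders of
magnitude larger.
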