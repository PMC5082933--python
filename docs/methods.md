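# Methods

This note records the model behind `tcgasync`, the design decisions taken
where the problem was genuinely open, and what the synthetic fixture does
and does not emulate.

## The remote model

The engine treats "the remote" as a directory contract with four source
stores, each with its own discovery dialect:

| store         | discovery                | versioning signal                  |
|---------------|--------------------------|------------------------------------|
| `dcc`         | archive serial + change lists | `CHANGES_DCC` per release     |
| `level4store` | archive serial           | listing diff by checksum           |
| `bamstore`    | last-modified date       | checksum diff of recent files      |
| `msstore`     | last-modified date       | checksum diff of recent files      |

A root-level `MD5SUMS.txt` manifest (standard `md5sum` format, one
`<hex>  <path>` line per file) is the integrity ground truth for transfers.

The historical `CHANGES_DCC.txt` grammar is not publicly documented, so the
fixture and parser use a deliberately minimal dialect: a `# serial=<n>`
comment followed by one `<ACTION>\t<relative path>` record per line with
`ACTION ∈ {ADDED, MODIFIED, DELETED}`. The dialect is isolated behind
`parse_changes_file`; nothing else inspects the text.

## Change planning

Serial-based stores: if the local serial equals the remote serial the plan
is empty (modulo recovery, below). Otherwise the change lists of every
intervening serial are unioned with *last action per path wins* — the same
result as replaying the lists in order. Files present in the release but in
no change list are *serial-bumped-unchanged*: only their referenced archive
serial is refreshed in metadata, with no download, no notification and no
change message ("meaningful difference" is operationalized as an MD5
change). Files listed remotely but absent locally are planned as additions
even at equal serials; this is what makes downloads that previously
exhausted their retries self-healing on the next run. A remote serial lower
than the local one is an error (remote regression), never silently
re-synced.

Date-based stores diff by checksum, restricted to files modified since the
last sync date; deletions are detected by absence from the listing
regardless of date.

## Transfer and containment

`fetch_file` verifies each attempt against the manifest MD5 and retries up
to `retry_limit` (default 3) times, logging every attempt as a JSON line.
Exhaustion produces a failed *result*, not an exception: per-file failures
are contained, reported, and recoverable from the download log
(`audit_download_log` returns paths whose latest attempt failed). Ingest
moves staged bytes into place atomically (write-then-rename), so an
interrupted run never leaves a half-written current file.

## Naming and layout

Repository file names join thirteen metadata components with `.`:
barcode, access, disease, center, platform, level, experiment id, analysis
revision, source revision, optional reference genome, optional portion
name, portion number (default 1), repository version — then the extension.
Hyphens occur only inside the barcode, and component values are sanitized
(dots and whitespace → `_`) before joining, so a single dot-split recovers
every component. Two optional middle components would make the grammar
ambiguous; it stays bijective because portion names are restricted to a
registered vocabulary (`red`/`grn`, the two-channel methylation array
files) and reference-genome labels may not collide with it.

The "source revision" component exists to discriminate same-typed files
arriving from different delivery batches; it is carried through from source
metadata as an opaque integer (the fixture increments it on modification).

Directory layout is `<disease>/<participant>/<sample>/<datatype>/<level>/`.
The datatype segment is recovered from the platform component via the
datatype registry, in which each code carries a distinct platform label; an
unregistered platform falls back to the platform string itself. Files from
non-DCC sources keep their original names (BAM stubs by analysis UUID);
mass-spectrometry files gain a `YYYYMMDD_` analysis-date prefix because
their source offers no versioning. Barcodes truncated above sample depth
(clinical data) reuse the participant barcode as the sample segment.

## Versioning semantics

The logical identity under which versions increment is
(datatype, barcode, level, experiment id, portion name, portion number);
for UUID-keyed alignments the experiment id is the analysis UUID, so a
re-analysis of the same sample is a new logical file, not a new version.
Versions are gapless `1..k` with exactly one current version (or none after
deletion). Identical re-ingest refreshes provenance only. Superseded
versions move under a parallel `archive/` subtree (version-suffixed where
the name does not embed the version) and are immutable thereafter.
Removal is policy-driven: `archive` retains bytes under `archive/`,
`delete` removes them and keeps a tombstone record. Retention is
"keep all" unless `delete` is configured.

Snapshots key on the repository's own ingest timestamps (the source does
not expose reliable event times across stores). Every catalog mutation is
stamped by an injectable clock whose values are strictly monotonized, which
makes `snapshot(t)` a pure function of the recorded history: a version is
in the snapshot iff ingested at or before `t` and neither superseded nor
removed by then. Supersession is stamped at the same instant as the
replacing ingest, so no probe instant observes zero current versions for a
live logical file.

## VCF harmonization

Input VCFs vary in header content and ordering. `harmonize_header` emits the
eight required entries in fixed order — values taken from the original
header when present (a few spelling aliases such as `##fileDate` and
`##reference` are recognized), else from file metadata; a value available
from neither is an error naming the key. Original lines carrying a required
key are consumed into the block rather than duplicated, and every other
original header line passes through unchanged and in order — the only
reading under which harmonization is idempotent while conserving
information. Whether the historical pipeline overwrote conflicting original
values is unknowable from the outside; here the original value wins and
metadata only fills gaps.

`sort_records` orders records numerically by POS within each chromosome
block; blocks keep first-appearance order (no karyotypic reordering) and
the sort is stable, so the operation is a minimal permutation. The required
header keys are spelled `genome_ref.name` / `genome_ref.url` (header keys
cannot contain spaces).

`split_by_sample` projects each sample column onto the nine fixed columns;
`no_split` is the identity. The sync pipeline applies a datatype's declared
policy; the default registry declares `no_split` for all VCF datatypes
(curated somatic VCFs ship pre-split in the fixture), so splitting is
exercised as a standalone operation.

## Validation decisions

The barcode↔UUID map is authoritative: a mismatch against a known UUID is
corrected to the map's barcode; an unknown UUID is only flagged — identity
is never invented. Tissue-source-site normalization trims, collapses
whitespace and case-folds before lookup, with a second pass treating
hyphens as spaces; the shipped mapping covers alternative names, hyphens,
misspellings and extra spaces, and canonical names are fixpoints by
construction.

## Metadata store

One embedded relational store (SQLite) is the system of record; the RDF
form is an export (subject = file id, predicate = field name, object =
value, N-Triples), not a second live backend — maintaining both live would
double the surface without adding test value. Predicate names mirror the
record's field names. Notifications are events appended to an outbox file;
e-mail transport is out of scope. Change messages are pydantic-validated
JSON documents, one per content add/modify/delete per run.

## The synthetic fixture

`mock_remote` generates the whole four-store universe deterministically:
identical (spec, seed) produce byte-identical trees, manifests and ledgers.
Timestamps come from a synthetic monotonic clock (one minute per file
event, one day per release); payloads are small but well-formed — VCFs with
embedded sample barcodes (sometimes unsorted, with center-dependent header
variation), tab-delimited MAFs and matrices, clinical tables, and opaque
seeded byte blobs for BAM/idat/svs stubs that are only ever checksummed.
Every change is recorded in a ground-truth event ledger whose replay is the
oracle for sync convergence. `inject_fault` corrupts the next *n* fetches
of a path to exercise the retry contract.

The fixture does not emulate: transport (HTTP/torrent), authentication,
bandwidth or scheduling; realistic file sizes; cross-sample level-4
bundles (summarized files are attached per-sample so the uniform
participant/sample hierarchy is exercised); or the real DCC change-list
grammar. Passing tests therefore demonstrate the engine's bookkeeping —
change detection, verification, versioning, provenance — not performance
or wire-protocol behaviour against the retired production endpoints.

## Problem sizes

The test suite and the acceptance script use 20 randomized histories of 5
releases with 1–3 participants and 2–4 datatypes each (tens of files per
history, well under the 200-file cap), 100 snapshot probe instants, 30
random toy VCFs, and 500 cases per serialization round trip. These sizes
exercise every code path, including multi-serial catch-up, deletion under
both policies, and fault recovery, while keeping the whole suite in
seconds.
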