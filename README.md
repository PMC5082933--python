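# tcgasync

Incremental synchronization, harmonization, versioning and provenance for
TCGA-style multi-source genomic archives.

Consortium-era cancer genomics data (The Cancer Genome Atlas and its
contemporaries) was distributed across several archives with different
discovery dialects — serial-numbered Data Coordinating Center (DCC) archives
with per-release change lists, an alignment store keyed by analysis UUID and
last-modified date, summarized copy-number bundles, and dated
mass-spectrometry deliveries. Using those data reproducibly required a local,
*versioned* mirror: know when a file was added, modified or deleted; fetch it
with checksum verification and retry; harmonize heterogeneous VCFs; file
everything under a participant/sample-oriented hierarchy with informative
names; and keep provenance metadata that supports manifests, date-freeze
snapshots, change notifications and downstream loaders. `tcgasync` is a
self-contained engine for exactly that workflow, testable end to end against
a built-in deterministic mock of the four-source remote.

## What the engine does

One sync run executes, per source store:

1. **Change detection.** DCC-style stores compare archive serials and parse
   the `CHANGES_DCC` list of every intervening release (`ADDED`/`MODIFIED`/
   `DELETED`, last action per path wins). The level-4 bundle store compares
   serials then diffs listings by checksum; the BAM and mass-spec stores are
   discovered by last-modified date. Files whose archive serial bumped
   without a content change only have their referenced serial refreshed in
   metadata — no download.
2. **Verified fetch.** Every file is fetched with MD5 verification against
   the remote manifest and bounded retry; every attempt is appended to a
   download log from which failed paths are recoverable for retry.
3. **Validation.** Barcode↔analysis-UUID agreement (the UUID map is
   authoritative; mismatches are corrected, unknown UUIDs flagged), tissue
   source site name normalization against a curated mapping table, VCF
   sortedness, checksums, and download-log audit.
4. **VCF harmonization.** Headers are rewritten to a fixed-order block —
   `fileformat, filedate, center, platform, genome_ref.name, genome_ref.url,
   patient_id, specimen_id` — followed by every original header line;
   records are sorted numerically by position within each chromosome block.
   Multi-sample files can be split one-per-sample.
5. **Versioned ingest.** Files land under
   `<disease>/<participant>/<sample>/<datatype>/<level>/` with a 13-component
   metadata file name (barcode, access, disease, center, platform, level,
   experiment id, analysis revision, source revision, reference genome,
   portion name, portion number, repository version). Changed content
   archives the previous version and bumps the repository version; deletions
   are policy-driven (archive or delete).
6. **Provenance metadata.** A relational store keyed by (logical id,
   version) answers manifest queries, reconstructs date-freeze snapshots,
   matches subscriptions to emit notification events, exports JSON change
   messages for downstream loaders, and dumps/reloads N-Triples.

## Worked example

```sh
tcgasync fixture generate --root remote --participants 2 \
    --datatypes Somatic_Mutations --datatypes Protected_Mutations \
    --datatypes WGS_cgHub --seed 7
tcgasync sync run --remote remote --workspace ws
```

The first run mirrors all six files (two MAFs, two VCFs, two BAM stubs):

```json
{"run_id": "sync-0001", "downloads": 6, "messages": 6, "events": 0, "failed": []}
```

Advance the remote by one release — one somatic-mutation file modified, one
added — and sync again:

```sh
tcgasync fixture advance --root remote --modify Somatic_Mutations=1 \
    --add Somatic_Mutations=1 --seed 1
tcgasync sync run --remote remote --workspace ws
```

```json
{
 "run_id": "sync-0002", "downloads": 2, "messages": 2,
 "outcomes": {
  "dcc/.../TCGA-06-CF10-01A-11D-PF91-01.2.maf": "ingested:added:v1",
  "dcc/.../TCGA-06-CF10-01A-11D-PF91-01.1.maf": "ingested:modified:v2",
  "dcc/.../TCGA-06-UJZD-01A-11D-8GXD-01.1.maf": "serial_refreshed",
  "...": "serial_refreshed"
 }
}
```

Only the two changed files were downloaded; the modified file became
repository version 2 (its previous bytes moved under `archive/`), and the
three untouched DCC files had their referenced archive serial refreshed
without a download. The repository now holds, for example:

```
BRCA/TCGA-06-CF10/TCGA-06-CF10-01A/Somatic_Mutations/Level_2/
  TCGA-06-CF10-01A-11D-PF91-01.public.BRCA.broad_mit_edu.IlluminaGA_DNASeq.2.Somatic_Mutations_BRCA_L2.1.2.hg19.1.2.maf
```

— the barcode plus twelve further metadata components ending in
`...portion 1, repository version 2` and the extension. A filtered manifest
(`tcgasync manifest --workspace ws --datatype Somatic_Mutations`) lists each
current file with its logical id, version, path and checksum;
`tcgasync snapshot --workspace ws --as-of <instant>` reconstructs the file
set at any past instant.

The same operations are available as library calls (`generate_remote`,
`run_sync`, `Repository.snapshot`, `MetadataStore.query_manifest`, …); the
CLI is a thin wrapper.

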