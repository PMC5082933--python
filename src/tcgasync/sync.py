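"""Incremental synchronization: change detection, verified fetch, ingest.

One sync run walks four source adapters (one per remote datastore),
plans a change set, fetches each new or modified file with MD5
verification and bounded retry, validates and harmonizes it, ingests it
into the versioned repository, upserts provenance metadata, and emits
notification events and JSON change messages.  Per-file failures are
contained — logged, reported, retried next run — and never abort the
run.  A run against an unchanged remote is a no-op fixpoint.

Change detection strategy per store:

* ``dcc`` — compare archive serials; on a bump, parse the per-release
  ``CHANGES_DCC`` lists for every intervening serial (last action per
  path wins).  Files whose serial bumped without a content change are
  routed to ``serial_bumped_unchanged`` and only have their referenced
  archive serial refreshed in metadata — no download, no message.
* ``level4store`` — compare serials, then diff the remote listing
  against local state by checksum.
* ``bamstore`` / ``msstore`` — date-based: consider files modified
  since the last sync date, diff by checksum; local files absent from
  the listing are deletions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import vcf as vcfmod
from .barcode import parse_barcode
from .metadata import (
    ADDED,
    DELETED,
    MODIFIED,
    FileMetadataRecord,
    MetadataStore,
)
from .mock_remote import RemoteState, md5_hex
from .naming import FileNameFields, ms_file_name
from .repository import Provenance, Repository
from .validation import (
    CORRECTED,
    FLAGGED,
    OK,
    Finding,
    TSSMappingTable,
    UUIDMap,
    check_barcode_uuid,
    check_vcf_sorted,
    normalize_tss,
)
from .vocab import DATATYPES, get_datatype


class SyncError(ValueError):
    pass


@dataclass
class SyncConfig:
    """Configuration for one sync run."""

    datatypes: List[str] = field(default_factory=lambda: sorted(DATATYPES))
    retry_limit: int = 3
    delete_policy: str = "archive"  # archive | delete
    uuid_map: Optional[str] = None  # path to the barcode<->UUID table
    tss_map: Optional[str] = None  # path to the tissue-source-site table

    def __post_init__(self) -> None:
        if self.retry_limit < 1:
            raise SyncError("retry_limit must be >= 1")
        if self.delete_policy not in ("archive", "delete"):
            raise SyncError(f"unknown delete_policy: {self.delete_policy!r}")
        for code in self.datatypes:
            if code not in DATATYPES:
                raise SyncError(f"unknown datatype code: {code!r}")

    @classmethod
    def from_yaml(cls, path: "Path | str") -> "SyncConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: "Path | str") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ChangeSet:
    """Planned work for one run; the four lists are pairwise disjoint."""

    added: List[str] = field(default_factory=list)
    modified: List[str] = field(default_factory=list)
    deleted: List[str] = field(default_factory=list)
    serial_bumped_unchanged: List[str] = field(default_factory=list)

    def validate(self) -> None:
        groups = [self.added, self.modified, self.deleted, self.serial_bumped_unchanged]
        seen: set[str] = set()
        for group in groups:
            for path in group:
                if path in seen:
                    raise SyncError(f"path {path!r} appears in two change lists")
                seen.add(path)

    def is_empty(self) -> bool:
        return not (self.added or self.modified or self.deleted)

    def merge(self, other: "ChangeSet") -> None:
        self.added.extend(other.added)
        self.modified.extend(other.modified)
        self.deleted.extend(other.deleted)
        self.serial_bumped_unchanged.extend(other.serial_bumped_unchanged)
        self.validate()


@dataclass
class FetchResult:
    path: str
    attempts: int
    verified: bool
    staged: Optional[Path] = None


@dataclass
class SyncReport:
    run_id: str
    outcomes: Dict[str, str] = field(default_factory=dict)
    failed: List[str] = field(default_factory=list)
    downloads: int = 0
    messages: int = 0
    events: int = 0
    findings: List[Finding] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    changes: List[tuple] = field(default_factory=list)  # (action, FileMetadataRecord)


# ---------------------------------------------------------------------------
# change-list parsing

_VERB_TO_ACTION = {"ADDED": ADDED, "MODIFIED": MODIFIED, "DELETED": DELETED}


def parse_changes_file(text: str) -> ChangeSet:
    """Parse one CHANGES_DCC change list into a ChangeSet."""
    cs = ChangeSet()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SyncError(f"changes line {lineno}: expected 'VERB<TAB>path', got {line!r}")
        verb, path = parts
        if verb not in _VERB_TO_ACTION:
            raise SyncError(f"changes line {lineno}: unknown verb {verb!r}")
        {"ADDED": cs.added, "MODIFIED": cs.modified, "DELETED": cs.deleted}[verb].append(path)
    cs.validate()
    return cs


# ---------------------------------------------------------------------------
# source adapters


class SourceAdapter:
    """Change-detection strategy for one remote datastore."""

    store: str

    def plan(self, remote: RemoteState, local: MetadataStore, config: SyncConfig) -> ChangeSet:
        raise NotImplementedError

    # listing of this store restricted to the selected datatypes
    def _listing(self, remote: RemoteState, config: SyncConfig) -> Dict[str, str]:
        from .mock_remote import list_remote

        selected = set(config.datatypes)
        return {
            path: md5
            for path, _, md5 in list_remote(remote, self.store)
            if remote.file_meta(path)["datatype"] in selected
        }

    def _local(self, local: MetadataStore) -> Dict[str, tuple[str, str]]:
        prefix = f"{self.store}/"
        return {
            p: v for p, v in local.current_paths().items() if p.startswith(prefix)
        }

    def _diff(self, listing: Dict[str, str], tracked: Dict[str, tuple[str, str]]) -> ChangeSet:
        cs = ChangeSet()
        for path in sorted(listing):
            if path not in tracked:
                cs.added.append(path)
            elif tracked[path][1] != listing[path]:
                cs.modified.append(path)
        cs.deleted.extend(sorted(set(tracked) - set(listing)))
        return cs


class DccAdapter(SourceAdapter):
    store = "dcc"

    def plan(self, remote: RemoteState, local: MetadataStore, config: SyncConfig) -> ChangeSet:
        local_serial, _ = local.get_sync_state(self.store)
        remote_serial = remote.serials[self.store]
        listing = self._listing(remote, config)
        tracked = self._local(local)
        if local_serial is None:
            # empty local repository: everything currently listed is new
            cs = ChangeSet(added=sorted(listing))
            cs.validate()
            return cs
        if remote_serial < local_serial:
            raise SyncError(
                f"remote regression: dcc serial {remote_serial} < local {local_serial}"
            )
        if remote_serial == local_serial:
            # no new release; still recover files listed remotely but never
            # ingested (e.g. downloads that exhausted their retries)
            cs = ChangeSet(added=sorted(set(listing) - set(tracked)))
            cs.validate()
            return cs
        # union of all intervening change lists, last action per path wins
        last_action: Dict[str, str] = {}
        for serial in range(local_serial + 1, remote_serial + 1):
            cs = parse_changes_file(remote.read_changes(serial))
            for path in cs.added:
                last_action[path] = ADDED
            for path in cs.modified:
                last_action[path] = MODIFIED
            for path in cs.deleted:
                last_action[path] = DELETED
        out = ChangeSet()
        for path in sorted(last_action):
            action = last_action[path]
            if action == DELETED:
                if path in tracked:
                    out.deleted.append(path)
            elif path in listing:  # ignore change entries for unselected datatypes
                if path in tracked:
                    (out.modified if action == MODIFIED else out.added).append(path)
                else:
                    out.added.append(path)
        # listed but untracked and not in any change list: recover it too
        leftover = set(listing) - set(last_action) - set(tracked)
        out.added.extend(sorted(leftover))
        # everything else in the release is a metadata-only serial bump
        out.serial_bumped_unchanged.extend(
            sorted(set(listing) - set(last_action) - leftover)
        )
        out.validate()
        return out


class Level4Adapter(SourceAdapter):
    store = "level4store"

    def plan(self, remote: RemoteState, local: MetadataStore, config: SyncConfig) -> ChangeSet:
        local_serial, _ = local.get_sync_state(self.store)
        remote_serial = remote.serials[self.store]
        if local_serial is not None:
            if remote_serial < local_serial:
                raise SyncError(
                    f"remote regression: level4 serial {remote_serial} < local {local_serial}"
                )
            if remote_serial == local_serial:
                listing = self._listing(remote, config)
                tracked = self._local(local)
                cs = ChangeSet(added=sorted(set(listing) - set(tracked)))
                cs.validate()
                return cs
        cs = self._diff(self._listing(remote, config), self._local(local))
        cs.validate()
        return cs


class DateStoreAdapter(SourceAdapter):
    """Date-based discovery: new/updated files since the last sync date."""

    def plan(self, remote: RemoteState, local: MetadataStore, config: SyncConfig) -> ChangeSet:
        _, last_date = local.get_sync_state(self.store)
        listing = self._listing(remote, config)
        tracked = self._local(local)
        if last_date is not None:
            # only files touched since the last sync need checksum diffing;
            # deletions are detected by absence from the listing regardless
            recent = {
                p: md5
                for p, md5 in listing.items()
                if remote.file_meta(p)["mtime"] > last_date or p not in tracked
            }
            cs = ChangeSet()
            for path in sorted(recent):
                if path not in tracked:
                    cs.added.append(path)
                elif tracked[path][1] != recent[path]:
                    cs.modified.append(path)
            cs.deleted.extend(sorted(set(tracked) - set(listing)))
        else:
            cs = self._diff(listing, tracked)
        cs.validate()
        return cs


class BamStoreAdapter(DateStoreAdapter):
    store = "bamstore"


class MsStoreAdapter(DateStoreAdapter):
    store = "msstore"


def default_adapters() -> List[SourceAdapter]:
    """The adapter registry: one per remote datastore."""
    return [DccAdapter(), BamStoreAdapter(), Level4Adapter(), MsStoreAdapter()]


def plan_sync(remote: RemoteState, local: MetadataStore, config: SyncConfig) -> ChangeSet:
    """Plan one run across all four stores."""
    combined = ChangeSet()
    for adapter in default_adapters():
        combined.merge(adapter.plan(remote, local, config))
    return combined


# ---------------------------------------------------------------------------
# verified fetch


def _log_attempt(log_path: Path, path: str, attempt: int, outcome: str, checksum: str) -> None:
    entry = {
        "timestamp": datetime.now().isoformat(),
        "path": path,
        "attempt": attempt,
        "outcome": outcome,
        "checksum": checksum,
    }
    log_path.parent.mkdir(parents=True, exist_ok=True)
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def fetch_file(
    remote: RemoteState,
    path: str,
    expected_md5: str,
    retry_limit: int,
    staging_dir: "Path | str",
    log_path: "Path | str",
) -> FetchResult:
    """Fetch with checksum verification; retry up to ``retry_limit`` attempts.

    Every attempt is appended to the download log.  Exhaustion yields a
    failed result (never an exception) so the run can continue and the
    log audit can schedule a retry.
    """
    staging_dir, log_path = Path(staging_dir), Path(log_path)
    for attempt in range(1, retry_limit + 1):
        data = remote.fetch(path)
        digest = md5_hex(data)
        ok = digest == expected_md5
        _log_attempt(log_path, path, attempt, "success" if ok else "failure", digest)
        if ok:
            staged = staging_dir / path
            staged.parent.mkdir(parents=True, exist_ok=True)
            staged.write_bytes(data)
            return FetchResult(path=path, attempts=attempt, verified=True, staged=staged)
    return FetchResult(path=path, attempts=retry_limit, verified=False)


# ---------------------------------------------------------------------------
# ingest pipeline

_GENOME_URLS = {
    "hg19": "http://hgdownload.cse.ucsc.edu/goldenPath/hg19/bigZips/",
    "GRCh37": "ftp://ftp.ensembl.org/pub/release-75/fasta/homo_sapiens/dna/",
}


def _fields_from_meta(meta: dict, barcode_text: str) -> FileNameFields:
    return FileNameFields(
        barcode=parse_barcode(barcode_text),
        access=meta["access"],
        disease=meta["disease"],
        center_name=meta["center_name"],
        platform=meta["platform"],
        level=meta["level"],
        experiment_id=meta["experiment_id"],
        analysis_revision=meta["analysis_revision"],
        tcga_revision=meta["tcga_revision"],
        ref_genome=meta.get("ref_genome"),
        portion_name=meta.get("portion_name"),
        portion_number=meta.get("portion_number", 1),
        extension=meta["extension"],
    )


def _record_from(stored, meta: dict, status: str) -> FileMetadataRecord:
    f = stored.fields
    return FileMetadataRecord(
        logical_id=stored.logical_id,
        repo_version=stored.repo_version,
        status=status,
        barcode=f.barcode.render(),
        access=f.access,
        disease=f.disease,
        center_code=meta.get("center_code"),
        center_name=f.center_name,
        platform=f.platform,
        level=f.level,
        experiment_id=f.experiment_id,
        analysis_revision=f.analysis_revision,
        tcga_revision=f.tcga_revision,
        datatype=f.datatype,
        extension=f.extension,
        md5=stored.md5,
        local_path=stored.local_path,
        ingest_ts=stored.ingest_timestamp,
        ref_genome=f.ref_genome,
        ref_genome_source=meta.get("ref_genome_source"),
        algorithm_name=meta.get("algorithm_name"),
        algorithm_version=meta.get("algorithm_version"),
        portion_name=f.portion_name,
        portion_number=f.portion_number,
        archive_name=stored.provenance.archive_name,
        archive_serial=stored.provenance.serial,
        source_md5=stored.source_md5,
        original_path=meta["path"],
        original_name=stored.provenance.original_name,
    )


def _harmonize_vcf_bytes(
    data: bytes, meta: dict, filedate: str, report: SyncReport, path: str
) -> bytes:
    text = data.decode()
    finding = check_vcf_sorted(text, path)
    report.findings.append(finding)
    if finding.severity == FLAGGED:
        text = vcfmod.sort_records(text)
    hmeta = vcfmod.HarmonizationMeta(
        center=meta["center_name"],
        platform=meta["platform"],
        patient_id="-".join(meta["barcode"].split("-")[:3]),
        specimen_id=meta["barcode"],
        genome_ref_name=meta.get("ref_genome") or "unknown",
        genome_ref_url=_GENOME_URLS.get(meta.get("ref_genome") or "", "unavailable"),
        filedate=filedate,
    )
    return vcfmod.harmonize_header(text, hmeta).encode()


def run_sync(
    remote: RemoteState,
    config: SyncConfig,
    repository: Repository,
    store: MetadataStore,
    workdir: "Path | str",
) -> SyncReport:
    """Plan, fetch, validate, harmonize, ingest, record, notify.

    Artifacts under ``workdir``: ``staging/`` (fetch target),
    ``logs/downloads.log`` (per-attempt audit), ``outbox.ndjson``
    (notification events), ``messages/<run id>.json`` (change
    messages).
    """
    workdir = Path(workdir)
    staging = workdir / "staging"
    log_path = workdir / "logs" / "downloads.log"
    outbox = workdir / "outbox.ndjson"
    messages_dir = workdir / "messages"
    messages_dir.mkdir(parents=True, exist_ok=True)

    uuid_map = UUIDMap.from_file(config.uuid_map) if config.uuid_map else None
    tss_table = (
        TSSMappingTable.from_file(config.tss_map)
        if config.tss_map
        else TSSMappingTable.load_default()
    )

    changes = plan_sync(remote, store, config)
    run_id = store.next_run_id()
    report = SyncReport(run_id=run_id, started=datetime.now().isoformat())
    filedate = remote.clock.strftime("%Y%m%d")

    for path, planned in [(p, ADDED) for p in changes.added] + [
        (p, MODIFIED) for p in changes.modified
    ]:
        try:
            report.outcomes[path] = _ingest_one(
                remote, config, repository, store, path, planned, report,
                staging, log_path, uuid_map, tss_table, filedate,
            )
        except Exception as exc:  # containment: a bad file never aborts the run
            report.outcomes[path] = f"error: {exc}"
            report.failed.append(path)

    tracked = store.current_paths()
    for path in changes.deleted:
        try:
            logical_id = tracked[path][0]
            stored = repository.remove_file(logical_id, config.delete_policy)
            store.set_status(logical_id, stored.repo_version, "deleted")
            rec = store.get_record(logical_id, stored.repo_version)
            report.changes.append((DELETED, rec))
            report.outcomes[path] = "deleted"
        except Exception as exc:
            report.outcomes[path] = f"error: {exc}"
            report.failed.append(path)

    for path in changes.serial_bumped_unchanged:
        logical_id = tracked.get(path, (None, None))[0]
        if logical_id is None:
            continue
        current = repository.current_version(logical_id)
        if current is not None:
            serial = remote.serials.get("dcc")
            store._db.execute(
                "UPDATE file_metadata SET archive_serial=? WHERE logical_id=? AND repo_version=?",
                (serial, logical_id, current.repo_version),
            )
            store._db.commit()
            report.outcomes[path] = "serial_refreshed"

    # notifications and change messages for content changes only
    events = store.emit_notifications(report.changes, run_id, outbox=outbox)
    report.events = len(events)
    messages = store.build_change_messages(run_id, report.changes)
    report.messages = len(messages)
    if messages:
        (messages_dir / f"{run_id}.json").write_text(store.serialize_messages(messages))

    # advance local sync cursors
    store.set_sync_state("dcc", remote.serials["dcc"], None)
    store.set_sync_state("level4store", remote.serials["level4store"], None)
    now_remote = remote.clock.isoformat()
    store.set_sync_state("bamstore", None, now_remote)
    store.set_sync_state("msstore", None, now_remote)

    report.finished = datetime.now().isoformat()
    return report


def _ingest_one(
    remote: RemoteState,
    config: SyncConfig,
    repository: Repository,
    store: MetadataStore,
    path: str,
    planned: str,
    report: SyncReport,
    staging: Path,
    log_path: Path,
    uuid_map: Optional[UUIDMap],
    tss_table: TSSMappingTable,
    filedate: str,
) -> str:
    meta = remote.file_meta(path)
    expected = remote.manifest[path]
    result = fetch_file(remote, path, expected, config.retry_limit, staging, log_path)
    report.downloads += result.attempts
    if not result.verified:
        report.failed.append(path)
        return "failed: checksum verification exhausted"

    barcode_text = meta["barcode"]
    if uuid_map is not None:
        finding = check_barcode_uuid({**meta, "path": path}, uuid_map)
        report.findings.append(finding)
        if finding.severity == CORRECTED:
            barcode_text = finding.corrected_value

    canonical_tss, tss_status = normalize_tss(meta.get("tss_name", ""), tss_table)
    if tss_status != OK:
        report.findings.append(
            Finding("tss_name", path, tss_status if tss_status != "unmapped" else FLAGGED,
                    f"{meta.get('tss_name')!r} -> {canonical_tss!r}")
        )
    meta["tss_name"] = canonical_tss

    staged = result.staged
    assert staged is not None
    if meta["extension"] == "vcf":
        data = _harmonize_vcf_bytes(staged.read_bytes(), meta, filedate, report, path)
        staged.write_bytes(data)

    fields = _fields_from_meta(meta, barcode_text)
    dt = get_datatype(meta["datatype"])
    if dt.source == "dcc":
        naming = Repository.GRAMMAR
        original_name = Path(path).name
    elif dt.source == "msstore":
        naming = Repository.ORIGINAL
        original_name = ms_file_name(Path(path).name, meta["mtime"])
    else:
        naming = Repository.ORIGINAL
        original_name = Path(path).name

    previous = repository.current_version_by_fields(fields)
    provenance = Provenance(
        archive_name=meta.get("archive_name", dt.source),
        serial=remote.serials.get("dcc") if dt.source == "dcc" else remote.serials.get(
            "level4store"
        ) if dt.source == "level4store" else None,
        original_name=original_name,
        original_location=path,
        source_md5=expected,
    )
    stored = repository.ingest_file(staged, fields, provenance, naming=naming)

    if previous is not None and stored.repo_version == previous.repo_version:
        # content unchanged at the source despite the change entry:
        # provenance refreshed, nothing to announce
        rec = _record_from(stored, meta, status="current")
        store.upsert_record(rec)
        return "unchanged"

    if previous is not None:
        store.set_status(previous.logical_id, previous.repo_version, "archived")
    rec = _record_from(stored, meta, status="current")
    store.upsert_record(rec)
    action = MODIFIED if stored.repo_version > 1 and previous is not None else ADDED
    report.changes.append((action, rec))
    return f"ingested:{action}:v{stored.repo_version}"
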