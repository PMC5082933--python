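"""Deterministic mock of the four-source remote archive.

Every downstream stage (change detection, checksum-verified fetch,
harmonization, versioned ingest, provenance metadata) is tested against
this fixture instead of retired network endpoints.  The "remote" is a
directory contract:

* ``dcc/`` — serial-numbered releases; each release past the first
  writes a ``CHANGES_DCC.<serial>.txt`` change list (``ACTION\\tpath``
  records preceded by a ``# serial=<n>`` comment) and the latest is
  mirrored to ``dcc/CHANGES_DCC.txt``;
* ``bamstore/`` — alignment stubs keyed by analysis UUID, discovered by
  last-modified date;
* ``level4store/`` — summarized copy-number bundles, serial-numbered
  but without change lists (discovered by listing diff);
* ``msstore/`` — dated mass-spectrometry deliveries.

``MD5SUMS.txt`` at the root is a standard ``md5sum``-format manifest of
every data file.  ``_remote_state.json`` holds serials, per-file source
metadata, the synthetic clock, pending fault injections, and the
ground-truth event ledger used as the oracle for sync convergence.

Determinism contract: identical (spec, seed) produce byte-identical
trees, manifests and ledgers.  All timestamps come from a synthetic
monotonic clock (one minute per file event, one day per release).
"""

from __future__ import annotations

import hashlib
import json
import random
import uuid as uuid_mod
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional

from .vocab import DATATYPES, STORE_NAMES, Datatype, Vocabulary, get_datatype

STATE_FILE = "_remote_state.json"
MANIFEST_FILE = "MD5SUMS.txt"
CHANGES_BASENAME = "CHANGES_DCC"
EPOCH = datetime(2014, 1, 6, 0, 0, 0)

ADDED, MODIFIED, DELETED = "added", "modified", "deleted"
ACTIONS = (ADDED, MODIFIED, DELETED)

_REF_GENOME = {"vcf": "hg19", "maf": "hg19", "bam": "hg19"}
_ALGORITHMS = {"vcf": ("MuTect", "1.1.4"), "maf": ("MuTect", "1.1.4")}


class RemoteError(ValueError):
    """Invalid fixture specification or remote operation."""


@dataclass(frozen=True)
class RemoteSpec:
    """Shape of the synthetic remote universe."""

    n_participants: int
    datatypes: tuple[str, ...]
    files_per_sample: int = 1
    seed: int = 0
    diseases: tuple[str, ...] = ("BRCA", "GBM")

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise RemoteError("n_participants must be >= 0")
        if self.files_per_sample < 1:
            raise RemoteError("files_per_sample must be >= 1")
        for code in self.datatypes:
            if code not in DATATYPES:
                raise RemoteError(f"unknown datatype code: {code!r}")


@dataclass(frozen=True)
class LedgerEvent:
    """One ground-truth change event in the remote's history."""

    serial: int
    action: str
    path: str
    md5: Optional[str]
    timestamp: str

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise RemoteError(f"unknown ledger action: {self.action!r}")


@dataclass
class MutationSpec:
    """Per-datatype counts of files to add, modify and delete."""

    adds: Dict[str, int] = field(default_factory=dict)
    modifies: Dict[str, int] = field(default_factory=dict)
    deletes: Dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def total(self) -> int:
        return sum(self.adds.values()) + sum(self.modifies.values()) + sum(self.deletes.values())


def md5_hex(data: bytes) -> str:
    return hashlib.md5(data).hexdigest()


def replay_ledger(events: List[LedgerEvent]) -> Dict[str, str]:
    """Fold the event history into the current path -> md5 mapping."""
    current: Dict[str, str] = {}
    for ev in events:
        if ev.action == ADDED:
            if ev.path in current:
                raise RemoteError(f"ledger: duplicate add for {ev.path}")
            current[ev.path] = ev.md5  # type: ignore[assignment]
        elif ev.action == MODIFIED:
            if ev.path not in current:
                raise RemoteError(f"ledger: modify of unknown path {ev.path}")
            current[ev.path] = ev.md5  # type: ignore[assignment]
        else:
            if ev.path not in current:
                raise RemoteError(f"ledger: delete of unknown path {ev.path}")
            del current[ev.path]
    return current


# ---------------------------------------------------------------------------
# payload builders — small but well-formed files with barcodes embedded

_CHROMS = ("1", "2", "7", "17", "X")
_GENES = ("TP53", "PIK3CA", "GATA3", "MAP3K1", "CDH1", "PTEN", "RB1", "EGFR")


def _vcf_payload(rng: random.Random, barcode: str, meta: dict) -> bytes:
    lines = ["##fileformat=VCFv4.1"]
    if rng.random() < 0.5:  # centers differ in how much header they ship
        lines.append(f"##center={meta['center_name']}")
    if rng.random() < 0.5:
        lines.append(f"##reference={meta['ref_genome']}")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total Depth">')
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append("##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + barcode
    )
    n = rng.randint(4, 8)
    chroms = sorted(rng.sample(_CHROMS, k=min(2, len(_CHROMS))))
    records = []
    for _ in range(n):
        chrom = rng.choice(chroms)
        pos = rng.randint(1, 5_000_000)
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        records.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{rng.randint(10, 99)}\tPASS\t"
            f"DP={rng.randint(5, 200)}\tGT\t0/1"
        )
    if rng.random() < 0.5:  # some centers deliver unsorted files
        rng.shuffle(records)
    return ("\n".join(lines + records) + "\n").encode()


def _maf_payload(rng: random.Random, barcode: str, meta: dict) -> bytes:
    header = "Hugo_Symbol\tChromosome\tStart_Position\tVariant_Classification\tTumor_Sample_Barcode"
    rows = [
        f"{rng.choice(_GENES)}\t{rng.choice(_CHROMS)}\t{rng.randint(1, 5_000_000)}\t"
        f"{rng.choice(('Missense_Mutation', 'Nonsense_Mutation', 'Silent'))}\t{barcode}"
        for _ in range(rng.randint(3, 6))
    ]
    return ("\n".join([header] + rows) + "\n").encode()


def _matrix_payload(rng: random.Random, barcode: str, meta: dict) -> bytes:
    header = f"gene\t{barcode}"
    rows = [f"{g}\t{rng.uniform(0, 12):.4f}" for g in rng.sample(_GENES, 5)]
    return ("\n".join([header] + rows) + "\n").encode()


def _clinical_payload(rng: random.Random, barcode: str, meta: dict) -> bytes:
    header = "bcr_patient_barcode\tage_at_diagnosis\tvital_status\ttissue_source_site"
    participant = "-".join(barcode.split("-")[:3])
    row = f"{participant}\t{rng.randint(30, 85)}\t{rng.choice(('Alive', 'Dead'))}\t{meta['tss_name']}"
    return (header + "\n" + row + "\n").encode()


def _blob_payload(rng: random.Random, barcode: str, meta: dict) -> bytes:
    # opaque stub for BAM/idat/svs — only ever checksummed, never parsed
    return rng.getrandbits(8 * 128).to_bytes(128, "big")


def _payload(rng: random.Random, ext: str, datatype: str, barcode: str, meta: dict) -> bytes:
    if ext == "vcf":
        return _vcf_payload(rng, barcode, meta)
    if ext == "maf":
        return _maf_payload(rng, barcode, meta)
    if datatype == "Clinical":
        return _clinical_payload(rng, barcode, meta)
    if ext in ("txt", "tsv"):
        return _matrix_payload(rng, barcode, meta)
    return _blob_payload(rng, barcode, meta)


# ---------------------------------------------------------------------------


class RemoteState:
    """A mock remote bound to a directory tree; persisted in the tree itself."""

    def __init__(self, root: "Path | str"):
        self.root = Path(root)
        self._state: dict = {}
        state_path = self.root / STATE_FILE
        if state_path.exists():
            self._state = json.loads(state_path.read_text())

    # -- persisted fields -------------------------------------------------

    @property
    def serials(self) -> Dict[str, int]:
        return self._state.setdefault("serials", {"dcc": 0, "level4store": 0})

    @property
    def manifest(self) -> Dict[str, str]:
        return self._state.setdefault("manifest", {})

    @property
    def files(self) -> Dict[str, dict]:
        """path -> source metadata record."""
        return self._state.setdefault("files", {})

    @property
    def faults(self) -> Dict[str, int]:
        return self._state.setdefault("faults", {})

    @property
    def ledger(self) -> List[LedgerEvent]:
        return [LedgerEvent(**ev) for ev in self._state.setdefault("ledger", [])]

    @property
    def clock(self) -> datetime:
        return datetime.fromisoformat(self._state.get("clock", EPOCH.isoformat()))

    def _set_clock(self, value: datetime) -> None:
        self._state["clock"] = value.isoformat()

    def _tick(self, seconds: int = 60) -> datetime:
        now = self.clock + timedelta(seconds=seconds)
        self._set_clock(now)
        return now

    def save(self) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / STATE_FILE).write_text(
            json.dumps(self._state, indent=1, sort_keys=True) + "\n"
        )
        lines = [f"{md5}  {path}" for path, md5 in sorted(self.manifest.items())]
        (self.root / MANIFEST_FILE).write_text("\n".join(lines) + ("\n" if lines else ""))

    # -- events -----------------------------------------------------------

    def _record(self, serial: int, action: str, path: str, md5: Optional[str]) -> None:
        ts = self._tick().isoformat()
        self._state.setdefault("ledger", []).append(
            asdict(LedgerEvent(serial=serial, action=action, path=path, md5=md5, timestamp=ts))
        )

    def _write_file(self, path: str, data: bytes) -> str:
        target = self.root / path
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        digest = md5_hex(data)
        self.manifest[path] = digest
        return digest

    # -- public surface ---------------------------------------------------

    def fetch(self, path: str) -> bytes:
        """Read a remote file's bytes, honouring pending fault injections."""
        if path not in self.manifest:
            raise RemoteError(f"unknown remote path: {path!r}")
        data = (self.root / path).read_bytes()
        pending = self.faults.get(path, 0)
        if pending > 0:
            self.faults[path] = pending - 1
            if self.faults[path] == 0:
                del self.faults[path]
            self.save()
            return data + b"\x00<truncated-transfer>"
        return data

    def file_meta(self, path: str) -> dict:
        if path not in self.files:
            raise RemoteError(f"unknown remote path: {path!r}")
        return dict(self.files[path])

    def changes_files(self) -> List[str]:
        """Per-serial change-list paths, in serial order (serials >= 2)."""
        out = []
        for serial in range(2, self.serials["dcc"] + 1):
            out.append(f"dcc/{CHANGES_BASENAME}.{serial}.txt")
        return out

    def read_changes(self, serial: int) -> str:
        path = self.root / "dcc" / f"{CHANGES_BASENAME}.{serial}.txt"
        if not path.exists():
            raise RemoteError(f"no change list for serial {serial}")
        return path.read_text()


def _participant_universe(spec: RemoteSpec, rng: random.Random, vocab: Vocabulary) -> List[dict]:
    tss_codes = sorted(vocab.tissue_source_site)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    participants = []
    seen = set()
    for _ in range(spec.n_participants):
        while True:
            pid = "".join(rng.choice(alphabet) for _ in range(4))
            if pid not in seen:
                seen.add(pid)
                break
        tss = rng.choice(tss_codes)
        plate = "".join(rng.choice(alphabet) for _ in range(4))
        participants.append(
            {
                "tss": tss,
                "tss_name": vocab.tissue_source_site[tss],
                "participant": pid,
                "plate": plate,
                "disease": rng.choice(sorted(spec.diseases)),
            }
        )
    return participants


def _analyte_for(ext: str) -> str:
    return {"vcf": "D", "maf": "D", "bam": "D"}.get(ext, "R")


def _aliquot_barcode(p: dict, ext: str) -> str:
    return (
        f"TCGA-{p['tss']}-{p['participant']}-01A-11{_analyte_for(ext)}-{p['plate']}-01"
    )


def _make_meta(
    dt: Datatype, participant: dict, level: str, ext: str, portion_name: Optional[str],
    index: int, rng: random.Random,
) -> dict:
    disease = participant["disease"]
    barcode = _aliquot_barcode(participant, ext)
    center_code = "01"
    center_name = "broad_mit_edu"
    experiment_id = f"{dt.code}_{disease}_L{level}"
    analysis_uuid = str(uuid_mod.UUID(int=rng.getrandbits(128)))
    meta = {
        "datatype": dt.code,
        "store": dt.source,
        "level": level,
        "extension": ext,
        "barcode": barcode,
        "uuid": analysis_uuid,
        "disease": disease,
        "tss_name": participant["tss_name"],
        "center_code": center_code,
        "center_name": center_name,
        "platform": dt.platform,
        "access": dt.access,
        "experiment_id": experiment_id,
        "analysis_revision": 1,
        "tcga_revision": 1,
        "ref_genome": _REF_GENOME.get(ext),
        "ref_genome_source": "NCBI" if ext in _REF_GENOME else None,
        "algorithm_name": _ALGORITHMS.get(ext, (None, None))[0],
        "algorithm_version": _ALGORITHMS.get(ext, (None, None))[1],
        "portion_name": portion_name,
        "portion_number": index,
    }
    stem = barcode if portion_name is None else f"{barcode}.{portion_name}"
    if dt.source == "dcc":
        archive = f"{center_name}_{disease}.{dt.platform}.Level_{level}"
        meta["path"] = f"dcc/{archive}/{stem}.{index}.{ext}"
        meta["archive_name"] = archive
    elif dt.source == "bamstore":
        meta["path"] = f"bamstore/{analysis_uuid}/{analysis_uuid}.{ext}"
        meta["archive_name"] = "bamstore"
        # alignments are identified by analysis UUID, not by archive batch
        meta["experiment_id"] = analysis_uuid
    elif dt.source == "level4store":
        archive = f"{dt.platform}_{disease}.Level_4"
        meta["path"] = f"level4store/{archive}/{stem}.L4.{index}.{ext}"
        meta["archive_name"] = archive
    else:  # msstore
        meta["path"] = f"msstore/{disease}/{stem}_run{index}.{ext}"
        meta["archive_name"] = "msstore"
    return meta


def _content_rng(seed: int, path: str, serial: int) -> random.Random:
    key = hashlib.sha256(f"{seed}|{path}|{serial}".encode()).digest()
    return random.Random(int.from_bytes(key[:8], "big"))


def _create_file(state: RemoteState, meta: dict, serial: int, spec_seed: int) -> None:
    rng = _content_rng(spec_seed, meta["path"], serial)
    data = _payload(rng, meta["extension"], meta["datatype"], meta["barcode"], meta)
    digest = state._write_file(meta["path"], data)
    state._record(serial, ADDED, meta["path"], digest)
    meta["mtime"] = state.clock.isoformat()
    state.files[meta["path"]] = meta


def generate_remote(spec: RemoteSpec, root: "Path | str") -> RemoteState:
    """Materialize a fresh remote tree at serial 1 with a complete ledger."""
    root = Path(root)
    if (root / STATE_FILE).exists():
        raise RemoteError(f"remote already exists at {root}")
    state = RemoteState(root)
    state._state = {
        "spec": {
            "n_participants": spec.n_participants,
            "datatypes": list(spec.datatypes),
            "files_per_sample": spec.files_per_sample,
            "seed": spec.seed,
            "diseases": list(spec.diseases),
        },
        "serials": {"dcc": 1, "level4store": 1},
        "clock": EPOCH.isoformat(),
        "manifest": {},
        "files": {},
        "faults": {},
        "ledger": [],
    }
    rng = random.Random(spec.seed)
    vocab = Vocabulary.load_default()
    participants = _participant_universe(spec, rng, vocab)
    state._state["participants"] = participants

    for participant in participants:
        for code in spec.datatypes:
            dt = get_datatype(code)
            for level, ext in sorted(dt.levels.items()):
                portions = dt.portion_names if ext == "idat" else (None,)
                for portion_name in portions:
                    for j in range(1, spec.files_per_sample + 1):
                        meta = _make_meta(dt, participant, level, ext, portion_name, j, rng)
                        _create_file(state, meta, serial=1, spec_seed=spec.seed)

    # uuid -> barcode ground truth, used by the barcode/UUID validation check
    uuid_rows = sorted(
        (m["uuid"], m["barcode"]) for m in state.files.values()
    )
    lines = ["uuid\tbarcode"] + [f"{u}\t{b}" for u, b in uuid_rows]
    root.mkdir(parents=True, exist_ok=True)
    (root / "uuid_map.tsv").write_text("\n".join(lines) + "\n")

    state.save()
    return state


def _existing_of_datatype(state: RemoteState, code: str) -> List[str]:
    return sorted(p for p, m in state.files.items() if m["datatype"] == code)


def advance_release(state: RemoteState, mut: MutationSpec) -> RemoteState:
    """Apply a mutation batch as one new release.

    Serials increment, the synthetic clock advances a day, mutated files
    are written, and the DCC change list for the new serial is emitted
    (``ACTION\\tpath`` records under a ``# serial=<n>`` header).
    """
    for code in list(mut.adds) + list(mut.modifies) + list(mut.deletes):
        if code not in DATATYPES:
            raise RemoteError(f"unknown datatype code: {code!r}")
    for code, count in {**mut.modifies}.items():
        if count > len(_existing_of_datatype(state, code)):
            raise RemoteError(f"cannot modify {count} {code} files; fewer exist")
    for code, count in {**mut.deletes}.items():
        if count + mut.modifies.get(code, 0) > len(_existing_of_datatype(state, code)):
            raise RemoteError(f"cannot delete {count} {code} files; fewer remain")

    spec = state._state["spec"]
    serial = state.serials["dcc"] + 1
    state.serials["dcc"] = serial
    state.serials["level4store"] += 1
    state._set_clock(state.clock + timedelta(days=1))

    key = hashlib.sha256(f"{spec['seed']}|release|{serial}|{mut.seed}".encode()).digest()
    rng = random.Random(int.from_bytes(key[:8], "big"))
    changed: List[tuple[str, str]] = []  # (ACTION, path) for dcc change list
    touched: set[str] = set()  # paths mutated this release; each path gets one verb

    # deletions and modifications draw from disjoint existing-path pools
    for code in sorted(set(mut.modifies) | set(mut.deletes)):
        pool = _existing_of_datatype(state, code)
        n_mod = mut.modifies.get(code, 0)
        n_del = mut.deletes.get(code, 0)
        picked = rng.sample(pool, n_mod + n_del)
        for path in picked[:n_mod]:
            meta = state.files[path]
            content_rng = _content_rng(spec["seed"], path, serial)
            data = _payload(content_rng, meta["extension"], meta["datatype"], meta["barcode"], meta)
            digest = state._write_file(path, data)
            meta["mtime"] = state.clock.isoformat()
            meta["tcga_revision"] = meta.get("tcga_revision", 1) + 1
            state._record(serial, MODIFIED, path, digest)
            touched.add(path)
            if meta["store"] == "dcc":
                changed.append(("MODIFIED", path))
        for path in picked[n_mod:]:
            meta = state.files.pop(path)
            (state.root / path).unlink()
            del state.manifest[path]
            state._record(serial, DELETED, path, None)
            touched.add(path)
            if meta["store"] == "dcc":
                changed.append(("DELETED", path))

    # additions: a new file index for a deterministically chosen sample
    participants = state._state.get("participants", [])
    for code in sorted(mut.adds):
        n_add = mut.adds[code]
        if n_add and not participants:
            raise RemoteError("cannot add files to an empty participant universe")
        dt = get_datatype(code)
        for _ in range(n_add):
            participant = rng.choice(participants)
            level, ext = sorted(dt.levels.items())[rng.randrange(len(dt.levels))]
            portion_name = rng.choice(dt.portion_names) if ext == "idat" else None
            # next free index for this sample/datatype/level
            j = 1
            while True:
                meta = _make_meta(dt, participant, level, ext, portion_name, j, rng)
                if meta["path"] not in state.files and meta["path"] not in touched:
                    break
                j += 1
            _create_file(state, meta, serial=serial, spec_seed=spec["seed"])
            touched.add(meta["path"])
            if meta["store"] == "dcc":
                changed.append(("ADDED", meta["path"]))

    # DCC change list for this serial
    lines = [f"# serial={serial}"] + [f"{action}\t{path}" for action, path in changed]
    text = "\n".join(lines) + "\n"
    changes_dir = state.root / "dcc"
    changes_dir.mkdir(parents=True, exist_ok=True)
    (changes_dir / f"{CHANGES_BASENAME}.{serial}.txt").write_text(text)
    (changes_dir / f"{CHANGES_BASENAME}.txt").write_text(text)

    state.save()
    return state


def inject_fault(state: RemoteState, path: str, n_failures: int) -> RemoteState:
    """Make the next ``n_failures`` fetches of ``path`` deliver corrupt bytes."""
    if path not in state.manifest:
        raise RemoteError(f"unknown remote path: {path!r}")
    if n_failures < 0:
        raise RemoteError("n_failures must be >= 0")
    if n_failures:
        state.faults[path] = n_failures
    else:
        state.faults.pop(path, None)
    state.save()
    return state


def list_remote(state: RemoteState, store_name: str) -> List[tuple[str, str, str]]:
    """(path, serial-or-date, md5) for every current file of one store."""
    if store_name not in STORE_NAMES:
        raise RemoteError(f"unknown store: {store_name!r}")
    listing = []
    for path in sorted(state.files):
        meta = state.files[path]
        if meta["store"] != store_name:
            continue
        if store_name in ("dcc", "level4store"):
            stamp = str(state.serials[store_name])
        else:
            stamp = meta["mtime"]
        listing.append((path, stamp, state.manifest[path]))
    return listing
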