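"""The five data-validation routines, as pure checks with findings.

1. barcode <-> analysis-UUID agreement (with correction from the
   authoritative UUID map);
2. tissue-source-site name normalization against a curated mapping
   table covering alternative names, hyphens, misspellings and extra
   whitespace;
3. VCF chromosome/position sortedness;
4. MD5 checksum verification;
5. download-log audit for failed attempts needing retry.

Checks never raise on bad *data* — they return findings with a severity
(``ok``, ``corrected``, ``flagged`` or ``error``) so a sync run can
contain per-file problems instead of aborting.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from .vcf import VcfError, _record_chrom_pos, _split_lines

OK, CORRECTED, FLAGGED, ERROR = "ok", "corrected", "flagged", "error"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Finding:
    """One validation outcome for one (check, path) pair."""

    check: str
    path: str
    severity: str
    detail: str = ""
    corrected_value: Optional[str] = None


@dataclass
class ValidationReport:
    findings: List[Finding] = field(default_factory=list)

    def add(self, finding: Finding) -> None:
        self.findings.append(finding)

    @property
    def worst(self) -> str:
        order = {OK: 0, CORRECTED: 1, FLAGGED: 2, ERROR: 3}
        return max((f.severity for f in self.findings), key=order.__getitem__, default=OK)

    def to_lines(self) -> str:
        return "\n".join(
            "\t".join(
                (f.check, f.path, f.severity, f.detail, f.corrected_value or "")
            )
            for f in self.findings
        )


# -- (1) barcode <-> UUID ----------------------------------------------------


class UUIDMap:
    """Analysis UUID -> authoritative barcode, per entity kind."""

    def __init__(self, mapping: Dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_file(cls, path: "Path | str") -> "UUIDMap":
        mapping: Dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                uuid = row["uuid"]
                if uuid in mapping:
                    raise ValueError(f"duplicate UUID in map: {uuid}")
                mapping[uuid] = row["barcode"]
        return cls(mapping)


def check_barcode_uuid(file_meta: dict, uuid_map: UUIDMap) -> Finding:
    """Check that a file's barcode matches its analysis UUID's barcode.

    The UUID map is authoritative: a mismatch against a known UUID is
    *corrected* to the map's barcode; an unknown UUID is only flagged
    (identity is never invented).
    """
    path = file_meta.get("path", "")
    barcode = file_meta.get("barcode", "")
    uuid = file_meta.get("uuid", "")
    expected = uuid_map.mapping.get(uuid)
    if expected is None:
        return Finding("barcode_uuid", path, FLAGGED, f"UUID {uuid} not in map")
    if expected == barcode:
        return Finding("barcode_uuid", path, OK)
    return Finding(
        "barcode_uuid",
        path,
        CORRECTED,
        f"barcode {barcode} corrected to {expected} per UUID {uuid}",
        corrected_value=expected,
    )


# -- (2) tissue source site normalization -----------------------------------

_WS_RE = re.compile(r"\s+")


def _fold(name: str) -> str:
    """Trim, collapse whitespace, case-fold — applied before lookup."""
    return _WS_RE.sub(" ", name.strip()).casefold()


class TSSMappingTable:
    """raw name -> canonical tissue-source-site name."""

    def __init__(self, mapping: Dict[str, str]):
        # canonical names are fixpoints: ensure every canonical value maps
        # to itself under the folded lookup
        self._lookup: Dict[str, str] = {}
        for raw, canonical in mapping.items():
            self._lookup[_fold(raw)] = canonical
        for canonical in set(mapping.values()):
            self._lookup.setdefault(_fold(canonical), canonical)
        self.canonical_names = frozenset(self._lookup[k] for k in self._lookup)

    @classmethod
    def from_file(cls, path: "Path | str") -> "TSSMappingTable":
        mapping: Dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                mapping[row["raw_name"]] = row["canonical_name"]
        return cls(mapping)

    @classmethod
    def load_default(cls) -> "TSSMappingTable":
        from importlib import resources

        with resources.files("tcgasync.data").joinpath("tss_name_map.tsv").open(
            encoding="utf-8"
        ) as fh:
            mapping = {
                row["raw_name"]: row["canonical_name"]
                for row in csv.DictReader(fh, delimiter="\t")
            }
        return cls(mapping)


def normalize_tss(raw_name: str, table: TSSMappingTable) -> tuple[str, str]:
    """-> (canonical name or the input, ``ok``/``corrected``/``unmapped``)."""
    folded = _fold(raw_name)
    canonical = table._lookup.get(folded)
    if canonical is None:
        # second pass: treat hyphens as spaces (hyphenation variants)
        canonical = table._lookup.get(_fold(raw_name.replace("-", " ")))
    if canonical is None:
        return raw_name, UNMAPPED
    return canonical, OK if canonical == raw_name else CORRECTED


# -- (3) VCF sortedness ------------------------------------------------------


def check_vcf_sorted(vcf_text: str, path: str = "") -> Finding:
    """ok iff POS is numerically non-decreasing within every CHROM block."""
    try:
        meta, column, records = _split_lines(vcf_text)
    except VcfError as exc:
        return Finding("vcf_sorted", path, ERROR, str(exc))
    header_offset = len(meta) + (1 if column is not None else 0)
    last_pos: Dict[str, int] = {}
    open_chrom: Optional[str] = None
    seen: set[str] = set()
    for i, line in enumerate(records):
        try:
            chrom, pos = _record_chrom_pos(line, header_offset + i + 1)
        except VcfError as exc:
            return Finding("vcf_sorted", path, ERROR, str(exc))
        if chrom != open_chrom:
            if chrom in seen:  # chromosome block split in two
                return Finding(
                    "vcf_sorted", path, FLAGGED,
                    f"record {i + 1}: CHROM {chrom} re-opens an earlier block",
                )
            seen.add(chrom)
            open_chrom = chrom
        elif pos < last_pos[chrom]:
            return Finding(
                "vcf_sorted", path, FLAGGED,
                f"record {i + 1}: POS {pos} < {last_pos[chrom]} within CHROM {chrom}",
            )
        last_pos[chrom] = pos
    return Finding("vcf_sorted", path, OK)


# -- (4) checksums -----------------------------------------------------------


def verify_checksum(path: "Path | str", expected_md5: str) -> Finding:
    p = Path(path)
    if not p.exists():
        return Finding("checksum", str(path), ERROR, "file missing")
    digest = hashlib.md5(p.read_bytes()).hexdigest()
    if digest == expected_md5:
        return Finding("checksum", str(path), OK)
    return Finding("checksum", str(path), FLAGGED, f"md5 {digest} != expected {expected_md5}")


# -- (5) download-log audit --------------------------------------------------


def audit_download_log(log_text: str) -> List[str]:
    """Paths whose *latest* logged attempt failed, deduplicated, in order.

    The log is line-delimited JSON records with at least ``path`` and
    ``outcome`` (``success``/``failure``) fields, appended per attempt.
    """
    latest: Dict[str, str] = {}
    order: List[str] = []
    for lineno, line in enumerate(log_text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            entry = json.loads(line)
            path, outcome = entry["path"], entry["outcome"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"corrupt download-log line {lineno}: {exc}") from None
        if outcome not in ("success", "failure"):
            raise ValueError(f"corrupt download-log line {lineno}: outcome {outcome!r}")
        if path not in latest:
            order.append(path)
        latest[path] = outcome
    return [p for p in order if latest[p] == "failure"]
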