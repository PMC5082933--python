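"""VCF header harmonization, record sorting and sample splitting.

TCGA-era VCFs vary wildly between analysis centers: different header
content, different numbers of samples per file, different callers.  The
harmonizer rewrites every file to a common shape:

* a fixed-order required header block —
  ``fileformat, filedate, center, platform, genome_ref.name,
  genome_ref.url, patient_id, specimen_id`` —
  whose values are taken from the original header when present and
  filled from file metadata otherwise;
* every other original header line preserved, in order, after the
  required block;
* data records sorted by position *numerically* within each chromosome
  block (chromosome blocks keep their first-appearance order; ties keep
  input order).

All operations are pure text -> text, idempotent, and conserve the
record multiset.  Parsing is deliberately line-based: the contract is
byte-level preservation of lines the harmonizer does not own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

#: Required header keys, in the order they must appear.
REQUIRED_KEYS = (
    "fileformat",
    "filedate",
    "center",
    "platform",
    "genome_ref.name",
    "genome_ref.url",
    "patient_id",
    "specimen_id",
)

#: Accepted spellings in *input* headers for each required key.  Output
#: always uses the canonical spelling (dots legal in header keys).
_KEY_ALIASES = {
    "fileformat": ("fileformat",),
    "filedate": ("filedate", "fileDate"),
    "center": ("center",),
    "platform": ("platform",),
    "genome_ref.name": ("genome_ref.name", "reference"),
    "genome_ref.url": ("genome_ref.url",),
    "patient_id": ("patient_id",),
    "specimen_id": ("specimen_id",),
}

NO_SPLIT = "no_split"
SPLIT = "split"


class VcfError(ValueError):
    """Malformed VCF text."""


@dataclass
class HarmonizationMeta:
    """Metadata used to fill required header values missing from the source."""

    center: Optional[str] = None
    platform: Optional[str] = None
    patient_id: Optional[str] = None
    specimen_id: Optional[str] = None
    genome_ref_name: Optional[str] = None
    genome_ref_url: Optional[str] = None
    filedate: Optional[str] = None

    def value_for(self, key: str) -> Optional[str]:
        return {
            "filedate": self.filedate,
            "center": self.center,
            "platform": self.platform,
            "genome_ref.name": self.genome_ref_name,
            "genome_ref.url": self.genome_ref_url,
            "patient_id": self.patient_id,
            "specimen_id": self.specimen_id,
        }.get(key)


def _split_lines(vcf_text: str) -> tuple[list[str], Optional[str], list[str]]:
    """-> (meta header lines ``##``, column header line ``#CHROM``, records)."""
    meta: list[str] = []
    column: Optional[str] = None
    records: list[str] = []
    for lineno, line in enumerate(vcf_text.splitlines(), start=1):
        if line.startswith("##"):
            if records or column is not None:
                raise VcfError(f"line {lineno}: header line after records")
            meta.append(line)
        elif line.startswith("#"):
            if column is not None:
                raise VcfError(f"line {lineno}: duplicate column header")
            column = line
        elif line.strip():
            records.append(line)
    if not meta or not meta[0].startswith("##fileformat="):
        raise VcfError("missing ##fileformat header line")
    return meta, column, records


def _join(meta: Sequence[str], column: Optional[str], records: Sequence[str]) -> str:
    lines = list(meta)
    if column is not None:
        lines.append(column)
    lines.extend(records)
    return "\n".join(lines) + "\n"


def _header_key(line: str) -> Optional[str]:
    body = line[2:]
    if "=" not in body:
        return None
    return body.split("=", 1)[0]


def harmonize_header(vcf_text: str, meta: HarmonizationMeta) -> str:
    """Rewrite the header to the eight-key standard block.

    Required values come from the original header when present there
    (under any accepted spelling), otherwise from ``meta``.  All other
    original header lines follow the block unchanged and in order.
    Record lines are untouched.  Idempotent.
    """
    meta_lines, column, records = _split_lines(vcf_text)

    alias_to_key = {
        alias: key for key, aliases in _KEY_ALIASES.items() for alias in aliases
    }
    found: dict[str, str] = {}
    passthrough: list[str] = []
    for line in meta_lines:
        key = _header_key(line)
        canonical = alias_to_key.get(key) if key is not None else None
        if canonical is not None and canonical not in found:
            found[canonical] = line.split("=", 1)[1]
        else:
            passthrough.append(line)

    block: list[str] = []
    for key in REQUIRED_KEYS:
        value = found.get(key)
        if value is None:
            value = meta.value_for(key)
        if value is None:
            raise VcfError(
                f"required header value {key!r} present neither in the file nor in metadata"
            )
        block.append(f"##{key}={value}")
    return _join(block + passthrough, column, records)


def _record_chrom_pos(line: str, lineno: int) -> tuple[str, int]:
    fields = line.split("\t")
    if len(fields) < 2:
        raise VcfError(f"line {lineno}: record has fewer than 2 columns")
    chrom, pos = fields[0], fields[1]
    try:
        pos_i = int(pos)
    except ValueError:
        raise VcfError(f"line {lineno}: POS {pos!r} is not an integer") from None
    return chrom, pos_i


def sort_records(vcf_text: str) -> str:
    """Sort records numerically by POS within each CHROM block.

    Chromosome blocks keep the order of their first appearance in the
    input; the sort is stable, so records at equal (CHROM, POS) keep
    input order.  Header lines pass through untouched.
    """
    meta, column, records = _split_lines(vcf_text)
    first_seen: dict[str, int] = {}
    keyed = []
    header_offset = len(meta) + (1 if column is not None else 0)
    for i, line in enumerate(records):
        chrom, pos = _record_chrom_pos(line, header_offset + i + 1)
        if chrom not in first_seen:
            first_seen[chrom] = len(first_seen)
        keyed.append((first_seen[chrom], pos, i, line))
    keyed.sort(key=lambda t: (t[0], t[1], t[2]))
    return _join(meta, column, [t[3] for t in keyed])


def split_by_sample(vcf_text: str, policy: str = NO_SPLIT) -> List[str]:
    """Split a multi-sample VCF into one single-sample file per column.

    ``no_split`` returns the input unchanged as a singleton.  ``split``
    emits one VCF per sample column, each carrying the nine fixed
    columns plus that sample's genotype column; record count is
    conserved in every output.
    """
    if policy not in (SPLIT, NO_SPLIT):
        raise VcfError(f"unknown split policy: {policy!r}")
    if policy == NO_SPLIT:
        return [vcf_text]
    meta, column, records = _split_lines(vcf_text)
    if column is None:
        raise VcfError("cannot split: missing #CHROM column header")
    cols = column.split("\t")
    if len(cols) <= 9:
        raise VcfError("cannot split: file has no sample columns")
    fixed, samples = cols[:9], cols[9:]
    outputs = []
    for sample_idx in range(len(samples)):
        new_column = "\t".join(fixed + [samples[sample_idx]])
        new_records = []
        for lineno, line in enumerate(records, start=1):
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise VcfError(f"record {lineno}: column count differs from header")
            new_records.append("\t".join(fields[:9] + [fields[9 + sample_idx]]))
        outputs.append(_join(meta, new_column, new_records))
    return outputs


def merge_split(outputs: Iterable[str]) -> str:
    """Column-wise inverse of ``split_by_sample`` (used for round-trip checks)."""
    parsed = [_split_lines(t) for t in outputs]
    if not parsed:
        raise VcfError("nothing to merge")
    meta, column0, records0 = parsed[0]
    fixed = column0.split("\t")[:9]
    samples = [p[1].split("\t")[9] for p in parsed]
    merged_records = []
    for rows in zip(*(p[2] for p in parsed)):
        base = rows[0].split("\t")[:9]
        merged_records.append("\t".join(base + [r.split("\t")[9] for r in rows]))
    return _join(meta, "\t".join(fixed + samples), merged_records)


def record_multiset(vcf_text: str) -> dict[tuple[str, int, str, str], int]:
    """Multiset of (CHROM, POS, REF, ALT) — the conservation invariant."""
    _, _, records = _split_lines(vcf_text)
    counts: dict[tuple[str, int, str, str], int] = {}
    for line in records:
        f = line.split("\t")
        key = (f[0], int(f[1]), f[3] if len(f) > 3 else "", f[4] if len(f) > 4 else "")
        counts[key] = counts.get(key, 0) + 1
    return counts
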