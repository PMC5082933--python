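"""Repository file-name grammar and directory layout.

Repository file names extend the TCGA barcode with the metadata a user
needs to subset files without opening them.  The thirteen metadata
components, in order, are::

    (1) TCGA barcode            (hyphen-delimited, dot-free)
    (2) access type             public | controlled
    (3) disease study           e.g. BRCA
    (4) analysis center         e.g. broad_mit_edu
    (5) analysis platform       e.g. IlluminaGA_DNASeq
    (6) data level              0-4
    (7) experiment id           from the source archive name
    (8) analysis revision       integer
    (9) source revision         integer ("bulk" discriminator, opaque)
    (10) reference genome       optional label, e.g. hg19
    (11) portion name           optional, e.g. red / grn for idat pairs
    (12) portion number         integer, default 1
    (13) repository version     integer >= 1, bumped on content change

followed by the file extension.  Components are joined with ``.``;
hyphens appear only inside the barcode, so a single dot-split recovers
every component.  Values are sanitized (dots and whitespace become
``_``) before joining.

Optional components (10) and (11) are disambiguated by vocabulary:
portion names come from a small registered set (``red``/``grn``) and a
reference-genome label may not collide with it.  This keeps
``parse_file_name(build_file_name(f)) == f`` exact.

Files from non-DCC sources keep their original names; mass-spectrometry
files additionally gain a ``YYYYMMDD_`` analysis-date prefix because no
versioning exists at their source.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import PurePosixPath
from typing import Optional

from .barcode import Barcode, parse_barcode, render_barcode
from .vocab import PORTION_NAME_VOCAB, datatype_for_platform

DELIM = "."
ACCESS_VALUES = ("public", "controlled")

_SANITIZE_RE = re.compile(r"[.\s]+")


class NamingError(ValueError):
    """Invalid file-name fields or an unparseable repository file name."""


def sanitize_component(value: str) -> str:
    """Make a metadata value safe for the dot-joined grammar."""
    return _SANITIZE_RE.sub("_", value.strip())


@dataclass(frozen=True)
class FileNameFields:
    """The metadata components of one repository file name."""

    barcode: Barcode
    access: str
    disease: str
    center_name: str
    platform: str
    level: str
    experiment_id: str
    analysis_revision: int
    tcga_revision: int
    ref_genome: Optional[str] = None
    portion_name: Optional[str] = None
    portion_number: int = 1
    repo_version: int = 1
    extension: str = "txt"

    def validate(self) -> None:
        mandatory = {
            "access": self.access,
            "disease": self.disease,
            "center_name": self.center_name,
            "platform": self.platform,
            "level": self.level,
            "experiment_id": self.experiment_id,
            "extension": self.extension,
        }
        for name, value in mandatory.items():
            if not value:
                raise NamingError(f"missing mandatory field: {name}")
        if self.access not in ACCESS_VALUES:
            raise NamingError(f"access must be one of {ACCESS_VALUES}, got {self.access!r}")
        if self.repo_version < 1:
            raise NamingError(f"repo_version must be >= 1, got {self.repo_version}")
        if self.portion_number < 1:
            raise NamingError(f"portion_number must be >= 1, got {self.portion_number}")
        if self.analysis_revision < 0 or self.tcga_revision < 0:
            raise NamingError("revision numbers must be non-negative")
        if self.portion_name is not None and self.portion_name not in PORTION_NAME_VOCAB:
            raise NamingError(
                f"portion_name {self.portion_name!r} not in the registered vocabulary "
                f"{sorted(PORTION_NAME_VOCAB)}"
            )
        if self.ref_genome is not None and self.ref_genome in PORTION_NAME_VOCAB:
            raise NamingError(
                f"ref_genome {self.ref_genome!r} collides with the portion-name vocabulary"
            )
        for name in (
            "access",
            "disease",
            "center_name",
            "platform",
            "level",
            "experiment_id",
            "ref_genome",
            "portion_name",
            "extension",
        ):
            value = getattr(self, name)
            if value is not None and sanitize_component(value) != value:
                raise NamingError(
                    f"field {name}={value!r} contains the naming delimiter or whitespace; "
                    f"sanitize it first"
                )

    @property
    def datatype(self) -> str:
        """Datatype code recovered from the platform label."""
        return datatype_for_platform(self.platform)

    def with_version(self, version: int) -> "FileNameFields":
        return replace(self, repo_version=version)

    @property
    def logical_key(self) -> tuple:
        """Identity under which repository versions increment."""
        return (
            self.datatype,
            render_barcode(self.barcode),
            self.level,
            self.experiment_id,
            self.portion_name or "",
            self.portion_number,
        )


def build_file_name(f: FileNameFields) -> str:
    """Render the dot-joined repository file name for ``f``."""
    f.validate()
    parts = [
        render_barcode(f.barcode),
        f.access,
        f.disease,
        f.center_name,
        f.platform,
        f.level,
        f.experiment_id,
        str(f.analysis_revision),
        str(f.tcga_revision),
    ]
    if f.ref_genome is not None:
        parts.append(f.ref_genome)
    if f.portion_name is not None:
        parts.append(f.portion_name)
    parts.append(str(f.portion_number))
    parts.append(str(f.repo_version))
    parts.append(f.extension)
    return DELIM.join(parts)


def _to_int(token: str, what: str, name: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise NamingError(f"file name {name!r}: {what} component {token!r} is not an integer")


def parse_file_name(text: str) -> FileNameFields:
    """Inverse of :func:`build_file_name`."""
    tokens = text.split(DELIM)
    if len(tokens) < 12 or len(tokens) > 14:
        raise NamingError(
            f"file name {text!r}: expected 12-14 dot-joined components, got {len(tokens)}"
        )
    barcode = parse_barcode(tokens[0])
    head = tokens[1:9]  # components (2)-(9)
    middle = tokens[9:-3]  # 0-2 optional components
    tail = tokens[-3:]  # portion number, repo version, extension

    ref_genome: Optional[str] = None
    portion_name: Optional[str] = None
    if len(middle) == 2:
        ref_genome, portion_name = middle
    elif len(middle) == 1:
        if middle[0] in PORTION_NAME_VOCAB:
            portion_name = middle[0]
        else:
            ref_genome = middle[0]
    if portion_name is not None and portion_name not in PORTION_NAME_VOCAB:
        raise NamingError(f"file name {text!r}: unknown portion name {portion_name!r}")

    fields = FileNameFields(
        barcode=barcode,
        access=head[0],
        disease=head[1],
        center_name=head[2],
        platform=head[3],
        level=head[4],
        experiment_id=head[5],
        analysis_revision=_to_int(head[6], "analysis revision", text),
        tcga_revision=_to_int(head[7], "source revision", text),
        ref_genome=ref_genome,
        portion_name=portion_name,
        portion_number=_to_int(tail[0], "portion number", text),
        repo_version=_to_int(tail[1], "repository version", text),
        extension=tail[2],
    )
    try:
        fields.validate()
    except NamingError as exc:
        raise NamingError(f"file name {text!r}: {exc}") from None
    return fields


@dataclass(frozen=True)
class RepoPath:
    """Participant/sample-oriented directory location of one file."""

    disease: str
    participant: str
    sample: str
    datatype: str
    level: str

    @property
    def relative(self) -> str:
        return str(
            PurePosixPath(self.disease)
            / self.participant
            / self.sample
            / self.datatype
            / f"Level_{self.level}"
        )

    def __str__(self) -> str:
        return self.relative


def build_directory_path(f: FileNameFields) -> RepoPath:
    """Directory for ``f``: ``<disease>/<participant>/<sample>/<datatype>/<level>/``.

    A barcode truncated above sample depth (e.g. clinical data keyed to
    the participant) reuses the participant barcode as the sample
    segment so the hierarchy stays uniform.
    """
    f.validate()
    participant = render_barcode(f.barcode.participant_barcode)
    if f.barcode.sample_type is not None:
        sample = render_barcode(f.barcode.sample_barcode)
    else:
        sample = participant
    return RepoPath(
        disease=f.disease,
        participant=participant,
        sample=sample,
        datatype=f.datatype,
        level=f.level,
    )


_MS_PREFIX_RE = re.compile(r"^\d{8}_")


def ms_file_name(original_name: str, analysis_date: "str | date | datetime") -> str:
    """Prefix a mass-spectrometry file name with its analysis date."""
    if isinstance(analysis_date, str):
        analysis_date = date.fromisoformat(analysis_date[:10])
    elif isinstance(analysis_date, datetime):
        analysis_date = analysis_date.date()
    return f"{analysis_date.strftime('%Y%m%d')}_{original_name}"


def ms_original_name(named: str) -> str:
    """Strip the analysis-date prefix, recovering the original name."""
    return _MS_PREFIX_RE.sub("", named, count=1)
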