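"""TCGA barcode parsing and rendering.

A TCGA barcode is a hyphen-delimited, hierarchical sample identifier::

    TCGA-A1-A0SB-01A-11D-A141-01
    ^    ^  ^    ^ ^  ^ ^  ^    ^
    |    |  |    | |  | |  |    +- center (2 digits)
    |    |  |    | |  | |  +------ plate (4 alphanumerics)
    |    |  |    | |  | +--------- analyte (1 letter, fused to portion)
    |    |  |    | |  +----------- portion (2 digits)
    |    |  |    | +-------------- vial (1 letter, fused to sample type)
    |    |  |    +---------------- sample type (2 digits)
    |    |  +--------------------- participant (alphanumeric id)
    |    +------------------------ tissue source site (2 alphanumerics)
    +----------------------------- project literal

Barcodes truncate only from the right: participant depth (3 segments),
sample depth (4), portion depth (5), plate depth (6), full aliquot depth
(7).  ``parse`` and ``render`` are exact inverses on every valid
truncation depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

PROJECT = "TCGA"

# One regex, one place. Optional trailing groups encode right-truncation.
_BARCODE_RE = re.compile(
    r"""^
    (?P<project>TCGA)
    -(?P<tss>[A-Z0-9]{2})
    -(?P<participant>[A-Z0-9]{4})
    (?:-(?P<sample_type>\d{2})(?P<vial>[A-Z])?
      (?:-(?P<portion>\d{2})(?P<analyte>[A-Z])?
        (?:-(?P<plate>[A-Z0-9]{4})
          (?:-(?P<center>\d{2}))?
        )?
      )?
    )?
    $""",
    re.VERBOSE,
)

_SEGMENT_NAMES = (
    "project literal",
    "tissue source site",
    "participant",
    "sample type/vial",
    "portion/analyte",
    "plate",
    "center",
)

_SEGMENT_RES = (
    re.compile(r"^TCGA$"),
    re.compile(r"^[A-Z0-9]{2}$"),
    re.compile(r"^[A-Z0-9]{4}$"),
    re.compile(r"^\d{2}[A-Z]?$"),
    re.compile(r"^\d{2}[A-Z]?$"),
    re.compile(r"^[A-Z0-9]{4}$"),
    re.compile(r"^\d{2}$"),
)


class BarcodeError(ValueError):
    """A barcode string that does not follow the published convention."""


@dataclass(frozen=True)
class Barcode:
    """A parsed TCGA barcode, populated to its truncation depth."""

    tss: str
    participant: str
    sample_type: Optional[str] = None
    vial: Optional[str] = None
    portion: Optional[str] = None
    analyte: Optional[str] = None
    plate: Optional[str] = None
    center: Optional[str] = None
    project: str = PROJECT

    @property
    def depth(self) -> int:
        """Number of hyphen-delimited segments when rendered."""
        for n, present in (
            (7, self.center),
            (6, self.plate),
            (5, self.portion),
            (4, self.sample_type),
        ):
            if present is not None:
                return n
        return 3

    @property
    def participant_barcode(self) -> "Barcode":
        """This barcode truncated to participant depth."""
        return Barcode(tss=self.tss, participant=self.participant)

    @property
    def sample_barcode(self) -> "Barcode":
        """This barcode truncated to sample depth (type + vial)."""
        if self.sample_type is None:
            raise BarcodeError("barcode has no sample segment")
        return Barcode(
            tss=self.tss,
            participant=self.participant,
            sample_type=self.sample_type,
            vial=self.vial,
        )

    def render(self) -> str:
        return render_barcode(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_barcode(text: str) -> Barcode:
    """Parse a barcode string, naming the offending segment on failure."""
    if not text:
        raise BarcodeError("empty barcode")
    m = _BARCODE_RE.match(text)
    if m is None:
        # Locate the first bad segment for the error message.
        segments = text.split("-")
        if len(segments) < 3 or len(segments) > 7:
            raise BarcodeError(
                f"barcode {text!r}: expected 3-7 hyphen-delimited segments, got {len(segments)}"
            )
        for seg, name, rx in zip(segments, _SEGMENT_NAMES, _SEGMENT_RES):
            if not rx.match(seg):
                raise BarcodeError(f"barcode {text!r}: bad {name} segment {seg!r}")
        raise BarcodeError(f"barcode {text!r} does not match the TCGA convention")
    g = m.groupdict()
    # Hierarchy check: deeper groups require the shallower ones (the regex
    # nesting guarantees this; keep the contract explicit).
    return Barcode(
        tss=g["tss"],
        participant=g["participant"],
        sample_type=g["sample_type"],
        vial=g["vial"],
        portion=g["portion"],
        analyte=g["analyte"],
        plate=g["plate"],
        center=g["center"],
    )


def render_barcode(b: Barcode) -> str:
    """Render to canonical hyphen-joined text; inverse of :func:`parse_barcode`."""
    parts = [b.project, b.tss, b.participant]
    if b.sample_type is not None:
        parts.append(b.sample_type + (b.vial or ""))
        if b.portion is not None:
            parts.append(b.portion + (b.analyte or ""))
            if b.plate is not None:
                parts.append(b.plate)
                if b.center is not None:
                    parts.append(b.center)
    return "-".join(parts)


def truncate(b: Barcode, depth: int) -> Barcode:
    """Right-truncate a barcode to ``depth`` segments (3-7)."""
    if depth < 3 or depth > 7:
        raise BarcodeError(f"depth must be 3-7, got {depth}")
    out = b
    if depth < 7:
        out = replace(out, center=None)
    if depth < 6:
        out = replace(out, plate=None)
    if depth < 5:
        out = replace(out, portion=None, analyte=None)
    if depth < 4:
        out = replace(out, sample_type=None, vial=None)
    return out
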