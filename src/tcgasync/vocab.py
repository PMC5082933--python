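"""Datatype registry and controlled vocabularies.

The registry enumerates the managed TCGA datatype codes, the source
datastore each one is pulled from, the data levels it is delivered at,
and the file type per level.  Four source stores exist:

``dcc``
    Serial-numbered archives with per-release change lists and an MD5
    manifest (the Data Coordinating Center dialect).
``bamstore``
    Sequence-alignment stubs keyed by analysis UUID and last-modified
    date (the cgHub dialect).
``level4store``
    Summarized (level 4) copy-number bundles, serial-numbered.
``msstore``
    Dated mass-spectrometry deliveries; files keep their original names
    and gain an analysis-date prefix on ingest.

Each registry code carries a distinct platform label so the datatype can
be recovered from a repository file name (which embeds the platform but
not the datatype code).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

STORE_NAMES = ("dcc", "bamstore", "level4store", "msstore")

#: VCF sample-splitting policies a datatype may declare.
SPLIT = "split"
NO_SPLIT = "no_split"


@dataclass(frozen=True)
class Datatype:
    """One managed datatype: where it lives and what it ships."""

    code: str
    source: str  # one of STORE_NAMES
    levels: Mapping[str, str]  # level code -> file extension
    platform: str
    access: str = "public"  # public | controlled
    split_policy: str = NO_SPLIT
    portion_names: tuple[str, ...] = ()  # e.g. ("red", "grn") for idat

    def __post_init__(self) -> None:
        if self.source not in STORE_NAMES:
            raise ValueError(f"unknown source store: {self.source!r}")


def _dt(code, source, levels, platform, **kw) -> tuple[str, Datatype]:
    return code, Datatype(code, source, levels, platform, **kw)


#: The managed-datatype universe.  Level-4 copy number and mass
#: spectrometry are their own codes so each code routes to one store.
DATATYPES: dict[str, Datatype] = dict(
    [
        _dt("WGS_cgHub", "bamstore", {"1": "bam"}, "IlluminaHiSeq_WGS", access="controlled"),
        _dt("WXS_cgHub", "bamstore", {"1": "bam"}, "IlluminaHiSeq_WXS", access="controlled"),
        _dt(
            "Protected_Mutations",
            "dcc",
            {"2": "vcf"},
            "IlluminaGA_DNASeq_curated",
            access="controlled",
            split_policy=NO_SPLIT,
        ),
        _dt(
            "Protected_Mutations_MAF",
            "dcc",
            {"2": "maf"},
            "IlluminaGA_DNASeq_protected",
            access="controlled",
        ),
        _dt("Somatic_Mutations", "dcc", {"2": "maf"}, "IlluminaGA_DNASeq"),
        _dt("RNASeq_cgHub", "bamstore", {"1": "bam"}, "IlluminaHiSeq_RNASeq_aln", access="controlled"),
        _dt("RNASeq", "dcc", {"2": "vcf", "3": "txt"}, "IlluminaHiSeq_RNASeq", access="controlled"),
        _dt("RNASeqV2", "dcc", {"3": "txt"}, "IlluminaHiSeq_RNASeqV2"),
        _dt("CNV_CN_Array", "dcc", {"1": "txt", "2": "txt", "3": "txt"}, "HG-CGH-244A"),
        _dt("CNV_SNP_Array", "dcc", {"1": "txt", "2": "txt", "3": "txt"}, "Genome_Wide_SNP_6"),
        _dt("CNV_SNP_Array_Level4", "level4store", {"4": "txt"}, "GISTIC2"),
        _dt(
            "CNV_Low_Pass_DNASeq",
            "dcc",
            {"2": "vcf"},
            "IlluminaHiSeq_DNASeq_lowpass",
            access="controlled",
        ),
        _dt("Expression_Exon", "dcc", {"1": "txt", "2": "txt", "3": "txt"}, "HuEx-1_0-st-v2"),
        _dt("Expression_Gene", "dcc", {"1": "txt", "2": "txt", "3": "txt"}, "AgilentG4502A_07_3"),
        _dt("Expression_Protein", "dcc", {"1": "txt", "2": "txt", "3": "txt"}, "MDA_RPPA_Core"),
        _dt("Mass_Spectrometry", "msstore", {"4": "tsv"}, "LTQ_Orbitrap_Velos"),
        _dt("Bisulfite_Seq_cgHub", "bamstore", {"1": "bam"}, "IlluminaHiSeq_Bisulfite", access="controlled"),
        _dt(
            "DNA_Methylation",
            "dcc",
            {"1": "idat", "2": "txt", "3": "txt"},
            "HumanMethylation450",
            portion_names=("red", "grn"),
        ),
        _dt("miRNASeq_cgHub", "bamstore", {"1": "bam"}, "IlluminaHiSeq_miRNASeq_aln", access="controlled"),
        _dt("miRNASeq", "dcc", {"3": "txt"}, "IlluminaHiSeq_miRNASeq"),
        _dt("Fragment_Analysis_Result", "dcc", {"1": "txt"}, "ABI_3730"),
        _dt("Diagnostic_images", "dcc", {"1": "svs"}, "Aperio_diagnostic"),
        _dt("Tissue_images", "dcc", {"1": "svs"}, "Aperio_tissue"),
        _dt("Clinical", "dcc", {"2": "txt"}, "BCR_Biotab"),
    ]
)

#: platform label -> datatype code (platforms are unique in the registry).
PLATFORM_TO_DATATYPE: dict[str, str] = {dt.platform: dt.code for dt in DATATYPES.values()}

#: Portion-name vocabulary used to disambiguate optional file-name
#: components; a ref-genome label must never collide with these.
PORTION_NAME_VOCAB = frozenset(
    name for dt in DATATYPES.values() for name in dt.portion_names
)


def get_datatype(code: str) -> Datatype:
    try:
        return DATATYPES[code]
    except KeyError:
        raise KeyError(f"unknown datatype code: {code!r}") from None


def datatype_for_platform(platform: str) -> str:
    """Datatype code for a platform label; the label itself if unregistered."""
    return PLATFORM_TO_DATATYPE.get(platform, platform)


def _read_tsv(name: str) -> list[dict[str, str]]:
    with resources.files("tcgasync.data").joinpath(name).open(encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@dataclass
class Vocabulary:
    """Controlled vocabularies: code -> display name per table."""

    disease_study: dict[str, str] = field(default_factory=dict)
    tissue_source_site: dict[str, str] = field(default_factory=dict)
    center: dict[str, str] = field(default_factory=dict)
    sample_type: dict[str, str] = field(default_factory=dict)
    portion_analyte: dict[str, str] = field(default_factory=dict)

    TABLES = (
        "disease_study",
        "tissue_source_site",
        "center",
        "sample_type",
        "portion_analyte",
    )

    @classmethod
    def load_default(cls) -> "Vocabulary":
        v = cls()
        for table in cls.TABLES:
            rows = _read_tsv(f"{table}.tsv")
            mapping = getattr(v, table)
            for row in rows:
                code = row["code"]
                if code in mapping:
                    raise ValueError(f"duplicate code {code!r} in {table}")
                mapping[code] = row["name"]
        return v

    def resolve(self, table: str, code: str) -> str:
        if table not in self.TABLES:
            raise KeyError(f"unknown vocabulary table: {table!r}")
        mapping: dict[str, str] = getattr(self, table)
        if code not in mapping:
            raise KeyError(f"unknown {table} code: {code!r}")
        return mapping[code]
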