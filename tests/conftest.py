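"""Shared fixtures: synthetic remotes, toy VCFs, deterministic clocks."""

from __future__ import annotations

import random
from datetime import datetime, timedelta

import pytest

from tcgasync.mock_remote import RemoteSpec, generate_remote
from tcgasync.repository import Repository


SMALL_DATATYPES = (
    "Somatic_Mutations",
    "Protected_Mutations",
    "WGS_cgHub",
    "CNV_SNP_Array_Level4",
    "Mass_Spectrometry",
    "DNA_Methylation",
)


@pytest.fixture
def make_remote(tmp_path):
    """Factory for small synthetic remotes in per-test directories."""

    counter = {"n": 0}

    def _make(
        n_participants=2,
        datatypes=SMALL_DATATYPES,
        files_per_sample=1,
        seed=0,
        diseases=("BRCA", "GBM"),
    ):
        counter["n"] += 1
        root = tmp_path / f"remote{counter['n']}"
        spec = RemoteSpec(
            n_participants=n_participants,
            datatypes=tuple(datatypes),
            files_per_sample=files_per_sample,
            seed=seed,
            diseases=tuple(diseases),
        )
        return generate_remote(spec, root)

    return _make


class TickingClock:
    """Deterministic clock advancing a fixed step per call."""

    def __init__(self, start=datetime(2015, 1, 1), step_seconds=60):
        self.now = start
        self.step = timedelta(seconds=step_seconds)

    def __call__(self) -> datetime:
        self.now += self.step
        return self.now


@pytest.fixture
def make_repo(tmp_path):
    counter = {"n": 0}

    def _make(clock=None):
        counter["n"] += 1
        return Repository(tmp_path / f"repo{counter['n']}", clock=clock or TickingClock())

    return _make


def toy_vcf(records, header_extra=(), samples=("TCGA-AA-0001-01A",)):
    """Build a small VCF text from (chrom, pos) or full record tuples."""
    lines = ["##fileformat=VCFv4.1", *header_extra]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        if len(rec) == 2:
            chrom, pos = rec
            ref, alt = "A", "T"
        else:
            chrom, pos, ref, alt = rec
        cols = [str(chrom), str(pos), ".", ref, alt, "50", "PASS", "DP=10", "GT"]
        cols += ["0/1"] * len(samples)
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def random_toy_vcf(rng: random.Random, n_records=10, n_samples=1):
    samples = tuple(f"TCGA-AA-{i:04d}-01A" for i in range(n_samples))
    records = [
        (rng.choice(["1", "2", "10", "X"]), rng.randint(1, 10000)) for _ in range(n_records)
    ]
    return toy_vcf(records, samples=samples)
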