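"""Shared domain types and conventions for the stem-cell drift pipeline.

Coordinates are 0-based half-open throughout the library (BED convention);
VCF emission converts to 1-based on output only.  A genome is a plain ordered
mapping ``chrom -> length`` so the pipeline is build-agnostic: the bundled
:data:`GENOME_HG19` covers autosomes + X + Y, and tests use small toy genomes.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "GENOME_HG19",
    "GenomicInterval",
    "SampleMeta",
    "PipelineConfig",
    "interval_overlap",
    "load_genome",
    "write_genome",
]

#: hg19/b37-style chromosome lengths (bp), autosomes + X + Y.
GENOME_HG19: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` in base pairs.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def size_mb(self) -> float:
        """Interval size in Mb, rounded to 3 decimals (karyotype-report style)."""
        return round((self.end - self.start) / 1e6, 3)

    def validate(self, genome: Mapping[str, int]) -> None:
        """Check the interval lies on a declared chromosome."""
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome[self.chrom]}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return interval_overlap(self, other) > 0


def interval_overlap(
    a: GenomicInterval,
    b: GenomicInterval,
    genome: Mapping[str, int] | None = None,
) -> int:
    """Length (bp) of the intersection of two intervals; 0 when disjoint.

    When *genome* is given, both intervals are validated against it first
    and an unknown chromosome raises :class:`ValueError` naming it.
    """
    if genome is not None:
        a.validate(genome)
        b.validate(genome)
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced sample within a line's passage series.

    ``rank`` is the ordinal sampling position inside the line (1 = earliest
    tested sample); it is distinct from the absolute ``passage`` number.
    """

    line_id: str
    passage: int
    rank: int

    def __post_init__(self) -> None:
        if self.passage < 1:
            raise ValueError("passage must be a positive integer")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")

    @property
    def sample_id(self) -> str:
        return f"{self.line_id}_p{self.passage}"


def check_manifest_order(samples: list[SampleMeta]) -> None:
    """Within each line, rank must increase strictly with passage."""
    by_line: dict[str, list[SampleMeta]] = {}
    for s in samples:
        by_line.setdefault(s.line_id, []).append(s)
    for line_id, group in by_line.items():
        group = sorted(group, key=lambda s: s.rank)
        for prev, cur in zip(group, group[1:]):
            if cur.passage <= prev.passage or cur.rank <= prev.rank:
                raise ValueError(
                    f"line {line_id}: rank must increase strictly with passage "
                    f"(rank {prev.rank} passage {prev.passage} vs "
                    f"rank {cur.rank} passage {cur.passage})"
                )


@dataclass
class PipelineConfig:
    """Thresholds for the variant-retention cascade and the CNV caller.

    Defaults mirror the validated clinical-panel settings this pipeline
    models: 50 kb coverage bins, a 1% population-frequency cutoff, a 3%
    allele-fraction floor for non-hotspot calls, >=25 supporting reads,
    removal of facility-recurrent artifacts above 0.01%, exclusion of
    CDC27 (pseudogene-prone), ~1500x panel depth and ~0.1x shallow WGS.
    """

    bin_size: int = 50_000
    pop_freq_max: float = 0.01
    min_af_nonhotspot: float = 0.03
    min_alt_reads: int = 25
    recurrence_max: float = 0.0001
    excluded_genes: list[str] = field(default_factory=lambda: ["CDC27"])
    panel_depth: int = 1500
    shallow_coverage: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("bin_size", "min_alt_reads", "panel_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("pop_freq_max", "min_af_nonhotspot", "recurrence_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.shallow_coverage <= 0:
            raise ValueError("shallow_coverage must be strictly positive")

    def to_yaml(self, path: str | os.PathLike | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | os.PathLike) -> "PipelineConfig":
        """Load from a YAML file path or a YAML string."""
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(io.StringIO(str(source)))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_genome(path: str | os.PathLike) -> dict[str, int]:
    """Read a genome dictionary from a two-column TSV (chrom, length)."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            chrom, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}:{ln}: non-positive length for {chrom}")
            genome[chrom] = length
    if not genome:
        raise ValueError(f"{path}: empty genome file")
    return genome


def write_genome(genome: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
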