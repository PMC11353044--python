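"""Shared fixtures: toy genomes, constructed filter records, injected histories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stemdrift.cnv import BinnedCoverage
from stemdrift.core import GENOME_HG19, GenomicInterval  # noqa: F401
from stemdrift.sim import Clone, CultureHistory, MutationEvent, SimParams
from stemdrift.snv import VariantCall


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, int]:
    """Two autosomes, 1000 50kb bins total — big enough for a GC fit."""
    return {"chr1": 30_000_000, "chr2": 20_000_000}


@pytest.fixture(scope="session")
def hg19() -> dict[str, int]:
    return GENOME_HG19


def make_coverage(genome: dict[str, int], counts: np.ndarray,
                  gc: np.ndarray, sample_id: str = "s1",
                  bin_size: int = 50_000,
                  blacklisted: np.ndarray | None = None) -> BinnedCoverage:
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_size)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + bin_size, length),
        }))
    bins = pd.concat(rows, ignore_index=True)
    bins["gc"] = np.asarray(gc, dtype=float)
    bins["count"] = np.asarray(counts)
    bins["blacklisted"] = (np.zeros(len(bins), dtype=bool)
                           if blacklisted is None else blacklisted)
    return BinnedCoverage(sample_id, bins)


def n_bins(genome: dict[str, int], bin_size: int = 50_000) -> int:
    return sum(-(-length // bin_size) for length in genome.values())


def single_clone_history(
    event: MutationEvent | None,
    genome: dict[str, int],
    line_id: str = "inj",
    germline: list | None = None,
    fraction: float = 1.0,
) -> CultureHistory:
    """One-passage history: a mutant clone at *fraction*, rest wild-type."""
    clones = {0: Clone(0, None, None)}
    frac0 = {0: 1.0}
    if event is None:
        frac1 = {0: 1.0}
        log = []
    else:
        clones[1] = Clone(1, 0, event, fitness=1.0 + event.fitness_advantage)
        frac1 = ({1: 1.0} if fraction >= 1.0
                 else {0: 1.0 - fraction, 1: fraction})
        log = [(1, 1, event)]
    return CultureHistory(
        line_id=line_id, genome=genome, params=SimParams(seed=0),
        germline=germline or [], clones=clones,
        fractions=[frac0, frac1], event_log=log,
    )


def _call(sample_id="s1", gene="TP53", chrom="chr17", pos=7_577_121,
          ref="C", alt="T", af=0.5, alt_reads=750, depth=1500,
          pop=0.0, hotspot=False, recurrence=0.0, effect="missense",
          deleterious=False, cosmic="none") -> VariantCall:
    return VariantCall(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
        alt=alt, af=af, alt_reads=alt_reads, depth=depth,
        pop_freq={"gnomad": pop, "1000g": 0.0, "esp6500": 0.0},
        effect=effect, deleterious=deleterious, cosmic=cosmic,
        hotspot=hotspot, recurrence_freq=recurrence,
    )


@pytest.fixture()
def filter_fixture() -> list[VariantCall]:
    """Ten engineered records: exactly 4 retained.

    Expected per-rule removal tallies: R1:2, R2:2, R3:1, R4:1, R5:1, with
    one record (common polymorphism at low AF) failing two rules at once.
    """
    return [
        # fails R1 only: common in gnomAD
        _call(gene="EGFR", chrom="chr7", pos=55_259_515, pop=0.02),
        # fails R1 + R2: common AND low-AF non-hotspot
        _call(gene="KRAS", chrom="chr12", pos=25_398_284, pop=0.05,
              af=0.02, alt_reads=30),
        # fails R2 only: low-AF non-hotspot
        _call(gene="PTEN", chrom="chr10", pos=89_692_905, af=0.02,
              alt_reads=30),
        # fails R3 only: facility-recurrent artifact
        _call(gene="APC", chrom="chr5", pos=112_175_240, recurrence=2e-4),
        # fails R4 only: 24 alt reads (hotspot, so R2 does not bite)
        _call(gene="BRAF", chrom="chr7", pos=140_453_136, af=0.016,
              alt_reads=24, hotspot=True),
        # fails R5 only: excluded pseudogene-prone gene
        _call(gene="CDC27", chrom="chr17", pos=45_214_556),
        # retained: ordinary heterozygous call
        _call(gene="TP53", chrom="chr17", pos=7_577_121),
        # retained: hotspot below the non-hotspot AF floor
        _call(gene="PIK3CA", chrom="chr3", pos=178_936_091, af=0.02,
              alt_reads=30, hotspot=True),
        # retained: homozygous call
        _call(gene="RB1", chrom="chr13", pos=48_941_648, af=0.98,
              alt_reads=1470),
        # retained: low-ish AF but above every threshold
        _call(gene="ATM", chrom="chr11", pos=108_098_576, af=0.05,
              alt_reads=75),
    ]
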