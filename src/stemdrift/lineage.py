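"""Temporal classification of variants within a line's passage series.

A variant detected at the earliest tested sample of a line is taken to be
germline; a variant first appearing at a later rank is de novo, acquired in
culture.  The classification is per line and per variant key; it is exact
whenever the first sampled passage precedes every somatic event, and can
only misclassify events that predate the first sample — a limitation shared
with any multi-passage sequencing design.

Trajectories summarize how the allele fraction moves across ranks (stable /
increasing / decreasing / lost), and zygosity is read off the AF under the
local copy number via the expected-AF model: ~0.5 heterozygous, ~1.0
homozygous, copy-number-adjusted when a duplicated or lost region shifts
the expectation (e.g. 2/3 for a germline het on a duplicated haplotype).
"Detected" means surviving the retention cascade in that sample; dropping
below the detection floor is indistinguishable from true loss here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cnv import CnvSegment
from .integrate import AfModelInput, expected_af
from .snv import VariantCall

__all__ = [
    "ClassifiedVariant",
    "classify_origin",
    "call_trajectory",
    "call_zygosity",
    "classify_variants",
    "de_novo_load",
    "acquisition_points",
]

#: minimum AF change across ranks to call a trajectory non-stable; an order
#: of magnitude above binomial noise at 1500x depth (sigma ~ 0.013)
TRAJECTORY_DELTA = 0.15

ZYGOSITY_TOL = 0.10


@dataclass
class ClassifiedVariant:
    """A variant's line-level temporal classification."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    line_id: str
    origin: str  # germline | de_novo | ambiguous
    first_seen_rank: int
    af_by_rank: dict[int, float]
    trajectory: str  # stable | increasing | decreasing | lost
    zygosity: str  # heterozygous | homozygous | cn_adjusted | ambiguous
    segment_label: str | None = None
    info: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.gene, self.chrom, self.pos, self.ref, self.alt)


def classify_origin(
    af_by_rank: Mapping[int, float],
    ranks: Sequence[int],
) -> tuple[str, int]:
    """(origin, first_seen_rank) from a detection series over tested ranks.

    Germline iff detected at the earliest tested rank.  A single-rank line
    cannot separate germline from de novo and yields ``ambiguous``.
    """
    ranks = sorted(ranks)
    if not af_by_rank:
        raise ValueError("variant was never detected")
    first_seen = min(af_by_rank)
    if first_seen not in ranks:
        raise ValueError(f"detection at untested rank {first_seen}")
    if len(ranks) < 2:
        return "ambiguous", first_seen
    return ("germline" if first_seen == ranks[0] else "de_novo"), first_seen


def call_trajectory(
    af_by_rank: Mapping[int, float],
    ranks: Sequence[int],
    delta: float = TRAJECTORY_DELTA,
) -> str:
    """lost / increasing / decreasing / stable over the detection series."""
    if not af_by_rank:
        raise ValueError("variant was never detected")
    ranks = sorted(ranks)
    if ranks[-1] not in af_by_rank:
        return "lost"
    detected = [af_by_rank[r] for r in ranks if r in af_by_rank]
    change = detected[-1] - detected[0]
    if change > delta:
        return "increasing"
    if change < -delta:
        return "decreasing"
    return "stable"


def call_zygosity(
    af: float,
    local_copy_number: int = 2,
    clonal_fraction: float = 1.0,
    tol: float = ZYGOSITY_TOL,
) -> str:
    """Zygosity call from AF under the local copy number.

    heterozygous when AF ~ 0.5 at copy number 2; homozygous when
    AF >= 1 - tol; otherwise copy-number-adjusted when the AF matches any
    configuration achievable at the given copy number and clonal fraction
    under the expected-AF model; else ambiguous.
    """
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"AF {af} outside [0, 1]")
    if local_copy_number < 1:
        raise ValueError("copy number must be >= 1")
    if abs(af - 0.5) <= tol and local_copy_number == 2:
        return "heterozygous"
    if af >= 1.0 - tol:
        return "homozygous"
    for m in range(1, local_copy_number + 1):
        for m0 in (0, 1, 2):
            exp = expected_af(AfModelInput(local_copy_number, m, m0,
                                           clonal_fraction))
            if exp > 0 and abs(af - exp) <= tol:
                return "cn_adjusted"
    return "ambiguous"


def _segment_copy_number(
    chrom: str, pos: int, segments: Sequence[CnvSegment],
) -> tuple[int, str | None]:
    """Locus copy number from the single overlapping called segment.

    Segments within a sample are non-overlapping, so at most one applies;
    a gain is treated as one extra copy, a loss as one fewer, absence as
    diploid.
    """
    for seg in segments:
        iv = seg.interval
        if iv.chrom == chrom and iv.start < pos <= iv.end:
            cn = 3 if seg.direction == "gain" else 1
            return cn, seg.recurrent_label or f"{iv.chrom}:{iv.start}-{iv.end}"
    return 2, None


def classify_variants(
    line_id: str,
    calls_by_rank: Mapping[int, Sequence[VariantCall]],
    segments_by_rank: Mapping[int, Sequence[CnvSegment]] | None = None,
    delta: float = TRAJECTORY_DELTA,
    zygosity_tol: float = ZYGOSITY_TOL,
) -> list[ClassifiedVariant]:
    """Classify every variant observed in a line's filtered call sets.

    *calls_by_rank* maps sample rank (1 = earliest) to the retained calls of
    that sample; *segments_by_rank* optionally supplies the called CNV
    segments per rank for copy-number-aware zygosity.  Zygosity is read at
    the last detected rank, where any copy-number context has had the
    longest time to establish.
    """
    ranks = sorted(calls_by_rank)
    if not ranks:
        raise ValueError("no sampled ranks")
    by_key: dict[tuple, dict] = {}
    for rank in ranks:
        for call in calls_by_rank[rank]:
            entry = by_key.setdefault(call.key, {"afs": {}, "call": call})
            entry["afs"][rank] = call.af
            entry["call"] = call  # keep the latest observation
    out: list[ClassifiedVariant] = []
    for key, entry in by_key.items():
        afs: dict[int, float] = entry["afs"]
        origin, first_seen = classify_origin(afs, ranks)
        trajectory = call_trajectory(afs, ranks, delta=delta)
        last_rank = max(afs)
        segs = (segments_by_rank or {}).get(last_rank, [])
        cn, label = _segment_copy_number(key[1], key[2], segs)
        zygosity = call_zygosity(afs[last_rank], cn, tol=zygosity_tol)
        call: VariantCall = entry["call"]
        out.append(ClassifiedVariant(
            gene=key[0], chrom=key[1], pos=key[2], ref=key[3], alt=key[4],
            line_id=line_id, origin=origin, first_seen_rank=first_seen,
            af_by_rank=dict(sorted(afs.items())), trajectory=trajectory,
            zygosity=zygosity, segment_label=label, info=dict(call.info),
        ))
    out.sort(key=lambda v: (v.chrom, v.pos, v.gene))
    return out


def de_novo_load(
    classified: Sequence[ClassifiedVariant], rank: int,
) -> int:
    """Number of de novo variants detected in the sample at *rank*."""
    return sum(
        1 for v in classified if v.origin == "de_novo" and rank in v.af_by_rank
    )


def acquisition_points(
    classified: Sequence[ClassifiedVariant],
    rank_to_passage: Mapping[int, int],
) -> list[tuple[int, int, int]]:
    """(rank, passage, acquired) per sample after the first.

    ``acquired`` is 1 when the sample shows at least one de novo variant not
    detected at any earlier rank — the per-passage acquisition event used by
    the logistic rate regression.
    """
    ranks = sorted(rank_to_passage)
    points = []
    for rank in ranks[1:]:
        new = sum(
            1 for v in classified
            if v.origin == "de_novo" and v.first_seen_rank == rank
        )
        points.append((rank, rank_to_passage[rank], int(new > 0)))
    return points
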