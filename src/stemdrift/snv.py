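"""Variant-retention cascade for cancer-panel SNV calls.

Raw panel calls are noisy: common population polymorphisms, facility-level
recurrent artifacts, low-support calls and pseudogene-prone genes must be
removed before any call can be interpreted as a culture-acquired mutation.
The cascade applies five independent predicates:

R1  population frequency above the cutoff in any population database
R2  non-hotspot call with allele fraction below the validated floor
R3  facility-recurrent artifact (seen in too many unrelated samples)
R4  fewer supporting alt reads than the minimum
R5  gene on the exclusion list (default: CDC27, pseudogene-prone)
R6  optional: call inside a user-supplied exclusion region (off by default)

A variant is retained iff it fails no rule; the report tallies every failure
independently, so the same variant can count against several rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .core import GenomicInterval, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["VariantCall", "FilterReport", "apply_filters", "summarize_effects",
           "FILTER_RULES", "EFFECT_CLASSES"]

EFFECT_CLASSES = (
    "missense", "synonymous", "stop_gain", "splice", "utr5", "intronic",
    "inframe_del",
)

FILTER_RULES: dict[str, str] = {
    "R1": "population frequency above cutoff",
    "R2": "non-hotspot allele fraction below floor",
    "R3": "facility-recurrent artifact",
    "R4": "insufficient alt reads",
    "R5": "excluded gene",
    "R6": "excluded region",
}

#: fields that must be present (non-None) for the cascade to run
_REQUIRED_FIELDS = ("gene", "af", "alt_reads", "depth", "hotspot",
                    "recurrence_freq")


@dataclass
class VariantCall:
    """One annotated SNV/indel observation in one sample.

    ``pos`` is 1-based (VCF convention).  ``pop_freq`` maps population
    database name to frequency; ``deleterious`` is a precomputed
    SIFT-style flag and is never computed here (``None`` means
    not annotated and is treated as non-deleterious downstream).
    ``info`` is a passthrough map for fields the pipeline does not
    interpret (e.g. simulator ground-truth annotations).
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    alt_reads: int
    depth: int
    pop_freq: dict[str, float] = field(default_factory=dict)
    effect: str = "missense"
    deleterious: bool | None = None
    cosmic: Literal["none", "reported", "tier1"] = "none"
    hotspot: bool = False
    recurrence_freq: float = 0.0
    info: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"{self.key}: AF {self.af} outside [0, 1]")
        if self.alt_reads > self.depth:
            raise ValueError(f"{self.key}: alt_reads {self.alt_reads} exceeds "
                             f"depth {self.depth}")
        if self.depth > 0:
            tol = 0.005 + 1.0 / self.depth
            if abs(self.af - self.alt_reads / self.depth) > tol:
                raise ValueError(
                    f"{self.key}: AF {self.af} inconsistent with "
                    f"{self.alt_reads}/{self.depth}"
                )
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"{self.key}: unknown effect class {self.effect!r}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.gene, self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_id(self) -> str:
        return f"{self.gene}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterReport:
    """Per-variant filter outcomes plus per-rule removal tallies."""

    failed_rules: list[tuple[VariantCall, list[str]]] = field(default_factory=list)

    @property
    def rule_counts(self) -> dict[str, int]:
        counts = {rule: 0 for rule in FILTER_RULES}
        for _, failed in self.failed_rules:
            for rule in failed:
                counts[rule] += 1
        return counts

    @property
    def n_removed(self) -> int:
        return sum(1 for _, failed in self.failed_rules if failed)

    def retained(self, variant: VariantCall) -> bool:
        for v, failed in self.failed_rules:
            if v is variant:
                return not failed
        raise KeyError(f"{variant.variant_id} not in report")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": v.sample_id,
                "variant": v.variant_id,
                "retained": not failed,
                "failed_rules": ";".join(failed),
            }
            for v, failed in self.failed_rules
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "variant", "retained", "failed_rules"]
        )


def _check_required(v: VariantCall) -> None:
    for name in _REQUIRED_FIELDS:
        if getattr(v, name) is None:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} in {v.sample_id}: "
                f"missing required annotation {name!r}"
            )
    if v.pop_freq is None:
        raise ValueError(
            f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} in {v.sample_id}: "
            "missing required annotation 'pop_freq'"
        )


def apply_filters(
    variants: Sequence[VariantCall],
    cfg: PipelineConfig | None = None,
    exclusion_regions: Iterable[GenomicInterval] = (),
) -> tuple[list[VariantCall], FilterReport]:
    """Run the retention cascade; returns (retained variants, report).

    Rules are independent predicates, so the result is invariant to both
    rule order and input order.  *exclusion_regions* enables the optional
    R6 region filter (1-based variant position tested against 0-based
    half-open intervals).
    """
    if cfg is None:
        cfg = PipelineConfig()
    excluded_genes = set(cfg.excluded_genes)
    regions = list(exclusion_regions)
    report = FilterReport()
    retained: list[VariantCall] = []
    for v in variants:
        _check_required(v)
        if v.deleterious is None:
            logger.debug("%s: deleterious flag absent, treated as benign",
                         v.variant_id)
        failed: list[str] = []
        pop_max = max(v.pop_freq.values(), default=0.0)
        if pop_max > cfg.pop_freq_max:
            failed.append("R1")
        if not v.hotspot and v.af < cfg.min_af_nonhotspot:
            failed.append("R2")
        if v.recurrence_freq > cfg.recurrence_max:
            failed.append("R3")
        if v.alt_reads < cfg.min_alt_reads:
            failed.append("R4")
        if v.gene in excluded_genes:
            failed.append("R5")
        if regions and any(
            r.chrom == v.chrom and r.start < v.pos <= r.end for r in regions
        ):
            failed.append("R6")
        report.failed_rules.append((v, failed))
        if not failed:
            retained.append(v)
    for rule, n in report.rule_counts.items():
        if n:
            logger.info("filter %s (%s): removed %d call(s)",
                        rule, FILTER_RULES[rule], n)
    return retained, report


def summarize_effects(variants: Iterable[VariantCall]) -> pd.DataFrame:
    """Contingency counts of effect class x deleterious x COSMIC status.

    Always returns the full cross of categories (zeros included); the grand
    total equals the number of input variants.
    """
    idx = pd.MultiIndex.from_product(
        [EFFECT_CLASSES, [False, True], ["none", "reported", "tier1"]],
        names=["effect", "deleterious", "cosmic"],
    )
    counts = pd.Series(0, index=idx, name="count")
    for v in variants:
        counts.loc[(v.effect, bool(v.deleterious), v.cosmic)] += 1
    return counts.reset_index()
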