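"""Serial-passage clonal-evolution simulator for cultured pluripotent stem cells.

Models a culture as a set of clones evolving across discrete passages.  At
every passage three things happen, in order:

1. **Selection** — each clone's population fraction is multiplied by its
   relative fitness (product of ``1 + s`` over its mutations) and the
   fractions are renormalized.
2. **Drift** — the culture is bottlenecked by multinomial resampling of
   ``bottleneck_size`` cells (the replated fraction after a 1:10-1:100
   split); clones drawn zero times go extinct.
3. **Mutation** — each surviving clone may spawn a child clone carrying one
   new event: a recurrent driver CNV (gain of 20q11.21/1q/12/17q or loss of
   18q, with a fitness advantage ``s_recurrent``), a neutral rare CNV, or a
   neutral SNV in a panel gene.  A child inherits its parent's full event
   list, so an SNV arising in a clone that carries a driver CNV hitchhikes
   with the sweep — the mechanism behind de novo SNVs appearing after
   recurrent chromosomal gains.

Ground truth is kept per clone and per haplotype, so the allele fraction of
any variant at any passage follows from the clone-fraction-weighted copy
configuration (see :mod:`stemdrift.integrate`).  Renderers turn a history
into the two observable data types: negative-binomial binned read counts at
shallow-WGS scale and binomially sampled panel variant calls at ~1500x.

Per-passage acquisition probabilities cannot be constrained by published
observations (raw data are not deposited); the defaults are order-of-
magnitude choices calibrated so a default cohort shows germline and de novo
SNV counts per line in the published range.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import GENOME_HG19, GenomicInterval
from .cnv import BinnedCoverage, RecurrentCatalog, default_catalog
from .integrate import expected_af_multi
from .snv import VariantCall

__all__ = [
    "MutationEvent",
    "Clone",
    "GermlineVariant",
    "CultureHistory",
    "SimParams",
    "CoverageParams",
    "PanelGene",
    "make_panel",
    "make_gc_track",
    "gc_bias_quadratic",
    "simulate_line",
    "simulate_cohort",
    "render_coverage",
    "render_variants",
]

_BASES = ("A", "C", "G", "T")

#: sampling distribution of functional effect classes for simulated SNVs
_EFFECT_PROBS = {
    "missense": 0.45, "synonymous": 0.24, "stop_gain": 0.08, "splice": 0.05,
    "utr5": 0.02, "intronic": 0.13, "inframe_del": 0.03,
}


@dataclass(frozen=True)
class MutationEvent:
    """One acquired mutation: a CNV (interval, +/-1 copy) or a panel SNV."""

    event_id: int
    kind: Literal["cnv_gain", "cnv_loss", "snv"]
    fitness_advantage: float = 0.0
    # CNV fields
    region: GenomicInterval | None = None
    copies_delta: int | None = None
    recurrent_label: str | None = None
    # SNV fields
    gene: str | None = None
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    effect: str | None = None
    deleterious: bool | None = None
    cosmic: str | None = None
    hotspot: bool = False
    #: haplotype affected (which parental copy is duplicated/lost/mutated)
    hap: int = 0

    def __post_init__(self) -> None:
        if self.fitness_advantage < 0:
            raise ValueError("fitness advantage must be >= 0")
        if self.kind == "snv":
            if self.copies_delta is not None or self.gene is None:
                raise ValueError("snv events carry a gene and no copies_delta")
        else:
            if self.gene is not None or self.copies_delta not in (1, -1):
                raise ValueError("cnv events carry copies_delta +/-1, no gene")

    @property
    def is_driver_cnv(self) -> bool:
        return self.kind != "snv" and self.fitness_advantage > 0


@dataclass(frozen=True)
class GermlineVariant:
    """A variant present in every cell from the line's establishment."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Literal["heterozygous", "homozygous"]
    hap: int
    effect: str = "missense"
    deleterious: bool = False
    cosmic: str = "none"
    hotspot: bool = False


@dataclass
class Clone:
    clone_id: int
    parent_id: int | None
    new_event: MutationEvent | None  # None for the founder
    fitness: float = 1.0


@dataclass
class SimParams:
    """Study conditions for one simulated line.

    Probabilities are per clone per passage.  ``split_ratio`` records the
    passaging regime; the resampled ``bottleneck_size`` is the effective
    number of replated founder cells, the scale that sets genetic drift.
    """

    n_passages: int = 50
    bottleneck_size: int = 500
    split_ratio: tuple[int, int] = (10, 100)
    p_cnv_recurrent: float = 0.05
    p_cnv_rare: float = 0.01
    p_snv: float = 0.15
    s_recurrent: float = 0.3
    s_rare: float = 0.0
    snv_rate_multiplier_given_driver: float = 1.0
    n_germline_range: tuple[int, int] = (6, 17)
    p_germline_hom: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cnv_recurrent", "p_cnv_rare", "p_snv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bottleneck_size < 10:
            raise ValueError("bottleneck_size must be >= 10")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.snv_rate_multiplier_given_driver < 1.0:
            raise ValueError("snv_rate_multiplier_given_driver must be >= 1")
        if self.s_recurrent < 0 or self.s_rare < 0:
            raise ValueError("fitness advantages must be >= 0")


@dataclass(frozen=True)
class PanelGene:
    gene: str
    interval: GenomicInterval


def _substream(seed: int, *tokens: object) -> np.random.Generator:
    """Independent, reproducible substream keyed by (seed, tokens)."""
    tag = zlib.crc32(":".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


def make_panel(
    genome: dict[str, int] | None = None,
    n_genes: int = 380,
    seed: int = 7,
    gene_size: int = 100_000,
) -> list[PanelGene]:
    """A synthetic cancer-style gene panel: loci spread over the autosomes.

    Gene positions are deterministic given *seed* and independent of any
    simulation stream, so the same panel can be shared across lines.
    """
    if genome is None:
        genome = GENOME_HG19
    autosomes = [c for c in genome if c not in ("chrX", "chrY", "X", "Y")]
    lengths = np.array([genome[c] for c in autosomes], dtype=float)
    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(autosomes), size=n_genes, p=lengths / lengths.sum())
    panel = []
    for i, ci in enumerate(chrom_idx):
        chrom = autosomes[ci]
        start = int(rng.integers(0, genome[chrom] - gene_size))
        panel.append(PanelGene(f"PG{i + 1:04d}",
                               GenomicInterval(chrom, start, start + gene_size)))
    return panel


def make_gc_track(
    genome: dict[str, int] | None = None,
    bin_size: int = 50_000,
    seed: int = 7,
    gc_mean: float = 0.41,
    gc_sd: float = 0.06,
) -> pd.DataFrame:
    """Tile the genome into bins with plausible per-bin GC fractions."""
    if genome is None:
        genome = GENOME_HG19
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        gc = np.clip(rng.normal(gc_mean, gc_sd, size=len(starts)), 0.25, 0.65)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "gc": gc,
        }))
    return pd.concat(rows, ignore_index=True)


def gc_bias_quadratic(amplitude: float = 0.2, peak: float = 0.45,
                      half_width: float = 0.25) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth unimodal GC bias: read yield peaks at *peak* GC and falls by
    *amplitude* at ``peak +/- half_width``."""

    def bias(gc: np.ndarray) -> np.ndarray:
        return np.maximum(1.0 - amplitude * ((np.asarray(gc) - peak) / half_width) ** 2,
                          0.05)

    return bias


@dataclass
class CultureHistory:
    """Ground truth for one simulated line.

    ``fractions[p]`` maps clone id to population fraction after passage
    ``p`` (index 0 is the founding state).  Every clone's effective event
    list is its parent's plus its own new event, so genotypes are nested
    along the clone tree by construction.
    """

    line_id: str
    genome: dict[str, int]
    params: SimParams
    germline: list[GermlineVariant]
    clones: dict[int, Clone]
    fractions: list[dict[int, float]]
    event_log: list[tuple[int, int, MutationEvent]]

    # -- genotype queries ------------------------------------------------

    def events_of(self, clone_id: int) -> list[MutationEvent]:
        """Full inherited event list, oldest first."""
        chain: list[MutationEvent] = []
        cid: int | None = clone_id
        while cid is not None:
            clone = self.clones[cid]
            if clone.new_event is not None:
                chain.append(clone.new_event)
            cid = clone.parent_id
        return chain[::-1]

    def copy_number(self, clone_id: int, chrom: str, pos: int) -> int:
        cn = 2
        for e in self.events_of(clone_id):
            if e.kind != "snv" and e.region.chrom == chrom and \
                    e.region.start <= pos < e.region.end:
                cn += e.copies_delta
        return max(cn, 0)

    def locus_config(
        self,
        clone_id: int,
        variant: MutationEvent | GermlineVariant,
    ) -> tuple[float, int]:
        """(mutant copies m, total copies c) of *variant* in one clone.

        Walks the clone's ordered event list maintaining per-haplotype copy
        counts: a gain duplicates one copy of one haplotype (carrying any
        variant already on it), a loss removes one.  A de novo SNV enters
        with one copy on its haplotype at its event's position in the list;
        a variant not in this clone's lineage has m = 0.
        """
        if isinstance(variant, GermlineVariant):
            chrom, pos = variant.chrom, variant.pos
            hap_m = {0: 0.0, 1: 0.0}
            if variant.zygosity == "homozygous":
                hap_m = {0: 1.0, 1: 1.0}
            else:
                hap_m[variant.hap] = 1.0
            pending_snv = None
        else:
            chrom, pos = variant.chrom, variant.pos
            hap_m = {0: 0.0, 1: 0.0}
            pending_snv = variant
        hap_c = {0: 1, 1: 1}
        for e in self.events_of(clone_id):
            if pending_snv is not None and e.event_id == pending_snv.event_id:
                if hap_c[e.hap] > 0:
                    hap_m[e.hap] += 1.0
                pending_snv = None
            elif e.kind != "snv" and e.region.chrom == chrom and \
                    e.region.start <= pos < e.region.end:
                h = e.hap if hap_c[e.hap] > 0 or e.copies_delta > 0 else (1 - e.hap)
                if e.copies_delta > 0:
                    if hap_c[h] > 0:
                        hap_m[h] += hap_m[h] / hap_c[h]
                    hap_c[h] += 1
                elif hap_c[h] > 0:
                    hap_m[h] -= hap_m[h] / hap_c[h]
                    hap_c[h] -= 1
        m = hap_m[0] + hap_m[1]
        c = hap_c[0] + hap_c[1]
        if pending_snv is not None:  # variant not in this lineage
            m = 0.0
        return m, c

    def variant_af(self, passage: int,
                   variant: MutationEvent | GermlineVariant) -> float:
        """Population allele fraction of a variant at a passage."""
        mix = []
        for cid, f in self.fractions[passage].items():
            if f <= 0:
                continue
            m, c = self.locus_config(cid, variant)
            mix.append((f, m, c))
        if sum(f * c for f, _, c in mix) <= 0:
            # locus homozygously deleted culture-wide: nothing to sequence
            return 0.0
        return expected_af_multi(mix)

    def mean_copy_profile(self, passage: int, bins: pd.DataFrame) -> np.ndarray:
        """Clone-fraction-weighted mean copy number per bin (diploid = 2)."""
        profile = np.zeros(len(bins), dtype=float)
        chrom_arr = bins["chrom"].to_numpy()
        start_arr = bins["start"].to_numpy()
        end_arr = bins["end"].to_numpy()
        for cid, f in self.fractions[passage].items():
            if f <= 0:
                continue
            cn = np.full(len(bins), 2.0)
            for e in self.events_of(cid):
                if e.kind == "snv":
                    continue
                sel = (chrom_arr == e.region.chrom) & \
                      (start_arr < e.region.end) & (end_arr > e.region.start)
                cn[sel] += e.copies_delta
            profile += f * np.maximum(cn, 0.0)
        return profile

    def snv_events(self) -> list[MutationEvent]:
        return [e for _, _, e in self.event_log if e.kind == "snv"]

    def cnv_events(self) -> list[MutationEvent]:
        return [e for _, _, e in self.event_log if e.kind != "snv"]

    def event_passage(self, event_id: int) -> int:
        for passage, _, e in self.event_log:
            if e.event_id == event_id:
                return passage
        raise KeyError(event_id)

    def driver_fraction(self, passage: int) -> float:
        """Total fraction of cells carrying at least one driver CNV."""
        total = 0.0
        for cid, f in self.fractions[passage].items():
            if f > 0 and any(e.is_driver_cnv for e in self.events_of(cid)):
                total += f
        return total

    def validate(self) -> None:
        for p, frac in enumerate(self.fractions):
            s = sum(frac.values())
            if abs(s - 1.0) > 1e-9:
                raise AssertionError(f"passage {p}: fractions sum to {s}")


# -- event generation ----------------------------------------------------

_RECURRENT_WEIGHTS = {
    "20q11.21/BCL2L1": 0.45, "1q/MDM4": 0.35, "18q/SALL3": 0.10,
    "12": 0.05, "17q": 0.05,
}


def _snap(x: int, bin_size: int = 50_000) -> int:
    return int(round(x / bin_size) * bin_size)


def _draw_recurrent_cnv(rng: np.random.Generator, genome: dict[str, int],
                        catalog: RecurrentCatalog, s: float,
                        event_id: int) -> MutationEvent:
    labels = [e.label for e in catalog.entries]
    weights = np.array([_RECURRENT_WEIGHTS.get(lb, 0.05) for lb in labels])
    entry = catalog.entries[rng.choice(len(labels), p=weights / weights.sum())]
    chrom = entry.interval.chrom
    chrom_len = genome[chrom]
    anchor = entry.driver if entry.driver is not None else entry.interval
    if entry.label.startswith("20q"):
        # common proximal breakpoint, variable distal extent
        start = entry.interval.start
        end = _snap(int(rng.integers(entry.interval.end, chrom_len)))
    elif entry.label in ("12",):
        start, end = 0, chrom_len
    elif entry.driver is not None:
        # terminal segment with a variable proximal breakpoint spanning the
        # driver locus (distal 1q, 18q)
        lo = max(entry.interval.start - 6_000_000, 0)
        start = _snap(int(rng.integers(lo, anchor.start - 50_000)))
        end = chrom_len
    else:
        # terminal arm-level segment without a named driver (17q)
        start = _snap(int(rng.integers(entry.interval.start,
                                       chrom_len - 5_000_000)))
        end = chrom_len
    end = min(max(end, start + 50_000), chrom_len)
    return MutationEvent(
        event_id=event_id,
        kind="cnv_gain" if entry.direction == "gain" else "cnv_loss",
        region=GenomicInterval(chrom, start, end),
        copies_delta=1 if entry.direction == "gain" else -1,
        recurrent_label=entry.label,
        fitness_advantage=s,
        hap=int(rng.integers(2)),
    )


def _draw_rare_cnv(rng: np.random.Generator, genome: dict[str, int],
                   s: float, event_id: int) -> MutationEvent:
    autosomes = [c for c in genome if c not in ("chrX", "chrY", "X", "Y")]
    lengths = np.array([genome[c] for c in autosomes], dtype=float)
    chrom = autosomes[rng.choice(len(autosomes), p=lengths / lengths.sum())]
    size = _snap(int(rng.integers(1_000_000, 20_000_001)))
    start = _snap(int(rng.integers(0, max(genome[chrom] - size, 1))))
    gain = rng.random() < 0.8  # gains outnumber losses in culture
    return MutationEvent(
        event_id=event_id,
        kind="cnv_gain" if gain else "cnv_loss",
        region=GenomicInterval(chrom, start, min(start + size, genome[chrom])),
        copies_delta=1 if gain else -1,
        fitness_advantage=s,
        hap=int(rng.integers(2)),
    )


def _draw_snv_annotations(rng: np.random.Generator) -> dict:
    effects = list(_EFFECT_PROBS)
    effect = effects[rng.choice(len(effects), p=np.array(list(_EFFECT_PROBS.values())))]
    deleterious = bool(
        effect in ("missense", "stop_gain", "splice")
        and rng.random() < (0.9 if effect == "stop_gain" else 0.55)
    )
    cosmic = ["none", "reported", "tier1"][rng.choice(3, p=[0.72, 0.18, 0.10])]
    return {
        "effect": effect,
        "deleterious": deleterious,
        "cosmic": cosmic,
        "hotspot": bool(rng.random() < 0.05),
    }


def _draw_snv(rng: np.random.Generator, panel: Sequence[PanelGene],
              event_id: int) -> MutationEvent:
    g = panel[int(rng.integers(len(panel)))]
    pos = int(rng.integers(g.interval.start + 1, g.interval.end + 1))
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return MutationEvent(
        event_id=event_id,
        kind="snv",
        gene=g.gene,
        chrom=g.interval.chrom,
        pos=pos,
        ref=_BASES[ref],
        alt=_BASES[alt],
        hap=int(rng.integers(2)),
        **_draw_snv_annotations(rng),
    )


def _draw_germline(rng: np.random.Generator, panel: Sequence[PanelGene],
                   params: SimParams) -> list[GermlineVariant]:
    lo, hi = params.n_germline_range
    n = int(rng.integers(lo, hi + 1))
    out = []
    for gi in rng.choice(len(panel), size=min(n, len(panel)), replace=False):
        g = panel[int(gi)]
        pos = int(rng.integers(g.interval.start + 1, g.interval.end + 1))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        ann = _draw_snv_annotations(rng)
        out.append(GermlineVariant(
            gene=g.gene, chrom=g.interval.chrom, pos=pos,
            ref=_BASES[ref], alt=_BASES[alt],
            zygosity="homozygous" if rng.random() < params.p_germline_hom
            else "heterozygous",
            hap=int(rng.integers(2)),
            **ann,
        ))
    return out


# -- the simulator -------------------------------------------------------

def simulate_line(
    params: SimParams,
    line_id: str = "line",
    genome: dict[str, int] | None = None,
    panel: Sequence[PanelGene] | None = None,
    catalog: RecurrentCatalog | None = None,
) -> CultureHistory:
    """Run selection / drift / mutation across ``params.n_passages`` passages.

    Fully reproducible from ``params.seed`` (per-line substreams are keyed
    on the line id).  With all acquisition probabilities zero the history
    contains a single wild-type clone at fraction 1 throughout.
    """
    if genome is None:
        genome = GENOME_HG19
    if panel is None:
        panel = make_panel(genome)
    if catalog is None:
        catalog = default_catalog()
    rng = _substream(params.seed, line_id, "evolve")

    clones: dict[int, Clone] = {0: Clone(0, None, None, fitness=1.0)}
    fractions: list[dict[int, float]] = [{0: 1.0}]
    event_log: list[tuple[int, int, MutationEvent]] = []
    germline = _draw_germline(_substream(params.seed, line_id, "germline"),
                              panel, params)
    next_event_id = 1
    next_clone_id = 1

    current = {0: 1.0}
    for passage in range(1, params.n_passages + 1):
        # selection
        ids = list(current)
        weights = np.array([current[c] * clones[c].fitness for c in ids])
        weights /= weights.sum()
        # drift: multinomial bottleneck
        counts = rng.multinomial(params.bottleneck_size, weights)
        survivors = {c: n / params.bottleneck_size
                     for c, n in zip(ids, counts) if n > 0}
        # mutation: each surviving clone may seed one child per event class
        new_children: dict[int, float] = {}
        seed_f = 1.0 / params.bottleneck_size
        for cid in list(survivors):
            has_driver = _clone_has_driver(clones, cid)
            p_snv_eff = min(params.p_snv * (
                params.snv_rate_multiplier_given_driver if has_driver else 1.0), 1.0)
            draws = (
                ("recurrent", params.p_cnv_recurrent),
                ("rare", params.p_cnv_rare),
                ("snv", p_snv_eff),
            )
            for kind, prob in draws:
                if prob <= 0 or rng.random() >= prob:
                    continue
                if survivors.get(cid, 0.0) < seed_f:
                    continue
                if kind == "recurrent":
                    ev = _draw_recurrent_cnv(rng, genome, catalog,
                                             params.s_recurrent, next_event_id)
                elif kind == "rare":
                    ev = _draw_rare_cnv(rng, genome, params.s_rare,
                                        next_event_id)
                else:
                    ev = _draw_snv(rng, panel, next_event_id)
                next_event_id += 1
                child_id = next_clone_id
                next_clone_id += 1
                clones[child_id] = Clone(
                    child_id, cid, ev,
                    fitness=clones[cid].fitness * (1.0 + ev.fitness_advantage),
                )
                new_children[child_id] = seed_f
                survivors[cid] -= seed_f
                event_log.append((passage, child_id, ev))
        current = {c: f for c, f in {**survivors, **new_children}.items() if f > 0}
        total = sum(current.values())
        current = {c: f / total for c, f in current.items()}
        fractions.append(dict(current))

    hist = CultureHistory(
        line_id=line_id, genome=genome, params=params, germline=germline,
        clones=clones, fractions=fractions, event_log=event_log,
    )
    hist.validate()
    return hist


def _clone_has_driver(clones: dict[int, Clone], clone_id: int) -> bool:
    cid: int | None = clone_id
    while cid is not None:
        clone = clones[cid]
        if clone.new_event is not None and clone.new_event.is_driver_cnv:
            return True
        cid = clone.parent_id
    return False


def sample_passages(params: SimParams, rng: np.random.Generator,
                    n_ranks: int = 3) -> list[int]:
    """Pick increasing sampled passages, one per equal-width stratum."""
    edges = np.linspace(1, params.n_passages + 1, n_ranks + 1).astype(int)
    return [int(rng.integers(edges[i], edges[i + 1])) for i in range(n_ranks)]


def simulate_cohort(
    n_lines: int,
    params: SimParams,
    n_ranks: int = 3,
    genome: dict[str, int] | None = None,
    panel: Sequence[PanelGene] | None = None,
    catalog: RecurrentCatalog | None = None,
    line_prefix: str = "SIM",
) -> list[tuple[CultureHistory, list[int]]]:
    """Simulate *n_lines* independent lines with sampled passage schedules."""
    out = []
    for i in range(n_lines):
        line_id = f"{line_prefix}{i + 1:03d}"
        hist = simulate_line(params, line_id=line_id, genome=genome,
                             panel=panel, catalog=catalog)
        sched = sample_passages(params, _substream(params.seed, line_id, "sched"),
                                n_ranks)
        out.append((hist, sched))
    return out


# -- rendering -----------------------------------------------------------

@dataclass
class CoverageParams:
    """Shallow-WGS rendering: expected reads per diploid bin and noise.

    ``dispersion`` is the extra (above-Poisson) coefficient of variation of
    the negative-binomial bin counts; 0 selects the deterministic limit
    where every bin equals its expectation.
    """

    base_count: float = 113.0  # ~7e6 50 bp read pairs over ~62k 50 kb bins
    dispersion: float = 0.03
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None


def render_coverage(
    history: CultureHistory,
    passage: int,
    gc_track: pd.DataFrame,
    depth_params: CoverageParams | None = None,
    seed: int | None = None,
) -> BinnedCoverage:
    """Render a shallow-WGS binned coverage profile at one passage.

    Expected count per bin = base_count x (mean copy number / 2) x
    gc_bias(gc); counts are negative-binomial (gamma-Poisson) with the
    configured extra dispersion.
    """
    if depth_params is None:
        depth_params = CoverageParams()
    if not (0 <= passage < len(history.fractions)):
        raise ValueError(f"passage {passage} not in history")
    for chrom in gc_track["chrom"].unique():
        if chrom not in history.genome:
            raise ValueError(f"bin grid chromosome {chrom!r} not in genome")
    rng = _substream(seed if seed is not None else history.params.seed,
                     history.line_id, passage, "coverage")
    profile = history.mean_copy_profile(passage, gc_track)
    gc = gc_track["gc"].to_numpy(dtype=float)
    bias = depth_params.gc_bias(gc) if depth_params.gc_bias is not None else 1.0
    expected = depth_params.base_count * (profile / 2.0) * bias
    d = depth_params.dispersion
    if d <= 0:
        counts = np.round(expected).astype(int)
    else:
        lam = expected * rng.gamma(shape=1.0 / d**2, scale=d**2, size=len(expected))
        counts = rng.poisson(lam)
    bins = gc_track[["chrom", "start", "end", "gc"]].copy()
    bins["count"] = counts
    bins["blacklisted"] = False
    sample_id = f"{history.line_id}_p{passage}"
    return BinnedCoverage(sample_id, bins)


def render_variants(
    history: CultureHistory,
    passage: int,
    panel: Sequence[PanelGene],
    depth: int = 1500,
    seed: int | None = None,
    af_floor: float = 0.005,
) -> list[VariantCall]:
    """Render panel variant calls at one passage.

    Each germline variant and every SNV event segregating in the culture is
    observed with alt reads ~ Binomial(site depth, AF), site depth ~
    Poisson(*depth*).  Variants whose realized AF falls below *af_floor*
    (sub-mosaicism detection limit) or that lie outside the panel are not
    emitted.  Ground truth (origin, event passage, true AF) rides along in
    the ``info`` passthrough map.
    """
    if not (0 <= passage < len(history.fractions)):
        raise ValueError(f"passage {passage} not in history")
    rng = _substream(seed if seed is not None else history.params.seed,
                     history.line_id, passage, "variants")
    panel_genes = {g.gene for g in panel}
    sample_id = f"{history.line_id}_p{passage}"
    calls: list[VariantCall] = []

    def emit(variant: MutationEvent | GermlineVariant, origin: str,
             event_passage: int) -> None:
        if variant.gene not in panel_genes:
            return
        true_af = history.variant_af(passage, variant)
        if true_af <= 0:
            return
        site_depth = max(int(rng.poisson(depth)), 1)
        alt = int(rng.binomial(site_depth, min(true_af, 1.0)))
        af = alt / site_depth
        if af < af_floor or alt == 0:
            return
        calls.append(VariantCall(
            sample_id=sample_id,
            gene=variant.gene, chrom=variant.chrom, pos=variant.pos,
            ref=variant.ref, alt=variant.alt,
            af=af, alt_reads=alt, depth=site_depth,
            pop_freq={"gnomad": 0.0, "1000g": 0.0, "esp6500": 0.0},
            effect=variant.effect,
            deleterious=variant.deleterious,
            cosmic=variant.cosmic,
            hotspot=variant.hotspot,
            recurrence_freq=0.0,
            info={
                "true_origin": origin,
                "event_passage": str(event_passage),
                "true_af": f"{true_af:.6f}",
            },
        ))

    for gv in history.germline:
        emit(gv, "germline", 0)
    for ev_passage, _, ev in history.event_log:
        if ev.kind == "snv":
            emit(ev, "de_novo", ev_passage)
    return calls
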