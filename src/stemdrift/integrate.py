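"""Joint interpretation of CNV segments and SNV allele fractions.

When part of a culture is taken over by a clone carrying a copy-number
change, the allele fraction of an SNV inside the changed region departs
from the diploid expectations (0.5 heterozygous, 1.0 homozygous).  With a
mutant clone at population fraction ``f`` carrying ``m`` mutant copies out
of ``c`` total copies at the locus, and the remaining cells diploid with
``m0`` mutant copies, the expected alt-read fraction is

    AF = (f*m + (1-f)*m0) / (f*c + (1-f)*2)

e.g. a germline heterozygote whose mutant haplotype is duplicated in a
fully clonal gain gives 2/3, and a de novo single copy in a triplicated
locus gives 1/3.  ``match_af`` inverts this by grid search to flag observed
AFs as CNV-explained, and ``association_table`` builds the karyotype-status
vs de-novo-SNV-carriage contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import Table2x2

__all__ = [
    "AfModelInput",
    "IntegrationRecord",
    "expected_af",
    "expected_af_multi",
    "match_af",
    "association_table",
]


@dataclass(frozen=True)
class AfModelInput:
    """Copy configuration of a variant locus in a two-population culture.

    total_copies_mutant_clone
        ``c``, total copies of the locus in the mutant clone (>= 1).
    mutant_copies
        ``m``, copies carrying the variant allele in the mutant clone.
    wildtype_mutant_copies
        ``m0``, variant copies in the diploid remainder (0 de novo,
        1 germline het, 2 germline hom).
    clonal_fraction
        ``f``, fraction of the culture descended from the mutant clone.
    """

    total_copies_mutant_clone: int
    mutant_copies: int
    wildtype_mutant_copies: int = 0
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        c, m, m0, f = (
            self.total_copies_mutant_clone,
            self.mutant_copies,
            self.wildtype_mutant_copies,
            self.clonal_fraction,
        )
        if c < 1:
            raise ValueError("total copies in the mutant clone must be >= 1")
        if not (0 <= m <= c):
            raise ValueError(f"mutant copies {m} outside [0, {c}]")
        if m0 not in (0, 1, 2):
            raise ValueError("wild-type mutant copies must be 0, 1 or 2")
        if not (0.0 <= f <= 1.0):
            raise ValueError("clonal fraction must lie in [0, 1]")


def expected_af(inp: AfModelInput) -> float:
    """Expected allele fraction under copy number and clonality."""
    c = inp.total_copies_mutant_clone
    m = inp.mutant_copies
    m0 = inp.wildtype_mutant_copies
    f = inp.clonal_fraction
    denom = f * c + (1.0 - f) * 2.0
    return (f * m + (1.0 - f) * m0) / denom


def expected_af_multi(clones: Sequence[tuple[float, int, int]]) -> float:
    """Allele fraction for an arbitrary clone mixture.

    *clones* is a sequence of ``(fraction, mutant_copies, total_copies)``.
    Reduces to :func:`expected_af` for the two-population case.
    """
    num = sum(f * m for f, m, _ in clones)
    den = sum(f * c for f, _, c in clones)
    if den <= 0:
        raise ValueError("total copy mass is zero across the mixture")
    return num / den


@dataclass
class IntegrationRecord:
    """Best-fit copy-configuration explanation of one observed AF."""

    observed_af: float
    copy_number: int
    segment_label: str | None
    expected_af: float
    best_m: int
    best_m0: int
    best_f: float
    cnv_explained: bool


#: clonal-fraction grid used by the AF matcher
_F_GRID = np.round(np.arange(0.1, 1.01, 0.1), 10)


def match_af(
    observed_af: float,
    copy_number: int,
    tol: float = 0.10,
    segment_label: str | None = None,
    m0_values: Sequence[int] = (0, 1),
) -> IntegrationRecord:
    """Grid-search the AF model for the configuration closest to an observation.

    Searches mutant copies ``m`` in [0, c], background copies ``m0`` over
    *m0_values* (restrict to ``(0,)`` for variants known to be de novo) and
    clonal fraction ``f`` over 0.1..1.0 in steps of 0.1.  The observation is
    CNV-explained when the best |obs - exp| <= *tol*.
    """
    if not (0.0 <= observed_af <= 1.0):
        raise ValueError("observed AF must lie in [0, 1]")
    if copy_number < 1:
        raise ValueError("copy number must be >= 1")
    best: tuple[float, int, int, float, float] | None = None
    for m in range(copy_number + 1):
        for m0 in m0_values:
            for f in _F_GRID:
                exp = expected_af(
                    AfModelInput(copy_number, m, m0, float(f))
                )
                err = abs(observed_af - exp)
                if best is None or err < best[0] - 1e-12:
                    best = (err, m, m0, float(f), exp)
    assert best is not None
    err, m, m0, f, exp = best
    return IntegrationRecord(
        observed_af=observed_af,
        copy_number=copy_number,
        segment_label=segment_label,
        expected_af=exp,
        best_m=m,
        best_m0=m0,
        best_f=f,
        cnv_explained=err <= tol,
    )


def association_table(
    samples: Iterable[Mapping[str, object] | tuple[str, bool]],
) -> Table2x2:
    """Karyotype status vs de novo SNV carriage as a 2x2 table.

    Each sample contributes ``(karyotype_status, carries_de_novo_snv)``;
    mappings with keys ``karyotype`` and ``has_de_novo`` are also accepted.
    Rows are (normal, abnormal), columns (has de novo SNV, none).
    """
    counts = {("normal", True): 0, ("normal", False): 0,
              ("abnormal", True): 0, ("abnormal", False): 0}
    for i, s in enumerate(samples):
        if isinstance(s, Mapping):
            status, carrier = s.get("karyotype"), s.get("has_de_novo")
        else:
            status, carrier = s
        if status not in ("normal", "abnormal") or carrier is None:
            raise ValueError(f"sample {i} lacks a karyotype or carriage label")
        counts[(status, bool(carrier))] += 1
    return Table2x2(
        a=counts[("normal", True)],
        b=counts[("normal", False)],
        c=counts[("abnormal", True)],
        d=counts[("abnormal", False)],
    )
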