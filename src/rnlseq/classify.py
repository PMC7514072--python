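"""Helper-NLR (RNL) dependency classification of ETI-regulated genes.

"ETI-regulated" genes are those differentially expressed in the
effector-vs-empty-vector contrast at a matched timepoint in wild type.
Each such gene is classified by where the response survives among the
mutants: genes still responding in the pentuple *helperless* mutant
are RNL-independent; among RNL-dependent genes, loss of the response
in both single-family mutants means the families act synergistically,
persistence in both means they act redundantly, and loss in exactly
one family's mutant marks the other family's response as
family-specific.  Fraction reports mirror the study's accounting of
those categories per effector, timepoint and direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .model import (
    CATEGORY_GENOTYPES,
    ETI_TIMEPOINTS,
    Genotype,
    RNLCategory,
    Treatment,
    ValidationError,
)
from .diffexpr import DirectionalGeneSet

logger = logging.getLogger("rnlseq")

__all__ = [
    "DEStatusVector",
    "classify_gene",
    "pti_sets",
    "eti_regulated",
    "status_vectors",
    "assign_categories",
    "FractionReport",
    "fraction_report",
    "venn_counts",
]


@dataclass(frozen=True)
class DEStatusVector:
    """Per-gene DE flags across the four genotypes for one effector/time."""

    gene_id: str
    effector: Treatment
    time_hpi: float
    direction: str
    de_flags: Mapping[Genotype, bool]

    def __post_init__(self) -> None:
        if set(self.de_flags) != set(Genotype):
            missing = sorted(g.value for g in set(Genotype) - set(self.de_flags))
            raise ValidationError(f"gene {self.gene_id!r}: missing DE flags for {missing}")


def classify_gene(status: DEStatusVector) -> RNLCategory:
    """Five-way epistasis decision table over the four genotypes' DE flags.

    Not DE in wild type -> NOT_ETI.  DE in helperless -> RNL_INDEPENDENT
    (the response needs no helper NLR).  Otherwise the two single-family
    mutants decide: response lost in both -> SYNERGISTIC; kept in
    both -> REDUNDANT; kept only in *nrg1.1 nrg1.2* (i.e. lost without
    ADR1s) -> ADR1_SPECIFIC; kept only in *adr1 triple* -> NRG1_SPECIFIC.
    """
    f = status.de_flags
    if not f[Genotype.COL0]:
        return RNLCategory.NOT_ETI
    if f[Genotype.HELPERLESS]:
        return RNLCategory.RNL_INDEPENDENT
    in_adr1_mut = f[Genotype.ADR1_TRIPLE]
    in_nrg1_mut = f[Genotype.NRG1_DOUBLE]
    if not in_adr1_mut and not in_nrg1_mut:
        return RNLCategory.SYNERGISTIC
    if in_adr1_mut and in_nrg1_mut:
        return RNLCategory.REDUNDANT
    if in_nrg1_mut:  # survives without NRG1s' target, lost without ADR1s
        return RNLCategory.ADR1_SPECIFIC
    return RNLCategory.NRG1_SPECIFIC


def _consistency_check() -> None:
    # classifier must invert the simulator's category -> genotype map
    for cat, genos in CATEGORY_GENOTYPES.items():
        flags = {g: g in genos for g in Genotype}
        sv = DEStatusVector("x", Treatment.AVRRPS4, 4.0, "up", flags)
        assert classify_gene(sv) is cat, cat


_consistency_check()


DEGKey = tuple[Genotype, Treatment, float, str]  # genotype, treatment, time, direction


def pti_sets(
    deg_calls: Mapping[DEGKey, DirectionalGeneSet],
    times: Sequence[float] = (0.5, 4.0, 8.0),
) -> dict[tuple[Genotype, float, str], DirectionalGeneSet]:
    """EV-induced (and repressed) gene sets per genotype and time.

    ``deg_calls`` maps (genotype, treatment, time, direction) to the DEG
    set of that treatment's vs-time-0 contrast.
    """
    out: dict[tuple[Genotype, float, str], DirectionalGeneSet] = {}
    for g in Genotype:
        for t in times:
            for d in ("up", "down"):
                key = (g, Treatment.EV, t, d)
                if key not in deg_calls:
                    raise ValidationError(
                        f"missing EV-vs-time-0 contrast for genotype {g.value} "
                        f"at {t:g} hpi ({d})"
                    )
                out[(g, t, d)] = deg_calls[key]
    return out


def eti_regulated(
    deg_calls: Mapping[DEGKey, DirectionalGeneSet],
    genotype: Genotype,
    effector: Treatment,
    time_hpi: float,
    direction: str = "up",
) -> DirectionalGeneSet:
    """DEG set of the effector-vs-EV contrast for one genotype/time.

    For wild type this is the "ETI-regulated" set.  Defined at 4 and 8
    hpi only: NLR activation effects on expression are not visible
    earlier.
    """
    if time_hpi not in ETI_TIMEPOINTS:
        raise ValidationError(
            f"ETI sets are defined at {ETI_TIMEPOINTS} hpi only, got {time_hpi:g}"
        )
    key = (genotype, effector, time_hpi, direction)
    if key not in deg_calls:
        raise ValidationError(
            f"missing effector-vs-EV contrast for {genotype.value}, "
            f"{effector.value}, {time_hpi:g} hpi ({direction})"
        )
    return deg_calls[key]


def status_vectors(
    deg_calls: Mapping[DEGKey, DirectionalGeneSet],
    effector: Treatment,
    time_hpi: float,
    direction: str = "up",
) -> list[DEStatusVector]:
    """Build DE-status vectors for every ETI-regulated (wild-type DE) gene.

    A gene DE in a mutant only with the opposite sign to wild type is
    treated as not DE in that mutant for this direction (logged).
    """
    col0 = eti_regulated(deg_calls, Genotype.COL0, effector, time_hpi, direction)
    other = "down" if direction == "up" else "up"
    vectors = []
    n_opposite = 0
    for gene in sorted(col0.genes):
        flags = {}
        for g in Genotype:
            same = gene in eti_regulated(deg_calls, g, effector, time_hpi, direction).genes
            if not same and gene in eti_regulated(
                deg_calls, g, effector, time_hpi, other
            ).genes:
                n_opposite += 1
            flags[g] = same
        vectors.append(DEStatusVector(gene, effector, time_hpi, direction, flags))
    if n_opposite:
        logger.info(
            "%s %g hpi (%s): %d mutant DE calls had opposite sign to Col-0; "
            "treated as not DE",
            effector.value, time_hpi, direction, n_opposite,
        )
    return vectors


def assign_categories(vectors: Sequence[DEStatusVector]) -> dict[str, RNLCategory]:
    return {v.gene_id: classify_gene(v) for v in vectors}


def _pct(num: int, den: int) -> float | None:
    """Percentage rounded half-up to one decimal; None when undefined."""
    if den == 0:
        return None
    return float(
        (Decimal(num) * 100 / Decimal(den)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class FractionReport:
    """Category accounting for one effector x time x direction cell."""

    effector: Treatment
    time_hpi: float
    direction: str
    n_eti: int
    n_rnl_independent: int
    n_synergistic: int
    n_redundant: int
    n_adr1_specific: int
    n_nrg1_specific: int

    @property
    def n_rnl_dependent(self) -> int:
        return (
            self.n_synergistic
            + self.n_redundant
            + self.n_adr1_specific
            + self.n_nrg1_specific
        )

    @property
    def n_shared(self) -> int:
        return self.n_synergistic + self.n_redundant

    @property
    def n_specific(self) -> int:
        return self.n_adr1_specific + self.n_nrg1_specific

    # all percentages are one-decimal, round-half-up; None when the base is 0
    @property
    def rnl_dependent_pct(self) -> float | None:
        return _pct(self.n_rnl_dependent, self.n_eti)

    @property
    def shared_pct(self) -> float | None:
        return _pct(self.n_shared, self.n_rnl_dependent)

    @property
    def specific_pct(self) -> float | None:
        return _pct(self.n_specific, self.n_rnl_dependent)

    @property
    def synergistic_pct(self) -> float | None:
        return _pct(self.n_synergistic, self.n_rnl_dependent)

    @property
    def redundant_pct(self) -> float | None:
        return _pct(self.n_redundant, self.n_rnl_dependent)

    @property
    def adr1_of_specific_pct(self) -> float | None:
        return _pct(self.n_adr1_specific, self.n_specific)

    @property
    def nrg1_of_specific_pct(self) -> float | None:
        return _pct(self.n_nrg1_specific, self.n_specific)

    def __post_init__(self) -> None:
        counts = (
            self.n_eti, self.n_rnl_independent, self.n_synergistic,
            self.n_redundant, self.n_adr1_specific, self.n_nrg1_specific,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("negative category count")
        if self.n_rnl_dependent + self.n_rnl_independent != self.n_eti:
            raise ValidationError(
                "category counts do not sum to the ETI set size: "
                f"{self.n_rnl_dependent} + {self.n_rnl_independent} != {self.n_eti}"
            )


def fraction_report(
    assignments: Mapping[str, RNLCategory],
    effector: Treatment,
    time_hpi: float,
    direction: str = "up",
) -> FractionReport:
    """Tally category assignments into a fraction report."""
    tally = {cat: 0 for cat in RNLCategory}
    for cat in assignments.values():
        tally[cat] += 1
    n_not = tally.pop(RNLCategory.NOT_ETI)
    if n_not:
        raise ValidationError(f"{n_not} NOT_ETI genes passed to fraction_report")
    return FractionReport(
        effector=effector,
        time_hpi=time_hpi,
        direction=direction,
        n_eti=sum(tally.values()),
        n_rnl_independent=tally[RNLCategory.RNL_INDEPENDENT],
        n_synergistic=tally[RNLCategory.SYNERGISTIC],
        n_redundant=tally[RNLCategory.REDUNDANT],
        n_adr1_specific=tally[RNLCategory.ADR1_SPECIFIC],
        n_nrg1_specific=tally[RNLCategory.NRG1_SPECIFIC],
    )


def venn_counts(sets: Sequence[DirectionalGeneSet | frozenset | set]) -> dict[tuple[bool, ...], int]:
    """Region counts for a 2- or 3-set Venn diagram.

    Keys are membership tuples (in set 1, in set 2[, in set 3]); the
    all-False region is omitted.  Region counts sum to the cardinality
    of the union.
    """
    k = len(sets)
    if k not in (2, 3):
        raise ValidationError(f"venn_counts supports 2 or 3 sets, got {k}")
    plain = [s.genes if isinstance(s, DirectionalGeneSet) else frozenset(s) for s in sets]
    universe = frozenset().union(*plain)
    out = {}
    for mask in itertools.product([True, False], repeat=k):
        if not any(mask):
            continue
        region = universe
        for s, inside in zip(plain, mask):
            region = region & s if inside else region - s
        out[mask] = len(region)
    return out
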