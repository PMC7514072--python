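"""Core data model shared by every pipeline stage.

The experimental design is a 4 genotype x 4 treatment x 4 timepoint
factorial: wild-type Col-0 and three helper-NLR mutants (the *adr1
triple*, the *nrg1.1 nrg1.2* double, and the pentuple *helperless*
mutant lacking both RNL families) infiltrated with Pf0-1 carrying an
empty vector (PTI control) or delivering one of three effectors
(AvrRps4, AvrRpt2, AvrRpm1), sampled before treatment and at 0.5, 4
and 8 hours post infiltration.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Treatment",
    "RNLCategory",
    "SampleMeta",
    "CountMatrix",
    "ContrastSpec",
    "RunConfig",
    "ValidationError",
    "TIMEPOINTS",
    "EFFECTORS",
    "ETI_TIMEPOINTS",
    "CATEGORY_GENOTYPES",
]


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class Genotype(str, enum.Enum):
    COL0 = "col0"
    ADR1_TRIPLE = "adr1_triple"
    NRG1_DOUBLE = "nrg1_double"
    HELPERLESS = "helperless"


class Treatment(str, enum.Enum):
    NONE = "none"
    EV = "EV"
    AVRRPS4 = "AvrRps4"
    AVRRPT2 = "AvrRpt2"
    AVRRPM1 = "AvrRpm1"


class RNLCategory(str, enum.Enum):
    """Five-way epistasis label for an ETI-regulated gene.

    The label encodes in which helper-NLR mutant backgrounds the gene
    remains differentially expressed during effector-triggered immunity.
    """

    NOT_ETI = "NOT_ETI"
    RNL_INDEPENDENT = "RNL_INDEPENDENT"
    SYNERGISTIC = "SYNERGISTIC"
    REDUNDANT = "REDUNDANT"
    ADR1_SPECIFIC = "ADR1_SPECIFIC"
    NRG1_SPECIFIC = "NRG1_SPECIFIC"


TIMEPOINTS: tuple[float, ...] = (0.0, 0.5, 4.0, 8.0)
EFFECTORS: tuple[Treatment, ...] = (
    Treatment.AVRRPS4,
    Treatment.AVRRPT2,
    Treatment.AVRRPM1,
)
ETI_TIMEPOINTS: tuple[float, ...] = (4.0, 8.0)

# Genotypes in which an ETI gene of each category is differentially
# expressed (effector vs EV).  Single source of truth for both the
# count simulator and the classifier; the classifier's decision table
# is the inverse of this map.
CATEGORY_GENOTYPES: dict[RNLCategory, frozenset[Genotype]] = {
    RNLCategory.RNL_INDEPENDENT: frozenset(Genotype),
    RNLCategory.SYNERGISTIC: frozenset({Genotype.COL0}),
    RNLCategory.REDUNDANT: frozenset(
        {Genotype.COL0, Genotype.ADR1_TRIPLE, Genotype.NRG1_DOUBLE}
    ),
    RNLCategory.ADR1_SPECIFIC: frozenset({Genotype.COL0, Genotype.NRG1_DOUBLE}),
    RNLCategory.NRG1_SPECIFIC: frozenset({Genotype.COL0, Genotype.ADR1_TRIPLE}),
}

_GENOTYPE_TOKENS = {
    "col0": Genotype.COL0,
    "col-0": Genotype.COL0,
    "columbia": Genotype.COL0,
    "columbia-0": Genotype.COL0,
    "wt": Genotype.COL0,
    "adr1triple": Genotype.ADR1_TRIPLE,
    "adr1_triple": Genotype.ADR1_TRIPLE,
    "adr1-triple": Genotype.ADR1_TRIPLE,
    "adr1": Genotype.ADR1_TRIPLE,
    "nrg1double": Genotype.NRG1_DOUBLE,
    "nrg1_double": Genotype.NRG1_DOUBLE,
    "nrg1.1nrg1.2": Genotype.NRG1_DOUBLE,
    "nrg1.1_nrg1.2": Genotype.NRG1_DOUBLE,
    "nrg1": Genotype.NRG1_DOUBLE,
    "helperless": Genotype.HELPERLESS,
}

_TREATMENT_TOKENS = {
    "none": Treatment.NONE,
    "mock": Treatment.NONE,
    "untreated": Treatment.NONE,
    "ev": Treatment.EV,
    "pf0-ev": Treatment.EV,
    "pf0ev": Treatment.EV,
    "empty_vector": Treatment.EV,
    "avrrps4": Treatment.AVRRPS4,
    "pf0-avrrps4": Treatment.AVRRPS4,
    "avrrpt2": Treatment.AVRRPT2,
    "pf0-avrrpt2": Treatment.AVRRPT2,
    "avrrpm1": Treatment.AVRRPM1,
    "pf0-avrrpm1": Treatment.AVRRPM1,
}


def parse_genotype(token: str) -> Genotype:
    key = str(token).strip().lower().replace(" ", "")
    try:
        return _GENOTYPE_TOKENS[key]
    except KeyError:
        raise ValidationError(
            f"unknown genotype {token!r}; allowed tokens include "
            f"{sorted(set(_GENOTYPE_TOKENS))}"
        ) from None


def parse_treatment(token: str) -> Treatment:
    key = str(token).strip().lower().replace(" ", "")
    try:
        return _TREATMENT_TOKENS[key]
    except KeyError:
        raise ValidationError(
            f"unknown treatment {token!r}; allowed tokens include "
            f"{sorted(set(_TREATMENT_TOKENS))}"
        ) from None


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample of the factorial design."""

    sample_id: str
    genotype: Genotype
    treatment: Treatment
    time_hpi: float
    experiment: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.time_hpi not in TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: time_hpi must be one of "
                f"{TIMEPOINTS}, got {self.time_hpi}"
            )
        # Samples at time 0 were collected before any treatment.
        if (self.time_hpi == 0) != (self.treatment is Treatment.NONE):
            raise ValidationError(
                f"sample {self.sample_id!r}: time_hpi = 0 iff treatment = none "
                f"(got time {self.time_hpi}, treatment {self.treatment.value})"
            )
        if self.experiment < 1 or self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: experiment and replicate are >= 1"
            )

    @property
    def condition(self) -> tuple[Genotype, Treatment, float]:
        return (self.genotype, self.treatment, self.time_hpi)


def validate_design(design: Sequence[SampleMeta]) -> None:
    """Check uniqueness of (genotype, treatment, time, experiment, replicate)."""
    seen: set[tuple] = set()
    for s in design:
        key = (s.genotype, s.treatment, s.time_hpi, s.experiment, s.replicate)
        if key in seen:
            raise ValidationError(f"duplicate design cell {key} (sample {s.sample_id!r})")
        seen.add(key)
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in design")


class CountMatrix:
    """Non-negative integer gene x sample expression counts."""

    def __init__(
        self,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        counts: np.ndarray,
    ) -> None:
        self.gene_ids = list(map(str, gene_ids))
        self.sample_ids = list(map(str, sample_ids))
        counts = np.asarray(counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = ~np.isclose(counts, rounded, atol=1e-9) | ~np.isfinite(counts)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count {counts[g, s]!r} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count {counts[g, s]} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.index, df.columns, df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, sample_ids, self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.gene_ids)} genes x {len(self.sample_ids)} samples)"


class Denominator(str, enum.Enum):
    EV_SAME_TIME = "EV_same_time"
    TIME_ZERO = "time_zero"


@dataclass(frozen=True)
class ContrastSpec:
    """A two-condition contrast within one genotype.

    ``EV_same_time`` compares a treatment against the empty-vector
    control at the matched timepoint (the ETI-vs-PTI contrast);
    ``time_zero`` compares against the pre-treatment baseline (the
    PTI-induction contrast).
    """

    label: str
    genotype: Genotype
    time_hpi: float
    numerator_treatment: Treatment
    denominator: Denominator = Denominator.EV_SAME_TIME

    def __post_init__(self) -> None:
        if self.numerator_treatment is Treatment.NONE:
            raise ValidationError("numerator treatment cannot be 'none'")
        if (
            self.denominator is Denominator.EV_SAME_TIME
            and self.numerator_treatment is Treatment.EV
        ):
            raise ValidationError("numerator and denominator conditions coincide")

    @property
    def numerator_condition(self) -> tuple[Genotype, Treatment, float]:
        return (self.genotype, self.numerator_treatment, self.time_hpi)

    @property
    def denominator_condition(self) -> tuple[Genotype, Treatment, float]:
        if self.denominator is Denominator.EV_SAME_TIME:
            return (self.genotype, Treatment.EV, self.time_hpi)
        return (self.genotype, Treatment.NONE, 0.0)


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run.

    alpha_fdr / fc_threshold are the DEG-calling thresholds
    (FDR-adjusted p < alpha and fold change > fc, both strict).
    """

    alpha_fdr: float = 0.05
    fc_threshold: float = 2.0
    min_count_filter: float = 5.0
    seed: int = 1
    top_k_terms: int = 25
    dispersion_shrink: float = 0.5
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ValidationError(f"alpha_fdr must be in (0, 1), got {self.alpha_fdr}")
        if self.fc_threshold <= 1:
            raise ValidationError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if self.min_count_filter < 0:
            raise ValidationError("min_count_filter must be >= 0")
        if self.top_k_terms < 1:
            raise ValidationError("top_k_terms must be >= 1")
        if not 0 <= self.dispersion_shrink <= 1:
            raise ValidationError("dispersion_shrink must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
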