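"""Infection-phenotype statistics.

Disease-index scoring of fungal symptom categories, downy-mildew
sporangiophore binning, bacterial cfu/cm^2 conversion, total ROS burst
(trapezoidal integral of a luminescence time course), and one-way
ANOVA with Tukey's HSD summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import ValidationError

__all__ = [
    "SymptomTally",
    "disease_index",
    "bin_sporangiophores",
    "SPORANGIOPHORE_BINS",
    "PlateCount",
    "cfu_per_cm2",
    "total_ros",
    "anova_tukey",
    "TukeyResult",
]

SYMPTOM_CATEGORIES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SymptomTally:
    """Leaf counts per symptom category 1 (no symptoms) .. 6 (sporulation)."""

    genotype: str
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if set(self.counts) - set(SYMPTOM_CATEGORIES):
            raise ValidationError(
                f"symptom categories must be within {SYMPTOM_CATEGORIES}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative leaf count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def disease_index(tally: SymptomTally, scale: str = "percent") -> float:
    """DI = sum_i i * n_i with n_i the percentage of leaves in category i.

    On the default percentage scale DI ranges from 100 (all leaves
    symptomless) to 600 (all leaves sporulating).  ``scale="fraction"``
    uses leaf fractions instead, giving the 1-6 range some figures use.
    """
    total = tally.total
    if total == 0:
        raise ValidationError("disease index needs at least one leaf")
    unit = 100.0 if scale == "percent" else 1.0
    if scale not in ("percent", "fraction"):
        raise ValidationError(f"unknown scale {scale!r}")
    return float(
        sum(i * unit * tally.counts.get(i, 0) / total for i in SYMPTOM_CATEGORIES)
    )


# sporulation severity bins: none, light (two classes), medium, heavy
SPORANGIOPHORE_BINS: tuple[tuple[int, float], ...] = (
    (0, 0),
    (1, 5),
    (6, 10),
    (11, 15),
    (16, float("inf")),
)
_BIN_LABELS = ("0", "1-5", "6-10", "11-15", ">15")


def bin_sporangiophores(counts: Sequence[int]) -> tuple[dict[str, float], float]:
    """Fractions of cotyledons per sporulation bin, plus the mean count.

    Bins (inclusive integer bounds): 0, 1-5, 6-10, 11-15, >15.  The mean
    sporangiophores/cotyledon is rounded to two decimals.
    """
    if len(counts) == 0:
        raise ValidationError("need at least one cotyledon")
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValidationError("negative sporangiophore count")
    n = len(arr)
    fractions = {}
    for label, (lo, hi) in zip(_BIN_LABELS, SPORANGIOPHORE_BINS):
        fractions[label] = float(((arr >= lo) & (arr <= hi)).sum() / n)
    return fractions, float(round(arr.mean(), 2))


@dataclass(frozen=True)
class PlateCount:
    """One dilution-plating observation from a leaf-disc extract."""

    colonies: int
    dilution_exponent: int  # e.g. -3 for a 10^-3 dilution
    plated_volume: float  # same unit as extract_volume
    extract_volume: float
    disc_area: float  # cm^2

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValidationError("negative colony count")
        if self.dilution_exponent > 0:
            raise ValidationError("dilution exponent must be <= 0")
        if min(self.plated_volume, self.extract_volume, self.disc_area) <= 0:
            raise ValidationError("volumes and disc area must be > 0")


def cfu_per_cm2(plate: PlateCount) -> float:
    """Colony-forming units per cm^2 of leaf tissue.

    cfu/cm^2 = colonies * 10^(-dilution) * (extract/plated volume) / area.
    """
    return (
        plate.colonies
        * 10.0 ** (-plate.dilution_exponent)
        * (plate.extract_volume / plate.plated_volume)
        / plate.disc_area
    )


def total_ros(timeseries: Sequence[tuple[float, float]]) -> float:
    """Total ROS burst: trapezoidal integral of luminescence over time."""
    if len(timeseries) < 2:
        raise ValidationError("need >= 2 time points")
    t = np.asarray([p[0] for p in timeseries], dtype=float)
    y = np.asarray([p[1] for p in timeseries], dtype=float)
    if (np.diff(t) < 0).any():
        raise ValidationError("time points must be non-decreasing")
    return float(np.trapezoid(y, t))


@dataclass
class TukeyResult:
    f_stat: float
    p_value: float
    significant_pairs: set[frozenset[str]]
    letters: dict[str, str]


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA plus Tukey HSD with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} has < 2 observations")
    labels = list(groups)
    f_stat, p_value = stats.f_oneway(*(np.asarray(groups[g], float) for g in labels))

    values = np.concatenate([np.asarray(groups[g], float) for g in labels])
    tags = np.concatenate([[g] * len(groups[g]) for g in labels])
    hsd = pairwise_tukeyhsd(values, tags, alpha=alpha)
    sig = {
        frozenset((a, b))
        for (a, b), rej in zip(
            ((r[0], r[1]) for r in hsd.summary().data[1:]), hsd.reject
        )
        if rej
    }
    letters = _compact_letter_display(labels, sig, order_by=lambda g: -np.mean(groups[g]))
    return TukeyResult(float(f_stat), float(p_value), sig, letters)


def _compact_letter_display(
    labels: Sequence[str],
    significant_pairs: set[frozenset[str]],
    order_by=None,
) -> dict[str, str]:
    """Sweep-and-absorb construction of a compact letter display.

    Start with one letter covering all groups; every significant pair
    splits any letter containing both; subset letters are absorbed.
    """
    ordered = sorted(labels, key=order_by) if order_by else list(labels)
    letter_sets: list[set[str]] = [set(ordered)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            letter_sets.extend([s - {a}, s - {b}])
        # absorb: drop empty sets and sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(letter_sets)
            if s
            and not any(
                (s < t) or (s == t and i > j) for j, t in enumerate(letter_sets) if i != j
            )
        ]
    kept = sorted(letter_sets, key=lambda s: min(ordered.index(l) for l in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, kept):
        for lab in ordered:
            if lab in s:
                out[lab] += letter
    return out
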