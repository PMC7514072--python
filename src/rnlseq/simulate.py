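"""Synthetic factorial RNA-seq counts with planted immunity genes.

The generator plants three gene classes — background, PTI-induced
(responding to any Pf0-1 infiltration, including the empty-vector
control) and ETI genes (responding to specific delivered effectors on
top of the PTI response) — and stamps each ETI gene with one of five
helper-NLR dependency categories.  The category determines in which
mutant backgrounds the effector response survives, which is exactly
the decision table the classifier inverts, so recovery of the planted
labels is a meaningful end-to-end benchmark.

Counts are negative-binomial with variance mu + alpha * mu^2
(gamma-Poisson mixture), per-sample library-size factors, and a
per-experiment log-normal batch factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rio
from .model import (
    CATEGORY_GENOTYPES,
    EFFECTORS,
    CountMatrix,
    Genotype,
    RNLCategory,
    SampleMeta,
    Treatment,
    ValidationError,
    validate_design,
)

__all__ = [
    "GeneTruth",
    "SimParams",
    "default_design",
    "plant_truth",
    "simulate_counts",
    "nb_sample",
    "write_fixture",
    "read_truth",
]

# Five-way category mix among planted ETI genes, echoing the observed
# split of AvrRps4-induced genes at 8 hpi (45 + 512 + 330 + 407 + 155
# of 1,449): almost fully RNL-dependent, shared regulation dominating,
# ADR1-specific outweighing NRG1-specific.
DEFAULT_RNL_PROPORTIONS: dict[str, float] = {
    RNLCategory.RNL_INDEPENDENT.value: 45 / 1449,
    RNLCategory.SYNERGISTIC.value: 512 / 1449,
    RNLCategory.REDUNDANT.value: 330 / 1449,
    RNLCategory.ADR1_SPECIFIC.value: 407 / 1449,
    RNLCategory.NRG1_SPECIFIC.value: 155 / 1449,
}

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "background": 0.75,
    "PTI_induced": 0.10,
    "ETI": 0.15,
}


@dataclass(frozen=True)
class GeneTruth:
    """Planted ground truth for one gene."""

    gene_id: str
    klass: str  # background | PTI_induced | ETI
    effector_scope: frozenset[Treatment] = frozenset()
    rnl_category: RNLCategory | None = None
    direction: str = "up"
    log2_effect: float = 0.0
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    onset_hpi: float = 4.0

    def __post_init__(self) -> None:
        if self.klass not in ("background", "PTI_induced", "ETI"):
            raise ValidationError(f"unknown gene class {self.klass!r}")
        if self.klass == "background" and self.log2_effect != 0:
            raise ValidationError("background genes carry zero effect")
        if self.klass == "ETI" and self.rnl_category is None:
            raise ValidationError("ETI genes need an rnl_category")
        if self.klass != "ETI" and self.rnl_category is not None:
            raise ValidationError("rnl_category is ETI-only")
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up/down, got {self.direction!r}")


@dataclass
class SimParams:
    """Knobs of the count simulator; defaults are the test-scale study design."""

    n_genes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    rnl_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RNL_PROPORTIONS)
    )
    effect_range: tuple[float, float] = (2.0, 4.0)  # log2 units
    direction_up_prob: float = 0.8
    # dispersion trend alpha(mu) = a0 + s / mu
    dispersion_model: tuple[float, float] = (0.05, 1.0)
    signal_baseline_range: tuple[float, float] = (50.0, 500.0)
    background_baseline_log_mean: float = 3.5  # ln scale
    background_baseline_log_sd: float = 1.2
    library_size_range: tuple[float, float] = (0.7, 1.3)
    batch_sd: float = 0.1
    pti_boost_log2: float = 0.5  # over-induction of PTI genes under effector delivery
    eti_onset_probs: dict[float, float] = field(
        default_factory=lambda: {4.0: 0.6, 8.0: 0.4}
    )
    seed: int = 1

    def __post_init__(self) -> None:
        for name, props in (
            ("class_proportions", self.class_proportions),
            ("rnl_proportions", self.rnl_proportions),
        ):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {sum(props.values())})")
            if any(v < 0 for v in props.values()):
                raise ValidationError(f"{name} contains negative entries")
        if self.effect_range[0] < 0:
            raise ValidationError("effect_range lower bound must be >= 0")
        if self.batch_sd < 0:
            raise ValidationError("batch_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eti_onset_probs"] = {str(k): v for k, v in self.eti_onset_probs.items()}
        return d


def default_design(
    n_experiments: int = 3, samples_per_experiment: int = 2
) -> list[SampleMeta]:
    """The study's factorial design: 4 genotypes x (time-0 baseline +
    {EV, AvrRps4, AvrRpt2, AvrRpm1} x {0.5, 4, 8} hpi) x replicates."""
    design: list[SampleMeta] = []
    conditions: list[tuple[Treatment, float]] = [(Treatment.NONE, 0.0)]
    for trt in (Treatment.EV, *EFFECTORS):
        for t in (0.5, 4.0, 8.0):
            conditions.append((trt, t))
    for g in Genotype:
        for trt, t in conditions:
            for e in range(1, n_experiments + 1):
                for r in range(1, samples_per_experiment + 1):
                    tstr = f"{t:g}".replace(".", "p")
                    design.append(
                        SampleMeta(
                            sample_id=f"{g.value}_{trt.value}_{tstr}_e{e}_r{r}",
                            genotype=g,
                            treatment=trt,
                            time_hpi=t,
                            experiment=e,
                            replicate=r,
                        )
                    )
    validate_design(design)
    return design


def _largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer apportionment of n items to categories (deterministic)."""
    keys = list(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def plant_truth(params: SimParams) -> list[GeneTruth]:
    """Assign every gene a class, category, direction and effect size."""
    rng = np.random.default_rng(params.seed)
    counts = _largest_remainder(params.n_genes, params.class_proportions)
    n_eti = counts.get("ETI", 0)
    rnl_counts = _largest_remainder(n_eti, params.rnl_proportions) if n_eti else {}
    a0, s = params.dispersion_model
    width = len(str(params.n_genes))

    klasses: list[str] = []
    for k in ("background", "PTI_induced", "ETI"):
        klasses += [k] * counts.get(k, 0)

    rnl_labels: list[RNLCategory] = []
    for cat_name, c in rnl_counts.items():
        rnl_labels += [RNLCategory(cat_name)] * c

    truths: list[GeneTruth] = []
    i_eti = 0
    onsets = list(params.eti_onset_probs)
    onset_p = np.array([params.eti_onset_probs[t] for t in onsets])
    onset_p = onset_p / onset_p.sum()
    for i, klass in enumerate(klasses):
        gene_id = f"g{i + 1:0{width}d}"
        if klass == "background":
            base = float(
                np.exp(
                    rng.normal(
                        params.background_baseline_log_mean,
                        params.background_baseline_log_sd,
                    )
                )
            )
            truths.append(
                GeneTruth(
                    gene_id=gene_id,
                    klass="background",
                    baseline_mean=base,
                    dispersion=a0 + s / base,
                )
            )
            continue
        lo, hi = params.signal_baseline_range
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        effect = float(rng.uniform(*params.effect_range))
        direction = "up" if rng.random() < params.direction_up_prob else "down"
        if klass == "PTI_induced":
            truths.append(
                GeneTruth(
                    gene_id=gene_id,
                    klass="PTI_induced",
                    effector_scope=frozenset(EFFECTORS),
                    direction=direction,
                    log2_effect=effect,
                    baseline_mean=base,
                    dispersion=a0 + s / base,
                    onset_hpi=0.5,
                )
            )
        else:
            n_scope = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
            scope = frozenset(
                rng.choice(
                    [t.value for t in EFFECTORS], size=n_scope, replace=False
                ).tolist()
            )
            onset = float(onsets[int(rng.choice(len(onsets), p=onset_p))])
            truths.append(
                GeneTruth(
                    gene_id=gene_id,
                    klass="ETI",
                    effector_scope=frozenset(Treatment(t) for t in scope),
                    rnl_category=rnl_labels[i_eti],
                    direction=direction,
                    log2_effect=effect,
                    baseline_mean=base,
                    dispersion=a0 + s / base,
                    onset_hpi=onset,
                )
            )
            i_eti += 1
    return truths


def nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray, size=None
) -> np.ndarray:
    """Negative-binomial draws with variance mu + alpha * mu^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pos = dispersion > 0
    if pos.any():
        shape = 1.0 / dispersion[pos]
        lam = rng.gamma(shape=shape, scale=mean[pos] * dispersion[pos])
        out[pos] = rng.poisson(lam)
    if (~pos).any():
        out[~pos] = rng.poisson(mean[~pos])
    return out


def _log2_effect(truth: GeneTruth, sample: SampleMeta, pti_boost: float) -> float:
    """Planted log2 shift of gene ``truth`` in sample ``sample``."""
    sign = 1.0 if truth.direction == "up" else -1.0
    t, trt, g = sample.time_hpi, sample.treatment, sample.genotype
    if truth.klass == "background" or trt is Treatment.NONE:
        return 0.0
    if truth.klass == "PTI_induced":
        if t < truth.onset_hpi:
            return 0.0
        e = truth.log2_effect
        if trt in truth.effector_scope:
            e += pti_boost  # over-induction under effector delivery
        return sign * e
    # ETI: effector response on top of (absent) PTI component, present only
    # in the genotypes where the gene's category leaves the pathway intact.
    if (
        trt in truth.effector_scope
        and t >= truth.onset_hpi
        and g in CATEGORY_GENOTYPES[truth.rnl_category]
    ):
        return sign * truth.log2_effect
    return 0.0


def simulate_counts(
    truth: Sequence[GeneTruth],
    design: Sequence[SampleMeta],
    params: SimParams,
) -> CountMatrix:
    """Draw NB counts for every gene x sample of the design."""
    if not design:
        raise ValidationError("design is empty")
    ids = [t.gene_id for t in truth]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids in truth")
    validate_design(list(design))
    rng = np.random.default_rng(params.seed + 1)  # independent of plant_truth stream

    n_g, n_s = len(truth), len(design)
    lib = rng.uniform(*params.library_size_range, size=n_s)
    experiments = sorted({s.experiment for s in design})
    batch_factor = {
        e: float(np.exp(rng.normal(0.0, params.batch_sd))) for e in experiments
    }
    sample_factor = np.array(
        [lib[j] * batch_factor[design[j].experiment] for j in range(n_s)]
    )

    base = np.array([t.baseline_mean for t in truth])
    disp = np.array([t.dispersion for t in truth])
    eff = np.zeros((n_g, n_s))
    for i, t in enumerate(truth):
        if t.klass == "background":
            continue
        for j, s in enumerate(design):
            eff[i, j] = _log2_effect(t, s, params.pti_boost_log2)
    mean = base[:, None] * sample_factor[None, :] * np.exp2(eff)
    counts = nb_sample(rng, mean, disp[:, None] * np.ones((1, n_s)))
    return CountMatrix(ids, [s.sample_id for s in design], counts)


def write_fixture(
    truth: Sequence[GeneTruth],
    counts: CountMatrix,
    design: Sequence[SampleMeta],
    out_dir: str | Path,
    params: SimParams | None = None,
) -> dict[str, Path]:
    """Write counts.tsv / metadata.tsv / truth.tsv (+ params.json)."""
    if not truth:
        raise ValidationError("empty truth list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    rio.write_counts(counts, paths["counts"])
    rio.write_metadata(design, paths["metadata"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            "gene_id\tklass\teffector_scope\trnl_category\tdirection\t"
            "log2_effect\tbaseline_mean\tdispersion\tonset_hpi\n"
        )
        for t in truth:
            scope = ",".join(sorted(e.value for e in t.effector_scope)) or "-"
            cat = t.rnl_category.value if t.rnl_category else "-"
            fh.write(
                f"{t.gene_id}\t{t.klass}\t{scope}\t{cat}\t{t.direction}\t"
                f"{t.log2_effect:.17g}\t{t.baseline_mean:.17g}\t"
                f"{t.dispersion:.17g}\t{t.onset_hpi:g}\n"
            )
    if params is not None:
        paths["params"] = out / "params.json"
        with open(paths["params"], "w") as fh:
            json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return paths


def read_truth(path: str | Path) -> list[GeneTruth]:
    """Read a truth.tsv written by :func:`write_fixture`."""
    truths = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        row = dict(zip(header, ln.split("\t")))
        scope = frozenset(
            Treatment(t) for t in row["effector_scope"].split(",") if t and t != "-"
        )
        cat = None if row["rnl_category"] == "-" else RNLCategory(row["rnl_category"])
        truths.append(
            GeneTruth(
                gene_id=row["gene_id"],
                klass=row["klass"],
                effector_scope=scope,
                rnl_category=cat,
                direction=row["direction"],
                log2_effect=float(row["log2_effect"]),
                baseline_mean=float(row["baseline_mean"]),
                dispersion=float(row["dispersion"]),
                onset_hpi=float(row["onset_hpi"]),
            )
        )
    return truths
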