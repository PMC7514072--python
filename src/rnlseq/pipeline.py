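"""Pipeline orchestration: simulate/read -> DE -> classify -> enrich -> report.

Every stage writes plain TSV/JSON files so any stage can be re-run
standalone; a JSON manifest records the effective configuration, input
digests, stage timings and output inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import classify as rc
from . import diffexpr as de
from . import io as rio
from . import simulate as sim
from .model import (
    EFFECTORS,
    ETI_TIMEPOINTS,
    ContrastSpec,
    CountMatrix,
    Denominator,
    Genotype,
    RunConfig,
    SampleMeta,
    Treatment,
    ValidationError,
)

logger = logging.getLogger("rnlseq")

__all__ = [
    "compute_deg_calls",
    "pca_qc",
    "table1_report",
    "run_pipeline",
    "recovery_metrics",
    "RunManifest",
]


def compute_deg_calls(
    cm: CountMatrix,
    design: Sequence[SampleMeta],
    config: RunConfig,
    effectors: Sequence[Treatment] = EFFECTORS,
    pti_times: Sequence[float] = (0.5, 4.0, 8.0),
) -> dict[rc.DEGKey, de.DirectionalGeneSet]:
    """All DEG sets the classifier needs.

    EV keys hold the EV-vs-time-0 (PTI induction) DEG sets; effector
    keys hold the effector-vs-EV (ETI) DEG sets at 4 and 8 hpi.
    """
    factors = de.size_factors(cm, pseudo_reference=True)
    dispersions = de.estimate_dispersion(cm, design, factors, shrink=config.dispersion_shrink)
    calls: dict[rc.DEGKey, de.DirectionalGeneSet] = {}
    contrasts: list[ContrastSpec] = []
    for g in Genotype:
        for t in pti_times:
            contrasts.append(
                ContrastSpec(
                    label=f"{g.value}_EV_{t:g}_vs_t0",
                    genotype=g,
                    time_hpi=t,
                    numerator_treatment=Treatment.EV,
                    denominator=Denominator.TIME_ZERO,
                )
            )
        for eff in effectors:
            for t in ETI_TIMEPOINTS:
                contrasts.append(
                    ContrastSpec(
                        label=f"{g.value}_{eff.value}_{t:g}_vs_EV",
                        genotype=g,
                        time_hpi=t,
                        numerator_treatment=eff,
                    )
                )
    for spec in contrasts:
        table = de.nb_wald_test(
            cm, design, factors, dispersions, spec, min_count_filter=config.min_count_filter
        )
        up, down = de.call_degs(table, config, label=spec.label, contrast=spec)
        key_trt = spec.numerator_treatment
        calls[(spec.genotype, key_trt, spec.time_hpi, "up")] = up
        calls[(spec.genotype, key_trt, spec.time_hpi, "down")] = down
    return calls


def pca_qc(
    zscores: pd.DataFrame, design: Sequence[SampleMeta], n_top_genes: int = 2000
) -> pd.DataFrame:
    """Sample coordinates on the first two principal components.

    Computed on the z-score matrix restricted to ``n_top_genes`` genes
    with the largest dynamic range across samples (z-scoring equalizes
    per-gene variance, so range is the remaining variability proxy).
    """
    if zscores.shape[1] < 3:
        raise ValidationError("PCA QC needs >= 3 samples")
    arr = zscores.to_numpy()
    if zscores.shape[0] > n_top_genes:
        spread = np.ptp(arr, axis=1)
        keep = np.argsort(-spread, kind="stable")[:n_top_genes]
        arr = arr[keep]
    mat = arr.T  # samples x genes
    pca = PCA(n_components=2)
    coords = pca.fit_transform(mat - mat.mean(axis=0, keepdims=True))
    meta = {s.sample_id: s for s in design}
    rows = []
    for sid, (pc1, pc2) in zip(zscores.columns, coords):
        s = meta[sid]
        rows.append(
            {
                "sample_id": sid,
                "PC1": pc1,
                "PC2": pc2,
                "genotype": s.genotype.value,
                "treatment": s.treatment.value,
                "time_hpi": s.time_hpi,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["variance_explained"] = pca.explained_variance_ratio_.tolist()
    return out


def recovery_metrics(
    truth: Sequence[sim.GeneTruth],
    calls: Mapping[rc.DEGKey, de.DirectionalGeneSet],
    effectors: Sequence[Treatment] = EFFECTORS,
) -> dict[str, float]:
    """Benchmark classification against planted ETI truth.

    A planted ETI gene is *eligible* in every (effector, time,
    direction) cell where its scope, onset and direction apply; it is
    *recovered* when the wild-type effector-vs-EV DEG call picks it up.
    Returns the recall (recovered/eligible), the five-way category
    accuracy among recovered genes, and the binary RNL-dependent vs
    RNL-independent accuracy among recovered genes.
    """
    n_eligible = n_recovered = n_correct5 = n_correct_dep = 0
    for eff in effectors:
        for t in ETI_TIMEPOINTS:
            for d in ("up", "down"):
                assignments = rc.assign_categories(rc.status_vectors(calls, eff, t, d))
                for tr in truth:
                    if (
                        tr.klass != "ETI"
                        or eff not in tr.effector_scope
                        or t < tr.onset_hpi
                        or tr.direction != d
                    ):
                        continue
                    n_eligible += 1
                    cat = assignments.get(tr.gene_id)
                    if cat is None:
                        continue
                    n_recovered += 1
                    n_correct5 += cat is tr.rnl_category
                    indep = rc.RNLCategory.RNL_INDEPENDENT
                    n_correct_dep += (cat is indep) == (tr.rnl_category is indep)
    return {
        "n_eligible": n_eligible,
        "n_recovered": n_recovered,
        "recall": n_recovered / n_eligible if n_eligible else float("nan"),
        "five_way_accuracy": n_correct5 / n_recovered if n_recovered else float("nan"),
        "dependency_accuracy": n_correct_dep / n_recovered if n_recovered else float("nan"),
    }


_T1_ROWS = (
    ("RNL dependent", "n_rnl_dependent", "n_eti", "rnl_dependent_pct"),
    ("Shared regulation", "n_shared", "n_rnl_dependent", "shared_pct"),
    ("Synergistic", "n_synergistic", "n_rnl_dependent", "synergistic_pct"),
    ("Redundant", "n_redundant", "n_rnl_dependent", "redundant_pct"),
    ("Specific regulation", "n_specific", "n_rnl_dependent", "specific_pct"),
    ("ADR1s specific", "n_adr1_specific", "n_specific", "adr1_of_specific_pct"),
    ("NRG1s specific", "n_nrg1_specific", "n_specific", "nrg1_of_specific_pct"),
)


def _cell(report: rc.FractionReport, num_attr: str, den_attr: str, pct_attr: str) -> str:
    pct = getattr(report, pct_attr)
    if pct is None:
        return "-"
    num = getattr(report, num_attr)
    den = getattr(report, den_attr)
    return f"{pct:.1f}%({num:,}/{den:,})"


def table1_report(reports: Sequence[rc.FractionReport]) -> pd.DataFrame:
    """Fraction table per effector x time: cells ``pct%(num/den)``."""
    if not reports:
        raise ValidationError("table1_report needs >= 1 report")
    cols = {}
    for rep in reports:
        name = f"{rep.effector.value} {rep.time_hpi:g} hpi"
        cols[name] = [_cell(rep, *row[1:]) for row in _T1_ROWS]
    return pd.DataFrame(cols, index=[row[0] for row in _T1_ROWS])


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "inputs": self.inputs,
                "stage_seconds": self.stage_seconds,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    sim_params: sim.SimParams | None = None,
    effectors: Sequence[Treatment] = EFFECTORS,
) -> RunManifest:
    """Execute simulate/read -> DE -> classify -> report and write outputs.

    When counts/metadata paths are configured they are read; otherwise a
    synthetic fixture is generated with ``sim_params`` (defaults seeded
    from the run config).
    """
    if config.out_dir is None:
        raise ValidationError("run_pipeline requires out_dir")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    def stage(name):
        class _T:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()

            def __exit__(self_t, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_t.t0, 3)
                if exc is not None:
                    logger.error("stage %r failed: %s", name, exc)

        return _T()

    truth = None
    with stage("read"):
        if config.counts_path and config.metadata_path:
            cm = rio.read_counts(config.counts_path)
            design = rio.read_metadata(config.metadata_path)
            manifest.inputs["counts"] = _digest(Path(config.counts_path))
            manifest.inputs["metadata"] = _digest(Path(config.metadata_path))
        else:
            params = sim_params or sim.SimParams(seed=config.seed)
            truth = sim.plant_truth(params)
            design = sim.default_design()
            cm = sim.simulate_counts(truth, design, params)
            paths = sim.write_fixture(truth, cm, design, out / "fixture", params)
            manifest.inputs = {k: _digest(p) for k, p in paths.items()}

    with stage("de"):
        calls = compute_deg_calls(cm, design, config, effectors=effectors)
        factors = de.size_factors(cm, pseudo_reference=True)
        z = de.vst_zscore(cm, factors)

    with stage("classify"):
        reports = []
        assignment_rows = []
        for eff in effectors:
            for t in ETI_TIMEPOINTS:
                for direction in ("up", "down"):
                    vectors = rc.status_vectors(calls, eff, t, direction)
                    assignments = rc.assign_categories(vectors)
                    reports.append(rc.fraction_report(assignments, eff, t, direction))
                    for gene, cat in sorted(assignments.items()):
                        assignment_rows.append(
                            (gene, eff.value, t, direction, cat.value)
                        )

    with stage("report"):
        table = table1_report([r for r in reports if r.direction == "up"])
        table.to_csv(out / "table1_up.tsv", sep="\t", lineterminator="\n")
        pd.DataFrame(
            assignment_rows,
            columns=["gene_id", "effector", "time_hpi", "direction", "category"],
        ).to_csv(out / "assignments.tsv", sep="\t", index=False, lineterminator="\n")
        frac_rows = []
        for r in reports:
            frac_rows.append(
                {
                    "effector": r.effector.value,
                    "time_hpi": r.time_hpi,
                    "direction": r.direction,
                    "n_eti": r.n_eti,
                    "n_rnl_independent": r.n_rnl_independent,
                    "n_rnl_dependent": r.n_rnl_dependent,
                    "n_synergistic": r.n_synergistic,
                    "n_redundant": r.n_redundant,
                    "n_adr1_specific": r.n_adr1_specific,
                    "n_nrg1_specific": r.n_nrg1_specific,
                }
            )
        pd.DataFrame(frac_rows).to_csv(
            out / "fractions.tsv", sep="\t", index=False, lineterminator="\n"
        )
        # wild-type vs helperless overlap per effector/time, plus the
        # three-effector overlap of wild-type ETI sets at 8 hpi
        venn_rows = []
        for eff in effectors:
            for t in ETI_TIMEPOINTS:
                col0 = rc.eti_regulated(calls, Genotype.COL0, eff, t, "up")
                hl = rc.eti_regulated(calls, Genotype.HELPERLESS, eff, t, "up")
                for mask, n in rc.venn_counts([col0, hl]).items():
                    venn_rows.append(
                        {
                            "comparison": f"col0_vs_helperless_{eff.value}_{t:g}",
                            "region": "".join("1" if m else "0" for m in mask),
                            "n": n,
                        }
                    )
        if len(effectors) == 3:
            sets8 = [
                rc.eti_regulated(calls, Genotype.COL0, eff, 8.0, "up") for eff in effectors
            ]
            for mask, n in rc.venn_counts(sets8).items():
                venn_rows.append(
                    {
                        "comparison": "col0_three_effectors_8hpi",
                        "region": "".join("1" if m else "0" for m in mask),
                        "n": n,
                    }
                )
        pd.DataFrame(venn_rows).to_csv(
            out / "venn.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with stage("qc"):
        coords = pca_qc(z, design)
        coords.to_csv(out / "pca.tsv", sep="\t", index=False, lineterminator="\n")
        z.round(4).to_csv(out / "zscores.tsv", sep="\t", lineterminator="\n")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _digest(p)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
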