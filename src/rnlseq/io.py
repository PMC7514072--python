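"""Readers and writers for the pipeline's plain-text interchange formats.

Counts travel as a gene x sample TSV (leading header cell ``gene_id``)
or as a MatrixMarket-style triplet file with companion gene/sample
index files; metadata as TSV; gene sets as GMT; term annotations as a
two-column TSV; configuration as a flat key: value document.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CountMatrix,
    RunConfig,
    SampleMeta,
    ValidationError,
    parse_genotype,
    parse_treatment,
    validate_design,
)

logger = logging.getLogger("rnlseq")

_META_COLUMNS = ("sample_id", "genotype", "treatment", "time_hpi", "experiment", "replicate")


def read_counts(path: str | os.PathLike, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from ``tsv`` or ``mtx_triplet`` format.

    For triplet format, ``path`` names the triplet file and companion
    ``<stem>.genes.txt`` / ``<stem>.samples.txt`` files hold the row
    and column identifiers, one per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals % 1 != 0)
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValidationError(
                    f"non-integer count {df.loc[gene, col]!r} at gene {gene!r}, "
                    f"sample {col!r} in {path}"
                )
        cm = CountMatrix(df.index, df.columns, df.to_numpy(dtype=np.int64))
    elif format == "mtx_triplet":
        genes = _read_lines(path.with_suffix(".genes.txt"))
        samples = _read_lines(path.with_suffix(".samples.txt"))
        mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 3:
                raise ValidationError(f"{path}: expected 'n_genes n_samples nnz' header")
            for line in fh:
                if not line.strip():
                    continue
                i, j, v = line.split()
                fi, fj, fv = int(i) - 1, int(j) - 1, int(v)
                if fv < 0:
                    raise ValidationError(
                        f"negative count {fv} at gene {genes[fi]!r}, sample {samples[fj]!r}"
                    )
                mat[fi, fj] = fv
        cm = CountMatrix(genes, samples, mat)
    else:
        raise ValidationError(f"unknown counts format {format!r}")
    logger.info("read counts %s: %d genes x %d samples", path, *cm.shape)
    return cm


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"companion index file missing: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_counts(cm: CountMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = cm.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n")
    elif format == "mtx_triplet":
        path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
        gi, sj = np.nonzero(cm.counts)
        with open(path, "w") as fh:
            fh.write(f"{len(cm.gene_ids)} {len(cm.sample_ids)} {len(gi)}\n")
            for i, j in zip(gi, sj):
                fh.write(f"{i + 1} {j + 1} {cm.counts[i, j]}\n")
    else:
        raise ValidationError(f"unknown counts format {format!r}")


def read_metadata(path: str | os.PathLike) -> list[SampleMeta]:
    """Read and validate the sample table (TSV).

    Required columns: sample_id, genotype, treatment, time_hpi.
    Missing experiment/replicate columns default to 1 with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "genotype", "treatment", "time_hpi"):
        if col not in df.columns:
            raise ValidationError(f"metadata {path}: missing required column {col!r}")
    for col in ("experiment", "replicate"):
        if col not in df.columns:
            logger.warning("metadata %s: column %r absent, defaulting to 1", path, col)
            df[col] = "1"
    records = [
        SampleMeta(
            sample_id=str(row.sample_id),
            genotype=parse_genotype(row.genotype),
            treatment=parse_treatment(row.treatment),
            time_hpi=float(row.time_hpi),
            experiment=int(row.experiment),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]
    validate_design(records)
    return records


def write_metadata(design: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "genotype": [s.genotype.value for s in design],
            "treatment": [s.treatment.value for s in design],
            "time_hpi": [s.time_hpi for s in design],
            "experiment": [s.experiment for s in design],
            "replicate": [s.replicate for s in design],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_config(path: str | os.PathLike | None = None) -> RunConfig:
    """Load a flat key: value configuration file; absent keys take defaults."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw) if raw.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config {path}: expected flat key: value pairs")
        data = loaded
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"config: unknown keys {sorted(unknown)}")
    cfg = RunConfig(**data)
    logger.info("effective config: %s", cfg.to_dict())
    return cfg


def read_gene_sets(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line with < 3 fields: {ln[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        sets[name] = set(g for g in parts[2:] if g)
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | os.PathLike,
                    descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_annotation(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column term_id <tab> gene_id table into term -> genes."""
    ann: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"annotation line with < 2 fields: {ln[:60]!r}")
        ann.setdefault(parts[0], set()).add(parts[1])
    return ann
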