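# rnlseq

Factorial RNA-seq analysis of helper-NLR dependency in plant immunity.

Plant intracellular immune receptors (NLRs) that sense pathogen
effectors rely on two "helper" NLR families of the RNL subclass — the
ADR1s and the NRG1s — to mount effector-triggered immunity (ETI).
`rnlseq` implements the transcriptome-epistasis analysis that
quantifies this reliance gene by gene: given counts from a 4-genotype
(wild-type Col-0, *adr1 triple*, *nrg1.1 nrg1.2*, pentuple
*helperless*) × 4-treatment (*Pf0-1* empty vector, AvrRps4, AvrRpt2,
AvrRpm1) × 4-timepoint (0, 0.5, 4, 8 hpi) design, it

- performs negative-binomial differential expression (median-of-ratios
  size factors, method-of-moments dispersion with trend shrinkage, a
  per-gene Wald test), calling DEGs at FDR-adjusted *p* < 0.05 and
  fold change > 2;
- derives PTI-induced sets (empty vector vs time 0) and ETI-regulated
  sets (effector vs empty vector at a matched timepoint);
- classifies every ETI-regulated gene into five dependency categories
  from its DE status across the four genotypes:

  | DE in Col-0 | DE in *adr1* | DE in *nrg1* | DE in *helperless* | category |
  |---|---|---|---|---|
  | yes | yes | yes | yes | RNL-independent |
  | yes | no  | no  | no  | synergistic (needs both families) |
  | yes | yes | yes | no  | redundant (either family suffices) |
  | yes | no  | yes | no  | ADR1-specific |
  | yes | yes | no  | no  | NRG1-specific |

- reports category fractions per effector × timepoint × direction
  (counts and one-decimal percentages), Venn overlap counts, PCA QC
  coordinates, hypergeometric GO-term over-representation, and the
  infection-phenotype statistics (disease index DI = Σ i·nᵢ,
  sporangiophore binning, cfu/cm², total ROS, one-way ANOVA + Tukey
  HSD letter displays).

A synthetic-data generator plants PTI and ETI genes with known
dependency categories in NB-distributed counts, so the whole pipeline
is benchmarked end to end against planted truth without external data.

## Worked example

```python
from rnlseq import classify as rc, pipeline as pl, simulate as sim
from rnlseq.model import RunConfig, Treatment

params = sim.SimParams(seed=1)          # 2,000 genes, planted categories
truth = sim.plant_truth(params)
design = sim.default_design()           # 312 samples: 4 x 13 x 6
counts = sim.simulate_counts(truth, design, params)

calls = pl.compute_deg_calls(counts, design, RunConfig(seed=1))
vectors = rc.status_vectors(calls, Treatment.AVRRPS4, 8.0, "up")
report = rc.fraction_report(rc.assign_categories(vectors),
                            Treatment.AVRRPS4, 8.0, "up")
print(pl.table1_report([report]))
```

prints

```
                      AvrRps4 8 hpi
RNL dependent        95.3%(123/129)
Shared regulation     60.2%(74/123)
Synergistic           41.5%(51/123)
Redundant             18.7%(23/123)
Specific regulation   39.8%(49/123)
ADR1s specific         67.3%(33/49)
NRG1s specific         32.7%(16/49)
```

i.e. of the 129 genes up-regulated by AvrRps4 delivery at 8 hpi in the
simulated wild type, 95.3% require at least one helper family, 60% are
shared between families (synergistic + redundant), and ADR1s dominate
the family-specific remainder — mirroring the planted category mix.
The same run recovers the planted five-way category of every recovered
ETI gene (`pl.recovery_metrics`).

The equivalent shell pipeline is `rnlseq run --seed 1 --out runs/demo`
(stage outputs and a digest manifest land in `runs/demo`); see
`rnlseq --help` for the `simulate`, `de`, `classify`, `enrich` and
`pheno` subcommands.

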