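# stableref

Reference-gene (housekeeping-gene) discovery, validation and use for
transcriptomics. Accurate RT-qPCR and ratio-based expression analysis both
depend on internal-control genes whose expression is genuinely stable across
the conditions under study — and the classic controls (UBQ, Actin, tubulin,
EF1α, 18S rRNA) frequently are not. `stableref` implements the full workflow
for finding better ones from data you already have:

1. **Genome-wide screening** of an RNA-seq expression matrix (FPKM or
   counts) for stably expressed transcripts, using the coefficient of
   variation (CV = SD/mean, in %), the maximum fold change
   (MFC = max/min over samples), constitutive detection in every sample,
   a mean-expression window, and isoform uniqueness from a GTF annotation.
   The default filter keeps a transcript iff it is detected everywhere,
   MFC < 2, and CV < 20 % (or |CV| of log₂ expression < 5 %).
2. **RT-qPCR validation** of a candidate panel from Cq values: assay QC
   (efficiency > 1.8, calibration R² > 0.99, Cq < 40), then the four
   standard stability algorithms —

   * geNorm: M_j = mean over partners k of SD_samples[log₂(q_j/q_k)], with
     stepwise exclusion and the pairwise-variation curve V(n/n+1)
     (cutoff 0.15) for the optimal number of reference genes;
   * comparative ΔCt: mean over partners of SD_samples[Cq_j − Cq_k];
   * BestKeeper: Cq dispersion (MAD from the mean) plus the per-sample
     geometric-mean index and each gene's correlation with it;
   * NormFinder: model-based intra-group variance + shrunken inter-group
     bias on −Cq;

   aggregated into a consensus by the geometric mean of the four ordinal
   ranks.
3. **Normalization and DE calling**: per-sample normalization factors as the
   geometric mean of the chosen reference genes, and strict fold-change
   (FC > 2) up/down calls between condition groups, with a concordance
   summary against any external DE table.

A synthetic-data module generates FPKM matrices and Cq panels with known
ground truth under the emulated study design (2 tissues × infected/control ×
3 replicates), so every stage is testable end to end.

The analysis classes follow scikit-learn conventions (`StabilityScreen`,
`GeNorm`, `NormFinder`, `BestKeeper`, `DeltaCt`, `ConsensusRanker`,
`ReferenceNormalizer`: `fit`/`transform`, `get_params`, trailing-underscore
attributes) and compose with sklearn pipelines; plain functions over the io
containers expose the same operations.

## Worked example

```python
import pandas as pd
from stableref import CqMatrix, evaluate_panel, SampleDesign, relative_quantities, genorm

cq = CqMatrix(pd.DataFrame(
    {"s1": [20.0, 22.0, 25.0], "s2": [21.0, 23.0, 24.0],
     "s3": [20.0, 22.0, 26.0], "s4": [21.0, 23.0, 23.0]},
    index=["A", "B", "C"]))
design = SampleDesign({"s1": "I", "s2": "I", "s3": "N", "s4": "N"})

report, gn = evaluate_panel(cq, design, use_groups=True)
print(report[["deltact_value", "genorm_value", "geomean", "final_rank"]].round(4))
```

prints

```
      deltact_value  genorm_value  geomean  final_rank
gene
A            0.9129        0.0000      1.0           1
B            0.9129        0.0000      2.0           2
C            1.8257        1.8257      3.0           3
```

Genes A and B track each other perfectly (their Cq profiles differ by a
constant 2 cycles, so the SD of their log-ratio is 0): geNorm keeps them as
the final, maximally stable pair (M = 0), ΔCt gives each a stability of
0.9129 (the mean of 0 against its partner and 1.8257 against noisy C), and
the consensus ranks A best. `gn.optimal_n` reports how many reference genes
the V-curve supports.

From the shell, the same stages run as `stableref screen`, `stableref qpcr`,
`stableref normde`, `stableref simulate` and `stableref run --config
pipeline.yaml` (multi-stage, with a JSON run manifest).

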