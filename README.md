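# methdyn

DNA-methylation dynamics of brown vs. white adipogenesis from RRBS data.

`methdyn` implements the differential-methylation analysis used to compare
brown adipocytes (BAT), white adipocytes (WAT) and norepinephrine-treated
"brown-induced" white adipocytes (BWAT) across differentiation days 0, 4
and 6: per-CpG testing, promoter-level aggregation, genomic and CpG-island
context annotation, cross-timepoint consistency, methylation–expression
integration and sample clustering. It ships with a synthetic-study
generator with planted ground truth, so every stage is testable end to end
without any sequencing data.

It is written for epigenomics analysts who have per-CpG methylation call
tables (bismark-coverage-style), gene models (refFlat/BED12), CpG-island
intervals (BED) and, optionally, a gene-level FPKM matrix.

## The statistics at the core

**Per-CpG differential methylation.** For a sample pair, only autosomal
CpGs with sequencing depth ≥ 10 in *every* sample are analyzed. A CpG with
methylated/unmethylated counts (m₁, u₁) and (m₂, u₂) and methylation
difference Δ = m₁/(m₁+u₁) − m₂/(m₂+u₂) enters a two-sided Fisher exact
test only when |Δ| ≥ 0.10. Two-sided p-values sum the hypergeometric
probabilities of all tables with the observed margins whose probability
does not exceed that of the observed table. p-values are
Benjamini–Hochberg adjusted over exactly the tested CpGs of that
comparison; a CpG is a **DMC** when |Δ| ≥ 0.10 and q < 0.05.

**Promoter aggregation.** Promoters span 1 kb upstream through 500 bp
downstream of the TSS. A promoter is a **DMP** when it contains ≥ 2
significant CpGs, all shifted in the same direction. A gene is
*consistently* differentially methylated when it is a DMP with one
direction in the WAT-vs-BAT comparison at all three days.

**Context and dynamics.** CpGs are labelled promoter/exon/intron/
intergenic (precedence in that order, across all genes) and
island/shore/shelf/open-sea (shores = 2 kb island flanks, shelves = the
next 2 kb; island > shore > shelf). Methylation levels are classed as
lowly (< 30%), partially (30–70%) or highly (> 70%) methylated.
Hyper/hypo dominance within a comparison is tested with a two-sided exact
binomial test against 0.5; gene-family enrichment in the consistent set
with an upper-tail hypergeometric test; the promoter-methylation vs
expression-change link with a Spearman correlation and a permutation
p-value on log2((FPKM+1) ratio) fold changes (genes with FPKM < 1
everywhere are dropped first).

**Clustering.** CpGs closer than 500 bp are merged into regions whose
per-sample value is the unweighted mean methylation; samples are clustered
with average linkage (euclidean on region methylation; 1 − Pearson on
log2(FPKM+1)) and embedded by PCA. Agreement with known groupings is
scored by the adjusted Rand index (ARI).

## Worked example

Generate the standard synthetic design (nine samples, 50,000 CpGs, 600
genes, 50 planted differentially methylated promoters at effect size 0.30)
and run the full analysis:

```python
from methdyn import AnalysisConfig, analyze_study
from methdyn.simulate import SimulationConfig, simulate_study, evaluate_recovery
import pandas as pd

study = simulate_study(SimulationConfig(), seed=42)
cfg = AnalysisConfig(autosomes={f"chr{i}" for i in range(1, 6)})
report = analyze_study(study.matrix, study.truth.catalog, cfg,
                       expression=study.expression,
                       family_genes=study.truth.family_genes, seed=42)
```

Printing the headline numbers from `report` gives:

```text
CpGs passing the common >=10x filter: 45060
WAT vs BAT (day 0): 3805 significant DMCs (2640 hyper / 1165 hypo), binomial dominance p = 1.69e-129, 76 DMPs
consistently differentially methylated genes (all 3 days): 46 (34 hyper, 12 hypo in WAT)
recovery vs planted truth: recall=0.92, FDR=0.00, direction accuracy=1.00
promoter methylation vs expression: Spearman rho=-0.255, permutation p=0.0001 (n=526 genes)
clustering ARI: methylome vs lineage=1.0, transcriptome vs day=1.0
synthetic gene-family enrichment: 9/46 hits, hypergeometric p = 1.49e-07
```

Reading the output: white-lineage samples are globally hypermethylated
relative to brown (hyper ≫ hypo DMCs), 46 of the 50 planted DMP genes are
recovered with no false positives and every direction called correctly,
promoter methylation is anti-correlated with expression, and the
methylome clusters samples by cell lineage while the transcriptome
clusters them by differentiation day — the signature dichotomy this
pipeline is built to expose.

The same run is available from the shell:

```sh
methdyn simulate --seed 42 --out simdir/
methdyn run --config analysis.yaml       # paths + thresholds + comparisons
```

plus per-stage commands (`methdyn annotate`, `dmc`, `dmp`, `consistent`,
`enrich`, `correlate`, `cluster`, `filter`, `classes`). File formats are
documented in `docs/formats.md`, the scientific model and its knobs in
`docs/methods.md`.

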