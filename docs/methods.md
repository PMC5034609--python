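# Methods

This note documents the statistical model behind `methdyn`, the design
choices made where the method left room, the synthetic-data generator and
what it does and does not emulate, and the numerical conventions.

## Differential methylation model

Methylation at a CpG in one sample is summarized by counts (methylated,
unmethylated) from bisulfite reads. The per-CpG test for a sample pair is
a two-sided Fisher exact test on the 2×2 count table — a conditional
exact test that makes no large-sample assumption and is well suited to
RRBS depths of tens of reads. Two design rules shape the testing
universe:

* **Effect prefilter.** Only CpGs whose raw methylation difference |Δ|
  reaches `min_diff` (default 0.10) are tested; BH adjustment runs over
  exactly that set, per comparison, and comparisons are adjusted
  independently. The alternative (adjusting pooled across comparisons) is
  a one-line change in the caller but is not the default.
* **Joint significance rule.** A significant CpG (DMC) must satisfy both
  |Δ| ≥ `min_diff` and q < `alpha` (default 0.05). Because untested CpGs
  cannot be significant, the prefilter only affects the multiple-testing
  denominator, never admits sub-threshold effects.

Δ is computed from aggregate counts (no smoothing or shrinkage), so the
reported effect is the raw difference of proportions. Deltas are always
*target minus reference*: the later day in time-course comparisons, WAT
in depot comparisons; "hyper" always means the target is more methylated.

Promoter aggregation (DMP) requires `min_dmcs_per_dmp` (default 2)
significant CpGs in the promoter, unanimous in direction. Mixed-direction
promoters are *not* DMPs by default; a `majority` mode (call the majority
direction when it alone reaches the threshold) exists for sensitivity
analyses. A CpG inside two genes' promoters contributes to both genes, so
gene-level results are gene-complete.

The cross-timepoint consistency rule — a gene must be a DMP with the same
direction at every required timepoint — is deliberately conservative:
under a null methylome it requires the same promoter to produce two
same-direction false-positive CpGs at three independent comparisons,
which is why the consistent set is empty in essentially every null run.

### Known dispersion caveat

Fisher's test assumes binomial counts. Real bisulfite data (and the
generator, see below) are overdispersed, which inflates the tails of the
null p-value distribution. Two features keep the practical error rate
controlled anyway: the |Δ| prefilter concentrates the tested set where
effects are large relative to depth-30 noise, and BH over a tested set
containing thousands of genuine signals raises the effective rejection
threshold only for small p. The type-I acceptance check measures the
realized per-comparison significant fraction on overdispersed null data
(observed ≈ 0.005, well under the 0.05 FDR target); a dispersion-aware
model (beta-binomial regression) is explicitly out of scope.

## Region definitions

With TSS t on the plus strand: promoter [t−1000, t+499] (1500 bp),
gene body [t+500, TTS]; mirrored on the minus strand. "500 bp from TSS"
is read as 500 bp *into* the gene, which is what makes "gene body starts
at the end of the promoter" compose exactly. Genes shorter than 500 bp
have an empty body and are promoter throughout. Multiple transcripts per
gene are collapsed to the union of exons and the 5′-most TSS.

Genic assignment precedence: promoter > exon > intron > intergenic,
evaluated across all genes; exons are the per-gene collapsed union, and
intron means "in a gene body, not exonic". CGI bands: shores are the 2 kb
island flanks, shelves the next 2 kb, with precedence island > shore >
shelf; bands from different islands union, so a position's label is
equivalent to thresholding its distance to the nearest island (0 /
≤ 2 kb / ≤ 4 kb / beyond).

Methylation-level classes use lowly < 0.30, highly > 0.70, with both
boundaries assigned to the partial class (the 30–70% band is closed).

## Analysis parameters

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 10 reads | per-sample depth floor, required in all samples |
| `min_diff` | 0.10 | methylation-difference prefilter and significance floor |
| `alpha` | 0.05 | BH-adjusted significance level |
| `lm_cut`, `hm_cut` | 0.30, 0.70 | methylation class boundaries |
| `merge_gap` | 500 bp | strict upper bound on intra-region CpG gaps |
| `min_fpkm` | 1.0 | a gene is expressed if any sample reaches this |
| `promoter_up/down` | 1000/500 bp | promoter extent around the TSS |
| `shore_bp`, `shelf_bp` | 2000 bp each | CGI band widths |
| `min_dmcs_per_dmp` | 2 | same-direction significant CpGs per DMP |
| `autosomes` | chr1–chr19 | mouse default; configurable for other genomes |

## Integration and clustering choices

* Expression fold change is log2((FPKM_t + 1)/(FPKM_r + 1)); the
  pseudocount stabilizes silent genes.
* The methylation–expression association is Spearman's rho with a
  permutation p-value (10,000 label permutations, seeded); rank-based
  because FPKM is heavy-tailed, permutation-based to avoid distributional
  assumptions at modest gene counts.
* The enrichment universe defaults to genes whose promoter contains at
  least one analyzable CpG — family membership outside the measurable
  universe carries no evidence. Family membership is supplied as a plain
  gene list, never inferred from symbols.
* Clustering uses average linkage: euclidean distance on merged-region
  mean methylation (regions share the 0–1 scale, so no feature scaling),
  1 − Pearson on log2(FPKM+1) for expression. Region means are unweighted
  across member CpGs. PCA centers but does not scale features.
* Region merging chains consecutive CpGs with gaps strictly below
  `merge_gap`; a gap of exactly 500 bp splits.

## The synthetic study

The generator produces the full nine-sample design — BAT, WAT and
NE-treated WAT (BWAT) at days 0, 4, 6 — with known ground truth, used for
calibration, recovery testing and as the default demonstration data.

Structure, with defaults:

* **Genome/annotation**: 5 chromosomes totalling 30 Mb; 600 genes with
  non-overlapping bodies and 2–8 exons; 300 CpG islands, half centred on
  promoters. 50,000 CpG sites; every promoter carries 6–12 CpGs
  (RRBS enriches CpG-dense promoters, and ≥ 2 significant CpGs must be
  possible for promoter-level calls), the rest island-weighted (30%) or
  uniform.
* **Baseline methylation**: a two-mode Beta mixture (means 0.08 and 0.85,
  55% low, concentration 12), mimicking the strongly bimodal LM/HM
  genome of vertebrate methylomes.
* **Counts**: depth ~ 1 + NegBin(size 8, mean 29); methylated counts are
  beta-binomial with dispersion 0.02, so the Fisher test is evaluated
  against realistically overdispersed noise rather than its own null.
* **Planted truth**: 50 genes whose promoter CpGs are shifted by ±0.30 in
  the white lineage (WAT and BWAT) relative to BAT, 70% upward —
  mirroring the observed excess of WAT-hypermethylated promoters.
* **Lineage background**: 10% of *non-promoter* CpGs carry WAT/BWAT
  offsets of ±0.2–0.4 (70% positive). Keeping these out of promoters
  matches the observation that depot DMCs are mostly intronic/intergenic
  and keeps the planted set the only promoter-level truth, which is what
  makes the empirical FDR of the recovery test interpretable.
* **Treatment signature**: 5% of non-promoter CpGs shift by ±0.25 in BWAT
  only — enough to separate BWAT from WAT at lineage resolution while
  leaving the white lineages far closer to each other than to BAT.
* **Differentiation drift**: 20% of CpGs gain 0.02 per day (positive-only
  by default, producing the hyper-dominant time courses; a symmetric mode
  exists for null testing).
* **Expression**: log2 expression = gene baseline (N(3, 1.5²), 10% silent
  genes at N(−2, 1)) + an independent per-day expression program shared
  across lineages (sd 1.0) + `expression_link` (−4) × the sample's
  promoter-methylation deviation from the gene's cross-sample mean +
  N(0, 0.4) noise; FPKM = 2^x − 1 clipped at 0. Day programs are
  independent per day rather than linear in day so that differentiation
  stages form distinct expression states, giving the transcriptome its
  day-wise clustering while the methylome clusters by lineage.

Everything is deterministic given the seed (separate generator streams
for annotation, methylation design, counts and expression).

**What the generator does not emulate**: read-level artifacts (bisulfite
conversion error, mapping bias, fragment/MspI digestion structure of
RRBS), strand asymmetry, chromosome-scale covariance of methylation,
non-CpG methylation, copy-number or purity effects, and realistic gene
length/expression distributions. Passing recovery and calibration tests
therefore demonstrates correctness of the analysis logic under a
plausible noise model, not performance on any particular real dataset.

## Problem sizes used by the test and acceptance runs

The standard design (50,000 CpGs, 600 genes, nine samples) is the unit of
the recovery, clustering, anti-correlation and type-I checks; null
calibration uses ten independent seeds of the same size, and the
monotonicity and planted-null property tests use a 5,000-CpG, 60-gene
variant across seed grids. Oracle checks run 10,000 random Fisher tables
(total count ≤ 60), 1,000 random BH vectors, and 100 random 100-kb toy
genomes for annotation. These sizes give stable statistics (binomial
standard errors well below the tested margins) at interactive runtimes.

## Numerical conventions

* Internal coordinates are 1-based inclusive; BED I/O converts at the
  boundary. DMC output BED uses 0-based starts and caps −log10(q) scores
  at 300 (q = 0 is representable output of BH on underflowing p).
* Fisher p-values are computed by vectorized log-gamma enumeration of the
  hypergeometric support; a table is counted into the two-sided tail when
  its probability is ≤ (1 + 1e−7) × the observed table's probability (the
  standard two-sided convention). Agreement with exact integer
  enumeration is ~1e−13 relative.
* Degenerate Fisher margins (an empty row or column) give p = 1.
* Hyper:hypo ratios with a zero denominator are reported as infinite, not
  clamped.
* Ties in hierarchical clustering are resolved by scipy's deterministic
  ordering, so a given input order always yields the same tree.
* Empty inputs: an empty call file parses to an empty table with a
  warning; an empty feature set is an error for coverage statistics; a
  filter that removes every CpG raises rather than propagating an empty
  matrix.

## Limitations

* Per-CpG Fisher testing ignores biological replication (the design has
  one library per lineage-day) and overdispersion; results on real data
  should be read as descriptive screening, as in the original analysis
  style this package reproduces.
* The promoter definition is fixed-width and TSS-anchored; enhancer
  methylation and distal regulation are out of scope.
* The consistency rule is all-or-nothing across timepoints; a gene
  missing depth at one day cannot be recovered.
* Strand collapsing of CpG dyads is an input-level option
  (`collapse_strands`), not an inference: tables are otherwise assumed
  plus-strand-collapsed, one record per CpG.
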