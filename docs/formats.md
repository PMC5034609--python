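# File formats

All genomic coordinates inside `methdyn` are **1-based inclusive**, one
position per CpG cytosine on the plus strand. BED-family inputs and
outputs are 0-based half-open on disk and converted at the I/O boundary.
All files are plain TSV/text.

## CpG call tables (input)

Two dialects, selected with `dialect=`:

### `coverage_percent` (bismark coverage layout)

```
<chrom> <start(1-based)> <end> <methylation %> <count methylated> <count unmethylated>
```

The percentage is cross-checked against the counts; a discrepancy above
0.5 percentage points is a validation error. Rows with zero total depth
are rejected.

### `counts`

```
<chrom> <pos(1-based)> <count methylated> <count unmethylated>
```

Options: `collapse_strands=True` sums a record at `pos+1` (the
minus-strand cytosine of a CpG dyad) into the plus-strand record at
`pos` when both are present. Duplicate `(chrom, pos)` records are always
an error. The sample id defaults to the file name with stacked
`.cov/.tsv/.txt` extensions stripped.

## Sample metadata (input)

TSV with a header:

```
sample_id  lineage  day  treatment
BAT_d0     BAT      0    none
...
```

`lineage` ∈ {BAT, WAT, BWAT}; `day` ∈ {0, 4, 6}; `treatment` ∈ {none, NE}.

## Gene models (input)

* **refFlat** (UCSC column order): geneName, name, chrom, strand,
  txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds —
  0-based half-open on disk.
* **BED12**: blocks are converted to exons; 0-based half-open.

Exon blocks outside the transcript bounds, unsorted or overlapping exons
are validation errors. Multiple rows sharing a `gene_id` are collapsed to
one gene (exon union, 5′-most TSS).

## Interval BED (input)

BED3+ for CpG islands and any other interval set. `start >= end` (an
empty interval in half-open coordinates) is a validation error.
Overlapping intervals are retained.

## Expression matrix (input)

TSV, first column `gene_id`, header row of sample ids, FPKM values.
Missing cells, negative values and duplicated gene/sample ids are errors.

## Clone-bisulfite matrix (input)

TSV, first column a clone label, remaining column headers the CpG
positions; cells are 1 (methylated) / 0 (unmethylated).

## DMC BED6+ (output)

```
#chrom  start(0-based)  end  name  score  strand  delta  p  q  direction  significant
```

`score = min(-log10 q, 300)`; `strand` is always `.`; `delta` is
target − reference. Readable back with `read_dmc_bed`.

## DMP / consistent-gene tables (output)

TSV: `gene_id, n_sig_cpgs, direction, mean_delta, covered_cpgs` for DMPs;
`gene_id, direction, mean_delta` for the consistent set.

## Run config (input to `methdyn run`)

```yaml
inputs:
  calls:
    - {path: simdir/BAT_d0.cov.tsv}     # optional: sample_id, dialect,
    - ...                               #   assembly, collapse_strands
  samples: simdir/samples.tsv
  genes: simdir/genes.refflat           # genes_format: refFlat | bed12
  cgi: simdir/cgi.bed
  expression: simdir/fpkm.tsv           # optional
  family: simdir/family.txt             # optional, one gene id per line
analysis:                               # AnalysisConfig fields
  min_depth: 10
  autosomes: [chr1, chr2, chr3, chr4, chr5]
comparisons:                            # optional; default: the 7 headline pairs
  - {label: WAT-BAT_d0, target: WAT_d0, reference: BAT_d0}
consistency_comparisons: [WAT-BAT_d0, WAT-BAT_d4, WAT-BAT_d6]   # optional
seed: 0
out_dir: out/
```

The report is written to `out_dir/report.json`; per-comparison DMC/DMP
tables to `out_dir/comparison_<label>/`.

## Simulation output (`methdyn simulate`)

One coverage-dialect call table per sample, `genes.refflat`, `cgi.bed`,
`fpkm.tsv`, `samples.tsv`, `family.txt` and `truth.json` (seed, full
generator config, planted genes with directions and effect sizes).
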