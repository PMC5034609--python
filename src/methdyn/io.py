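"""File formats and domain containers.

Everything external the pipeline touches passes through this module:
bismark-coverage-style CpG call tables, refFlat / BED12 gene models, BED
interval files (CpG islands), FPKM expression matrices, and the result
tables the pipeline writes back out.

Coordinate convention: **internal coordinates are 1-based inclusive**, one
position per CpG cytosine on the plus strand. BED input/output is 0-based
half-open and is converted at this boundary only; nothing downstream ever
sees BED coordinates. Readers reject malformed input rather than repairing
it silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("methdyn")

__all__ = [
    "SampleMeta",
    "CpGCallTable",
    "GeneModel",
    "IntervalSet",
    "ExpressionTable",
    "CloneMatrix",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_gene_models",
    "write_gene_models",
    "read_interval_bed",
    "write_interval_bed",
    "read_expression_table",
    "write_expression_table",
    "read_clone_matrix",
    "write_result_tables",
    "read_dmc_bed",
]

LINEAGES = ("BAT", "WAT", "BWAT")
TREATMENTS = ("none", "NE")
STUDY_DAYS = (0, 4, 6)


class ParseError(ValueError):
    """Malformed input file (carries the offending line number)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sample in the nine-sample adipogenesis design.

    The full design crosses three lineages (brown adipocytes BAT, white
    adipocytes WAT, and norepinephrine-treated "brown-induced" white
    adipocytes BWAT) with three differentiation days (0, 4, 6).
    """

    sample_id: str
    lineage: str
    day: int
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"lineage must be one of {LINEAGES}, got {self.lineage!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.day not in STUDY_DAYS:
            raise ValueError(f"day must be one of {STUDY_DAYS}, got {self.day!r}")


@dataclass
class CpGCallTable:
    """Per-CpG methylated/unmethylated read counts for one sample.

    ``data`` has columns ``chrom, pos, meth, unmeth`` with ``pos`` the
    1-based plus-strand cytosine position, unique per chromosome.
    """

    sample_id: str
    data: pd.DataFrame
    assembly: str = "unknown"

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "meth", "unmeth"]
        if list(self.data.columns[:4]) != required:
            raise ValueError(f"CpGCallTable columns must start with {required}")
        d = self.data
        if len(d):
            if (d["pos"] < 1).any():
                raise ValueError("positions must be >= 1")
            if (d["meth"] < 0).any() or (d["unmeth"] < 0).any():
                raise ValueError("counts must be non-negative")
            if ((d["meth"] + d["unmeth"]) < 1).any():
                raise ValueError("every CpG record needs total depth >= 1")
            if d.duplicated(["chrom", "pos"]).any():
                dup = d[d.duplicated(["chrom", "pos"])].iloc[0]
                raise ValueError(
                    f"duplicate CpG record at {dup['chrom']}:{dup['pos']} "
                    f"in sample {self.sample_id}"
                )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneModel:
    """One gene with 1-based inclusive transcript bounds and exons.

    ``tx_start <= tx_end`` always; strand is recorded separately, so the TSS
    of a minus-strand gene is ``tx_end``.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}] outside transcript bounds")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class IntervalSet:
    """A named set of 1-based inclusive intervals, sorted per chromosome.

    ``data`` has columns ``chrom, start, end`` (plus optional annotation
    columns such as ``name``). Overlapping intervals are allowed.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end"]
        if list(self.data.columns[:3]) != required:
            raise ValueError(f"IntervalSet columns must start with {required}")
        d = self.data
        if len(d):
            if (d["start"] > d["end"]).any():
                raise ValueError(f"{self.name}: interval start > end")
            if (d["start"] < 1).any():
                raise ValueError(f"{self.name}: coordinates must be >= 1")
        self.data = d.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Return ``{chrom: (n, 2) array of [start, end]}``."""
        out = {}
        for chrom, grp in self.data.groupby("chrom", sort=False):
            out[chrom] = grp[["start", "end"]].to_numpy()
        return out


@dataclass
class ExpressionTable:
    """Gene x sample FPKM matrix."""

    fpkm: pd.DataFrame  # index gene_id, columns sample_id

    def __post_init__(self) -> None:
        f = self.fpkm
        if f.index.duplicated().any():
            raise ValueError("duplicated gene_id in expression table")
        if f.columns.duplicated().any():
            raise ValueError("duplicated sample_id in expression table")
        if f.isna().any().any():
            raise ValueError("expression table contains missing values")
        if (f.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class CloneMatrix:
    """Clone-bisulfite sequencing result: clones x CpG sites, binary.

    1 = methylated cytosine, 0 = unmethylated, as read off a lollipop plot
    of individually cloned bisulfite PCR products.
    """

    positions: list[int]
    values: np.ndarray  # (n_clones, n_sites), dtype int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("clone matrix needs >=1 clone and >=1 site")
        if v.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of site columns")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("clone matrix entries must be 0 or 1")
        self.values = v.astype(np.int8)


# ---------------------------------------------------------------------------
# CpG call tables
# ---------------------------------------------------------------------------

def read_cpg_calls(
    path: str | Path,
    dialect: str = "coverage_percent",
    sample_id: str | None = None,
    collapse_strands: bool = False,
    assembly: str = "unknown",
) -> CpGCallTable:
    """Read a per-CpG methylation call table.

    Two TSV dialects are supported:

    ``coverage_percent``
        bismark coverage layout: chrom, start(1-based), end, %methylation,
        count methylated, count unmethylated. The stated percentage is
        cross-checked against the counts (0.5 percentage-point tolerance).
    ``counts``
        chrom, pos(1-based), count methylated, count unmethylated.

    ``collapse_strands`` sums a record at ``pos+1`` (the minus-strand
    cytosine of the same CpG dyad) into the plus-strand record at ``pos``
    when both are present.
    """
    path = Path(path)
    if dialect not in ("coverage_percent", "counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "coverage_percent":
                    if len(parts) < 6:
                        raise ValueError("expected 6 columns")
                    chrom, start, _end, pct, meth, unmeth = parts[:6]
                    pos, pct = int(start), float(pct)
                    meth, unmeth = int(meth), int(unmeth)
                else:
                    if len(parts) < 4:
                        raise ValueError("expected 4 columns")
                    chrom, pos, meth, unmeth = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                    pct = None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            total = meth + unmeth
            if total == 0:
                raise ParseError(f"{path}:{lineno}: zero total depth")
            if pct is not None:
                recomputed = 100.0 * meth / total
                if abs(recomputed - pct) > 0.5:
                    raise ParseError(
                        f"{path}:{lineno}: stated {pct:.2f}% inconsistent with "
                        f"counts ({recomputed:.2f}%)"
                    )
            rows.append((chrom, pos, meth, unmeth))
    if not rows:
        logger.warning("empty CpG call file: %s", path)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    if collapse_strands and len(df):
        df = _collapse_strands(df)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if sample_id is None:
        sample_id = path.name
        while True:  # strip stacked extensions: X.cov.tsv -> X
            base, dot, ext = sample_id.rpartition(".")
            if dot and ext.lower() in ("tsv", "txt", "cov", "bedgraph", "counts"):
                sample_id = base
            else:
                break
    return CpGCallTable(sample_id=sample_id, data=df, assembly=assembly)


def _collapse_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Sum pos+1 records into pos records where both exist (CpG dyads)."""
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    key = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
    partner = pd.MultiIndex.from_arrays([df["chrom"], df["pos"] - 1])
    has_plus = partner.isin(key)  # row is the minus-strand mate of an existing plus record
    minus = df[has_plus]
    if len(minus):
        add = minus.assign(pos=minus["pos"] - 1).groupby(["chrom", "pos"], sort=False)[
            ["meth", "unmeth"]
        ].sum()
        keep = df[~has_plus].set_index(["chrom", "pos"])
        keep[["meth", "unmeth"]] = keep[["meth", "unmeth"]].add(add, fill_value=0).astype(int)
        df = keep.reset_index()
    return df


def write_cpg_calls(table: CpGCallTable, path: str | Path, dialect: str = "coverage_percent") -> Path:
    """Write a call table in either dialect; round-trips through the reader."""
    path = Path(path)
    d = table.data
    with open(path, "w") as fh:
        for row in d.itertuples(index=False):
            total = row.meth + row.unmeth
            if dialect == "coverage_percent":
                pct = 100.0 * row.meth / total
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.6f}\t{row.meth}\t{row.unmeth}\n")
            elif dialect == "counts":
                fh.write(f"{row.chrom}\t{row.pos}\t{row.meth}\t{row.unmeth}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "refFlat") -> list[GeneModel]:
    """Read gene models from refFlat (UCSC column order) or BED12.

    Both formats carry 0-based half-open coordinates on disk and are
    converted to 1-based inclusive here.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "refFlat":
                    genes.append(_parse_refflat(parts))
                elif format == "bed12":
                    genes.append(_parse_bed12(parts))
                else:
                    raise ValueError(f"unknown gene model format {format!r}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_refflat(parts: list[str]) -> GeneModel:
    # geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds
    if len(parts) < 11:
        raise ValueError("refFlat needs 11 columns")
    symbol, name, chrom, strand = parts[0], parts[1], parts[2], parts[3]
    tx_start, tx_end = int(parts[4]) + 1, int(parts[5])
    starts = [int(x) + 1 for x in parts[9].rstrip(",").split(",") if x]
    ends = [int(x) for x in parts[10].rstrip(",").split(",") if x]
    if len(starts) != len(ends) or len(starts) != int(parts[8]):
        raise ValueError("exon count mismatch")
    return GeneModel(gene_id=name, symbol=symbol, chrom=chrom, strand=strand,
                     tx_start=tx_start, tx_end=tx_end, exons=list(zip(starts, ends)))


def _parse_bed12(parts: list[str]) -> GeneModel:
    if len(parts) < 12:
        raise ValueError("BED12 needs 12 columns")
    chrom, chrom_start, chrom_end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
    strand = parts[5]
    tx_start, tx_end = chrom_start + 1, chrom_end
    n_blocks = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in parts[11].rstrip(",").split(",") if x]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError("block count mismatch")
    exons = [(tx_start + off, tx_start + off + size - 1) for off, size in zip(offsets, sizes)]
    return GeneModel(gene_id=name, symbol=name, chrom=chrom, strand=strand,
                     tx_start=tx_start, tx_end=tx_end, exons=exons)


def write_gene_models(genes: list[GeneModel], path: str | Path) -> Path:
    """Write gene models as refFlat (round-trips through the reader)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s - 1) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.symbol}\t{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start - 1}\t{g.tx_end}"
                f"\t{g.tx_start - 1}\t{g.tx_end}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )
    return path


# ---------------------------------------------------------------------------
# interval BED
# ---------------------------------------------------------------------------

def read_interval_bed(path: str | Path, name: str) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into 1-based inclusive intervals."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED row") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: empty/inverted BED interval ({start} >= {end})")
            rows.append((chrom, start + 1, end))
    return IntervalSet(name=name, data=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def write_interval_bed(iset: IntervalSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for row in iset.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")
    return path


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a gene x sample FPKM TSV (first column gene_id, header row)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric FPKM cell: {exc}") from exc
    df.index = df.index.astype(str)
    return ExpressionTable(fpkm=df)


def write_expression_table(expr: ExpressionTable, path: str | Path) -> Path:
    path = Path(path)
    expr.fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    return path


def read_clone_matrix(path: str | Path) -> CloneMatrix:
    """Read a clone x CpG-site binary TSV; header row holds CpG positions."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    positions = [int(c) for c in df.columns]
    return CloneMatrix(positions=positions, values=df.to_numpy())


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

MAX_BED_SCORE = 300.0  # -log10(q) cap for q == 0


def write_result_tables(
    dmcs: pd.DataFrame | None,
    dmps: pd.DataFrame | None,
    consistent_set: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write DMC/DMP/consistent-gene results.

    DMCs go to BED6+ (0-based start, ``score = min(-log10 q, 300)``) with
    delta, p, q, direction, significant as extra columns; DMPs and the
    consistent-gene set go to TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if dmcs is not None:
        p = out_dir / "dmc.bed"
        with open(p, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tdelta\tp\tq\tdirection\tsignificant\n")
            for i, row in enumerate(dmcs.itertuples(index=False)):
                with np.errstate(divide="ignore"):
                    score = min(-np.log10(row.q) if row.q > 0 else np.inf, MAX_BED_SCORE)
                fh.write(
                    f"{row.chrom}\t{row.pos - 1}\t{row.pos}\tdmc_{i}\t{score:.4f}\t.\t"
                    f"{row.delta:.6f}\t{row.p:.6g}\t{row.q:.6g}\t{row.direction}\t"
                    f"{int(row.significant)}\n"
                )
        paths["dmc"] = p
    if dmps is not None:
        p = out_dir / "dmp.tsv"
        dmps.to_csv(p, sep="\t", index=False)
        paths["dmp"] = p
    if consistent_set is not None:
        p = out_dir / "consistent_genes.tsv"
        consistent_set.to_csv(p, sep="\t", index=False)
        paths["consistent"] = p
    return paths


def read_dmc_bed(path: str | Path) -> pd.DataFrame:
    """Read back a DMC BED6+ file written by :func:`write_result_tables`."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "delta", "p", "q", "direction", "significant"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols)
    df["pos"] = df["end"].astype(int)
    df["significant"] = df["significant"].astype(bool)
    return df[["chrom", "pos", "delta", "p", "q", "direction", "significant"]]
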