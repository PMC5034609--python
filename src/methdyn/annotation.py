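"""Genomic and CpG-island context annotation.

Region definitions:

* promoter — 1 kb upstream of the TSS through 500 bp into the gene
  (``[TSS-1000, TSS+499]`` on the plus strand, mirrored on the minus
  strand), so every promoter spans exactly 1500 bp;
* gene body — from the end of the promoter to the TTS;
* CGI shores — the 2 kb flanks of each CpG island; shelves — the next
  2 kb beyond the shores. Precedence island > shore > shelf resolves
  overlaps between bands of neighbouring islands.

Genic assignment precedence is promoter > exon > intron > intergenic,
evaluated across all genes (a position in one gene's intron and another
gene's promoter is a promoter position). Exons use the per-gene collapsed
exon union; intron means "inside a gene body but not exonic".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import AnalysisConfig
from .io import GeneModel, IntervalSet

__all__ = [
    "FeatureCatalog",
    "build_feature_catalog",
    "assign_genic_context",
    "assign_cgi_context",
    "assign_contexts",
    "region_cpg_coverage",
    "merge_intervals",
    "subtract_intervals",
]

GENIC_LABELS = ("promoter", "exon", "intron", "intergenic")
CGI_LABELS = ("island", "shore", "shelf", "open_sea")


# ---------------------------------------------------------------------------
# interval arithmetic (1-based inclusive throughout)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of 1-based inclusive intervals; adjacent intervals merge."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for 1-based inclusive interval arrays."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def _points_in_sorted(intervals: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted *disjoint* intervals."""
    if len(intervals) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] <= intervals[idx[ok], 1]
    return ok


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass
class FeatureCatalog:
    """Derived analysis regions for one gene/CGI annotation.

    ``promoters`` and ``gene_bodies`` are keyed by gene_id (column
    ``gene_id``); ``exons`` is the collapsed exon union; the three CGI bands
    are mutually disjoint after island > shore > shelf precedence.
    """

    promoters: IntervalSet
    gene_bodies: IntervalSet
    exons: IntervalSet
    cgi_islands: IntervalSet
    cgi_shores: IntervalSet
    cgi_shelves: IntervalSet


def _collapse_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Collapse transcripts sharing a gene_id: union span/exons, 5'-most TSS."""
    by_id: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_id.setdefault(g.gene_id, []).append(g)
    out = []
    for gid, models in by_id.items():
        if len(models) == 1:
            out.append(models[0])
            continue
        chroms = {m.chrom for m in models}
        strands = {m.strand for m in models}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gid}: transcripts disagree on chromosome/strand")
        tx_start = min(m.tx_start for m in models)
        tx_end = max(m.tx_end for m in models)
        exon_union = merge_intervals(
            np.array([iv for m in models for iv in m.exons], dtype=np.int64).reshape(-1, 2)
        )
        out.append(GeneModel(
            gene_id=gid, symbol=models[0].symbol, chrom=models[0].chrom,
            strand=models[0].strand, tx_start=tx_start, tx_end=tx_end,
            exons=[tuple(iv) for iv in exon_union],
        ))
    return out


def build_feature_catalog(
    genes: list[GeneModel],
    cgis: IntervalSet,
    cfg: AnalysisConfig | None = None,
) -> FeatureCatalog:
    """Derive promoters, gene bodies, exon union, and CGI bands."""
    cfg = cfg or AnalysisConfig()
    genes = _collapse_genes(genes)

    prom_rows, body_rows, exon_rows = [], [], []
    for g in genes:
        if g.strand == "+":
            p_start, p_end = g.tss - cfg.promoter_up, g.tss + cfg.promoter_down - 1
            b_start, b_end = g.tss + cfg.promoter_down, g.tts
        else:
            p_start, p_end = g.tss - cfg.promoter_down + 1, g.tss + cfg.promoter_up
            b_start, b_end = g.tts, g.tss - cfg.promoter_down
        prom_rows.append((g.chrom, max(p_start, 1), p_end, g.gene_id))
        if b_start <= b_end:  # genes shorter than promoter_down have no body
            body_rows.append((g.chrom, b_start, b_end, g.gene_id))
        for s, e in g.exons:
            exon_rows.append((g.chrom, s, e))

    promoters = IntervalSet("promoters", pd.DataFrame(
        prom_rows, columns=["chrom", "start", "end", "gene_id"]))
    gene_bodies = IntervalSet("gene_bodies", pd.DataFrame(
        body_rows, columns=["chrom", "start", "end", "gene_id"]))

    exon_union_rows = []
    if exon_rows:
        edf = pd.DataFrame(exon_rows, columns=["chrom", "start", "end"])
        for chrom, grp in edf.groupby("chrom", sort=False):
            for s, e in merge_intervals(grp[["start", "end"]].to_numpy()):
                exon_union_rows.append((chrom, s, e))
    exons = IntervalSet("exons", pd.DataFrame(
        exon_union_rows, columns=["chrom", "start", "end"]))

    islands, shores, shelves = _cgi_bands(cgis, cfg)
    return FeatureCatalog(promoters=promoters, gene_bodies=gene_bodies, exons=exons,
                          cgi_islands=islands, cgi_shores=shores, cgi_shelves=shelves)


def _cgi_bands(cgis: IntervalSet, cfg: AnalysisConfig) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Island / shore / shelf bands with island > shore > shelf precedence."""
    isl_rows, sho_rows, she_rows = [], [], []
    for chrom, iv in cgis.by_chrom().items():
        isl = merge_intervals(iv)
        flanks = []
        for s, e in isl:
            flanks.append((max(s - cfg.shore_bp, 1), s - 1))
            flanks.append((e + 1, e + cfg.shore_bp))
        flanks = np.array([f for f in flanks if f[0] <= f[1]], dtype=np.int64).reshape(-1, 2)
        sho = subtract_intervals(flanks, isl)
        shelf_raw = []
        for s, e in isl:
            shelf_raw.append((max(s - cfg.shore_bp - cfg.shelf_bp, 1), s - cfg.shore_bp - 1))
            shelf_raw.append((e + cfg.shore_bp + 1, e + cfg.shore_bp + cfg.shelf_bp))
        shelf_raw = np.array([f for f in shelf_raw if f[0] <= f[1]], dtype=np.int64).reshape(-1, 2)
        she = subtract_intervals(subtract_intervals(shelf_raw, isl), sho)
        isl_rows += [(chrom, s, e) for s, e in isl]
        sho_rows += [(chrom, s, e) for s, e in sho]
        she_rows += [(chrom, s, e) for s, e in she]
    cols = ["chrom", "start", "end"]
    return (IntervalSet("cgi_islands", pd.DataFrame(isl_rows, columns=cols)),
            IntervalSet("cgi_shores", pd.DataFrame(sho_rows, columns=cols)),
            IntervalSet("cgi_shelves", pd.DataFrame(she_rows, columns=cols)))


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------

def _build_trees(iset: IntervalSet, payload_col: str | None = None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in iset.data.itertuples(index=False):
        t = trees.setdefault(row.chrom, IntervalTree())
        payload = getattr(row, payload_col) if payload_col else None
        t.addi(row.start, row.end + 1, payload)  # intervaltree is half-open
    return trees


def assign_genic_context(
    positions: pd.DataFrame,
    catalog: FeatureCatalog,
) -> pd.DataFrame:
    """Label each (chrom, pos) as promoter/exon/intron/intergenic.

    Returns a DataFrame aligned with ``positions`` with columns ``genic``
    and ``gene_ids`` (comma-joined ids of every gene whose promoter contains
    the position; empty string otherwise).
    """
    prom_trees = _build_trees(catalog.promoters, "gene_id")
    body_by_chrom = {c: merge_intervals(iv) for c, iv in catalog.gene_bodies.by_chrom().items()}
    exon_by_chrom = {c: merge_intervals(iv) for c, iv in catalog.exons.by_chrom().items()}

    labels = np.full(len(positions), "intergenic", dtype=object)
    gene_ids = np.full(len(positions), "", dtype=object)
    pos_arr = positions["pos"].to_numpy()
    for chrom, grp_idx in positions.groupby("chrom", sort=False).indices.items():
        pos = pos_arr[grp_idx]
        in_exon = _points_in_sorted(exon_by_chrom.get(chrom, np.empty((0, 2), int)), pos)
        in_body = _points_in_sorted(body_by_chrom.get(chrom, np.empty((0, 2), int)), pos)
        tree = prom_trees.get(chrom)
        for local, (p, ex, bd) in enumerate(zip(pos, in_exon, in_body)):
            i = grp_idx[local]
            hits = sorted(iv.data for iv in tree[p]) if tree is not None else []
            if hits:
                labels[i] = "promoter"
                gene_ids[i] = ",".join(hits)
            elif ex and bd:
                labels[i] = "exon"
            elif bd:
                labels[i] = "intron"
            elif ex:
                labels[i] = "exon"
    return pd.DataFrame({"genic": labels, "gene_ids": gene_ids}, index=positions.index)


def assign_cgi_context(positions: pd.DataFrame, catalog: FeatureCatalog) -> pd.Series:
    """Label each (chrom, pos) as island/shore/shelf/open_sea."""
    band_sets = [("island", catalog.cgi_islands), ("shore", catalog.cgi_shores),
                 ("shelf", catalog.cgi_shelves)]
    labels = np.full(len(positions), "open_sea", dtype=object)
    pos_arr = positions["pos"].to_numpy()
    for chrom, grp_idx in positions.groupby("chrom", sort=False).indices.items():
        pos = pos_arr[grp_idx]
        assigned = np.zeros(len(pos), dtype=bool)
        for name, iset in band_sets:
            iv = iset.by_chrom().get(chrom)
            if iv is None:
                continue
            hit = _points_in_sorted(merge_intervals(iv), pos) & ~assigned
            labels[grp_idx[hit]] = name
            assigned |= hit
    return pd.Series(labels, index=positions.index, name="cgi")


def assign_contexts(positions: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Genic and CGI context for each position, one row per input row."""
    out = assign_genic_context(positions, catalog)
    out["cgi"] = assign_cgi_context(positions, catalog)
    return pd.concat([positions.reset_index(drop=True),
                      out.reset_index(drop=True)], axis=1)


def region_cpg_coverage(positions: pd.DataFrame, features: IntervalSet) -> tuple[int, float]:
    """Count and fraction of features containing at least two CpG positions."""
    if len(features) == 0:
        raise ValueError("empty feature set")
    pos_by_chrom = {c: np.unique(g["pos"].to_numpy())
                    for c, g in positions.groupby("chrom", sort=False)}
    n_covered = 0
    for row in features.data.itertuples(index=False):
        pos = pos_by_chrom.get(row.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        if hi - lo >= 2:
            n_covered += 1
    return n_covered, n_covered / len(features)
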