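"""Cross-timepoint consistency and methylation-expression integration.

A gene is *consistently* differentially methylated when it is called a DMP
with the same direction at every required timepoint (here: the BAT-vs-WAT
comparison at days 0, 4 and 6 of differentiation). Gene-family enrichment
within that set uses an upper-tail hypergeometric test; the link between
promoter methylation change and expression change is quantified by a
Spearman correlation with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr

from .config import AnalysisConfig
from .io import ExpressionTable

__all__ = [
    "ConsistentGeneSet",
    "EnrichmentResult",
    "consistent_dmps",
    "hypergeometric_enrichment",
    "filter_expressed",
    "expression_log2_fold_change",
    "methylation_expression_correlation",
]


@dataclass
class ConsistentGeneSet:
    """Genes that are DMPs with one direction at every timepoint."""

    genes: pd.DataFrame  # gene_id, direction, mean_delta (averaged over timepoints)
    timepoints: list[str]
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def hyper(self) -> list[str]:
        return list(self.genes.loc[self.genes["direction"] == "hyper", "gene_id"])

    @property
    def hypo(self) -> list[str]:
        return list(self.genes.loc[self.genes["direction"] == "hypo", "gene_id"])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int
    family_size: int
    set_size: int
    hits_in_set: int
    p: float


def consistent_dmps(dmp_lists: list[tuple[str, pd.DataFrame]]) -> ConsistentGeneSet:
    """Intersect DMP calls across timepoints, requiring one direction.

    ``dmp_lists`` pairs a timepoint label with the DMP table of that
    timepoint's comparison. A gene is kept iff it is a DMP at *every*
    timepoint and its direction never flips.
    """
    if len(dmp_lists) < 2:
        raise ValueError("need DMP tables from at least two timepoints")
    labels = [lab for lab, _ in dmp_lists]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate timepoint labels")
    per_tp = {}
    for lab, df in dmp_lists:
        if df.duplicated("gene_id").any():
            raise ValueError(f"timepoint {lab}: duplicate gene_id in DMP table")
        per_tp[lab] = df.set_index("gene_id")
    common = set(per_tp[labels[0]].index)
    for lab in labels[1:]:
        common &= set(per_tp[lab].index)
    rows = []
    for gid in sorted(common):
        dirs = {per_tp[lab].loc[gid, "direction"] for lab in labels}
        if len(dirs) == 1:
            mean_delta = float(np.mean([per_tp[lab].loc[gid, "mean_delta"] for lab in labels]))
            rows.append((gid, dirs.pop(), mean_delta))
    genes = pd.DataFrame(rows, columns=["gene_id", "direction", "mean_delta"])
    return ConsistentGeneSet(genes=genes, timepoints=labels,
                             provenance={lab: df for lab, df in dmp_lists})


def hypergeometric_enrichment(
    set_genes, family_genes, universe_genes
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene family in a gene set.

    p = P(X >= observed hits) with X ~ Hypergeom(universe, family, set).
    """
    universe = set(universe_genes)
    gset = set(set_genes)
    family = set(family_genes) & universe
    if not gset <= universe:
        raise ValueError("gene set must be contained in the universe")
    hits = len(gset & family)
    p = float(hypergeom.sf(hits - 1, len(universe), len(family), len(gset)))
    return EnrichmentResult(universe_size=len(universe), family_size=len(family),
                            set_size=len(gset), hits_in_set=hits, p=min(p, 1.0))


def filter_expressed(
    expr: ExpressionTable,
    cfg: AnalysisConfig | None = None,
    autosomal_genes: set[str] | None = None,
) -> ExpressionTable:
    """Drop genes whose FPKM stays below ``min_fpkm`` in every sample.

    When ``autosomal_genes`` is given, non-autosomal genes are dropped too.
    """
    cfg = cfg or AnalysisConfig()
    f = expr.fpkm
    keep = (f >= cfg.min_fpkm).any(axis=1)
    if autosomal_genes is not None:
        keep &= f.index.isin(autosomal_genes)
    return ExpressionTable(fpkm=f[keep])


def expression_log2_fold_change(
    expr: ExpressionTable,
    target_samples: list[str],
    reference_samples: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean FPKM target + pc) / (mean FPKM reference + pc))."""
    f = expr.fpkm
    t = f[target_samples].mean(axis=1)
    r = f[reference_samples].mean(axis=1)
    return np.log2((t + pseudocount) / (r + pseudocount)).rename("lfc")


def methylation_expression_correlation(
    promoter_deltas: pd.Series,
    expression_lfc: pd.Series,
    n_permutations: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Spearman correlation between promoter methylation change and
    expression change over the shared gene set, with a permutation p-value.

    Returns ``{"rho", "p", "n", "n_ties"}``; ``n_ties`` counts genes whose
    methylation delta is tied with another gene's.
    """
    shared = promoter_deltas.index.intersection(expression_lfc.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared between inputs")
    x = promoter_deltas.loc[shared].to_numpy(dtype=float)
    y = expression_lfc.loc[shared].to_numpy(dtype=float)
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    # permute one margin; rank-correlation of x with permuted y
    from scipy.stats import rankdata
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = float(np.mean(rx * ry))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = np.mean(rx * rng.permutation(ry))
    if alternative == "two-sided":
        exceed = np.abs(null) >= abs(obs) - 1e-12
    elif alternative == "less":
        exceed = null <= obs + 1e-12
    elif alternative == "greater":
        exceed = null >= obs - 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float((1 + exceed.sum()) / (1 + n_permutations))
    _, tie_counts = np.unique(x, return_counts=True)
    n_ties = int(tie_counts[tie_counts > 1].sum())
    return {"rho": rho, "p": p, "n": int(len(shared)), "n_ties": n_ties}
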