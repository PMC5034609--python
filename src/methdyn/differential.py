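"""Differential methylation calling.

A CpG is differentially methylated (DMC) between a sample pair when

1. the raw methylation difference is at least ``min_diff`` (default 10
   percentage points) — only such CpGs enter the test, and
2. the two-sided Fisher exact p-value, BH-adjusted across exactly the
   tested CpGs of that comparison, is below ``alpha``.

A promoter is differentially methylated (DMP) when it contains at least
``min_dmcs_per_dmp`` significant CpGs, all shifted in the same direction.

The Fisher test is computed in-package as a vectorized hypergeometric
enumeration (log-gamma arithmetic): a p-value is the total probability of
all 2x2 tables with the observed margins whose probability does not exceed
that of the observed table (relative tolerance 1e-7, the usual two-sided
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .annotation import FeatureCatalog
from .config import AnalysisConfig
from .methylome import MethylomeMatrix

__all__ = [
    "ComparisonSpec",
    "fisher_exact_two_sided",
    "fisher_exact_many",
    "bh_adjust",
    "call_dmcs",
    "call_dmps",
    "direction_dominance_test",
    "dmc_category_breakdown",
]

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison; deltas are target minus reference."""

    target: str
    reference: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.target == self.reference:
            raise ValueError("target and reference must differ")


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_many(
    meth_t: np.ndarray, depth_t: np.ndarray,
    meth_r: np.ndarray, depth_r: np.ndarray,
    chunk: int = 20000,
) -> np.ndarray:
    """Two-sided Fisher exact p-values for many 2x2 tables at once.

    Table i is ``[[meth_t, depth_t-meth_t], [meth_r, depth_r-meth_r]]``.
    Margins with zero total in a row or column give p = 1 by convention.
    """
    meth_t = np.asarray(meth_t, dtype=np.int64)
    depth_t = np.asarray(depth_t, dtype=np.int64)
    meth_r = np.asarray(meth_r, dtype=np.int64)
    depth_r = np.asarray(depth_r, dtype=np.int64)
    if (meth_t < 0).any() or (meth_r < 0).any() or (meth_t > depth_t).any() or (meth_r > depth_r).any():
        raise ValueError("need 0 <= meth <= depth for both samples")
    n = len(meth_t)
    out = np.empty(n, dtype=float)
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        out[sl] = _fisher_chunk(meth_t[sl], depth_t[sl], meth_r[sl], depth_r[sl])
    return out


def _fisher_chunk(a, n1, c, n2) -> np.ndarray:
    N = n1 + n2
    K = a + c  # methylated margin; X = methylated count in sample 1
    lo = np.maximum(0, K - n2)
    hi = np.minimum(K, n1)
    width = int((hi - lo).max()) + 1 if len(a) else 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xc = np.where(valid, x, 0)

    def logc(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    logpmf = (logc(K[:, None], xc) + logc((N - K)[:, None], n1[:, None] - xc)
              - logc(N, n1)[:, None])
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = (logc(K, a) + logc(N - K, n1 - a) - logc(N, n1))
    include = logpmf <= log_obs[:, None] + np.log1p(_REL_TOL)
    p = np.exp(logpmf, where=include & valid, out=np.zeros_like(logpmf))
    p[~(include & valid)] = 0.0
    return np.minimum(p.sum(axis=1), 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``[[a, b], [c, d]]``."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    return float(fisher_exact_many(
        np.array([a]), np.array([a + b]), np.array([c]), np.array([c + d]))[0])


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMC / DMP calling
# ---------------------------------------------------------------------------

def call_dmcs(m: MethylomeMatrix, spec: ComparisonSpec, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-CpG differential methylation for one comparison.

    Returns one row per *tested* CpG (|delta| >= min_diff) with columns
    ``chrom, pos, delta, p, q, direction, significant``. BH adjustment runs
    over exactly this tested set.
    """
    cfg = cfg or AnalysisConfig()
    jt, jr = m.sample_index(spec.target), m.sample_index(spec.reference)
    mt, dt = m.meth[:, jt], m.depth[:, jt]
    mr, dr = m.meth[:, jr], m.depth[:, jr]
    if (dt == 0).any() or (dr == 0).any():
        raise ValueError("matrix must be common-coverage filtered before DMC calling")
    delta = mt / dt - mr / dr
    tested = np.abs(delta) >= cfg.min_diff - 1e-12
    idx = np.flatnonzero(tested)
    p = fisher_exact_many(mt[idx], dt[idx], mr[idx], dr[idx])
    q = bh_adjust(p)
    out = pd.DataFrame({
        "chrom": m.sites["chrom"].to_numpy()[idx],
        "pos": m.sites["pos"].to_numpy()[idx],
        "delta": delta[idx],
        "p": p,
        "q": q,
        "direction": np.where(delta[idx] > 0, "hyper", "hypo"),
        "significant": q < cfg.alpha,
    })
    return out


def call_dmps(
    dmcs: pd.DataFrame,
    catalog: FeatureCatalog,
    cfg: AnalysisConfig | None = None,
    mode: str = "strict",
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Promoter-level aggregation of significant DMCs for one comparison.

    ``mode="strict"`` (default) requires every significant CpG in the
    promoter to share one direction; ``mode="majority"`` calls the majority
    direction provided the majority alone reaches ``min_dmcs_per_dmp``.
    A CpG lying in two genes' promoters contributes to both genes. Returns
    columns ``gene_id, n_sig_cpgs, direction, mean_delta, covered_cpgs``.
    """
    cfg = cfg or AnalysisConfig()
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown DMP mode {mode!r}")
    sig = dmcs[dmcs["significant"]]
    sig_by_chrom = {c: g.sort_values("pos") for c, g in sig.groupby("chrom", sort=False)}
    cov_by_chrom = None
    if sites is not None:
        cov_by_chrom = {c: np.sort(g["pos"].to_numpy())
                        for c, g in sites.groupby("chrom", sort=False)}
    rows = []
    for prom in catalog.promoters.data.itertuples(index=False):
        g = sig_by_chrom.get(prom.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, prom.start, side="left")
        hi = np.searchsorted(pos, prom.end, side="right")
        if hi - lo == 0:
            continue
        sub = g.iloc[lo:hi]
        n_hyper = int((sub["direction"] == "hyper").sum())
        n_hypo = len(sub) - n_hyper
        if mode == "strict":
            if min(n_hyper, n_hypo) > 0 or len(sub) < cfg.min_dmcs_per_dmp:
                continue
            direction = "hyper" if n_hyper else "hypo"
            contrib = sub
        else:
            n_major = max(n_hyper, n_hypo)
            if n_major < cfg.min_dmcs_per_dmp or n_hyper == n_hypo:
                continue
            direction = "hyper" if n_hyper > n_hypo else "hypo"
            contrib = sub[sub["direction"] == direction]
        if cov_by_chrom is not None:
            allpos = cov_by_chrom.get(prom.chrom, np.empty(0, dtype=int))
            covered = int(np.searchsorted(allpos, prom.end, side="right")
                          - np.searchsorted(allpos, prom.start, side="left"))
        else:
            covered = len(sub)
        rows.append((prom.gene_id, len(contrib), direction,
                     float(contrib["delta"].mean()), covered))
    return pd.DataFrame(rows, columns=["gene_id", "n_sig_cpgs", "direction",
                                       "mean_delta", "covered_cpgs"])


def direction_dominance_test(n_hyper: int, n_hypo: int) -> float:
    """Two-sided exact binomial test of hyper vs hypo counts against 0.5."""
    if n_hyper < 0 or n_hypo < 0:
        raise ValueError("counts must be non-negative")
    n = n_hyper + n_hypo
    if n == 0:
        raise ValueError("dominance test needs at least one CpG")
    return float(binomtest(n_hyper, n, 0.5, alternative="two-sided").pvalue)


def dmc_category_breakdown(dmcs: pd.DataFrame, contexts: pd.DataFrame) -> pd.DataFrame:
    """Hyper/hypo counts of significant DMCs per genic category.

    ``contexts`` must carry ``chrom, pos, genic`` for every DMC position.
    The hyper:hypo ratio is +inf where no hypo DMC exists in a category.
    """
    sig = dmcs[dmcs["significant"]]
    merged = sig.merge(contexts[["chrom", "pos", "genic"]], on=["chrom", "pos"], how="left")
    if merged["genic"].isna().any():
        missing = merged[merged["genic"].isna()].iloc[0]
        raise ValueError(f"no context for DMC at {missing['chrom']}:{missing['pos']}")
    rows = []
    for cat in ("promoter", "exon", "intron", "intergenic"):
        sub = merged[merged["genic"] == cat]
        n_hyper = int((sub["direction"] == "hyper").sum())
        n_hypo = int((sub["direction"] == "hypo").sum())
        if n_hypo > 0:
            ratio = n_hyper / n_hypo
        else:
            ratio = np.inf if n_hyper > 0 else np.nan
        rows.append((cat, n_hyper, n_hypo, ratio))
    return pd.DataFrame(rows, columns=["category", "n_hyper", "n_hypo", "ratio"])
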