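"""Region merging, PCA embedding and hierarchical clustering of samples.

Nearby CpGs (gap strictly below ``merge_gap`` bp, default 500) are chained
into regions whose per-sample value is the unweighted mean methylation
fraction of the member CpGs. Samples are then embedded by PCA (features
centered, not scaled) and clustered hierarchically with average linkage;
partition agreement with known groupings (lineage, differentiation day) is
scored with the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .config import AnalysisConfig
from .methylome import MethylomeMatrix

__all__ = [
    "RegionMatrix",
    "merge_cpg_regions",
    "pca_embed",
    "hierarchical_cluster",
    "grouping_agreement",
]


@dataclass
class RegionMatrix:
    """Merged-CpG regions x samples mean-methylation matrix."""

    regions: pd.DataFrame  # chrom, start, end, n_cpgs
    sample_ids: list[str]
    values: np.ndarray  # (n_regions, n_samples)

    def __len__(self) -> int:
        return len(self.regions)


def merge_cpg_regions(m: MethylomeMatrix, cfg: AnalysisConfig | None = None) -> RegionMatrix:
    """Chain consecutive CpGs closer than ``merge_gap`` bp into regions.

    Single-linkage chaining per chromosome: a CpG joins the current region
    when its distance to the previous CpG is strictly less than the gap.
    Region values are unweighted means of member-CpG fractions.
    """
    cfg = cfg or AnalysisConfig()
    fr = m.fractions()
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    order = np.lexsort((pos, chroms))
    chroms_o, pos_o = chroms[order], pos[order]
    new_chrom = np.ones(len(order), dtype=bool)
    new_chrom[1:] = chroms_o[1:] != chroms_o[:-1]
    gap_break = np.ones(len(order), dtype=bool)
    gap_break[1:] = (pos_o[1:] - pos_o[:-1]) >= cfg.merge_gap
    starts = np.flatnonzero(new_chrom | gap_break)

    if len(order) == 0:
        regions = pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs"])
        return RegionMatrix(regions=regions, sample_ids=m.sample_ids,
                            values=np.empty((0, fr.shape[1])))
    counts = np.diff(np.append(starts, len(order)))
    sums = np.add.reduceat(fr[order], starts, axis=0)
    values = sums / counts[:, None]
    regions = pd.DataFrame({
        "chrom": chroms_o[starts],
        "start": pos_o[starts],
        "end": pos_o[starts + counts - 1],
        "n_cpgs": counts,
    })
    return RegionMatrix(regions=regions, sample_ids=m.sample_ids, values=values)


def pca_embed(values: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples from a features x samples matrix.

    Features are centered but not scaled; zero-variance features are
    dropped first. Returns (sample coordinates, explained-variance
    fractions).
    """
    X = np.asarray(values, dtype=float).T  # samples x features
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > n_samples - 1:
        raise ValueError(f"n_components={n_components} exceeds samples-1={n_samples - 1}")
    var = X.var(axis=0)
    X = X[:, var > 0]
    if X.shape[1] == 0:
        raise ValueError("no feature varies across samples; PCA undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    return coords, model.explained_variance_ratio_


def hierarchical_cluster(
    values: np.ndarray,
    k: int,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of samples from features x samples values.

    ``metric`` is ``euclidean`` or ``correlation`` (1 - Pearson). Returns
    the scipy linkage matrix and flat cluster labels at ``k`` clusters.
    """
    X = np.asarray(values, dtype=float).T
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("clustering needs at least two samples")
    if not 1 <= k <= n_samples:
        raise ValueError(f"k must be in [1, {n_samples}]")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    d = pdist(X, metric=metric)
    if metric == "correlation":
        d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    Z = linkage(d, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, labels


def grouping_agreement(labels, truth_groups) -> float:
    """Adjusted Rand index between a clustering and a known grouping."""
    labels = list(labels)
    truth = list(truth_groups)
    if len(labels) != len(truth):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(truth, labels))
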