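"""The nine-sample methylome matrix and methylation-level summaries.

The matrix holds integer methylated/total counts per CpG per sample. The
common-coverage filter retains only autosomal CpGs observed with depth >=
``min_depth`` in *every* sample, so downstream code never sees missing
cells. Methylation levels are classified as lowly (<30%), partially
(30-70%, boundaries inclusive) or highly (>70%) methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CloneMatrix, CpGCallTable, SampleMeta

__all__ = [
    "MethylomeMatrix",
    "assemble_matrix",
    "filter_common_autosomal",
    "methylation_fraction",
    "classify_level",
    "classify_levels",
    "class_dynamics",
    "summarize_clone_matrix",
]

LEVEL_CLASSES = ("LM", "PM", "HM")


@dataclass
class MethylomeMatrix:
    """CpG sites x samples count matrix with sample metadata.

    ``sites`` is a DataFrame with columns ``chrom, pos`` (1-based cytosine
    positions); ``meth`` and ``depth`` are aligned integer arrays of shape
    ``(n_sites, n_samples)``.
    """

    sites: pd.DataFrame
    samples: list[SampleMeta]
    meth: np.ndarray
    depth: np.ndarray
    assembly: str = "unknown"

    def __post_init__(self) -> None:
        n, k = self.meth.shape
        if self.depth.shape != (n, k):
            raise ValueError("meth and depth shapes differ")
        if len(self.sites) != n or len(self.samples) != k:
            raise ValueError("sites/samples lengths do not match matrix shape")
        if (self.meth < 0).any() or (self.meth > self.depth).any():
            raise ValueError("need 0 <= meth <= depth elementwise")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def fractions(self) -> np.ndarray:
        """Per-cell methylation fraction; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.meth / np.maximum(self.depth, 1), np.nan)

    def __len__(self) -> int:
        return len(self.sites)


def assemble_matrix(tables: list[CpGCallTable], metas: list[SampleMeta]) -> MethylomeMatrix:
    """Join per-sample call tables over the union of CpG sites.

    Sites absent from a sample get depth 0 (they are removed later by the
    common-coverage filter).
    """
    if len(tables) != len(metas):
        raise ValueError("one SampleMeta per table required")
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id")
    assemblies = {t.assembly for t in tables}
    if len(assemblies) > 1:
        raise ValueError(f"tables declare conflicting assemblies: {sorted(assemblies)}")
    by_id = {t.sample_id: t for t in tables}
    if set(by_id) != set(ids):
        raise ValueError("table sample_ids do not match metadata sample_ids")

    frames = []
    for sid in ids:
        d = by_id[sid].data
        frames.append(pd.DataFrame({
            "chrom": d["chrom"], "pos": d["pos"],
            f"m_{sid}": d["meth"].to_numpy(),
            f"d_{sid}": (d["meth"] + d["unmeth"]).to_numpy(),
        }).set_index(["chrom", "pos"]))
    joined = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    joined = joined.sort_index()
    sites = joined.index.to_frame(index=False)
    meth = joined[[f"m_{sid}" for sid in ids]].to_numpy()
    depth = joined[[f"d_{sid}" for sid in ids]].to_numpy()
    return MethylomeMatrix(sites=sites, samples=list(metas), meth=meth, depth=depth,
                           assembly=next(iter(assemblies)) if assemblies else "unknown")


def filter_common_autosomal(m: MethylomeMatrix, cfg: AnalysisConfig) -> MethylomeMatrix:
    """Keep autosomal CpGs with depth >= ``cfg.min_depth`` in every sample."""
    autosomes = cfg.autosome_set()
    on_autosome = m.sites["chrom"].isin(autosomes).to_numpy()
    deep = (m.depth >= cfg.min_depth).all(axis=1)
    keep = on_autosome & deep
    if not keep.any():
        raise ValueError(
            f"no CpG passes the common filter (min_depth={cfg.min_depth}, "
            f"autosomes={sorted(autosomes)[:4]}...); review thresholds"
        )
    return MethylomeMatrix(
        sites=m.sites[keep].reset_index(drop=True),
        samples=m.samples,
        meth=m.meth[keep],
        depth=m.depth[keep],
        assembly=m.assembly,
    )


def methylation_fraction(m: MethylomeMatrix, site: int | tuple[str, int], sample: str) -> float:
    """Methylation fraction of one site in one sample (depth must be > 0)."""
    if isinstance(site, tuple):
        chrom, pos = site
        hit = np.flatnonzero((m.sites["chrom"] == chrom) & (m.sites["pos"] == pos))
        if len(hit) == 0:
            raise KeyError(f"site {chrom}:{pos} not in matrix")
        i = int(hit[0])
    else:
        i = site
    j = m.sample_index(sample)
    if m.depth[i, j] == 0:
        raise ValueError(f"methylation fraction undefined at depth 0 (site {i}, sample {sample})")
    return float(m.meth[i, j] / m.depth[i, j])


def classify_level(fraction: float, cfg: AnalysisConfig | None = None) -> str:
    """LM below ``lm_cut``, HM above ``hm_cut``, PM in between (inclusive)."""
    cfg = cfg or AnalysisConfig()
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    if fraction < cfg.lm_cut:
        return "LM"
    if fraction > cfg.hm_cut:
        return "HM"
    return "PM"


def classify_levels(fractions: np.ndarray, cfg: AnalysisConfig | None = None) -> np.ndarray:
    cfg = cfg or AnalysisConfig()
    fr = np.asarray(fractions, dtype=float)
    out = np.full(fr.shape, "PM", dtype=object)
    out[fr < cfg.lm_cut] = "LM"
    out[fr > cfg.hm_cut] = "HM"
    return out


def class_dynamics(
    m: MethylomeMatrix,
    pairings: list[tuple[str, str]],
    cfg: AnalysisConfig | None = None,
    cutoffs: tuple[float, ...] = (0.10, 0.20, 0.30),
) -> dict:
    """Per-sample LM/PM/HM counts and per-pairing hyper/hypo shift counts.

    Each pairing is ``(later_sample, earlier_sample)``; a CpG counts as
    hypermethylated at cutoff c if fraction(later) - fraction(earlier) >= c
    and hypomethylated if <= -c. Cutoff 0 counts every nonzero shift.
    """
    cfg = cfg or AnalysisConfig()
    fr = m.fractions()
    class_counts = {}
    for j, s in enumerate(m.samples):
        levels = classify_levels(fr[:, j], cfg)
        class_counts[s.sample_id] = {c: int((levels == c).sum()) for c in LEVEL_CLASSES}

    shifts = {}
    for later, earlier in pairings:
        jl, je = m.sample_index(later), m.sample_index(earlier)
        delta = fr[:, jl] - fr[:, je]
        per_cut = {}
        for c in cutoffs:
            if c > 0:
                n_hyper = int((delta >= c).sum())
                n_hypo = int((delta <= -c).sum())
            else:
                n_hyper = int((delta > 0).sum())
                n_hypo = int((delta < 0).sum())
            per_cut[c] = (n_hyper, n_hypo)
        shifts[(later, earlier)] = per_cut
    return {"class_counts": class_counts, "shifts": shifts}


def summarize_clone_matrix(cm: CloneMatrix) -> dict:
    """Per-site methylated fraction and the overall unmethylated-cell fraction."""
    v = cm.values
    per_site = v.mean(axis=0)
    return {
        "per_site_methylated_fraction": pd.Series(per_site, index=cm.positions),
        "unmethylated_fraction": float(1.0 - v.mean()),
        "n_clones": int(v.shape[0]),
        "n_sites": int(v.shape[1]),
    }
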