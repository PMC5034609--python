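"""Synthetic nine-sample adipogenesis methylome with known ground truth.

The generator emulates the statistical structure of an RRBS study of brown
(BAT), white (WAT) and norepinephrine-treated white (BWAT) adipocyte
differentiation sampled at days 0, 4 and 6:

* a bimodal per-CpG baseline methylation landscape (most CpGs either lowly
  or highly methylated);
* a mild global hypermethylation drift during differentiation (positive
  shifts on a subset of CpGs, growing with day);
* a lineage signature — CpGs outside promoters where WAT (and BWAT, which
  shares the white lineage) is offset from BAT, mostly upward;
* planted differentially methylated promoters: a known set of genes whose
  promoter CpGs are shifted in WAT/BWAT relative to BAT by a fixed effect
  size, in a known direction — the ground truth for recovery testing;
* a small NE-treatment signature separating BWAT from WAT;
* gene expression anti-correlated with promoter methylation, plus
  differentiation-stage expression programs shared across lineages.

Counts are beta-binomial (overdispersed relative to the binomial Fisher
null) with negative-binomial read depths. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureCatalog, build_feature_catalog
from .config import AnalysisConfig
from .io import (
    CpGCallTable,
    ExpressionTable,
    GeneModel,
    IntervalSet,
    SampleMeta,
    write_cpg_calls,
    write_expression_table,
    write_gene_models,
    write_interval_bed,
)
from .methylome import MethylomeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationResult",
    "generate_annotation",
    "build_truth",
    "generate_methylome_design",
    "generate_expression",
    "simulate_study",
    "evaluate_recovery",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults define the standard design."""

    # genome / annotation
    n_genes: int = 600
    n_cgis: int = 300
    genome_length: int = 30_000_000
    n_chroms: int = 5
    cgi_promoter_fraction: float = 0.5
    # CpG placement
    n_cpgs: int = 50_000
    min_promoter_cpgs: int = 6
    max_promoter_cpgs: int = 12
    cgi_cpg_fraction: float = 0.3
    # baseline methylation mixture
    baseline_low: float = 0.08
    baseline_high: float = 0.85
    weight_low: float = 0.55
    baseline_concentration: float = 12.0
    # planted promoter effects (WAT/BWAT relative to BAT)
    n_planted: int = 50
    effect_size: float = 0.30
    hyper_fraction: float = 0.7
    # genome-background lineage signature (outside promoters)
    lineage_fraction: float = 0.10
    lineage_effect_low: float = 0.2
    lineage_effect_high: float = 0.4
    lineage_hyper_fraction: float = 0.7
    # NE-treatment signature (BWAT only, outside promoters)
    treatment_fraction: float = 0.05
    treatment_effect: float = 0.25
    # differentiation drift
    drift_per_day: float = 0.02
    drift_fraction: float = 0.20
    drift_symmetric: bool = False
    # sequencing model
    depth_mean: float = 30.0
    depth_size: float = 8.0
    dispersion: float = 0.02
    # expression model
    expression_link: float = -4.0
    day_profile_sd: float = 1.0
    expr_noise_sd: float = 0.4
    base_expr_mean: float = 3.0
    base_expr_sd: float = 1.5
    silent_fraction: float = 0.10
    # synthetic gene family for enrichment testing
    family_planted: int = 10
    family_nonplanted: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.effect_size < 1:
            raise ValueError("effect_size must lie in (0, 1)")
        if self.n_planted > self.n_genes:
            raise ValueError("cannot plant more DMP genes than genes")
        if self.min_promoter_cpgs < 2:
            raise ValueError("planted promoters need at least 2 CpGs")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must lie in [0, 1)")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for one simulated study."""

    seed: int
    config: SimulationConfig
    genes: list[GeneModel]
    cgis: IntervalSet
    catalog: FeatureCatalog
    planted: pd.DataFrame  # gene_id, direction, effect_size
    family_genes: list[str]
    sample_metas: list[SampleMeta]
    cpg_sites: pd.DataFrame  # chrom, pos (sorted)
    pi: np.ndarray  # (n_cpgs, n_samples) expected methylation
    promoter_cpg_idx: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def planted_genes(self) -> list[str]:
        return list(self.planted["gene_id"])


@dataclass
class SimulationResult:
    truth: SyntheticTruth
    tables: list[CpGCallTable]
    metas: list[SampleMeta]
    matrix: MethylomeMatrix
    expression: ExpressionTable


def _study_metas() -> list[SampleMeta]:
    metas = []
    for lineage in ("BAT", "WAT", "BWAT"):
        for day in (0, 4, 6):
            metas.append(SampleMeta(
                sample_id=f"{lineage}_d{day}", lineage=lineage, day=day,
                treatment="NE" if lineage == "BWAT" else "none"))
    return metas


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    n_cgis: int,
    genome_length: int,
    seed: int,
    n_chroms: int = 5,
    cgi_promoter_fraction: float = 0.5,
) -> tuple[list[GeneModel], IntervalSet]:
    """Random gene models with non-overlapping bodies, plus CpG islands.

    A configurable fraction of promoters receives a CGI centered on the
    TSS; the remaining islands fall anywhere in the genome.
    """
    if min(n_genes, genome_length, n_chroms) < 0 or genome_length <= 0:
        raise ValueError("genome parameters must be positive")
    rng = np.random.default_rng([seed, 101])
    chrom_len = genome_length // n_chroms
    genes_per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                       for i in range(n_chroms)]
    genes: list[GeneModel] = []
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        k = genes_per_chrom[ci]
        if k == 0:
            continue
        # mean footprint per gene: length + flank for promoter and spacing
        slot = chrom_len // k
        if slot < 8000:
            raise ValueError("genome too small to place genes without overlap")
        cursor = 2000
        for j in range(k):
            length = int(rng.integers(3000, min(20000, slot - 4500) + 1))
            start = cursor + int(rng.integers(1500, slot - length - 2500 + 1))
            end = start + length - 1
            cursor = end + 1500  # keep promoters of neighbours apart
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 9))
            bounds = np.sort(rng.choice(np.arange(start + 1, end), size=2 * (n_ex - 1),
                                        replace=False))
            edges = np.concatenate([[start], bounds, [end]])
            exons = [(int(edges[2 * t]), int(edges[2 * t + 1])) for t in range(n_ex)]
            gi += 1
            gid = f"g{gi:04d}"
            genes.append(GeneModel(gene_id=gid, symbol=gid.upper(), chrom=chrom,
                                   strand=strand, tx_start=start, tx_end=end, exons=exons))

    cgi_rows = []
    promoter_cgi = rng.random(len(genes)) < cgi_promoter_fraction
    for g, has in zip(genes, promoter_cgi):
        if not has or len(cgi_rows) >= n_cgis:
            continue
        tss = g.tss
        half = int(rng.integers(200, 700))
        cgi_rows.append((g.chrom, max(1, tss - half), tss + half))
    while len(cgi_rows) < n_cgis:
        ci = int(rng.integers(n_chroms))
        s = int(rng.integers(1, chrom_len - 2000))
        cgi_rows.append((f"chr{ci + 1}", s, s + int(rng.integers(300, 1200))))
    cgis = IntervalSet("cgi", pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]))
    return genes, cgis


# ---------------------------------------------------------------------------
# methylation design
# ---------------------------------------------------------------------------

def _beta_around(rng, mean, concentration, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size if np.ndim(size) else (size,))
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mean * concentration, (1 - mean) * concentration)


def build_truth(cfg: SimulationConfig, seed: int) -> SyntheticTruth:
    """Lay out the genome, the CpG sites, and the expected methylation of
    every CpG in every sample (the noiseless design)."""
    genes, cgis = generate_annotation(
        cfg.n_genes, cfg.n_cgis, cfg.genome_length, seed,
        n_chroms=cfg.n_chroms, cgi_promoter_fraction=cfg.cgi_promoter_fraction)
    catalog = build_feature_catalog(genes, cgis)
    metas = _study_metas()
    rng = np.random.default_rng([seed, 202])
    chrom_len = cfg.genome_length // cfg.n_chroms

    # --- CpG placement: every promoter gets its quota, rest CGI-weighted ---
    pos_sets: dict[str, set[int]] = {f"chr{i + 1}": set() for i in range(cfg.n_chroms)}
    prom = catalog.promoters.data
    for row in prom.itertuples(index=False):
        quota = int(rng.integers(cfg.min_promoter_cpgs, cfg.max_promoter_cpgs + 1))
        span = np.arange(max(row.start, 1), row.end + 1)
        picks = rng.choice(span, size=min(quota, len(span)), replace=False)
        pos_sets[row.chrom].update(int(p) for p in picks)
    n_placed = sum(len(s) for s in pos_sets.values())
    n_rest = max(cfg.n_cpgs - n_placed, 0)
    cgi_arr = cgis.data
    while n_rest > 0:
        batch = max(int(n_rest * 1.2), 100)
        in_cgi = rng.random(batch) < cfg.cgi_cpg_fraction
        for flag in (True, False):
            k = int(in_cgi.sum()) if flag else int((~in_cgi).sum())
            if k == 0:
                continue
            if flag and len(cgi_arr):
                rows = cgi_arr.iloc[rng.integers(len(cgi_arr), size=k)]
                chroms = rows["chrom"].to_numpy()
                offs = rng.random(k)
                ps = (rows["start"].to_numpy()
                      + (offs * (rows["end"] - rows["start"] + 1).to_numpy()).astype(int))
            else:
                chroms = np.array([f"chr{c + 1}" for c in rng.integers(cfg.n_chroms, size=k)])
                ps = rng.integers(1, chrom_len, size=k)
            for ch, p in zip(chroms, ps):
                if n_rest <= 0:
                    break
                p = int(p)
                if p not in pos_sets[ch]:
                    pos_sets[ch].add(p)
                    n_rest -= 1
    sites = pd.DataFrame(
        [(ch, p) for ch in sorted(pos_sets) for p in sorted(pos_sets[ch])],
        columns=["chrom", "pos"])
    n = len(sites)

    # index CpGs per promoter
    pos_by_chrom = {c: g["pos"].to_numpy() for c, g in sites.groupby("chrom", sort=False)}
    offset_by_chrom = {}
    off = 0
    for c in sorted(pos_sets):
        offset_by_chrom[c] = off
        off += len(pos_sets[c])
    promoter_cpg_idx: dict[str, np.ndarray] = {}
    in_promoter = np.zeros(n, dtype=bool)
    for row in prom.itertuples(index=False):
        arr = pos_by_chrom[row.chrom]
        lo = np.searchsorted(arr, row.start, side="left")
        hi = np.searchsorted(arr, row.end, side="right")
        idx = np.arange(lo, hi) + offset_by_chrom[row.chrom]
        promoter_cpg_idx[row.gene_id] = idx
        in_promoter[idx] = True

    # --- baseline mixture ---
    low = rng.random(n) < cfg.weight_low
    base = np.where(
        low,
        _beta_around(rng, cfg.baseline_low, cfg.baseline_concentration, n),
        _beta_around(rng, cfg.baseline_high, cfg.baseline_concentration, n),
    )

    # --- planted promoter effects ---
    gene_ids = [g.gene_id for g in genes]
    planted_ids = sorted(rng.choice(gene_ids, size=cfg.n_planted, replace=False))
    directions = np.where(rng.random(cfg.n_planted) < cfg.hyper_fraction, "hyper", "hypo")
    planted = pd.DataFrame({"gene_id": planted_ids, "direction": directions,
                            "effect_size": cfg.effect_size})
    white_effect = np.zeros(n)  # applied to WAT and BWAT columns
    for gid, direction in zip(planted_ids, directions):
        idx = promoter_cpg_idx[gid]
        if direction == "hyper":
            base[idx] = np.clip(
                _beta_around(rng, cfg.baseline_low, cfg.baseline_concentration, len(idx)),
                0.02, 0.95 - cfg.effect_size)
            white_effect[idx] = cfg.effect_size
        else:
            base[idx] = np.clip(
                _beta_around(rng, cfg.baseline_high, cfg.baseline_concentration, len(idx)),
                0.05 + cfg.effect_size, 0.98)
            white_effect[idx] = -cfg.effect_size

    # --- lineage background outside promoters ---
    non_prom = np.flatnonzero(~in_promoter)
    n_lin = int(round(cfg.lineage_fraction * n))
    lin_idx = rng.choice(non_prom, size=min(n_lin, len(non_prom)), replace=False)
    lin_sign = np.where(rng.random(len(lin_idx)) < cfg.lineage_hyper_fraction, 1.0, -1.0)
    lin_mag = rng.uniform(cfg.lineage_effect_low, cfg.lineage_effect_high, len(lin_idx))
    pos_mask = lin_sign > 0
    base[lin_idx[pos_mask]] = np.clip(base[lin_idx[pos_mask]], 0.02, 0.95 - lin_mag[pos_mask])
    base[lin_idx[~pos_mask]] = np.clip(base[lin_idx[~pos_mask]], 0.05 + lin_mag[~pos_mask], 0.98)
    white_effect[lin_idx] += lin_sign * lin_mag

    # --- NE treatment signature (BWAT only), disjoint from lineage CpGs ---
    remaining = np.setdiff1d(non_prom, lin_idx, assume_unique=False)
    n_tr = int(round(cfg.treatment_fraction * n))
    tr_idx = rng.choice(remaining, size=min(n_tr, len(remaining)), replace=False)
    tr_sign = np.where(rng.random(len(tr_idx)) < 0.5, 1.0, -1.0)
    treat_effect = np.zeros(n)
    treat_effect[tr_idx] = tr_sign * cfg.treatment_effect

    # --- differentiation drift ---
    n_drift = int(round(cfg.drift_fraction * n))
    drift_idx = rng.choice(n, size=n_drift, replace=False)
    drift_dir = np.ones(n_drift)
    if cfg.drift_symmetric:
        drift_dir = np.where(rng.random(n_drift) < 0.5, 1.0, -1.0)

    # --- assemble per-sample expected methylation ---
    pi = np.tile(base[:, None], (1, len(metas)))
    for j, meta in enumerate(metas):
        if meta.lineage in ("WAT", "BWAT"):
            pi[:, j] += white_effect
        if meta.lineage == "BWAT":
            pi[:, j] += treat_effect
        if meta.day and cfg.drift_per_day:
            pi[drift_idx, j] += drift_dir * cfg.drift_per_day * meta.day
    pi = np.clip(pi, 0.005, 0.995)

    return SyntheticTruth(
        seed=seed, config=cfg, genes=genes, cgis=cgis, catalog=catalog,
        planted=planted, family_genes=_pick_family(rng, cfg, planted_ids, gene_ids),
        sample_metas=metas, cpg_sites=sites, pi=pi,
        promoter_cpg_idx=promoter_cpg_idx,
    )


def _pick_family(rng, cfg: SimulationConfig, planted_ids, gene_ids) -> list[str]:
    """A synthetic gene family concentrated in the planted set, for
    enrichment testing (the analogue of a Hox-family gene list)."""
    k_in = min(cfg.family_planted, len(planted_ids))
    members = list(rng.choice(planted_ids, size=k_in, replace=False))
    others = sorted(set(gene_ids) - set(planted_ids))
    k_out = min(cfg.family_nonplanted, len(others))
    members += list(rng.choice(others, size=k_out, replace=False))
    return sorted(members)


def generate_methylome_design(
    truth: SyntheticTruth,
) -> tuple[list[CpGCallTable], list[SampleMeta], MethylomeMatrix]:
    """Draw read depths and beta-binomial methylation counts from the truth."""
    cfg = truth.config
    rng = np.random.default_rng([truth.seed, 303])
    n, k = truth.pi.shape
    r = cfg.depth_size
    p_nb = r / (r + (cfg.depth_mean - 1.0))
    depth = 1 + rng.negative_binomial(r, p_nb, size=(n, k))
    if cfg.dispersion > 0:
        c = (1.0 - cfg.dispersion) / cfg.dispersion
        p_cell = rng.beta(truth.pi * c, (1.0 - truth.pi) * c)
    else:
        p_cell = truth.pi
    meth = rng.binomial(depth, p_cell)

    matrix = MethylomeMatrix(sites=truth.cpg_sites.copy(), samples=list(truth.sample_metas),
                             meth=meth, depth=depth, assembly="synthetic")
    tables = []
    for j, meta in enumerate(truth.sample_metas):
        df = pd.DataFrame({
            "chrom": truth.cpg_sites["chrom"],
            "pos": truth.cpg_sites["pos"],
            "meth": meth[:, j],
            "unmeth": depth[:, j] - meth[:, j],
        })
        tables.append(CpGCallTable(sample_id=meta.sample_id, data=df, assembly="synthetic"))
    return tables, list(truth.sample_metas), matrix


def generate_expression(truth: SyntheticTruth, metas: list[SampleMeta] | None = None) -> ExpressionTable:
    """Gene x sample FPKM driven by day programs and promoter methylation.

    log2 expression = gene baseline + a per-day expression program shared
    across lineages + ``expression_link`` times the deviation of the
    sample's promoter methylation from the gene's cross-sample mean +
    Gaussian noise. FPKM = 2^x - 1 clipped at zero.
    """
    cfg = truth.config
    metas = metas if metas is not None else truth.sample_metas
    rng = np.random.default_rng([truth.seed, 404])
    gene_ids = [g.gene_id for g in truth.genes]
    n_genes = len(gene_ids)

    base = rng.normal(cfg.base_expr_mean, cfg.base_expr_sd, n_genes)
    silent = rng.random(n_genes) < cfg.silent_fraction
    base[silent] = rng.normal(-2.0, 1.0, int(silent.sum()))
    day_programs = {d: rng.normal(0.0, cfg.day_profile_sd, n_genes) for d in (0, 4, 6)}

    # promoter methylation per gene per sample, from the noiseless design
    pm = np.zeros((n_genes, len(metas)))
    for gi, gid in enumerate(gene_ids):
        idx = truth.promoter_cpg_idx.get(gid, np.empty(0, dtype=int))
        if len(idx):
            pm[gi] = truth.pi[idx].mean(axis=0)
    pm_centered = pm - pm.mean(axis=1, keepdims=True)

    x = np.empty((n_genes, len(metas)))
    for j, meta in enumerate(metas):
        x[:, j] = (base + day_programs[meta.day]
                   + cfg.expression_link * pm_centered[:, j]
                   + rng.normal(0.0, cfg.expr_noise_sd, n_genes))
    fpkm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    df = pd.DataFrame(fpkm, index=gene_ids, columns=[m.sample_id for m in metas])
    return ExpressionTable(fpkm=df)


def simulate_study(cfg: SimulationConfig | None = None, seed: int = 42) -> SimulationResult:
    """Generate the full nine-sample design: methylome + expression + truth."""
    cfg = cfg or SimulationConfig()
    truth = build_truth(cfg, seed)
    tables, metas, matrix = generate_methylome_design(truth)
    expression = generate_expression(truth, metas)
    return SimulationResult(truth=truth, tables=tables, metas=metas,
                            matrix=matrix, expression=expression)


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(truth: SyntheticTruth, called) -> dict:
    """Score a consistent-gene call set against the planted truth.

    ``called`` is a :class:`~methdyn.integrate.ConsistentGeneSet` or a
    DataFrame with ``gene_id`` and ``direction``. Directions are relative
    to WAT (hyper = more methylated in WAT than BAT), matching the planted
    convention. FDR is NaN when nothing was called.
    """
    genes = called.genes if hasattr(called, "genes") else called
    planted = truth.planted.set_index("gene_id")["direction"]
    called_ids = list(genes["gene_id"])
    called_dirs = dict(zip(genes["gene_id"], genes["direction"]))
    n_called = len(called_ids)
    hits = [g for g in called_ids if g in planted.index]
    recall = len(hits) / len(planted) if len(planted) else float("nan")
    fdr = (n_called - len(hits)) / n_called if n_called else float("nan")
    if hits:
        acc = float(np.mean([called_dirs[g] == planted.loc[g] for g in hits]))
    else:
        acc = float("nan")
    return {"recall": recall, "fdr": fdr, "direction_accuracy": acc,
            "n_called": n_called, "n_planted": int(len(planted))}


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated study as the pipeline's external file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t in result.tables:
        paths[t.sample_id] = write_cpg_calls(t, out / f"{t.sample_id}.cov.tsv",
                                             dialect="coverage_percent")
    paths["genes"] = write_gene_models(result.truth.genes, out / "genes.refflat")
    paths["cgi"] = write_interval_bed(result.truth.cgis, out / "cgi.bed")
    paths["expression"] = write_expression_table(result.expression, out / "fpkm.tsv")
    meta_df = pd.DataFrame([asdict(m) for m in result.metas])
    meta_path = out / "samples.tsv"
    meta_df.to_csv(meta_path, sep="\t", index=False)
    paths["samples"] = meta_path
    truth_payload = {
        "seed": result.truth.seed,
        "config": asdict(result.truth.config),
        "planted_dmp_genes": result.truth.planted.to_dict(orient="records"),
        "family_genes": result.truth.family_genes,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
    paths["truth"] = truth_path
    fam_path = out / "family.txt"
    fam_path.write_text("\n".join(result.truth.family_genes) + "\n")
    paths["family"] = fam_path
    return paths
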