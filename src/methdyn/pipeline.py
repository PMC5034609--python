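"""End-to-end orchestration: filter -> annotate -> DMC/DMP -> consistency
-> enrichment -> correlation -> clustering, with a machine-readable report.

The heavy lifting lives in :func:`analyze_study`, which operates on
in-memory objects; :func:`run_full_analysis` is the file-based wrapper
driven by one YAML config. Every stage output is a pure function of
(inputs, config, seed), so a rerun reproduces the report exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import FeatureCatalog, assign_contexts, build_feature_catalog, region_cpg_coverage
from .cluster import grouping_agreement, hierarchical_cluster, merge_cpg_regions, pca_embed
from .config import AnalysisConfig
from .differential import (
    ComparisonSpec,
    call_dmcs,
    call_dmps,
    direction_dominance_test,
    dmc_category_breakdown,
)
from .integrate import (
    consistent_dmps,
    expression_log2_fold_change,
    filter_expressed,
    hypergeometric_enrichment,
    methylation_expression_correlation,
)
from .io import (
    ExpressionTable,
    SampleMeta,
    read_cpg_calls,
    read_expression_table,
    read_gene_models,
    read_interval_bed,
    write_result_tables,
)
from .methylome import MethylomeMatrix, assemble_matrix, class_dynamics, filter_common_autosomal

logger = logging.getLogger("methdyn")

__all__ = ["default_comparisons", "analyze_study", "depot_consistency",
           "run_full_analysis", "read_sample_table"]


def depot_consistency(
    matrix: MethylomeMatrix,
    catalog: FeatureCatalog,
    cfg: AnalysisConfig | None = None,
    days: tuple[int, ...] = (0, 4, 6),
):
    """WAT-vs-BAT DMC/DMP calling at each day plus the consistent-gene set.

    A focused subset of :func:`analyze_study` for recovery and calibration
    work: returns ``(dmc_tables, dmp_tables, consistent_set)`` keyed by
    day label. The matrix must already be common-coverage filtered.
    """
    cfg = cfg or AnalysisConfig()
    dmc_tables: dict[str, pd.DataFrame] = {}
    dmp_tables: dict[str, pd.DataFrame] = {}
    for day in days:
        label = f"WAT-BAT_d{day}"
        spec = ComparisonSpec(target=f"WAT_d{day}", reference=f"BAT_d{day}", label=label)
        dmcs = call_dmcs(matrix, spec, cfg)
        dmc_tables[label] = dmcs
        dmp_tables[label] = call_dmps(dmcs, catalog, cfg, sites=matrix.sites)
    consistent = consistent_dmps(list(dmp_tables.items()))
    return dmc_tables, dmp_tables, consistent


def default_comparisons(metas: list[SampleMeta]) -> tuple[list[ComparisonSpec], list[str]]:
    """The study's headline comparisons.

    Within-lineage time courses (day 4 - day 0, day 6 - day 0 for BAT and
    WAT; later day is the target) and the time-matched depot comparisons
    (WAT - BAT at days 0, 4, 6; WAT is the target). Returns the specs and
    the labels of the depot comparisons used for the consistency stage.
    """
    ids = {(m.lineage, m.day): m.sample_id for m in metas}
    specs: list[ComparisonSpec] = []
    for lineage in ("BAT", "WAT"):
        for day in (4, 6):
            if (lineage, day) in ids and (lineage, 0) in ids:
                specs.append(ComparisonSpec(target=ids[(lineage, day)],
                                            reference=ids[(lineage, 0)],
                                            label=f"{lineage}_d{day}-d0"))
    consistency = []
    for day in (0, 4, 6):
        if ("WAT", day) in ids and ("BAT", day) in ids:
            label = f"WAT-BAT_d{day}"
            specs.append(ComparisonSpec(target=ids[("WAT", day)],
                                        reference=ids[("BAT", day)], label=label))
            consistency.append(label)
    return specs, consistency


def analyze_study(
    matrix: MethylomeMatrix,
    catalog: FeatureCatalog,
    cfg: AnalysisConfig | None = None,
    expression: ExpressionTable | None = None,
    family_genes: list[str] | None = None,
    comparisons: list[ComparisonSpec] | None = None,
    consistency_labels: list[str] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every analysis stage on an assembled (unfiltered) matrix.

    Returns the run report as a JSON-serializable dict; when ``out_dir``
    is given, per-comparison DMC/DMP tables and the consistent-gene set
    are also written there.
    """
    cfg = cfg or AnalysisConfig()
    report: dict = {"tool_version": __version__, "seed": seed, "config": cfg.to_dict()}

    # ---- filter ----
    logger.info("common-coverage filter (min_depth=%d)", cfg.min_depth)
    n_raw = len(matrix)
    filtered = filter_common_autosomal(matrix, cfg)
    report["n_cpgs_raw"] = n_raw
    report["n_cpgs_filtered"] = len(filtered)

    # ---- annotation ----
    logger.info("annotating %d CpGs", len(filtered))
    contexts = assign_contexts(filtered.sites, catalog)
    report["genic_distribution"] = contexts["genic"].value_counts().to_dict()
    report["cgi_distribution"] = contexts["cgi"].value_counts().to_dict()
    coverage = {}
    for name, iset in (("promoters", catalog.promoters),
                       ("gene_bodies", catalog.gene_bodies),
                       ("cgis", catalog.cgi_islands)):
        if len(iset):
            n_cov, frac = region_cpg_coverage(filtered.sites, iset)
            coverage[name] = {"n_covered": n_cov, "fraction": frac}
    report["region_coverage"] = coverage

    # ---- methylation classes and time-course shifts ----
    metas = filtered.samples
    pairings = [(m.sample_id, ids0) for m in metas if m.day > 0
                for ids0 in [f"{m.lineage}_d0"]
                if ids0 in filtered.sample_ids]
    dyn = class_dynamics(filtered, pairings, cfg)
    report["class_counts"] = dyn["class_counts"]
    report["class_shifts"] = {f"{a}|{b}": {str(c): v for c, v in d.items()}
                              for (a, b), d in dyn["shifts"].items()}

    # ---- differential methylation ----
    if comparisons is None:
        comparisons, auto_consistency = default_comparisons(metas)
        if consistency_labels is None:
            consistency_labels = auto_consistency
    per_comp: dict[str, dict] = {}
    dmp_tables: dict[str, pd.DataFrame] = {}
    for spec in comparisons:
        logger.info("comparison %s: %s vs %s", spec.label, spec.target, spec.reference)
        dmcs = call_dmcs(filtered, spec, cfg)
        dmps = call_dmps(dmcs, catalog, cfg, sites=filtered.sites)
        dmp_tables[spec.label] = dmps
        sig = dmcs[dmcs["significant"]]
        n_hyper = int((sig["direction"] == "hyper").sum())
        n_hypo = int((sig["direction"] == "hypo").sum())
        entry = {
            "target": spec.target, "reference": spec.reference,
            "n_tested": int(len(dmcs)), "n_significant": int(len(sig)),
            "n_hyper": n_hyper, "n_hypo": n_hypo,
            "dominance_p": (direction_dominance_test(n_hyper, n_hypo)
                            if n_hyper + n_hypo > 0 else None),
            "n_dmps": int(len(dmps)),
        }
        breakdown = dmc_category_breakdown(dmcs, contexts)
        entry["category_breakdown"] = [
            {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in rec.items()}
            for rec in breakdown.to_dict(orient="records")
        ]
        per_comp[spec.label] = entry
        if out_dir is not None:
            comp_dir = Path(out_dir) / f"comparison_{spec.label}"
            write_result_tables(dmcs, dmps, None, comp_dir)
    report["comparisons"] = per_comp

    # ---- consistency across timepoints ----
    consistent = None
    if consistency_labels:
        missing = [lab for lab in consistency_labels if lab not in dmp_tables]
        if missing:
            raise ValueError(f"consistency labels not among comparisons: {missing}")
        if len(consistency_labels) >= 2:
            consistent = consistent_dmps(
                [(lab, dmp_tables[lab]) for lab in consistency_labels])
            report["consistency_labels"] = list(consistency_labels)
            report["consistent_genes"] = {
                "n": len(consistent),
                "n_hyper": len(consistent.hyper),
                "n_hypo": len(consistent.hypo),
                "genes": consistent.genes.to_dict(orient="records"),
            }
            if out_dir is not None:
                write_result_tables(None, None, consistent.genes, Path(out_dir))

    # ---- enrichment ----
    if family_genes is not None and consistent is not None:
        universe = _covered_promoter_genes(filtered.sites, catalog)
        gset = [g for g in consistent.genes["gene_id"] if g in universe]
        enr = hypergeometric_enrichment(gset, [g for g in family_genes if g in universe],
                                        universe)
        report["enrichment"] = asdict(enr)

    # ---- methylation-expression correlation ----
    if expression is not None:
        expressed = filter_expressed(expression, cfg)
        report["n_genes_expressed"] = len(expressed.genes)
        wat = [m.sample_id for m in metas if m.lineage == "WAT"]
        bat = [m.sample_id for m in metas if m.lineage == "BAT"]
        if wat and bat:
            deltas = _promoter_delta(filtered, catalog, wat, bat)
            lfc = expression_log2_fold_change(expressed, wat, bat)
            shared = deltas.index.intersection(lfc.index)
            if len(shared) >= 3:
                corr = methylation_expression_correlation(deltas, lfc, seed=seed)
                report["methylation_expression"] = corr

    # ---- clustering ----
    regions = merge_cpg_regions(filtered, cfg)
    report["n_regions"] = len(regions)
    k_lineage = len({m.lineage for m in metas})
    _, meth_labels = hierarchical_cluster(regions.values, k=k_lineage, metric="euclidean")
    lineage_truth = [m.lineage for m in metas]
    clustering = {"methylome_lineage_ari": grouping_agreement(meth_labels, lineage_truth)}
    _, evr = pca_embed(regions.values, n_components=2)
    clustering["methylome_pc1_variance"] = float(evr[0])
    if expression is not None:
        expressed = filter_expressed(expression, cfg)
        logf = np.log2(expressed.fpkm[ [m.sample_id for m in metas] ].to_numpy() + 1.0)
        k_day = len({m.day for m in metas})
        _, expr_labels = hierarchical_cluster(logf, k=k_day, metric="correlation")
        clustering["transcriptome_day_ari"] = grouping_agreement(
            expr_labels, [m.day for m in metas])
    report["clustering"] = clustering

    _check_report(report)
    return report


def _covered_promoter_genes(sites: pd.DataFrame, catalog: FeatureCatalog) -> list[str]:
    """Genes whose promoter contains at least one analyzable CpG."""
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in sites.groupby("chrom", sort=False)}
    out = []
    for row in catalog.promoters.data.itertuples(index=False):
        pos = pos_by_chrom.get(row.chrom)
        if pos is None:
            continue
        if (np.searchsorted(pos, row.end, side="right")
                - np.searchsorted(pos, row.start, side="left")) >= 1:
            out.append(row.gene_id)
    return out


def _promoter_delta(
    m: MethylomeMatrix, catalog: FeatureCatalog,
    target_samples: list[str], reference_samples: list[str],
) -> pd.Series:
    """Per-gene promoter methylation difference (mean fraction over promoter
    CpGs, averaged over target samples minus reference samples)."""
    fr = m.fractions()
    jt = [m.sample_index(s) for s in target_samples]
    jr = [m.sample_index(s) for s in reference_samples]
    pos_by_chrom = {}
    for c, g in m.sites.groupby("chrom", sort=False):
        pos_by_chrom[c] = (g["pos"].to_numpy(), g.index.to_numpy())
    vals = {}
    for row in catalog.promoters.data.itertuples(index=False):
        got = pos_by_chrom.get(row.chrom)
        if got is None:
            continue
        pos, idx = got
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        if hi - lo == 0:
            continue
        sub = fr[idx[lo:hi]]
        vals[row.gene_id] = float(sub[:, jt].mean() - sub[:, jr].mean())
    return pd.Series(vals, name="promoter_delta")


def _check_report(report: dict) -> None:
    """Internal consistency of the aggregated counts."""
    cons = report.get("consistent_genes")
    if cons is not None:
        n_dmps = [report["comparisons"][lab]["n_dmps"]
                  for lab in report.get("consistency_labels", [])
                  if lab in report["comparisons"]]
        if n_dmps and cons["n"] > min(n_dmps):
            raise AssertionError("consistent gene count exceeds a timepoint's DMP count")
    for comp in report["comparisons"].values():
        if comp["n_hyper"] + comp["n_hypo"] != comp["n_significant"]:
            raise AssertionError("hyper+hypo does not sum to significant DMCs")


# ---------------------------------------------------------------------------
# file-driven entry point
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV: sample_id, lineage, day, treatment."""
    df = pd.read_csv(path, sep="\t")
    return [SampleMeta(sample_id=str(r.sample_id), lineage=str(r.lineage),
                       day=int(r.day), treatment=str(getattr(r, "treatment", "none")))
            for r in df.itertuples(index=False)]


def run_full_analysis(config_path: str | Path) -> dict:
    """Execute the full pipeline from a YAML run config.

    The config carries input paths, analysis thresholds, the comparison
    list and the output directory; the effective configuration is echoed
    into the report. Any stage failure aborts with the stage name and
    leaves a FAILED marker next to the partial outputs.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        run_cfg = yaml.safe_load(fh)
    inputs = run_cfg.get("inputs", {})
    out_dir = Path(run_cfg.get("out_dir", config_path.parent / "methdyn_out"))
    cfg = AnalysisConfig(**run_cfg.get("analysis", {}))
    seed = int(run_cfg.get("seed", 0))

    # validate inputs before any computation
    required = ["samples", "genes", "cgi"]
    for key in required:
        if key not in inputs:
            raise ValueError(f"run config missing required input {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found: {inputs[key]}")
    stages = run_cfg.get("stages", {})
    if stages.get("correlation", True) and "expression" in inputs:
        if not Path(inputs["expression"]).exists():
            raise FileNotFoundError(f"expression file not found: {inputs['expression']}")
    calls_cfg = inputs.get("calls", [])
    if not calls_cfg:
        raise ValueError("run config must list CpG call files under inputs.calls")
    for entry in calls_cfg:
        if not Path(entry["path"]).exists():
            raise FileNotFoundError(f"call file not found: {entry['path']}")

    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "FAILED"
    stage = "io"
    try:
        metas = read_sample_table(inputs["samples"])
        meta_by_id = {m.sample_id: m for m in metas}
        tables = []
        for entry in calls_cfg:
            t = read_cpg_calls(entry["path"], dialect=entry.get("dialect", "coverage_percent"),
                               sample_id=entry.get("sample_id"),
                               assembly=entry.get("assembly", "unknown"),
                               collapse_strands=bool(entry.get("collapse_strands", False)))
            if t.sample_id not in meta_by_id:
                raise ValueError(f"call file sample {t.sample_id!r} missing from sample table")
            tables.append(t)
        genes = read_gene_models(inputs["genes"], format=inputs.get("genes_format", "refFlat"))
        cgis = read_interval_bed(inputs["cgi"], name="cgi")
        expression = (read_expression_table(inputs["expression"])
                      if "expression" in inputs else None)
        family = None
        if "family" in inputs:
            family = [l.strip() for l in Path(inputs["family"]).read_text().splitlines()
                      if l.strip()]

        stage = "assemble"
        ordered_metas = [meta_by_id[t.sample_id] for t in tables]
        matrix = assemble_matrix(tables, ordered_metas)
        catalog = build_feature_catalog(genes, cgis, cfg)

        stage = "analysis"
        comparisons = None
        if "comparisons" in run_cfg:
            comparisons = [ComparisonSpec(**c) for c in run_cfg["comparisons"]]
        report = analyze_study(
            matrix, catalog, cfg, expression=expression, family_genes=family,
            comparisons=comparisons,
            consistency_labels=run_cfg.get("consistency_comparisons"),
            seed=seed, out_dir=out_dir)

        stage = "report"
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        if marker.exists():
            marker.unlink()
        logger.info("report written to %s", report_path)
        return report
    except Exception as exc:
        marker.write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
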