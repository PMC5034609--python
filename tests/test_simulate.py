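import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn import AnalysisConfig
from methdyn.methylome import classify_levels, filter_common_autosomal
from methdyn.pipeline import depot_consistency
from methdyn.simulate import (
    SimulationConfig,
    build_truth,
    evaluate_recovery,
    generate_annotation,
    generate_expression,
    simulate_study,
    write_simulation,
)

SMALL = SimulationConfig(n_genes=60, n_cgis=40, genome_length=6_000_000,
                         n_chroms=2, n_cpgs=5000, n_planted=10)
CFG2 = AnalysisConfig(autosomes={"chr1", "chr2"})


def small_with(seed=1, **overrides):
    params = {**SMALL.__dict__, **overrides}
    return simulate_study(SimulationConfig(**params), seed=seed)


class TestAnnotationGeneration:
    def test_deterministic_and_valid(self):
        g1, c1 = generate_annotation(10, 5, 1_000_000, seed=1, n_chroms=1)
        g2, c2 = generate_annotation(10, 5, 1_000_000, seed=1, n_chroms=1)
        assert g1 == g2
        pd.testing.assert_frame_equal(c1.data, c2.data)
        assert len(g1) == 10
        # non-overlapping gene bodies (validated per chromosome)
        spans = sorted((g.tx_start, g.tx_end) for g in g1)
        assert all(spans[i][1] < spans[i + 1][0] for i in range(len(spans) - 1))

    def test_zero_genes_allowed(self):
        genes, cgis = generate_annotation(0, 5, 1_000_000, seed=1, n_chroms=1)
        assert genes == [] and len(cgis) == 5

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_annotation(100, 5, 100_000, seed=1, n_chroms=1)


class TestDeterminism:
    def test_same_seed_identical_study(self):
        a = small_with(seed=7)
        b = small_with(seed=7)
        assert np.array_equal(a.matrix.meth, b.matrix.meth)
        assert np.array_equal(a.matrix.depth, b.matrix.depth)
        pd.testing.assert_frame_equal(a.expression.fpkm, b.expression.fpkm)
        pd.testing.assert_frame_equal(a.truth.planted, b.truth.planted)

    def test_different_seed_differs(self):
        a = small_with(seed=7)
        b = small_with(seed=8)
        assert not np.array_equal(a.matrix.meth, b.matrix.meth)

    def test_written_files_bitwise_identical(self, tmp_path):
        pa = write_simulation(small_with(seed=3), tmp_path / "a")
        pb = write_simulation(small_with(seed=3), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key


class TestPlantedStructure:
    def test_planted_promoters_have_enough_cpgs(self, small_sim):
        truth = small_sim.truth
        for gid in truth.planted_genes:
            assert len(truth.promoter_cpg_idx[gid]) >= truth.config.min_promoter_cpgs

    def test_planted_effect_visible_in_observed_means(self, default_sim):
        """Observed WAT-BAT promoter methylation gap matches the planted
        effect size to within 0.05, averaged over promoter CpGs."""
        truth = default_sim.truth
        m = default_sim.matrix
        fr = m.meth / m.depth
        wat = [j for j, s in enumerate(m.samples) if s.lineage == "WAT"]
        bat = [j for j, s in enumerate(m.samples) if s.lineage == "BAT"]
        gaps = []
        for rec in truth.planted.itertuples(index=False):
            idx = truth.promoter_cpg_idx[rec.gene_id]
            gap = fr[np.ix_(idx, wat)].mean() - fr[np.ix_(idx, bat)].mean()
            signed = gap if rec.direction == "hyper" else -gap
            gaps.append(signed - rec.effect_size)
        assert np.abs(np.mean(gaps)) < 0.05
        assert np.abs(gaps).max() < 0.15

    def test_null_effect_leaves_only_noise(self):
        sim = small_with(seed=5, n_planted=0, lineage_fraction=0.0,
                         treatment_fraction=0.0, drift_per_day=0.0)
        fr = sim.matrix.meth / sim.matrix.depth
        wat = [j for j, s in enumerate(sim.matrix.samples) if s.lineage == "WAT"]
        bat = [j for j, s in enumerate(sim.matrix.samples) if s.lineage == "BAT"]
        gap = fr[:, wat].mean() - fr[:, bat].mean()
        assert abs(gap) < 0.01


class TestDriftBehaviour:
    def test_zero_drift_day_class_distributions_match(self):
        """Without drift (or any other day-dependent effect) the LM/PM/HM
        composition is statistically identical across days."""
        pvals = []
        for seed in range(10):
            sim = small_with(seed=100 + seed, drift_per_day=0.0, n_planted=0,
                             lineage_fraction=0.0, treatment_fraction=0.0)
            m = filter_common_autosomal(sim.matrix, CFG2)
            fr = m.fractions()
            counts = []
            for day in (0, 6):
                j = m.sample_index(f"BAT_d{day}")
                lv = classify_levels(fr[:, j])
                counts.append([int((lv == c).sum()) for c in ("LM", "PM", "HM")])
            pvals.append(stats.chi2_contingency(np.array(counts)).pvalue)
        assert np.median(pvals) > 0.05
        assert sum(p > 0.01 for p in pvals) >= 9

    def test_positive_drift_inflates_hyper_calls(self):
        sim = small_with(seed=6, drift_per_day=0.04)
        m = filter_common_autosomal(sim.matrix, CFG2)
        fr = m.fractions()
        j6 = m.sample_index("BAT_d6")
        j0 = m.sample_index("BAT_d0")
        delta = fr[:, j6] - fr[:, j0]
        assert (delta >= 0.1).sum() > 2 * (delta <= -0.1).sum()


class TestExpressionLink:
    def _planted_delta_and_lfc(self, sim):
        truth = sim.truth
        pm = {g: truth.pi[truth.promoter_cpg_idx[g]].mean(axis=0)
              for g in truth.planted_genes}
        wat = [j for j, s in enumerate(truth.sample_metas) if s.lineage == "WAT"]
        bat = [j for j, s in enumerate(truth.sample_metas) if s.lineage == "BAT"]
        deltas = pd.Series({g: v[wat].mean() - v[bat].mean() for g, v in pm.items()})
        f = sim.expression.fpkm
        wat_ids = [s.sample_id for s in truth.sample_metas if s.lineage == "WAT"]
        bat_ids = [s.sample_id for s in truth.sample_metas if s.lineage == "BAT"]
        lfc = np.log2((f[wat_ids].mean(axis=1) + 1) / (f[bat_ids].mean(axis=1) + 1))
        return deltas, lfc.loc[deltas.index]

    def test_zero_link_gives_no_correlation(self):
        sim = small_with(seed=9, expression_link=0.0)
        deltas, lfc = self._planted_delta_and_lfc(sim)
        rho = stats.spearmanr(deltas, lfc).statistic
        assert abs(rho) < 0.5

    def test_default_link_anticorrelates(self):
        sim = small_with(seed=9)
        deltas, lfc = self._planted_delta_and_lfc(sim)
        rho = stats.spearmanr(deltas, lfc).statistic
        assert rho < -0.5  # 10 planted genes: rank correlation is coarse

    def test_zero_day_effect_removes_day_clustering(self):
        from methdyn.cluster import grouping_agreement, hierarchical_cluster
        sim = small_with(seed=9, day_profile_sd=0.0)
        logf = np.log2(sim.expression.fpkm.to_numpy() + 1.0)
        _, labels = hierarchical_cluster(logf, k=3, metric="correlation")
        ari = grouping_agreement(labels, [s.day for s in sim.metas])
        assert ari < 0.5


class TestRecoveryScoring:
    def test_perfect_caller(self, small_sim):
        truth = small_sim.truth
        perfect = truth.planted.rename(columns={"effect_size": "mean_delta"})
        res = evaluate_recovery(truth, perfect)
        assert (res["recall"], res["fdr"], res["direction_accuracy"]) == (1.0, 0.0, 1.0)

    def test_empty_caller(self, small_sim):
        empty = pd.DataFrame(columns=["gene_id", "direction"])
        res = evaluate_recovery(small_sim.truth, empty)
        assert res["recall"] == 0.0 and np.isnan(res["fdr"])

    def test_random_caller_fdr_matches_expectation(self, small_sim):
        truth = small_sim.truth
        rng = np.random.default_rng(2)
        all_genes = [g.gene_id for g in truth.genes]
        called = pd.DataFrame({
            "gene_id": rng.choice(all_genes, size=30, replace=False),
            "direction": "hyper"})
        res = evaluate_recovery(truth, called)
        planted_fraction = len(truth.planted) / len(all_genes)
        assert res["fdr"] == pytest.approx(1 - planted_fraction, abs=0.15)


class TestCalibrationProperties:
    def test_planted_null_rarely_calls_consistent_genes(self):
        """With no planted effects and no drift the cross-timepoint
        consistent set is empty in at least 95% of seeds."""
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim = small_with(seed=300 + seed, n_planted=0, lineage_fraction=0.0,
                             treatment_fraction=0.0, drift_per_day=0.0)
            m = filter_common_autosomal(sim.matrix, CFG2)
            _, _, consistent = depot_consistency(m, sim.truth.catalog, CFG2)
            empty += int(len(consistent) == 0)
        assert empty / n_seeds >= 0.95

    def test_recall_monotone_in_effect_and_depth(self):
        """Average consistent-DMP recall never decreases when the planted
        effect size or the mean depth grows (3x3 grid, 5 seeds per cell)."""
        effects = (0.15, 0.30, 0.50)
        depths = (20.0, 30.0, 60.0)
        recall = np.zeros((3, 3))
        for i, eff in enumerate(effects):
            for j, dep in enumerate(depths):
                vals = []
                for seed in range(5):
                    sim = small_with(seed=500 + seed, effect_size=eff, depth_mean=dep)
                    m = filter_common_autosomal(sim.matrix, CFG2)
                    _, _, consistent = depot_consistency(m, sim.truth.catalog, CFG2)
                    vals.append(evaluate_recovery(sim.truth, consistent)["recall"])
                recall[i, j] = np.mean(vals)
        tol = 0.05  # sampling noise allowance at 5 seeds per cell
        assert (np.diff(recall, axis=0) >= -tol).all(), recall
        assert (np.diff(recall, axis=1) >= -tol).all(), recall
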