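import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn import AnalysisConfig
from methdyn.annotation import build_feature_catalog
from methdyn.differential import (
    ComparisonSpec,
    bh_adjust,
    call_dmcs,
    call_dmps,
    direction_dominance_test,
    dmc_category_breakdown,
    fisher_exact_many,
    fisher_exact_two_sided,
)
from methdyn.io import GeneModel, IntervalSet, SampleMeta
from methdyn.methylome import MethylomeMatrix


def exact_fisher_oracle(a, b, c, d, rel_tol=1e-7):
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    n1, n2 = a + b, c + d
    k = a + c
    w_obs = math.comb(n1, a) * math.comb(n2, c)
    total = math.comb(n1 + n2, k)
    p = 0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        w = math.comb(n1, x) * math.comb(n2, k - x)
        if w <= w_obs or (w - w_obs) <= rel_tol * w_obs:
            p += w
    return p / total


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_value(self):
        # margins (10,10;10,10): the two extreme tables each carry 1/C(20,10)
        assert fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)

    def test_zero_methylated_margin_is_one(self):
        assert fisher_exact_two_sided(0, 10, 0, 10) == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        tables = rng.integers(0, 25, size=(300, 4))
        a, b, c, d = tables.T
        got = fisher_exact_many(a, a + b, c, c + d)
        for i in range(len(tables)):
            want = stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]])[1]
            assert got[i] == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_matches_integer_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(1, 61))
            n1 = int(rng.integers(0, n + 1))
            n2 = n - n1
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            got = fisher_exact_two_sided(a, n1 - a, c, n2 - c)
            want = exact_fisher_oracle(a, n1 - a, c, n2 - c)
            assert got == pytest.approx(want, rel=1e-7, abs=1e-300)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_flattens_linear_ps(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_pair(self):
        assert bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_empty_list(self):
        assert bh_adjust([]).size == 0

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted-p order
            perm = rng.permutation(len(p))
            assert bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def two_sample_matrix(meth_t, depth_t, meth_r, depth_r):
    n = len(meth_t)
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1) * 1000})
    samples = [SampleMeta("T", "WAT", 0), SampleMeta("R", "BAT", 0)]
    return MethylomeMatrix(
        sites, samples,
        np.column_stack([meth_t, meth_r]).astype(int),
        np.column_stack([depth_t, depth_r]).astype(int))


SPEC = ComparisonSpec(target="T", reference="R")


class TestCallDmcs:
    def test_small_delta_not_tested(self):
        m = two_sample_matrix([12], [100], [4], [100])  # delta 0.08
        assert len(call_dmcs(m, SPEC)) == 0

    def test_saturated_difference_significant(self):
        m = two_sample_matrix([30], [30], [0], [30])
        out = call_dmcs(m, SPEC)
        assert out["delta"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(exact_fisher_oracle(30, 0, 0, 30), rel=1e-7)
        assert bool(out["significant"].iloc[0])

    def test_identical_samples_yield_nothing(self):
        m = two_sample_matrix([5, 20], [30, 30], [5, 20], [30, 30])
        assert len(call_dmcs(m, SPEC)) == 0

    def test_antisymmetry_under_swap(self, small_sim, small_cfg):
        from methdyn.methylome import filter_common_autosomal
        m = filter_common_autosomal(small_sim.matrix, small_cfg)
        fwd = call_dmcs(m, ComparisonSpec("WAT_d0", "BAT_d0"), small_cfg)
        rev = call_dmcs(m, ComparisonSpec("BAT_d0", "WAT_d0"), small_cfg)
        fwd = fwd.sort_values(["chrom", "pos"]).reset_index(drop=True)
        rev = rev.sort_values(["chrom", "pos"]).reset_index(drop=True)
        assert len(fwd) == len(rev)
        assert fwd["delta"].to_numpy() == pytest.approx(-rev["delta"].to_numpy())
        assert fwd["p"].to_numpy() == pytest.approx(rev["p"].to_numpy())
        assert fwd["q"].to_numpy() == pytest.approx(rev["q"].to_numpy())
        assert (fwd["significant"].to_numpy() == rev["significant"].to_numpy()).all()
        swapped = fwd["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        assert (swapped.to_numpy() == rev["direction"].to_numpy()).all()

    def test_unfiltered_matrix_rejected(self):
        m = two_sample_matrix([0], [10], [0], [10])
        m.depth[0, 0] = 0
        m.meth[0, 0] = 0
        with pytest.raises(ValueError, match="filtered"):
            call_dmcs(m, SPEC)

    def test_missing_sample_rejected(self):
        m = two_sample_matrix([5], [10], [1], [10])
        with pytest.raises(KeyError):
            call_dmcs(m, ComparisonSpec("T", "nope"))


def promoter_catalog():
    gene = GeneModel("gA", "GA", "chr1", "+", 10_000, 30_000)
    cgis = IntervalSet("cgi", pd.DataFrame(columns=["chrom", "start", "end"]))
    return build_feature_catalog([gene], cgis)  # promoter [9000, 10499]


def dmc_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "delta", "p", "q",
                                       "direction", "significant"])


class TestCallDmps:
    def test_single_significant_cpg_is_not_dmp(self):
        dmcs = dmc_frame([("chr1", 9100, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 9200, 0.4, 0.5, 0.9, "hyper", False)])
        assert len(call_dmps(dmcs, promoter_catalog())) == 0

    def test_two_same_direction_cpgs_called(self):
        dmcs = dmc_frame([("chr1", 9100, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 9200, 0.2, 1e-4, 1e-3, "hyper", True)])
        out = call_dmps(dmcs, promoter_catalog())
        row = out.iloc[0]
        assert (row["gene_id"], row["direction"], row["n_sig_cpgs"]) == ("gA", "hyper", 2)
        assert row["mean_delta"] == pytest.approx(0.3)

    def test_mixed_directions_not_called_in_strict_mode(self):
        dmcs = dmc_frame([("chr1", 9100, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 9200, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 9300, -0.4, 1e-4, 1e-3, "hypo", True)])
        assert len(call_dmps(dmcs, promoter_catalog())) == 0
        out = call_dmps(dmcs, promoter_catalog(), mode="majority")
        assert out.iloc[0]["direction"] == "hyper" and out.iloc[0]["n_sig_cpgs"] == 2

    def test_outside_promoter_ignored(self):
        dmcs = dmc_frame([("chr1", 20_000, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 20_100, 0.4, 1e-4, 1e-3, "hyper", True)])
        assert len(call_dmps(dmcs, promoter_catalog())) == 0

    def test_covered_cpgs_counts_all_sites(self):
        dmcs = dmc_frame([("chr1", 9100, 0.4, 1e-4, 1e-3, "hyper", True),
                          ("chr1", 9200, 0.4, 1e-4, 1e-3, "hyper", True)])
        sites = pd.DataFrame({"chrom": "chr1", "pos": [9100, 9200, 9300, 20_000]})
        out = call_dmps(dmcs, promoter_catalog(), sites=sites)
        assert out.iloc[0]["covered_cpgs"] == 3


class TestDominance:
    def test_balanced_counts(self):
        assert direction_dominance_test(5, 5) == pytest.approx(1.0)

    def test_nine_one(self):
        assert direction_dominance_test(9, 1) == pytest.approx(22 / 1024)

    def test_symmetry(self):
        assert direction_dominance_test(1, 9) == pytest.approx(direction_dominance_test(9, 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_dominance_test(0, 0)


class TestCategoryBreakdown:
    def _contexts(self):
        return pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [1, 2, 3, 4],
            "genic": ["promoter", "promoter", "intron", "intergenic"]})

    def test_counts_and_ratio(self):
        dmcs = dmc_frame([
            ("chr1", 1, 0.4, 0, 0, "hyper", True),
            ("chr1", 2, -0.4, 0, 0, "hypo", True),
            ("chr1", 3, 0.4, 0, 0, "hyper", True),
            ("chr1", 4, 0.4, 0, 0, "hyper", False),  # not significant
        ])
        out = dmc_category_breakdown(dmcs, self._contexts()).set_index("category")
        assert out.loc["promoter", ["n_hyper", "n_hypo"]].tolist() == [1, 1]
        assert out.loc["promoter", "ratio"] == pytest.approx(1.0)
        assert out.loc["intron", "ratio"] == np.inf
        assert out[["n_hyper", "n_hypo"]].to_numpy().sum() == 3

    def test_missing_context_rejected(self):
        dmcs = dmc_frame([("chr1", 99, 0.4, 0, 0, "hyper", True)])
        with pytest.raises(ValueError, match="no context"):
            dmc_category_breakdown(dmcs, self._contexts())
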