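"""Weighted-level engine: arithmetic contracts, pooling invariance,
windowing, replicate correlation, strand symmetry and mC composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylome_kit import (genome_wide_levels, methylcytosine_composition,
                           pool_replicates, replicate_correlation,
                           strand_symmetry, weighted_level, window_levels)
from tests.conftest import make_counts


def sites(pairs, context="CG"):
    return make_counts([("c1", i + 1, "+", context, c, t)
                        for i, (c, t) in enumerate(pairs)])


class TestWeightedLevel:
    def test_forced_arithmetic(self):
        lvl = weighted_level(sites([(3, 1), (1, 3)]))
        assert lvl.weighted_level == 4 / 8 == 0.5
        assert lvl.covered_sites == 2 and lvl.total_reads == 8

    def test_zero_coverage_is_undefined_not_zero(self):
        lvl = weighted_level(sites([(0, 0)]))
        assert not lvl.defined
        assert np.isnan(lvl.weighted_level)

    def test_mixed_contexts_rejected(self):
        tbl = pd.concat([sites([(1, 1)], "CG"), sites([(1, 1)], "CHH")])
        with pytest.raises(ValueError, match="single context"):
            weighted_level(tbl)

    def test_matches_brute_force_and_differs_from_site_mean(self, rng):
        c = rng.integers(0, 30, size=1000)
        t = rng.integers(0, 30, size=1000)
        tbl = sites(list(zip(c, t)))
        lvl = weighted_level(tbl)
        assert lvl.weighted_level == pytest.approx(c.sum() / (c + t).sum(),
                                                   abs=1e-15)
        cov = c + t
        site_mean = np.mean(c[cov > 0] / cov[cov > 0])
        assert abs(lvl.weighted_level - site_mean) > 1e-6

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=30),
           st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=30))
    def test_pooling_invariance(self, a, b):
        """level(A u B) is the pooled count ratio, never the mean of the
        two region levels."""
        la, lb = weighted_level(sites(a)), weighted_level(sites(b))
        lab = weighted_level(sites(a + b))
        tot = la.total_reads + lb.total_reads
        if tot == 0:
            assert not lab.defined
        else:
            c_sum = sum(c for c, _ in a + b)
            assert lab.weighted_level == pytest.approx(c_sum / tot, abs=1e-12)


class TestGenomeWide:
    def test_single_site(self):
        levels = genome_wide_levels(sites([(4, 1)], "CG"))
        assert levels["CG"].weighted_level == pytest.approx(0.8)
        assert not levels["CHG"].defined and not levels["CHH"].defined

    def test_all_zero_coverage(self):
        tbl = make_counts([("c1", 1, "+", ctx, 0, 0)
                           for ctx in ("CG", "CHG", "CHH")])
        levels = genome_wide_levels(tbl)
        assert all(not l.defined for l in levels.values())

    def test_sites_missing_from_index_excluded(self, caplog):
        tbl = make_counts([("c1", 1, "+", "CG", 5, 5),
                           ("c1", 99, "+", "CG", 100, 0)])
        index = pd.DataFrame({"chrom": ["c1"], "pos": [1], "strand": ["+"],
                              "context": ["CG"]})
        levels = genome_wide_levels(tbl, index)
        assert levels["CG"].weighted_level == pytest.approx(0.5)


class TestWindows:
    def test_window_tiling_counts(self):
        tbl = make_counts([("c1", 1, "+", "CG", 1, 1),
                           ("c2", 3999, "+", "CG", 1, 1)])
        w = window_levels(tbl, 2000, chrom_sizes={"c1": 4000, "c2": 4000})
        per_chrom = w.groupby("chrom")["window_start"].nunique()
        assert (per_chrom == 2).all()
        assert sorted(w["window_start"].unique()) == [1, 2001]

    def test_single_site_window_level(self):
        tbl = make_counts([("c1", 10, "+", "CG", 3, 1),
                           ("c1", 2500, "+", "CG", 1, 3)])
        w = window_levels(tbl, 2000)
        lv = w.set_index("window_start")["weighted_level"]
        assert lv[1] == pytest.approx(0.75) and lv[2001] == pytest.approx(0.25)

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            window_levels(make_counts([]), 0)


class TestReplicateCorrelation:
    def test_identical_replicates(self, dataset):
        rc = replicate_correlation(dataset["rep1"], dataset["rep1"])
        assert all(r == pytest.approx(1.0) for r in rc.values())

    def test_symmetric_in_arguments(self, dataset):
        r12 = replicate_correlation(dataset["rep1"], dataset["rep2"])
        r21 = replicate_correlation(dataset["rep2"], dataset["rep1"])
        for ctx in r12:
            assert r12[ctx] == pytest.approx(r21[ctx], abs=1e-12)

    def test_shared_truth_gives_high_cg_correlation(self, dataset):
        rc = replicate_correlation(dataset["rep1"], dataset["rep2"])
        assert rc["CG"] > 0.9

    def test_independent_levels_give_null_correlation(self, rng):
        def random_table():
            rows = []
            for ctx in ("CG", "CHG", "CHH"):
                m = rng.random(1000)
                c = rng.binomial(20, m)
                rows.append(pd.DataFrame(
                    {"chrom": "c1", "pos": np.arange(1000) * 2000 + 1,
                     "strand": "+", "context": ctx, "c_count": c,
                     "t_count": 20 - c}))
            return pd.concat(rows, ignore_index=True)

        rc = replicate_correlation(random_table(), random_table())
        assert all(abs(r) < 0.1 for r in rc.values())

    def test_too_few_windows_errors(self):
        tbl = make_counts([("c1", 1, "+", "CG", 1, 1)])
        with pytest.raises(ValueError, match="jointly defined"):
            replicate_correlation(tbl, tbl)


class TestStrandSymmetry:
    def test_two_perfect_dyads(self):
        tbl = make_counts([
            ("c1", 10, "+", "CG", 5, 0), ("c1", 11, "-", "CG", 5, 0),
            ("c1", 50, "+", "CG", 0, 5), ("c1", 51, "-", "CG", 0, 5)])
        r, dyads = strand_symmetry(tbl, context="CG")
        assert r == pytest.approx(1.0) and len(dyads) == 2

    def test_chh_rejected(self):
        with pytest.raises(ValueError, match="CG/CHG"):
            strand_symmetry(make_counts([]), context="CHH")

    def test_chg_dyads_pair_at_offset_two(self):
        tbl = make_counts([
            ("c1", 10, "+", "CHG", 8, 0), ("c1", 12, "-", "CHG", 8, 0),
            ("c1", 30, "+", "CHG", 0, 8), ("c1", 32, "-", "CHG", 1, 7)])
        r, dyads = strand_symmetry(tbl, context="CHG")
        assert len(dyads) == 2 and r > 0.99

    def test_shared_truth_high_symmetry(self, dataset, small_config):
        from methylome_kit import pool_replicates
        pooled = pool_replicates(dataset["rep1"], dataset["rep2"])
        r, _ = strand_symmetry(pooled, dataset["index"], "CG")
        assert r >= 0.9

    def test_independent_strands_null(self, rng):
        rows = []
        for i in range(1000):
            for strand, off in (("+", 0), ("-", 1)):
                c = rng.binomial(20, rng.random())
                rows.append(("c1", 10 * i + 1 + off, strand, "CG", c, 20 - c))
        r, dyads = strand_symmetry(make_counts(rows), context="CG")
        assert len(dyads) == 1000 and abs(r) < 0.1

    def test_involutive_under_strand_swap(self, rng):
        rows = []
        for i in range(200):
            lvl = rng.random()
            for strand, off in (("+", 0), ("-", 1)):
                c = rng.binomial(20, lvl)
                rows.append(("c1", 10 * i + 1 + off, strand, "CG", c, 20 - c))
        tbl = make_counts(rows)
        r1, _ = strand_symmetry(tbl, context="CG")
        swapped = tbl.copy()
        # mirror the genome so strand roles exchange
        swapped["strand"] = swapped["strand"].map({"+": "-", "-": "+"})
        swapped["pos"] = tbl["pos"].max() + 1 - swapped["pos"]
        r2, _ = strand_symmetry(swapped, context="CG")
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestComposition:
    def test_only_cg_called(self):
        tbl = make_counts([("c1", 1, "+", "CG", 10, 0),
                           ("c1", 5, "+", "CHH", 0, 10)])
        comp = methylcytosine_composition(tbl)
        assert comp == {"CG": 1.0, "CHG": 0.0, "CHH": 0.0}

    def test_equal_called_counts(self):
        tbl = make_counts([("c1", 1 + 3 * i, "+", ctx, 10, 0)
                           for i, ctx in enumerate(("CG", "CHG", "CHH"))])
        comp = methylcytosine_composition(tbl)
        assert all(v == pytest.approx(1 / 3) for v in comp.values())

    def test_no_calls_is_error(self):
        with pytest.raises(ValueError, match="no methyl-cytosines"):
            methylcytosine_composition(make_counts([("c1", 1, "+", "CG", 0, 9)]))

    def test_matches_brute_force_site_counting(self, dataset):
        tbl = dataset["rep1"]
        comp = methylcytosine_composition(tbl, call_threshold=0.5,
                                          min_coverage=4)
        cov = tbl["c_count"] + tbl["t_count"]
        lvl = tbl["c_count"] / cov.where(cov > 0)
        called = tbl[(cov >= 4) & (lvl >= 0.5)]
        n = len(called)
        for ctx in ("CG", "CHG", "CHH"):
            assert comp[ctx] == pytest.approx(
                (called["context"] == ctx).sum() / n)


def test_pool_replicates_sums_per_site():
    a = make_counts([("c1", 1, "+", "CG", 3, 1)])
    b = make_counts([("c1", 1, "+", "CG", 1, 3), ("c1", 9, "+", "CHH", 2, 2)])
    pooled = pool_replicates(a, b).set_index("pos")
    assert pooled.loc[1, ["c_count", "t_count"]].tolist() == [4, 4]
    assert len(pooled) == 2
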