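"""Metaplots, genic regions, expression stratification, rank tests and
TE-association classification."""

import numpy as np
import pandas as pd
import pytest

from methylome_kit import (classify_te_associated, compare_strata,
                           feature_metaplot, genic_region_levels,
                           group_genes_by_expression, stratified_metaplot)
from methylome_kit.contexts import reverse_complement
from methylome_kit.features import body_bin_edges
from tests.conftest import make_counts


def gene(id_, chrom, start, end, strand="+"):
    return dict(id=id_, chrom=chrom, start=start, end=end, strand=strand,
                kind="gene", family=None, age=np.nan)


def feature_df(*rows):
    return pd.DataFrame(rows)


class TestBinning:
    @pytest.mark.parametrize("length", [20, 37, 100, 1999, 2000, 2013])
    def test_body_bins_tile_exactly(self, length):
        edges = body_bin_edges(length)
        widths = np.diff(edges)
        assert widths.sum() == length
        assert edges[0] == 0 and edges[-1] == length
        assert (widths >= 0).all()

    def test_length_2000_gives_100bp_bins(self):
        assert (np.diff(body_bin_edges(2000)) == 100).all()

    def test_flat_methylome_gives_flat_profile(self, flat_dataset):
        genes = flat_dataset["features"][flat_dataset["features"].kind == "gene"]
        for ctx in ("CG", "CHG", "CHH"):
            prof = feature_metaplot(flat_dataset["counts"], genes, ctx)
            defined = prof.levels[~np.isnan(prof.levels)]
            assert len(defined) >= 55
            assert np.all(np.abs(defined - 0.5) < 0.03)

    def test_short_features_excluded(self, flat_dataset, caplog):
        genes = pd.concat([
            flat_dataset["features"][flat_dataset["features"].kind == "gene"],
            feature_df(gene("tiny", "chr1", 100, 110))], ignore_index=True)
        prof = feature_metaplot(flat_dataset["counts"], genes, "CG")
        assert prof.n_features == (flat_dataset["features"].kind == "gene").sum()

    def test_strand_flip_oracle(self, flat_dataset):
        """A minus-strand feature's profile equals the profile of the
        equivalent plus-strand feature on the reverse-complemented genome."""
        counts = flat_dataset["counts"]
        n = len(flat_dataset["genome"]["chr1"])
        f_minus = feature_df(gene("g", "chr1", 10_000, 12_000, "-"))
        prof_minus = feature_metaplot(counts, f_minus, "CG")

        mirrored = counts.copy()
        mirrored["pos"] = n + 1 - mirrored["pos"]
        mirrored["strand"] = mirrored["strand"].map({"+": "-", "-": "+"})
        f_plus = feature_df(gene("g", "chr1", n - 12_000, n - 10_000, "+"))
        prof_plus = feature_metaplot(mirrored, f_plus, "CG")
        np.testing.assert_allclose(prof_minus.levels, prof_plus.levels,
                                   atol=1e-12)

    def test_strand_reversal_reverses_profile(self, flat_dataset):
        """For a body length divisible by 20 the 60-bin profile of the
        reversed-strand feature is the exact mirror."""
        counts = flat_dataset["counts"]
        plus = feature_metaplot(counts, feature_df(
            gene("g", "chr1", 30_000, 34_000, "+")), "CHH")
        minus = feature_metaplot(counts, feature_df(
            gene("g", "chr1", 30_000, 34_000, "-")), "CHH")
        np.testing.assert_allclose(minus.levels, plus.levels[::-1], atol=1e-12)


class TestGenicRegions:
    def test_promoter_window_coordinates(self):
        """Plus-strand TSS at 5000 -> promoter [3000, 5000) 0-based."""
        rows = [("c1", 3000, "+", "CG", 9, 1),   # 0-based 2999: outside
                ("c1", 3001, "+", "CG", 1, 0),   # 0-based 3000: first inside
                ("c1", 5000, "+", "CG", 1, 0),   # 0-based 4999: last inside
                ("c1", 5001, "+", "CG", 9, 1)]   # 0-based 5000: body
        tbl = make_counts(rows)
        genes = feature_df(gene("g", "c1", 5000, 7000))
        lv = genic_region_levels(tbl, genes)
        prom = lv[(lv.region == "promoter") & (lv.context == "CG")].iloc[0]
        assert prom["total_reads"] == 2 and prom["weighted_level"] == 1.0

    def test_unmethylated_gene_all_zero(self):
        tbl = make_counts([("c1", p, "+", "CG", 0, 5)
                           for p in range(1001, 1050)])
        lv = genic_region_levels(tbl, feature_df(gene("g", "c1", 900, 1200)))
        defined = lv.dropna(subset=["weighted_level"])
        assert (defined["weighted_level"] == 0).all()
        assert len(defined) >= 1

    def test_chromosome_edge_truncated_and_flagged(self):
        tbl = make_counts([("c1", 10, "+", "CG", 1, 1)])
        lv = genic_region_levels(tbl, feature_df(gene("g", "c1", 100, 400)),
                                 chrom_sizes={"c1": 450})
        prom = lv[(lv.region == "promoter")]
        down = lv[(lv.region == "downstream")]
        assert prom["truncated"].all() and down["truncated"].all()

    def test_body_level_matches_brute_force(self, dataset):
        genes = dataset["features"][dataset["features"].kind == "gene"].head(5)
        tbl = dataset["rep1"]
        lv = genic_region_levels(tbl, genes)
        for g in genes.itertuples():
            inside = tbl[(tbl.chrom == g.chrom)
                         & (tbl.pos - 1 >= g.start) & (tbl.pos - 1 < g.end)
                         & (tbl.context == "CG")]
            expected = (inside["c_count"].sum()
                        / (inside["c_count"] + inside["t_count"]).sum())
            got = lv[(lv.gene_id == g.id) & (lv.region == "body")
                     & (lv.context == "CG")]["weighted_level"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)


class TestExpressionGroups:
    def test_five_group_rank_arithmetic(self):
        expr = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "fpkm": [0.0, 0.4, 1, 2, 3, 4, 5, 6, 7, 8]})
        out = group_genes_by_expression(expr, "five_group")
        by_group = out.groupby("group")["fpkm"].apply(list).to_dict()
        assert by_group[1] == [0.0, 0.4]
        assert by_group[2] == [1, 2] and by_group[3] == [3, 4]
        assert by_group[4] == [5, 6] and by_group[5] == [7, 8]

    def test_all_low_expression_degenerate(self):
        expr = pd.DataFrame({"gene_id": ["a", "b"], "fpkm": [0.0, 0.3]})
        out = group_genes_by_expression(expr, "five_group")
        assert (out["group"] == 1).all()

    def test_thirds_of_nine(self):
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(9)],
                             "fpkm": np.arange(9, dtype=float)})
        out = group_genes_by_expression(expr, "thirds")
        assert out["group"].value_counts().to_dict() == {
            "low": 3, "mid": 3, "high": 3}

    def test_group_sizes_and_partition(self, rng):
        expr = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(101)],
                             "fpkm": rng.lognormal(1, 1.5, size=101)})
        out = group_genes_by_expression(expr, "five_group")
        sizes = out["group"].value_counts()
        rest = sizes.drop(1)
        assert rest.max() - rest.min() <= 1
        assert sizes.sum() == 101

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            group_genes_by_expression(pd.DataFrame(columns=["gene_id", "fpkm"]))


class TestStratifiedMetaplot:
    def test_single_group_reduces_to_plain_metaplot(self, flat_dataset):
        genes = flat_dataset["features"][flat_dataset["features"].kind == "gene"]
        groups = pd.DataFrame({"gene_id": genes["id"], "fpkm": 1.0, "group": 1})
        profs = stratified_metaplot(flat_dataset["counts"], genes, groups, "CG")
        plain = feature_metaplot(flat_dataset["counts"], genes, "CG")
        np.testing.assert_array_equal(profs[1].levels, plain.levels)

    def test_identical_methylome_profiles_coincide(self, flat_dataset, rng):
        genes = flat_dataset["features"][flat_dataset["features"].kind == "gene"]
        groups = pd.DataFrame({
            "gene_id": genes["id"].to_numpy(),
            "fpkm": 1.0,
            "group": rng.permutation([1, 2, 3] * (len(genes) // 3 + 1))[:len(genes)]})
        profs = stratified_metaplot(flat_dataset["counts"], genes, groups, "CG")
        for p in profs.values():
            body = p.body[~np.isnan(p.body)]
            assert np.all(np.abs(body - 0.5) < 0.05)


class TestCompareStrata:
    def test_identical_samples(self, rng):
        x = rng.random(40)
        res = compare_strata(x, x)
        assert res.p_value >= 0.99

    def test_all_tied_degenerate_p_one(self):
        res = compare_strata([0.3] * 5, [0.3] * 7)
        assert res.p_value == 1.0

    def test_planted_separation(self, rng):
        a = np.clip(rng.normal(0.9, 0.05, 50), 0, 1)
        b = np.clip(rng.normal(0.1, 0.05, 50), 0, 1)
        res = compare_strata(a, b)
        assert res.p_value < 0.001
        assert res.median_a > res.median_b

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.random(30), rng.random(25)
        assert compare_strata(a, b).p_value == pytest.approx(
            compare_strata(b, a).p_value, abs=1e-12)

    def test_requires_three_defined_values(self):
        with pytest.raises(ValueError):
            compare_strata([0.5, np.nan, np.nan], [0.1, 0.2, 0.3])


class TestTEAssociation:
    def test_flank_overlap_is_associated(self):
        genes = feature_df(gene("g", "c1", 5000, 8000))
        tes = pd.DataFrame([dict(id="t", chrom="c1", start=2500, end=3500)])
        out, prop = classify_te_associated(genes, tes, flank=2000)
        assert out["te_associated"].iloc[0] and prop == 1.0

    def test_half_open_boundary_not_associated(self):
        genes = feature_df(gene("g", "c1", 5000, 8000))
        tes = pd.DataFrame([dict(id="t", chrom="c1", start=10_000, end=12_000)])
        out, prop = classify_te_associated(genes, tes, flank=2000)
        assert not out["te_associated"].iloc[0] and prop == 0.0

    def test_matches_brute_force_all_pairs(self, rng):
        genes = pd.DataFrame([
            dict(id=f"g{i}", chrom=f"c{rng.integers(3)}",
                 start=(s := int(rng.integers(0, 200_000))),
                 end=s + int(rng.integers(200, 3000)), strand="+",
                 kind="gene", family=None, age=np.nan)
            for i in range(200)])
        tes = pd.DataFrame([
            dict(id=f"t{i}", chrom=f"c{rng.integers(3)}",
                 start=(s := int(rng.integers(0, 200_000))),
                 end=s + int(rng.integers(100, 2000)))
            for i in range(400)])
        out, prop = classify_te_associated(genes, tes, flank=2000)
        expected = []
        for g in genes.itertuples():
            hit = any(t.chrom == g.chrom
                      and g.start - 2000 < t.end and t.start < g.end + 2000
                      for t in tes.itertuples())
            expected.append(hit)
        assert out["te_associated"].tolist() == expected
        assert prop == pytest.approx(np.mean(expected))

    def test_monotone_in_flank(self, rng):
        genes = pd.DataFrame([
            dict(id=f"g{i}", chrom="c1",
                 start=(s := int(rng.integers(0, 100_000))), end=s + 1000)
            for i in range(50)])
        tes = pd.DataFrame([
            dict(id=f"t{i}", chrom="c1",
                 start=(s := int(rng.integers(0, 100_000))), end=s + 500)
            for i in range(50)])
        prev = set()
        for flank in (0, 500, 2000, 5000):
            out, _ = classify_te_associated(genes, tes, flank=flank)
            cur = set(out.loc[out["te_associated"], "id"])
            assert prev <= cur
            prev = cur
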