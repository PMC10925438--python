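import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrpipe import profile as pm
from dmrpipe.config import SimulationConfig
from dmrpipe.simulate import simulate_dataset
from dmrpipe.types import FeatureCatalog, ValidationError

from conftest import make_sample


class TestCoverageFilter:
    def test_depth_five_retained_inclusive(self):
        s = make_sample([("chr1", 1, 3, 5)])
        assert len(pm.filter_by_coverage(s, 5)) == 1

    def test_depth_four_dropped(self):
        s = make_sample([("chr1", 1, 3, 4)])
        assert len(pm.filter_by_coverage(s, 5)) == 0

    def test_min_depth_zero_identity(self):
        s = make_sample([("chr1", 1, 0, 2), ("chr1", 5, 1, 1)])
        pd.testing.assert_frame_equal(pm.filter_by_coverage(s, 0).records, s.records)

    def test_idempotent(self):
        s = make_sample([("chr1", i, 1, d) for i, d in enumerate([1, 5, 9, 4, 30])])
        once = pm.filter_by_coverage(s, 5)
        twice = pm.filter_by_coverage(once, 5)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_order_preserved(self):
        s = make_sample([("chr1", 1, 1, 9), ("chr1", 4, 1, 2), ("chr1", 9, 1, 7)])
        assert pm.filter_by_coverage(s, 5).records["pos"].tolist() == [1, 9]


class TestIntersection:
    def test_basic(self):
        a = make_sample([("chr1", 100, 5, 10), ("chr1", 200, 5, 10)], "a")
        b = make_sample([("chr1", 200, 2, 10), ("chr1", 300, 5, 10)], "b")
        table = pm.intersect_common_cpgs([a, b])
        assert list(table.index) == [("chr1", 200)]
        assert table.loc[("chr1", 200), "a"] == pytest.approx(0.5)
        assert table.loc[("chr1", 200), "b"] == pytest.approx(0.2)

    def test_identical_samples_keep_all(self):
        a = make_sample([("chr1", 1, 1, 10), ("chr2", 5, 2, 10)], "a")
        b = make_sample([("chr1", 1, 1, 10), ("chr2", 5, 2, 10)], "b")
        assert len(pm.intersect_common_cpgs([a, b])) == 2

    def test_empty_intersection_warns(self, caplog):
        a = make_sample([("chr1", 1, 1, 10)], "a")
        b = make_sample([("chr1", 2, 1, 10)], "b")
        import logging
        with caplog.at_level(logging.WARNING):
            table = pm.intersect_common_cpgs([a, b])
        assert table.empty
        assert any("empty" in r.message for r in caplog.records)

    def test_matches_brute_force_on_simulated(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=80_000, n_genes=6,
                               n_controls=3, depth_mean=30, seed=13)
        ds = simulate_dataset(cfg)
        filtered = [pm.filter_by_coverage(c, 5) for c in ds.controls[:3]]
        table = pm.intersect_common_cpgs(filtered)
        # independent set-logic oracle
        sets = [set(zip(c.records["chrom"], c.records["pos"])) for c in filtered]
        expected = sets[0] & sets[1] & sets[2]
        assert set(table.index) == expected

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pm.intersect_common_cpgs([make_sample([("chr1", 1, 1, 10)])])


class TestBinning:
    def test_eighty_in_top_bin(self):
        counts = pm.bin_values([80.0])
        assert counts["75-100%"] == 1

    def test_boundary_25_in_first_bin(self):
        counts = pm.bin_values([25.0])
        assert counts["0-25%"] == 1

    def test_one_per_bin(self):
        counts = pm.bin_values([10, 30, 60, 90])
        assert counts.tolist() == [1, 1, 1, 1]

    def test_extremes_housed(self):
        counts = pm.bin_values([0.0, 100.0])
        assert counts["0-25%"] == 1 and counts["75-100%"] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pm.bin_values([101.0])

    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserve_total(self, values):
        assert pm.bin_values(values).sum() == len(values)


class TestPromoterMean:
    def catalog(self, strand="+"):
        return FeatureCatalog(pd.DataFrame(
            [("chr1", 1000, 3000, "promoter", "G1", strand)],
            columns=["chrom", "start", "end", "category", "gene_id", "strand"]))

    def test_simple_mean(self):
        s = make_sample([("chr1", 1500, 8, 10), ("chr1", 1600, 9, 10), ("chr1", 1700, 10, 10)])
        means = pm.promoter_mean_methylation(s, self.catalog())
        assert means["G1"] == pytest.approx(90.0)

    def test_no_covered_cpg_is_missing(self):
        s = make_sample([("chr1", 5000, 8, 10)])
        means = pm.promoter_mean_methylation(s, self.catalog())
        assert np.isnan(means["G1"])

    def test_half_open_boundaries(self):
        s = make_sample([("chr1", 999, 0, 10), ("chr1", 1000, 10, 10),
                         ("chr1", 2999, 10, 10), ("chr1", 3000, 0, 10)])
        means = pm.promoter_mean_methylation(s, self.catalog())
        assert means["G1"] == pytest.approx(100.0)

    def test_minus_strand_promoter_from_generator(self):
        from dmrpipe.simulate import promoter_interval
        start, end = promoter_interval(10_000, "-")
        assert (start, end) == (9_500, 11_500)


class TestPearson:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(20)
        table = pd.DataFrame({"a": x, "b": x})
        assert pm.pearson_matrix(table).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_centered_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        table = pd.DataFrame({"a": x, "b": -(x - x.mean())})
        assert pm.pearson_matrix(table).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        # textbook formula oracle
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        table = pd.DataFrame({"a": x, "b": y})
        assert pm.pearson_matrix(table).loc["a", "b"] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_is_nan_not_zero(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        r = pm.pearson_matrix(table)
        assert np.isnan(r.loc["a", "b"]) and np.isnan(r.loc["a", "a"])

    @given(scale=st.floats(min_value=0.1, max_value=50),
           shift=st.floats(min_value=-100, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.random((10, 3)), columns=list("abc"))
        base = pm.pearson_matrix(table)
        table2 = table.copy()
        table2["b"] = table2["b"] * scale + shift
        rescaled = pm.pearson_matrix(table2)
        np.testing.assert_allclose(base.to_numpy(), rescaled.to_numpy(), atol=1e-8)


class TestStrata:
    def test_identical_groups_p_one(self):
        meth = pd.Series({f"g{i}": v for i, v in enumerate([10, 12, 14, 80, 82, 84])})
        fpkm = pd.Series({f"g{i}": v for i, v in enumerate([5.0, 6.0, 7.0, 5.0, 6.0, 7.0])})
        _, tests = pm.methylation_expression_strata(meth, fpkm)
        row = tests[(tests.bin_a == "0-25%") & (tests.bin_b == "75-100%")].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["t"] == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        meth = pd.Series(dict(zip(genes, [10.0] * 50 + [90.0] * 50)))
        fpkm = pd.Series(dict(zip(genes, np.concatenate([
            rng.normal(100, 1, 50), rng.normal(1, 1, 50)]))))
        _, tests = pm.methylation_expression_strata(meth, fpkm)
        row = tests[(tests.bin_a == "0-25%") & (tests.bin_b == "75-100%")].iloc[0]
        assert row["p_value"] < 1e-10

    def test_small_bins_skipped(self):
        meth = pd.Series({"g1": 10.0, "g2": 90.0, "g3": 91.0})
        fpkm = pd.Series({"g1": 5.0, "g2": 1.0, "g3": 2.0})
        _, tests = pm.methylation_expression_strata(meth, fpkm)
        row = tests[(tests.bin_a == "0-25%") & (tests.bin_b == "75-100%")].iloc[0]
        assert bool(row["skipped"]) and np.isnan(row["p_value"])

    def test_simulated_coupling_monotone_decreasing(self, demo_dataset):
        from dmrpipe.expression import compute_fpkm

        control = pm.filter_by_coverage(demo_dataset.controls[0], 5)
        means = pm.promoter_mean_methylation(control, demo_dataset.genome.catalog)
        fpkm = compute_fpkm(demo_dataset.counts, demo_dataset.gene_lengths)["control_1"]
        summary, _ = pm.methylation_expression_strata(means, fpkm)
        filled = summary.dropna(subset=["mean_fpkm"])
        values = filled["mean_fpkm"].to_numpy()
        assert (np.diff(values) < 0).all()

    def test_spearman_negative_coupling(self, demo_dataset):
        from dmrpipe.expression import compute_fpkm
        from scipy import stats

        control = pm.filter_by_coverage(demo_dataset.controls[0], 5)
        means = pm.promoter_mean_methylation(control, demo_dataset.genome.catalog)
        fpkm = compute_fpkm(demo_dataset.counts, demo_dataset.gene_lengths)["control_1"]
        joined = pd.concat([means.rename("m"), fpkm.rename("f")], axis=1).dropna()
        rho, _ = stats.spearmanr(joined["m"], joined["f"])
        assert rho < 0
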