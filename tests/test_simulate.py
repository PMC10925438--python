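import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dmrpipe.config import ConfigError, SimulationConfig
from dmrpipe.simulate import (
    SizingError,
    generate_genome,
    promoter_interval,
    simulate_dataset,
    write_dataset,
)
from dmrpipe import profile as profile_mod


def small_config(**kw):
    base = dict(n_chromosomes=1, chrom_length=150_000, n_genes=10, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_promoter_count_and_width(self):
        genome = generate_genome(small_config())
        promoters = genome.catalog.promoters
        assert len(promoters) == 10
        assert ((promoters["end"] - promoters["start"]) == 2000).all()

    def test_promoter_interval_plus_strand(self):
        assert promoter_interval(50_000, "+") == (48_500, 50_500)

    def test_promoter_interval_minus_strand(self):
        assert promoter_interval(50_000, "-") == (49_500, 51_500)

    def test_positions_strictly_increasing(self):
        genome = generate_genome(small_config())
        for pos in genome.positions.values():
            assert (np.diff(pos) > 0).all()

    def test_mean_spacing(self):
        genome = generate_genome(small_config(chrom_length=240_000, cpg_spacing_mean=60.0))
        pos = genome.positions["chr1"]
        assert np.diff(pos).mean() == pytest.approx(60.0, rel=0.1)

    def test_sizing_error(self):
        with pytest.raises(SizingError, match="too short"):
            generate_genome(SimulationConfig(n_chromosomes=1, chrom_length=20_000, n_genes=10))

    def test_same_seed_same_genome(self):
        g1 = generate_genome(small_config())
        g2 = generate_genome(small_config())
        pd.testing.assert_frame_equal(g1.catalog.intervals, g2.catalog.intervals)
        for chrom in g1.positions:
            np.testing.assert_array_equal(g1.positions[chrom], g2.positions[chrom])


class TestDeterminism:
    def test_bit_identical_datasets(self):
        a = simulate_dataset(SimulationConfig(seed=5))
        b = simulate_dataset(SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.gene_lengths, b.gene_lengths)
        assert a.truth.planted_dmrs == b.truth.planted_dmrs
        assert a.truth.coupled_genes == b.truth.coupled_genes
        for sa, sb in zip(a.controls + a.tumors, b.controls + b.tumors):
            pd.testing.assert_frame_equal(sa.records, sb.records)

    def test_byte_identical_serialization(self, tmp_path):
        def digest_dir(d: Path) -> dict:
            return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(d.iterdir())}

        ds = simulate_dataset(small_config())
        write_dataset(ds, tmp_path / "a")
        write_dataset(simulate_dataset(small_config()), tmp_path / "b")
        assert digest_dir(tmp_path / "a") == digest_dir(tmp_path / "b")

    def test_different_seed_differs(self):
        a = simulate_dataset(small_config(seed=1))
        b = simulate_dataset(small_config(seed=2))
        assert not a.counts.equals(b.counts)


@pytest.fixture(scope="module")
def planted_ds():
    cfg = SimulationConfig(
        n_chromosomes=1, chrom_length=100_000, n_genes=8,
        coupled_gene_fraction=0.0, n_planted_hypo=4, n_planted_hyper=2,
        planted_effect=0.30, planted_width_cpgs=8, n_tumors=2,
        recurrence_schedule=[(0,)] * 6, seed=21,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def coupled_ds():
    """Coupled genes kept a small fraction of the library so FPKM fold
    changes are not distorted by composition; >= 100 replicate coupled
    genes accumulated across seeds."""
    cfg = SimulationConfig(
        n_chromosomes=2, chrom_length=500_000, n_genes=100,
        coupled_gene_fraction=0.05, n_planted_hypo=4, n_planted_hyper=2,
        planted_width_cpgs=4, seed=31,
    )
    return [simulate_dataset(dataclasses.replace(cfg, seed=31 + s)) for s in range(20)]


class TestMethylomes:
    @staticmethod
    def region_delta(ds, region, tumor_idx):
        pos = ds.genome.positions[region.chrom]
        mask = (pos >= region.start) & (pos < region.end)
        ctrl = np.mean([
            (c.records["count_meth"] / c.records["count_total"]).to_numpy()[mask]
            for c in ds.controls
        ], axis=0)
        t = ds.tumors[tumor_idx].records
        tf = (t["count_meth"] / t["count_total"]).to_numpy()[mask]
        return float((tf - ctrl).mean()), int(mask.sum())

    def test_carrier_shift_matches_effect(self, planted_ds):
        # empirical delta within 3 binomial standard errors at depth 30
        for region in planted_ds.truth.planted_dmrs:
            delta, n = self.region_delta(planted_ds, region, 0)
            expected = -0.30 if region.direction == "hypo" else 0.30
            se = 3 * np.sqrt(0.25 / 30 / n * (1 + 1 / len(planted_ds.controls)))
            assert delta == pytest.approx(expected, abs=max(3 * se, 0.08))

    def test_non_carrier_unshifted(self, planted_ds):
        for region in planted_ds.truth.planted_dmrs:
            delta, n = self.region_delta(planted_ds, region, 1)  # tumor 1 never carries
            assert abs(delta) < 0.1

    def test_depth_truncated_at_one(self, planted_ds):
        for s in planted_ds.controls + planted_ds.tumors:
            assert (s.records["count_total"] >= 1).all()

    def test_controls_highly_correlated(self, demo_dataset):
        controls = [profile_mod.filter_by_coverage(c, 5) for c in demo_dataset.controls]
        shared = profile_mod.intersect_common_cpgs(controls)
        r = profile_mod.pearson_matrix(shared)
        assert np.nanmin(r.to_numpy()) >= 0.95

    def test_mostly_high_methylation(self, demo_dataset):
        frac = demo_dataset.controls[0].fractions
        assert (frac > 0.75).mean() > 0.5


class TestExpression:
    def test_coupled_fold_change_close_to_ten(self, coupled_ds):
        from dmrpipe.expression import compute_fpkm

        ratios = []
        for ds in coupled_ds:
            fpkm = compute_fpkm(ds.counts, ds.gene_lengths)
            ctrl_cols = [c for c in fpkm.columns if c.startswith("control_")]
            for cg in ds.truth.coupled_genes:
                carriers = [f"tumor_{t + 1}" for t in cg.carriers]
                ratio = fpkm.loc[cg.gene_id, carriers].mean() / fpkm.loc[cg.gene_id, ctrl_cols].mean()
                ratios.append(ratio if cg.direction == "hypo" else 1.0 / ratio)
        ratios = np.asarray(ratios)
        assert len(ratios) >= 100
        assert np.median(ratios) == pytest.approx(10.0, rel=0.25)

    def test_non_coupled_ratio_near_one(self, coupled_ds):
        from dmrpipe.expression import compute_fpkm

        ds = coupled_ds[0]
        coupled = {g.gene_id for g in ds.truth.coupled_genes}
        fpkm = compute_fpkm(ds.counts, ds.gene_lengths)
        ctrl_cols = [c for c in fpkm.columns if c.startswith("control_")]
        tum_cols = [c for c in fpkm.columns if c.startswith("tumor_")]
        others = [g for g in fpkm.index if g not in coupled]
        log_ratios = np.log2(
            (fpkm.loc[others, tum_cols].mean(axis=1) + 0.1)
            / (fpkm.loc[others, ctrl_cols].mean(axis=1) + 0.1))
        assert abs(log_ratios.mean()) < 0.35

    def test_zero_dispersion_poisson_limit(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=150_000, n_genes=10,
                               n_controls=40, expression_dispersion=0.0,
                               coupled_gene_fraction=0.0,
                               n_planted_hypo=0, n_planted_hyper=0, seed=41)
        ds = simulate_dataset(cfg)
        ctrl_cols = [c for c in ds.counts.columns if c.startswith("control_")]
        counts = ds.counts[ctrl_cols]
        # library factors vary ~+-15%; variance/mean stays near 1 (Poisson),
        # far below the NB value at dispersion 0.1 (1 + 0.1*mu >> 1)
        vmr = (counts.var(axis=1) / counts.mean(axis=1)).median()
        assert vmr < 3.0
        cfg_nb = dataclasses.replace(cfg, expression_dispersion=0.2)
        counts_nb = simulate_dataset(cfg_nb).counts[ctrl_cols]
        vmr_nb = (counts_nb.var(axis=1) / counts_nb.mean(axis=1)).median()
        assert vmr_nb > 3 * vmr


class TestConfigValidation:
    def test_bad_fraction(self):
        with pytest.raises(ConfigError):
            SimulationConfig(baseline_high_meth=1.5).validate()

    def test_bad_effect(self):
        with pytest.raises(ConfigError):
            SimulationConfig(planted_effect=0.95).validate()

    def test_schedule_length(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_planted_hypo=2, n_planted_hyper=0,
                             recurrence_schedule=[(0,)]).validate()

    def test_schedule_out_of_range(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_planted_hypo=1, n_planted_hyper=0, n_tumors=2,
                             recurrence_schedule=[(5,)]).validate()

    def test_truth_carriers_match_schedule(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=150_000, n_genes=10,
                               n_planted_hypo=2, n_planted_hyper=1,
                               coupled_gene_fraction=0.0,
                               recurrence_schedule=[(0, 2), (1,), (0, 1, 2)],
                               n_tumors=3, seed=51)
        ds = simulate_dataset(cfg)
        assert [r.carriers for r in ds.truth.planted_dmrs] == [(0, 2), (1,), (0, 1, 2)]
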