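import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from dmrpipe.config import PipelineConfig, SimulationConfig
from dmrpipe.simulate import simulate_dataset
from dmrpipe.types import MethylomeSample


def make_sample(rows, sample_id="s"):
    """rows: iterable of (chrom, pos, count_meth, count_total)."""
    return MethylomeSample(
        sample_id,
        pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_total"]),
    ).validate()


def brute_force_mwu_p(x, y):
    """Independent exact two-sided MWU oracle: enumerate every rank split.

    U counts (x_i, y_j) pairs with y_j < x_i. Two-sided p =
    min(1, 2 * min(P(U <= u), P(U >= u))) over all C(m+n, m) splits.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    m, n = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if yj < xi)
    combined = sorted(x + y)
    us = []
    for x_idx in itertools.combinations(range(m + n), m):
        x_set = set(x_idx)
        u = 0
        for i in x_idx:
            u += sum(1 for j in range(m + n) if j not in x_set and j < i)
        us.append(u)
    us = np.array(us)
    lower = (us <= u_obs).mean()
    upper = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(lower, upper))


@pytest.fixture(scope="session")
def demo_dataset():
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def recovery_config():
    """Planted-recovery setting: effect 0.30, width 6 CpGs, depth 30,
    5 controls + 1 carrier tumor, all regions intergenic."""
    return SimulationConfig(
        n_chromosomes=1, chrom_length=42_000, n_genes=4,
        coupled_gene_fraction=0.0, n_planted_hypo=8, n_planted_hyper=4,
        planted_effect=0.30, planted_width_cpgs=6, n_tumors=1,
        recurrence_schedule=[(0,)] * 12,
    )


@pytest.fixture(scope="session")
def null_config():
    """Null-calibration setting: no planted regions; depth high enough
    that the 10-percentage-point DMC prefilter is not noise-driven."""
    return SimulationConfig(
        n_chromosomes=1, chrom_length=60_000, n_genes=5,
        coupled_gene_fraction=0.0, n_planted_hypo=0, n_planted_hyper=0,
        n_tumors=1, depth_mean=100,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    from dmrpipe.pipeline import run_all

    outdir = tmp_path_factory.mktemp("demo_run")
    manifest = run_all(outdir, SimulationConfig(seed=7), PipelineConfig())
    return outdir, manifest


def reseeded(config, seed):
    return dataclasses.replace(config, seed=seed)
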