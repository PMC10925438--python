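"""Differential methylation calling.

Control averaging, per-CpG DMC calling (tumor vs control mean, delta in
percentage points), segmentation of consecutive same-direction DMCs
into candidate regions, and a region-level two-sided Mann-Whitney U
test (exact for small tie-free groups, tie-corrected normal
approximation otherwise).

Conventions: the gap rule is inclusive (<= max_gap bp between
consecutive DMCs); region end = last member CpG + 1 (half-open); the
region test compares the tumor's per-CpG fractions at member DMCs
against the pooled per-control per-CpG fractions at the same sites. No
multiple-testing correction is applied by default; optional BH-FDR.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .profile import filter_by_coverage
from .types import Dmc, Dmr, MethylomeSample

#: exact MWU enumeration is used when both groups are at most this size
EXACT_MAX_N = 8


@dataclass
class ControlProfile:
    """Per-CpG mean methylation across controls, restricted to sites
    covered >= min_depth in ALL controls. ``fractions`` holds the
    per-control aligned fractions (one column per control) retained for
    region testing."""

    table: pd.DataFrame  # index (chrom, pos); columns: per-control fractions
    mean_fraction: pd.Series

    @property
    def n_controls(self) -> int:
        return self.table.shape[1]


@dataclass(frozen=True)
class DmrCandidate:
    """A maximal run of consecutive same-direction DMCs, pre-test."""

    chrom: str
    start: int
    end: int
    direction: str
    n_cpgs: int
    mean_delta: float
    positions: tuple[int, ...]


def average_controls(controls: Sequence[MethylomeSample], config: PipelineConfig | None = None,
                     prefiltered: bool = False) -> ControlProfile:
    """Average control methylomes site-wise (unweighted).

    Only sites covered >= ``config.min_depth`` in every control are
    retained (strict intersection policy). Raises if no site survives.
    """
    config = config or PipelineConfig()
    if not controls:
        raise ValueError("need >= 1 control sample")
    if not prefiltered:
        controls = [filter_by_coverage(c, config.min_depth) for c in controls]
    frames = []
    for c in controls:
        f = c.records.set_index(["chrom", "pos"])
        frames.append((f["count_meth"] / f["count_total"]).rename(c.sample_id))
    table = pd.concat(frames, axis=1, join="inner").sort_index()
    if table.empty:
        raise ValueError("no CpG site covered in all controls at the configured depth")
    return ControlProfile(table=table, mean_fraction=table.mean(axis=1))


def call_dmcs(tumor: MethylomeSample, profile: ControlProfile,
              config: PipelineConfig | None = None, prefiltered: bool = False) -> list[Dmc]:
    """Per-CpG deltas (percentage points, tumor - control mean) at sites
    shared between the tumor and the profile; |delta| >= dmc_min_delta
    (inclusive) qualifies as a DMC."""
    config = config or PipelineConfig()
    if not prefiltered:
        tumor = filter_by_coverage(tumor, config.min_depth)
    t = tumor.records.set_index(["chrom", "pos"])
    tfrac = (t["count_meth"] / t["count_total"]).rename("tumor")
    joined = pd.concat([tfrac, profile.mean_fraction.rename("control")], axis=1, join="inner")
    joined = joined.sort_index()
    delta = 100.0 * (joined["tumor"] - joined["control"])
    keep = delta.abs() >= config.dmc_min_delta
    return [Dmc(chrom=c, pos=int(p), delta=float(d))
            for (c, p), d in delta[keep].items()]


def segment_dmrs(dmcs: Sequence[Dmc], config: PipelineConfig | None = None) -> list[DmrCandidate]:
    """Maximal runs of same-direction DMCs with successive gaps
    <= dmr_max_gap and length >= dmr_min_cpgs. A chromosome change, a
    direction flip, or a larger gap terminates a run."""
    config = config or PipelineConfig()
    candidates: list[DmrCandidate] = []
    run: list[Dmc] = []

    def flush() -> None:
        if len(run) >= config.dmr_min_cpgs:
            deltas = [d.delta for d in run]
            candidates.append(DmrCandidate(
                chrom=run[0].chrom,
                start=run[0].pos,
                end=run[-1].pos + 1,
                direction=run[0].direction,
                n_cpgs=len(run),
                mean_delta=float(np.mean(deltas)),
                positions=tuple(d.pos for d in run),
            ))

    for dmc in dmcs:
        if run and (
            dmc.chrom != run[-1].chrom
            or dmc.pos - run[-1].pos > config.dmr_max_gap
            or dmc.direction != run[-1].direction
        ):
            flush()
            run = []
        run.append(dmc)
    flush()
    return candidates


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Null distribution of the U statistic: counts[u] = number of the
    C(m+n, m) rank arrangements with U = u (no ties). Classic DP on the
    recurrence f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1)."""
    size = m * n + 1
    # full 2D DP over (j, k) = (#x, #y) prefixes
    table: dict[tuple[int, int], list[int]] = {}
    for j in range(m + 1):
        for k in range(n + 1):
            if j == 0:
                table[(j, k)] = [1] + [0] * size
                continue
            row = [0] * (size + 1)
            prev_x = table[(j - 1, k)]
            prev_y = table[(j, k - 1)] if k > 0 else None
            for u in range(size):
                val = prev_x[u - k] if u - k >= 0 else 0
                if prev_y is not None:
                    val += prev_y[u]
                row[u] = val
            table[(j, k)] = row
    return tuple(table[(m, n)][: size])


def mwu_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided MWU p-value (tie-free groups).

    U counts the (x_i, y_j) pairs with y_j < x_i; the two-sided p is
    min(1, 2 * min(P(U <= u), P(U >= u))) under the exact null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if len(np.unique(combined)) != len(combined):
        raise ValueError("exact MWU path refuses ties")
    u = int((y[None, :] < x[:, None]).sum())
    counts = np.asarray(_u_counts(len(x), len(y)), dtype=float)
    total = counts.sum()
    lower = counts[: u + 1].sum() / total
    upper = counts[u:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def mwu_normal_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided MWU p via the tie-corrected normal approximation with
    continuity correction; mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    mu = m * n / 2.0
    big_n = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = m * n / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0
    diff = abs(u - mu) - 0.5
    if diff <= 0:
        return 1.0
    z = diff / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def mwu_region_test(tumor_fractions: Sequence[float],
                    control_fractions: Sequence[float] | np.ndarray) -> float:
    """Two-sided MWU comparing a tumor's per-CpG fractions over a region
    against pooled controls' per-CpG fractions.

    Exact null enumeration when both groups have <= 8 observations and
    no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(tumor_fractions, dtype=float).ravel()
    y = np.asarray(control_fractions, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        try:
            return mwu_exact_p(x, y)
        except ValueError:
            pass  # ties: fall through to the corrected approximation
    return mwu_normal_p(x, y)


# ---------------------------------------------------------------------------
# top-level calling
# ---------------------------------------------------------------------------

def test_candidate(candidate: DmrCandidate, tumor_fractions: pd.Series,
                   profile: ControlProfile) -> float:
    """Region p-value for one candidate: the tumor's fractions at every
    shared CpG inside [start, end) vs the pooled per-control fractions
    at the same CpGs (member DMCs plus any interspersed shared sites)."""
    chrom_tumor = tumor_fractions.loc[candidate.chrom]
    chrom_ctrl = profile.table.loc[candidate.chrom]
    shared = chrom_tumor.index.intersection(chrom_ctrl.index)
    in_span = shared[(shared >= candidate.start) & (shared < candidate.end)]
    x = chrom_tumor.loc[in_span].to_numpy()
    y = chrom_ctrl.loc[in_span].to_numpy().ravel()
    return mwu_region_test(x, y)


def call_dmrs(tumor: MethylomeSample, controls: Sequence[MethylomeSample],
              config: PipelineConfig | None = None) -> list[Dmr]:
    """Full per-tumor DMR calling: filter -> average controls -> DMCs ->
    segment -> region MWU -> retain p <= alpha (optionally BH-FDR)."""
    config = config or PipelineConfig()
    profile = average_controls(controls, config)
    tumor_f = filter_by_coverage(tumor, config.min_depth)
    return call_dmrs_with_profile(tumor_f, profile, config)


def call_dmrs_with_profile(tumor: MethylomeSample, profile: ControlProfile,
                           config: PipelineConfig | None = None) -> list[Dmr]:
    """As :func:`call_dmrs` but reusing a precomputed control profile;
    the tumor must already be coverage-filtered."""
    config = config or PipelineConfig()
    dmcs = call_dmcs(tumor, profile, config, prefiltered=True)
    candidates = segment_dmrs(dmcs, config)
    if not candidates:
        return []
    t = tumor.records.set_index(["chrom", "pos"])
    tumor_fractions = t["count_meth"] / t["count_total"]
    tested = [
        (c, test_candidate(c, tumor_fractions, profile))
        for c in candidates
    ]
    if config.fdr:
        pvals = np.array([p for _, p in tested])
        adj = stats.false_discovery_control(pvals, method="bh")
        tested = [(c, float(q)) for (c, _), q in zip(tested, adj)]
    return [
        Dmr(chrom=c.chrom, start=c.start, end=c.end, direction=c.direction,
            n_cpgs=c.n_cpgs, mean_delta=c.mean_delta, p_value=p)
        for c, p in tested
        if p <= config.alpha
    ]
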