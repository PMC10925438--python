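"""Descriptive methylome analyses: coverage filtering, CpG intersection,
methylation binning, promoter means, pairwise correlations, and
promoter-methylation / expression strata."""
from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureCatalog, MethylomeSample, ValidationError

logger = logging.getLogger(__name__)


def filter_by_coverage(sample: MethylomeSample, min_depth: int = 5) -> MethylomeSample:
    """Keep only CpGs sequenced to at least ``min_depth`` reads (inclusive)."""
    kept = sample.records[sample.records["count_total"] >= min_depth].reset_index(drop=True)
    return MethylomeSample(sample.sample_id, kept)


def intersect_common_cpgs(samples: Sequence[MethylomeSample]) -> pd.DataFrame:
    """Positions covered in every sample, with aligned methylation fractions.

    Returns a frame indexed by (chrom, pos) with one fraction column per
    sample (values in [0, 1]). Samples are expected to be
    coverage-filtered already.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to intersect")
    frames = []
    for s in samples:
        f = s.records.set_index(["chrom", "pos"])
        frac = (f["count_meth"] / f["count_total"]).rename(s.sample_id)
        frames.append(frac)
    table = pd.concat(frames, axis=1, join="inner").sort_index()
    if table.empty:
        logger.warning("intersection of %d samples is empty", len(samples))
    return table


def bin_values(values, edges: Sequence[float] = (0.0, 25.0, 50.0, 75.0, 100.0)) -> pd.Series:
    """Count values per methylation bin.

    The first bin is closed ``[e0, e1]``; subsequent bins are half-open
    ``(e_i, e_{i+1}]``, so the bins partition ``[e0, e_last]`` and both
    endpoints are housed. Values outside the range raise.
    """
    edges = list(edges)
    arr = np.asarray(values, dtype=float)
    if arr.size and ((arr < edges[0]) | (arr > edges[-1])).any():
        bad = arr[(arr < edges[0]) | (arr > edges[-1])][0]
        raise ValidationError(f"value {bad} outside [{edges[0]}, {edges[-1]}]")
    labels = [f"{int(lo) if float(lo).is_integer() else lo}-{int(hi) if float(hi).is_integer() else hi}%"
              for lo, hi in zip(edges[:-1], edges[1:])]
    # searchsorted with side='left' maps e_i -> bin (e_{i-1}, e_i]
    idx = np.searchsorted(edges, arr, side="left") - 1
    idx = np.clip(idx, 0, len(labels) - 1)  # lower edge value lands in bin 0
    counts = np.bincount(idx, minlength=len(labels)) if arr.size else np.zeros(len(labels), dtype=int)
    return pd.Series(counts, index=labels, name="count")


def promoter_mean_methylation(sample: MethylomeSample, catalog: FeatureCatalog) -> pd.Series:
    """Unweighted mean CpG methylation percent per gene promoter.

    Genes whose promoter contains no covered CpG get NaN (flagged
    missing; excluded from downstream bin counts).
    """
    promoters = catalog.promoters
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in sample.records.groupby("chrom", sort=False)
    }
    out = {}
    for row in promoters.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            out[row.gene_id] = np.nan
            continue
        pos = grp["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [row.start, row.end])
        if i1 <= i0:
            out[row.gene_id] = np.nan
            continue
        sub = grp.iloc[i0:i1]
        frac = sub["count_meth"].to_numpy() / sub["count_total"].to_numpy()
        out[row.gene_id] = 100.0 * float(frac.mean())
    return pd.Series(out, name=sample.sample_id)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson R between columns of an aligned value table.

    Zero-variance columns yield NaN entries (undefined, not 0); the
    diagonal is 1 for columns with variance.
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    if table.shape[0] < 3:
        raise ValueError("need >= 3 rows")
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    out = np.full((len(cols), len(cols)), np.nan)
    for i in range(len(cols)):
        for j in range(i, len(cols)):
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = float((centered[:, i] * centered[:, j]).sum() / (norms[i] * norms[j]))
            out[i, j] = out[j, i] = min(1.0, max(-1.0, r))
    return pd.DataFrame(out, index=cols, columns=cols)


def methylation_expression_strata(
    promoter_means: pd.Series,
    fpkm: pd.Series,
    edges: Sequence[float] = (0.0, 25.0, 50.0, 75.0, 100.0),
    min_n: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify genes by promoter methylation and summarize expression.

    Returns (summary, tests): per-bin n / mean FPKM / SEM, and all
    pairwise two-tailed Welch t-tests. Bins with fewer than ``min_n``
    genes have their tests skipped and flagged.
    """
    edges = list(edges)
    joined = pd.concat([promoter_means.rename("meth"), fpkm.rename("fpkm")], axis=1).dropna()
    labels = bin_values([], edges).index.tolist()
    idx = np.searchsorted(edges, joined["meth"].to_numpy(), side="left") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    joined["bin"] = [labels[i] for i in idx]

    summary_rows, groups = [], {}
    for k, label in enumerate(labels):
        vals = joined.loc[joined["bin"] == label, "fpkm"].to_numpy()
        groups[label] = vals
        summary_rows.append({
            "bin": label,
            "n": len(vals),
            "mean_fpkm": float(vals.mean()) if len(vals) else np.nan,
            "sem_fpkm": float(stats.sem(vals)) if len(vals) > 1 else np.nan,
        })
    summary = pd.DataFrame(summary_rows)

    test_rows = []
    for a, b in itertools.combinations(labels, 2):
        va, vb = groups[a], groups[b]
        if len(va) < min_n or len(vb) < min_n:
            test_rows.append({"bin_a": a, "bin_b": b, "t": np.nan, "p_value": np.nan,
                              "skipped": True})
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        test_rows.append({"bin_a": a, "bin_b": b, "t": float(t), "p_value": float(p),
                          "skipped": False})
    return summary, pd.DataFrame(test_rows)
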