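"""Cross-tumor recurrence signatures and methylation-expression
integration.

Recurrence is defined by base-pair coverage depth: a core region is a
maximal interval over which at least ``n_required`` tumors have a
same-direction DMR. The integrated lists pair promoter DMR recurrence
with expression change in the matching direction (hypo -> up,
hyper -> down).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedDmr
from .config import PipelineConfig
from .types import Dmr, FeatureCatalog


@dataclass(frozen=True)
class CoreRegion:
    chrom: str
    start: int
    end: int
    direction: str
    n_tumors: int
    support: tuple[tuple[int, ...], ...]  # per-tumor indices of supporting DMRs


@dataclass
class CoreMethylationSignature:
    regions: list[CoreRegion]
    n_required: int

    def __len__(self) -> int:
        return len(self.regions)


def _depth_intervals(intervals: list[tuple[int, int]], n_required: int) -> list[tuple[int, int]]:
    """Maximal intervals where coverage depth >= n_required (sweep-line)."""
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, +1))
        events.append((e, -1))
    events.sort()
    out: list[tuple[int, int]] = []
    depth = 0
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= n_required and open_start is None:
            open_start = pos
        elif depth < n_required and open_start is not None:
            if pos > open_start:
                out.append((open_start, pos))
            open_start = None
    return out


def recurrent_dmrs(per_tumor_dmrs: Sequence[Sequence[Dmr]], n_required: int,
                   direction: str) -> list[CoreRegion]:
    """Maximal genomic intervals covered by a same-direction DMR in at
    least ``n_required`` tumors, with supporting DMR indices per tumor.

    Within one tumor, overlapping same-direction DMRs (which the caller
    never produces, but external input might) count once per base.
    """
    n_tumors = len(per_tumor_dmrs)
    if n_required > n_tumors:
        raise ValueError(f"n_required {n_required} > number of tumors {n_tumors}")
    chroms = sorted({d.chrom for dmrs in per_tumor_dmrs for d in dmrs if d.direction == direction})
    regions: list[CoreRegion] = []
    for chrom in chroms:
        per_tumor_ivs = []
        for dmrs in per_tumor_dmrs:
            ivs = sorted((d.start, d.end) for d in dmrs if d.chrom == chrom and d.direction == direction)
            # merge within tumor so each tumor contributes depth <= 1 per base
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            per_tumor_ivs.append(merged)
        flat = [iv for ivs in per_tumor_ivs for iv in ivs]
        for start, end in _depth_intervals(flat, n_required):
            support = []
            for t, dmrs in enumerate(per_tumor_dmrs):
                idxs = tuple(
                    i for i, d in enumerate(dmrs)
                    if d.chrom == chrom and d.direction == direction
                    and d.start < end and start < d.end
                )
                support.append(idxs)
            regions.append(CoreRegion(chrom, start, end, direction, n_tumors, tuple(support)))
    return regions


def core_methylation_signature(per_tumor_dmrs: Sequence[Sequence[Dmr]],
                               n_required: int | None = None) -> CoreMethylationSignature:
    """Hypo and hyper core regions; ``n_required`` defaults to all tumors."""
    if n_required is None:
        n_required = len(per_tumor_dmrs)
    regions = recurrent_dmrs(per_tumor_dmrs, n_required, "hypo") + \
        recurrent_dmrs(per_tumor_dmrs, n_required, "hyper")
    return CoreMethylationSignature(regions=regions, n_required=n_required)


def core_expression_signature(results: Mapping[str, pd.DataFrame],
                              fc_threshold: float = 2.0) -> tuple[set[str], set[str]]:
    """Genes changed at least ``fc_threshold``-fold in EVERY tumor.

    up set: fold_change >= threshold in all tumors; down set:
    fold_change <= 1/threshold in all tumors. The sets are disjoint.
    """
    if not results:
        return set(), set()
    fc = pd.DataFrame({t: r["fold_change"] for t, r in results.items()})
    up = set(fc.index[(fc >= fc_threshold).all(axis=1)])
    down = set(fc.index[(fc <= 1.0 / fc_threshold).all(axis=1)])
    return up, down


def promoter_dmr_frequency(per_tumor_annotated: Sequence[Sequence[AnnotatedDmr]]) -> pd.DataFrame:
    """Per gene: in how many tumors its promoter carries >= 1 hypo
    (resp. hyper) DMR. A tumor contributes at most one per direction;
    the two directions are tallied independently."""
    counters: dict[str, dict[str, int]] = {}
    for annotated in per_tumor_annotated:
        seen: set[tuple[str, str]] = set()
        for a in annotated:
            for hit in a.hits:
                if hit.category == "promoter" and hit.gene_id is not None:
                    seen.add((hit.gene_id, a.dmr.direction))
        for gene_id, direction in seen:
            counters.setdefault(gene_id, {"hypo": 0, "hyper": 0})[direction] += 1
    frame = pd.DataFrame.from_dict(counters, orient="index").fillna(0).astype(int)
    for col in ("hypo", "hyper"):
        if col not in frame.columns:
            frame[col] = 0
    frame.index.name = "gene_id"
    return frame.rename(columns={"hypo": "hypo_count", "hyper": "hyper_count"}).sort_index()


def integrate(meth_frequencies: pd.DataFrame, results: Mapping[str, pd.DataFrame],
              config: PipelineConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrated gene lists: recurrent promoter methylation change plus
    matching expression change.

    hypo-up: hypo_count >= integration_min_tumors AND expression up
    (fold_change >= integration_expr_fc, p < alpha) in at least
    ``integration_expr_min_tumors`` tumors (default: majority + 1).
    hyper-down mirrors it with FC <= 1/threshold.
    """
    config = config or PipelineConfig()
    n_expr = len(results)
    min_expr = config.integration_expr_min_tumors
    if min_expr is None:
        min_expr = math.ceil(n_expr / 2) + 1
    fc = pd.DataFrame({t: r["fold_change"] for t, r in results.items()})
    pv = pd.DataFrame({t: r["p_value"] for t, r in results.items()})
    thr = config.integration_expr_fc

    up_hits = ((fc >= thr) & (pv < config.alpha)).sum(axis=1)
    down_hits = ((fc <= 1.0 / thr) & (pv < config.alpha)).sum(axis=1)
    mean_fc = fc.mean(axis=1)

    def build(direction_col: str, hits: pd.Series) -> pd.DataFrame:
        genes = meth_frequencies.index[
            meth_frequencies[direction_col] >= config.integration_min_tumors
        ]
        genes = [g for g in genes if g in hits.index and hits[g] >= min_expr]
        return pd.DataFrame({
            "gene_id": genes,
            "n_tumors_with_promoter_dmr": [int(meth_frequencies.loc[g, direction_col]) for g in genes],
            "n_tumors_expression_changed": [int(hits[g]) for g in genes],
            "mean_fold_change": [float(mean_fc[g]) for g in genes],
        }).set_index("gene_id")

    hypo_up = build("hypo_count", up_hits)
    hyper_down = build("hyper_count", down_hits)
    return hypo_up, hyper_down
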