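"""Genomic-element annotation of DMRs via an interval index.

Semantics mirror ``bedtools intersect``: half-open coordinates, minimum
overlap of 1 bp, and multi-hit annotation (a DMR counts toward every
category it overlaps, once per category). An optional exclusive
priority scheme (promoter > exon > intron > enhancer > repeat) is
provided for distribution-style summaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Dmr, FeatureCatalog

PRIORITY_ORDER = ("promoter", "exon", "intron", "enhancer", "repeat")
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class Hit:
    category: str
    gene_id: str | None
    overlap_bp: int


@dataclass
class AnnotatedDmr:
    dmr: Dmr
    hits: list[Hit]

    @property
    def categories(self) -> set[str]:
        return {h.category for h in self.hits}


class _ChromTree:
    """Static augmented interval tree over one chromosome's intervals.

    Built on the start-sorted interval array; each node stores the max
    end of its subtree so queries prune in O(log n + k).
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray, payload: list):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.payload = [payload[i] for i in order]
        self.max_end = np.zeros(len(starts), dtype=np.int64)
        self._build(0, len(starts))

    def _build(self, lo: int, hi: int) -> int:
        if lo >= hi:
            return -(2**62)
        mid = (lo + hi) // 2
        left = self._build(lo, mid)
        right = self._build(mid + 1, hi)
        self.max_end[mid] = max(int(self.ends[mid]), left, right)
        return int(self.max_end[mid])

    def query(self, qstart: int, qend: int, out: list) -> None:
        self._query(0, len(self.starts), qstart, qend, out)

    def _query(self, lo: int, hi: int, qstart: int, qend: int, out: list) -> None:
        if lo >= hi:
            return
        mid = (lo + hi) // 2
        # left subtree can only match if some end there exceeds qstart
        if lo < mid and self._subtree_max(lo, mid) > qstart:
            self._query(lo, mid, qstart, qend, out)
        s, e = int(self.starts[mid]), int(self.ends[mid])
        if s < qend and qstart < e:
            out.append((self.payload[mid], max(s, qstart), min(e, qend)))
        # right subtree starts are >= starts[mid]; prune when beyond qend
        if mid + 1 < hi and s < qend:
            self._query(mid + 1, hi, qstart, qend, out)

    def _subtree_max(self, lo: int, hi: int) -> int:
        if lo >= hi:
            return -(2**62)
        return int(self.max_end[(lo + hi) // 2])


class IntervalIndex:
    """Overlap-queryable index over a :class:`FeatureCatalog`."""

    def __init__(self, catalog: FeatureCatalog):
        catalog.validate()
        self._trees: dict[str, _ChromTree] = {}
        for chrom, grp in catalog.intervals.groupby("chrom", sort=False):
            payload = list(grp[["category", "gene_id"]].itertuples(index=False, name=None))
            self._trees[chrom] = _ChromTree(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64), payload
            )

    def query(self, chrom: str, start: int, end: int) -> list[Hit]:
        """All catalog intervals overlapping [start, end) by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        raw: list = []
        tree.query(start, end, raw)
        hits = [
            Hit(category=cat, gene_id=None if _isna(gid) else gid, overlap_bp=oe - os)
            for (cat, gid), os, oe in raw
        ]
        hits.sort(key=lambda h: (h.category, h.gene_id or "", -h.overlap_bp))
        return hits


def build_interval_index(catalog: FeatureCatalog) -> IntervalIndex:
    return IntervalIndex(catalog)


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def annotate_dmrs(dmrs: Sequence[Dmr], index: IntervalIndex) -> tuple[list[AnnotatedDmr], pd.DataFrame]:
    """Annotate each DMR with overlapping features and tally per-category
    hypo/hyper counts (a DMR counts once per category it touches; DMRs
    touching nothing land in the 'unannotated' tally)."""
    annotated = [AnnotatedDmr(d, index.query(d.chrom, d.start, d.end)) for d in dmrs]
    categories = list(PRIORITY_ORDER) + [UNANNOTATED]
    counts = pd.DataFrame(0, index=categories, columns=["hypo", "hyper"])
    for a in annotated:
        cats = a.categories or {UNANNOTATED}
        for cat in cats:
            counts.loc[cat, a.dmr.direction] += 1
    return annotated, counts


def _priority_category(a: AnnotatedDmr) -> str:
    for cat in PRIORITY_ORDER:
        if cat in a.categories:
            return cat
    return UNANNOTATED


def signature_element_distribution(annotated: Sequence[AnnotatedDmr]) -> pd.DataFrame:
    """Per-category counts and fractions for a DMR set, reported under
    both the multi-hit scheme (fractions may sum past 1) and the
    exclusive priority scheme (fractions sum to 1)."""
    categories = list(PRIORITY_ORDER) + [UNANNOTATED]
    out = pd.DataFrame(0, index=categories, columns=["count_multi", "count_priority"])
    if not annotated:
        import logging
        logging.getLogger(__name__).warning("empty signature: element distribution is empty")
    for a in annotated:
        for cat in a.categories or {UNANNOTATED}:
            out.loc[cat, "count_multi"] += 1
        out.loc[_priority_category(a), "count_priority"] += 1
    n = max(len(annotated), 1)
    out["frac_multi"] = out["count_multi"] / n
    out["frac_priority"] = out["count_priority"] / n
    return out
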