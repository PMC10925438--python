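"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere. One record per CpG
dinucleotide (strands pre-merged).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FEATURE_CATEGORIES = ("promoter", "enhancer", "exon", "intron", "repeat")

METHYLOME_COLUMNS = ("chrom", "pos", "count_meth", "count_total")
CATALOG_COLUMNS = ("chrom", "start", "end", "category", "gene_id", "strand")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class MethylomeSample:
    """One sample's position-sorted per-CpG methylation counts.

    ``records`` holds columns chrom, pos (0-based), count_meth, count_total.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METHYLOME_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"methylome table missing columns: {missing}")
        self.records = self.records.loc[:, list(METHYLOME_COLUMNS)].reset_index(drop=True)

    def validate(self) -> "MethylomeSample":
        rec = self.records
        if len(rec):
            if (rec["count_meth"] < 0).any() or (rec["count_total"] < 0).any():
                raise ValidationError(f"{self.sample_id}: negative counts")
            if (rec["count_meth"] > rec["count_total"]).any():
                bad = rec.index[rec["count_meth"] > rec["count_total"]][0]
                raise ValidationError(
                    f"{self.sample_id}: count_meth > count_total at row {bad}"
                )
            for chrom, grp in rec.groupby("chrom", sort=False):
                pos = grp["pos"].to_numpy()
                if len(pos) > 1 and not (np.diff(pos) > 0).all():
                    raise ValidationError(
                        f"{self.sample_id}: positions not strictly increasing on {chrom}"
                    )
        return self

    @property
    def fractions(self) -> pd.Series:
        """Methylation fraction per record; NaN where count_total == 0."""
        total = self.records["count_total"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, self.records["count_meth"] / total, np.nan)
        return pd.Series(frac, index=self.records.index, name=self.sample_id)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FeatureCatalog:
    """Strand-aware genomic intervals labeled by category.

    Promoter intervals carry gene_id and strand; others may have gene_id
    null and strand '.'.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.intervals.columns]
        if missing:
            raise ValidationError(f"feature catalog missing columns: {missing}")
        self.intervals = self.intervals.loc[:, list(CATALOG_COLUMNS)].reset_index(drop=True)

    def validate(self) -> "FeatureCatalog":
        iv = self.intervals
        if len(iv):
            if (iv["start"] >= iv["end"]).any():
                raise ValidationError("feature interval with start >= end")
            bad = set(iv["category"]) - set(FEATURE_CATEGORIES)
            if bad:
                raise ValidationError(f"unknown feature categories: {sorted(bad)}")
            prom = iv[iv["category"] == "promoter"]
            if prom["gene_id"].isna().any():
                raise ValidationError("promoter interval without gene_id")
            if (~prom["strand"].isin(["+", "-"])).any():
                raise ValidationError("promoter interval without strand")
        return self

    def by_category(self, category: str) -> pd.DataFrame:
        return self.intervals[self.intervals["category"] == category]

    @property
    def promoters(self) -> pd.DataFrame:
        return self.by_category("promoter")

    @staticmethod
    def concat(parts: Iterable["FeatureCatalog"]) -> "FeatureCatalog":
        frames = [p.intervals for p in parts]
        if not frames:
            return FeatureCatalog(pd.DataFrame(columns=list(CATALOG_COLUMNS)))
        return FeatureCatalog(pd.concat(frames, ignore_index=True))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class Dmc:
    """A differentially methylated cytosine (delta in percentage points)."""

    chrom: str
    pos: int
    delta: float

    @property
    def direction(self) -> str:
        return "hypo" if self.delta < 0 else "hyper"


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated region (half-open interval)."""

    chrom: str
    start: int
    end: int
    direction: str
    n_cpgs: int
    mean_delta: float
    p_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValidationError(f"bad DMR direction {self.direction!r}")
        if self.start >= self.end:
            raise ValidationError("DMR start >= end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class PlantedRegion:
    """A ground-truth differential region emitted by the simulator."""

    region_id: str
    chrom: str
    start: int
    end: int
    direction: str
    effect: float
    carriers: tuple[int, ...]  # tumor indices (0-based)


@dataclass(frozen=True)
class CoupledGene:
    """A gene whose expression is coupled to a planted promoter region."""

    gene_id: str
    region_id: str
    direction: str  # methylation direction of the planted promoter region
    fold_change: float
    carriers: tuple[int, ...]  # expression-tumor indices (0-based)


@dataclass
class TruthSet:
    """Planted regions and coupled genes, round-trippable to TSV."""

    planted_dmrs: list[PlantedRegion] = field(default_factory=list)
    coupled_genes: list[CoupledGene] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> "TruthSet":
        ids = {r.region_id for r in self.planted_dmrs}
        if len(ids) != len(self.planted_dmrs):
            raise ValidationError("duplicate planted region ids")
        for g in self.coupled_genes:
            if g.region_id not in ids:
                raise ValidationError(
                    f"coupled gene {g.gene_id} references unknown region {g.region_id}"
                )
        return self

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region_id": r.region_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "direction": r.direction,
                    "effect": r.effect,
                    "carriers": ",".join(map(str, r.carriers)),
                }
                for r in self.planted_dmrs
            ],
            columns=["region_id", "chrom", "start", "end", "direction", "effect", "carriers"],
        )

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "region_id": g.region_id,
                    "direction": g.direction,
                    "fold_change": g.fold_change,
                    "carriers": ",".join(map(str, g.carriers)),
                }
                for g in self.coupled_genes
            ],
            columns=["gene_id", "region_id", "direction", "fold_change", "carriers"],
        )


def parse_carriers(text: str) -> tuple[int, ...]:
    text = str(text).strip()
    if not text or text == "nan":
        return ()
    return tuple(int(t) for t in text.split(","))
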