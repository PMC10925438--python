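"""Readers and writers for every on-disk format the pipeline touches.

Formats: Bismark-coverage-style methylation TSV, BED3/BED6 feature
intervals, BED-like DMR tables, bedGraph exports, and TSV matrices
(counts, gene lengths, truth tables). Gzip is handled transparently
for any path ending in ``.gz``.

Dialect note: Bismark coverage files are 1-based inclusive in columns
2-3; they are converted to the internal 0-based half-open convention on
read and back on write. Chromosome names are taken verbatim.
"""
from __future__ import annotations

import gzip
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CATALOG_COLUMNS,
    CoupledGene,
    Dmr,
    FeatureCatalog,
    MethylomeSample,
    PlantedRegion,
    TruthSet,
    ValidationError,
    parse_carriers,
)

logger = logging.getLogger(__name__)

DMR_COLUMNS = ("chrom", "start", "end", "direction", "n_cpgs", "mean_delta", "p_value")

#: maximum tolerated disagreement (percentage points) between the %meth
#: column and the value recomputed from the count columns
PERCENT_TOLERANCE = 0.5


class ParseError(ValueError):
    pass


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_bismark_coverage(path: str | Path, sample_id: str | None = None) -> MethylomeSample:
    """Parse a Bismark coverage file into a :class:`MethylomeSample`.

    Expects 6 tab-separated columns: chrom, start (1-based), end
    (1-based inclusive), %methylation, count methylated, count
    unmethylated. The %meth column is cross-checked against the counts.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
            try:
                start = int(start_s)
                pct = float(pct_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            total = meth + unmeth
            if total > 0:
                expected_pct = 100.0 * meth / total
                if abs(expected_pct - pct) > PERCENT_TOLERANCE:
                    raise ValidationError(
                        f"{path}:{lineno}: %meth column {pct} disagrees with counts "
                        f"{meth}/{total} ({expected_pct:.2f}%)"
                    )
            rows.append((chrom, start - 1, meth, total))
    if not rows:
        logger.warning("%s: empty coverage file for sample %s", path, sample_id)
    records = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_total"])
    records = records.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return MethylomeSample(sample_id=sample_id, records=records).validate()


def write_bismark_coverage(sample: MethylomeSample, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for chrom, pos, meth, total in sample.records.itertuples(index=False):
            unmeth = total - meth
            pct = 100.0 * meth / total if total > 0 else 0.0
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:g}\t{meth}\t{unmeth}\n")


def write_bedgraph(sample: MethylomeSample, path: str | Path) -> None:
    """Export methylation percentages as bedGraph (browser track)."""
    with _open(path, "wt") as fh:
        for chrom, pos, meth, total in sample.records.itertuples(index=False):
            if total == 0:
                continue
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100.0 * meth / total:g}\n")


# ---------------------------------------------------------------------------
# BED features
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, category: str) -> FeatureCatalog:
    """Read a BED3/BED6 file as a single-category catalog fragment.

    The BED name column (4) is taken as gene_id when present; strand is
    '.' for BED3. Overlapping intervals are kept as-is (no merging).
    """
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            gene_id = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            rows.append((chrom, start, end, category, gene_id, strand))
    catalog = FeatureCatalog(pd.DataFrame(rows, columns=list(CATALOG_COLUMNS)))
    return catalog.validate()


def write_bed(catalog: FeatureCatalog, path: str | Path, category: str | None = None) -> None:
    iv = catalog.intervals
    if category is not None:
        iv = iv[iv["category"] == category]
    with _open(path, "wt") as fh:
        for row in iv.itertuples(index=False):
            name = row.gene_id if row.gene_id is not None and not _isna(row.gene_id) else "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


# ---------------------------------------------------------------------------
# DMR tables
# ---------------------------------------------------------------------------

def write_dmrs(dmrs: Sequence[Dmr], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(DMR_COLUMNS) + "\n")
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t{d.n_cpgs}\t"
                f"{d.mean_delta:.10g}\t{d.p_value:.10e}\n"
            )


def read_dmrs(path: str | Path) -> list[Dmr]:
    dmrs = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != DMR_COLUMNS:
            raise ParseError(f"{path}: unexpected DMR header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(DMR_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(DMR_COLUMNS)} columns")
            try:
                dmrs.append(
                    Dmr(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        direction=fields[3],
                        n_cpgs=int(fields[4]),
                        mean_delta=float(fields[5]),
                        p_value=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return dmrs


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids: {dupes[:5]}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ParseError(f"{path}: missing cell at gene {row!r}, sample {col!r}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids")
    lengths = df.iloc[:, 0]
    if (lengths <= 0).any():
        raise ValidationError(f"{path}: non-positive gene length")
    return lengths

def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, regions_path: str | Path, genes_path: str | Path) -> None:
    """Serialize a :class:`TruthSet` as two documented TSV tables.

    regions table columns: region_id, chrom, start, end, direction,
    effect, carriers (comma-joined tumor indices).
    genes table columns: gene_id, region_id, direction, fold_change,
    carriers (comma-joined expression-tumor indices).
    """
    truth.regions_frame().to_csv(regions_path, sep="\t", index=False)
    truth.genes_frame().to_csv(genes_path, sep="\t", index=False)


def read_truth(regions_path: str | Path, genes_path: str | Path, seed: int = 0) -> TruthSet:
    regions = pd.read_csv(regions_path, sep="\t", dtype={"carriers": str})
    genes = pd.read_csv(genes_path, sep="\t", dtype={"carriers": str})
    planted = [
        PlantedRegion(
            region_id=str(r.region_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            direction=str(r.direction),
            effect=float(r.effect),
            carriers=parse_carriers(r.carriers if isinstance(r.carriers, str) else ""),
        )
        for r in regions.itertuples(index=False)
    ]
    coupled = [
        CoupledGene(
            gene_id=str(g.gene_id),
            region_id=str(g.region_id),
            direction=str(g.direction),
            fold_change=float(g.fold_change),
            carriers=parse_carriers(g.carriers if isinstance(g.carriers, str) else ""),
        )
        for g in genes.itertuples(index=False)
    ]
    return TruthSet(planted_dmrs=planted, coupled_genes=coupled, seed=seed).validate()
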