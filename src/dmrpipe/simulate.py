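"""Synthetic WGBS + RNA-seq dataset generator with planted truth.

Generates a small genome of CpG positions and gene/enhancer/repeat
annotations, control and tumor methylomes sharing a latent methylation
profile, planted hypo-/hypermethylated regions carried by scheduled
tumor subsets, and a count matrix in which selected genes' expression is
inversely coupled to their promoter methylation.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the config, so identical configs produce bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .types import (
    CATALOG_COLUMNS,
    CoupledGene,
    FeatureCatalog,
    MethylomeSample,
    PlantedRegion,
    TruthSet,
)
from . import io as io_formats
from .config import PipelineConfig, dump_config


class SizingError(ValueError):
    """Requested genes/regions do not fit the configured genome."""


class ConsistencyError(ValueError):
    """Truth set disagrees with the simulated CpG landscape."""


# gaps between consecutive CpGs inside a planted run are kept below this,
# safely under the 100 bp segmentation cut-off
_PLANT_MAX_GAP = 95
_ISLAND_WIDTH_CPGS = 20


def promoter_interval(tss: int, strand: str, upstream: int = 1500, downstream: int = 500) -> tuple[int, int]:
    """Strand-aware promoter window around a TSS (0-based half-open).

    Plus strand: [tss - upstream, tss + downstream); minus strand the
    window is reflected: [tss - downstream, tss + upstream).
    """
    if strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream, tss + upstream
    raise ValueError(f"promoter requires stranded gene, got {strand!r}")


@dataclass
class SyntheticGenome:
    """CpG positions plus annotation and per-gene latent promoter level."""

    positions: dict[str, np.ndarray]
    catalog: FeatureCatalog
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    latent: dict[str, np.ndarray] = field(default_factory=dict)
    promoter_meth: pd.Series | None = None

    @property
    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SyntheticGenome
    truth: TruthSet
    controls: list[MethylomeSample]
    tumors: list[MethylomeSample]
    counts: pd.DataFrame
    gene_lengths: pd.Series


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _cpg_positions(config: SimulationConfig, rng: np.random.Generator, length: int) -> np.ndarray:
    mean_gap = config.cpg_spacing_mean
    if mean_gap <= 2:
        raise SizingError("cpg_spacing_mean must exceed 2 bp")
    n_draw = int(length / mean_gap * 1.5) + 50
    gaps = 2 + np.floor(rng.exponential(mean_gap - 2.0, size=n_draw)).astype(np.int64)
    pos = np.cumsum(gaps)
    pos = pos[pos < length]
    while len(pos) and pos[-1] < length - 10 * mean_gap:  # pragma: no cover - rare top-up
        extra = 2 + np.floor(rng.exponential(mean_gap - 2.0, size=50)).astype(np.int64)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos < length]
    return pos


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Simulate CpG positions and a feature catalog.

    Genes are laid out in per-chromosome territories; each gene gets a
    TSS, strand, a 2 kb promoter, and exon/intron structure. Enhancers
    and repeats fall in intergenic space, away from promoters.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes_per_chrom = [
        len(range(i, config.n_genes, config.n_chromosomes)) for i in range(config.n_chromosomes)
    ]
    body_max = 6000
    territory_need = body_max + 4000
    max_genes = max(genes_per_chrom)
    if max_genes * territory_need > config.chrom_length:
        raise SizingError(
            f"chrom_length {config.chrom_length} too short for {max_genes} genes per "
            f"chromosome (need >= {max_genes * territory_need} bp: "
            f"{territory_need} bp per gene territory)"
        )

    positions: dict[str, np.ndarray] = {}
    rows: list[tuple] = []
    gene_rows: list[tuple] = []
    gene_index = 0
    for ci, chrom in enumerate(chroms):
        positions[chrom] = _cpg_positions(config, rng, config.chrom_length)
        n_here = genes_per_chrom[ci]
        territory = config.chrom_length // max(n_here, 1)
        gene_spans = []
        for gi in range(n_here):
            gene_id = f"G{gene_index:04d}"
            gene_index += 1
            slot = gi * territory
            body_len = int(rng.integers(2500, body_max))
            strand = "+" if rng.random() < 0.5 else "-"
            # keep promoter + body inside the slot with 500 bp margins
            if strand == "+":
                tss = slot + 2000 + int(rng.integers(0, max(territory - body_len - 4500, 1)))
                gstart, gend = tss, tss + body_len
            else:
                tss = slot + 2000 + body_len + int(rng.integers(0, max(territory - body_len - 4500, 1)))
                gstart, gend = tss - body_len, tss
            pstart, pend = promoter_interval(tss, strand, 1500, 500)
            rows.append((chrom, pstart, pend, "promoter", gene_id, strand))
            # exon/intron structure: 3 exons, 2 introns
            cuts = np.sort(rng.integers(200, body_len - 200, size=4))
            bounds = [gstart, *(gstart + cuts).tolist(), gend]
            for k in range(3):
                estart, eend = bounds[2 * k], bounds[2 * k + 1]
                if estart < eend:
                    rows.append((chrom, estart, eend, "exon", gene_id, strand))
            for k in range(2):
                istart, iend = bounds[2 * k + 1], bounds[2 * k + 2]
                if istart < iend:
                    rows.append((chrom, istart, iend, "intron", gene_id, strand))
            gene_rows.append((gene_id, chrom, tss, strand))
            gene_spans.append((min(pstart, gstart), max(pend, gend)))
        # enhancers and repeats in intergenic space at the tail of each slot
        for gi in range(n_here):
            slot_end = (gi + 1) * territory
            span_end = gene_spans[gi][1]
            free = slot_end - span_end
            if free > 2500:
                estart = span_end + 500 + int(rng.integers(0, free - 2500))
                rows.append((chrom, estart, estart + int(rng.integers(400, 1200)), "enhancer", None, "."))
            if free > 4500:
                rstart = span_end + 2500 + int(rng.integers(0, free - 4500))
                rows.append((chrom, rstart, rstart + int(rng.integers(300, 1500)), "repeat", None, "."))

    catalog = FeatureCatalog(pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))).validate()
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])
    return SyntheticGenome(positions=positions, catalog=catalog, genes=genes)


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

def _find_run(positions: np.ndarray, lo: int, hi: int, width: int,
              taken: list[tuple[int, int]], chrom: str,
              rng: np.random.Generator) -> tuple[int, int] | None:
    """A window of `width` consecutive CpGs inside [lo, hi) with small gaps,
    not overlapping already-planted intervals. Returns (i0, i1) indices."""
    idx = np.nonzero((positions >= lo) & (positions < hi))[0]
    if len(idx) < width:
        return None
    starts = list(range(len(idx) - width + 1))
    rng.shuffle(starts)
    for s in starts:
        window = idx[s : s + width]
        if not np.array_equal(window, np.arange(window[0], window[0] + width)):
            continue  # must be consecutive CpGs genome-wide, not just in range
        pos = positions[window]
        if np.diff(pos).max(initial=0) > _PLANT_MAX_GAP:
            continue
        start, end = int(pos[0]), int(pos[-1]) + 1
        if any(c == chrom and start < e and s2 < end for c, s2, e in
               ((c, s2, e) for c, s2, e in taken)):
            continue
        return int(window[0]), int(window[-1]) + 1
    return None


def plant_truth(config: SimulationConfig, genome: SyntheticGenome,
                rng: np.random.Generator | None = None) -> TruthSet:
    """Choose planted region locations, carrier schedules, and coupled genes.

    A proportional share of planted hypo/hyper regions is placed inside
    promoters of distinct genes (these genes become expression-coupled);
    the rest land on intergenic CpG runs. Placement guarantees runs of
    >= planted_width_cpgs consecutive CpGs with gaps < 100 bp so a
    correct caller can recover them.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    n_hypo, n_hyper = config.n_planted_hypo, config.n_planted_hyper
    n_regions = n_hypo + n_hyper
    n_coupled = int(round(config.coupled_gene_fraction * config.n_genes))
    n_coupled = min(n_coupled, n_regions, config.n_genes)
    if n_regions:
        n_coupled_hypo = min(n_hypo, int(round(n_coupled * n_hypo / n_regions)))
    else:
        n_coupled_hypo = 0
    n_coupled_hyper = min(n_hyper, n_coupled - n_coupled_hypo)
    n_coupled = n_coupled_hypo + n_coupled_hyper

    gene_order = genome.genes.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1)))
    coupled_genes_rows = list(gene_order.itertuples(index=False))

    taken: list[tuple[int, int]] = []  # (chrom, start, end)
    planted: list[PlantedRegion] = []
    coupled: list[CoupledGene] = []

    directions = ["hypo"] * n_coupled_hypo + ["hyper"] * n_coupled_hyper
    # promoter-planted (coupled) regions first
    gi = 0
    for direction in directions:
        placed = False
        while gi < len(coupled_genes_rows):
            gene = coupled_genes_rows[gi]
            gi += 1
            pstart, pend = promoter_interval(int(gene.tss), gene.strand, 1500, 500)
            run = _find_run(genome.positions[gene.chrom], pstart, pend,
                           config.planted_width_cpgs, taken, gene.chrom, rng)
            if run is None:
                continue
            i0, i1 = run
            pos = genome.positions[gene.chrom]
            start, end = int(pos[i0]), int(pos[i1 - 1]) + 1
            rid = f"R{len(planted):03d}"
            taken.append((gene.chrom, start, end))
            planted.append(PlantedRegion(rid, gene.chrom, start, end, direction,
                                         config.planted_effect, carriers=()))
            coupled.append(CoupledGene(gene.gene_id, rid, direction,
                                       config.fold_change_coupled, carriers=()))
            placed = True
            break
        if not placed:
            raise SizingError(
                "could not place a planted region inside any remaining promoter: "
                f"need {config.planted_width_cpgs} consecutive CpGs with gaps "
                f"<= {_PLANT_MAX_GAP} bp inside a 2,000 bp promoter window"
            )

    # remaining regions on intergenic CpG runs (outside every promoter)
    promoters = genome.catalog.promoters
    remaining = (["hypo"] * (n_hypo - n_coupled_hypo)) + (["hyper"] * (n_hyper - n_coupled_hyper))
    chrom_names = list(genome.positions)
    for direction in remaining:
        placed = False
        for _attempt in range(400):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            pos = genome.positions[chrom]
            if len(pos) < config.planted_width_cpgs:
                continue
            i0 = int(rng.integers(0, len(pos) - config.planted_width_cpgs + 1))
            i1 = i0 + config.planted_width_cpgs
            window = pos[i0:i1]
            if np.diff(window).max(initial=0) > _PLANT_MAX_GAP:
                continue
            start, end = int(window[0]), int(window[-1]) + 1
            prom_here = promoters[promoters["chrom"] == chrom]
            if ((prom_here["start"] < end) & (prom_here["end"] > start)).any():
                continue
            if any(c == chrom and start < e and s < end for c, s, e in taken):
                continue
            rid = f"R{len(planted):03d}"
            taken.append((chrom, start, end))
            planted.append(PlantedRegion(rid, chrom, start, end, direction,
                                         config.planted_effect, carriers=()))
            placed = True
            break
        if not placed:
            raise SizingError(
                "could not place an intergenic planted region: genome has too few "
                f"runs of {config.planted_width_cpgs} CpGs with gaps <= {_PLANT_MAX_GAP} bp"
            )

    # carrier schedules
    all_tumors = tuple(range(config.n_tumors))
    coupled_region_ids = {g.region_id for g in coupled}
    schedules: list[tuple[int, ...]] = []
    if config.recurrence_schedule is not None:
        schedules = [tuple(sorted(int(t) for t in entry)) for entry in config.recurrence_schedule]
    else:
        for k, region in enumerate(planted):
            if region.region_id in coupled_region_ids:
                # coupled regions recur in all tumors or all-but-one (>= 6/7)
                if k % 2 == 0 or config.n_tumors < 2:
                    schedules.append(all_tumors)
                else:
                    drop = int(rng.integers(0, config.n_tumors))
                    schedules.append(tuple(t for t in all_tumors if t != drop))
            else:
                size = int(rng.integers(max(1, config.n_tumors - 4), config.n_tumors + 1))
                schedules.append(tuple(sorted(rng.choice(config.n_tumors, size=size, replace=False).tolist())))
    planted = [
        PlantedRegion(r.region_id, r.chrom, r.start, r.end, r.direction, r.effect, schedules[k])
        for k, r in enumerate(planted)
    ]

    # expression carriers: ~9 of 10 tumors carry the coupled change
    n_expr_carriers = max(1, int(round(0.9 * config.n_expression_tumors)))
    coupled = [
        CoupledGene(
            g.gene_id, g.region_id, g.direction, g.fold_change,
            tuple(sorted(rng.choice(config.n_expression_tumors, size=n_expr_carriers,
                                    replace=False).tolist())),
        )
        for g in coupled
    ]
    return TruthSet(planted_dmrs=planted, coupled_genes=coupled, seed=config.seed).validate()


# ---------------------------------------------------------------------------
# latent profile + methylome sampling
# ---------------------------------------------------------------------------

def build_latent_profile(config: SimulationConfig, genome: SyntheticGenome,
                         truth: TruthSet, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Fill in the shared latent methylation fraction per CpG.

    Baseline is high methylation with per-site jitter; low-methylation
    islands and a subset of promoters are low; promoters of coupled
    genes get levels that leave room for the planted shift.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    coupled_dir = {g.gene_id: g.direction for g in truth.coupled_genes}

    latent: dict[str, np.ndarray] = {}
    for chrom, pos in genome.positions.items():
        base = rng.normal(config.baseline_high_meth, config.site_jitter_sd, size=len(pos))
        n_islands = int(round(config.frac_low_meth_islands * len(pos) / _ISLAND_WIDTH_CPGS))
        for _ in range(n_islands):
            if len(pos) <= _ISLAND_WIDTH_CPGS:
                break
            i0 = int(rng.integers(0, len(pos) - _ISLAND_WIDTH_CPGS))
            base[i0 : i0 + _ISLAND_WIDTH_CPGS] = rng.normal(
                config.baseline_low_meth, 0.03, size=_ISLAND_WIDTH_CPGS
            )
        latent[chrom] = np.clip(base, 0.0, 1.0)

    prom_levels: dict[str, float] = {}
    for gene in genome.genes.itertuples(index=False):
        direction = coupled_dir.get(gene.gene_id)
        if direction == "hypo":
            level = rng.uniform(0.75, 0.95)
        elif direction == "hyper":
            level = rng.uniform(0.05, 0.20)
        elif rng.random() < config.frac_low_meth_promoters:
            level = rng.uniform(0.02, 0.35)
        else:
            level = rng.uniform(0.45, 0.97)
        prom_levels[gene.gene_id] = level
        pstart, pend = promoter_interval(int(gene.tss), gene.strand, 1500, 500)
        pos = genome.positions[gene.chrom]
        mask = (pos >= pstart) & (pos < pend)
        latent[gene.chrom][mask] = np.clip(
            level + rng.normal(0.0, 0.03, size=int(mask.sum())), 0.0, 1.0
        )

    # planted regions outside promoters need baseline headroom for their
    # shift (a hypo shift on an island would clamp at 0 and vanish)
    coupled_rids = {g.region_id for g in truth.coupled_genes}
    for region in truth.planted_dmrs:
        if region.region_id in coupled_rids:
            continue  # promoter levels above already leave headroom
        pos = genome.positions[region.chrom]
        mask = (pos >= region.start) & (pos < region.end)
        n = int(mask.sum())
        if region.direction == "hypo":
            lo, hi = min(region.effect + 0.12, 0.98), 1.0
            level = max(config.baseline_high_meth, region.effect + 0.2)
        else:
            lo, hi = 0.0, max(1.0 - region.effect - 0.12, 0.02)
            level = min(0.15, hi)
        latent[region.chrom][mask] = np.clip(rng.normal(level, 0.03, size=n), lo, hi)

    genome.latent = latent
    genome.promoter_meth = pd.Series(prom_levels, name="promoter_meth")
    return genome


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    depth = rng.poisson(mean, size=size)
    while (depth == 0).any():
        zero = depth == 0
        depth[zero] = rng.poisson(mean, size=int(zero.sum()))
    return depth


def _region_masks(genome: SyntheticGenome, truth: TruthSet) -> dict[str, np.ndarray]:
    """Per-region boolean masks over CpG indices; errors if a planted
    region covers no simulated CpG or does not start on one."""
    masks: dict[str, np.ndarray] = {}
    for region in truth.planted_dmrs:
        pos = genome.positions.get(region.chrom)
        if pos is None:
            raise ConsistencyError(f"planted region {region.region_id} on unknown {region.chrom}")
        mask = (pos >= region.start) & (pos < region.end)
        if not mask.any() or int(pos[mask][0]) != region.start:
            raise ConsistencyError(
                f"planted region {region.region_id} does not lie on simulated CpGs"
            )
        masks[region.region_id] = mask
    return masks


def simulate_methylomes(config: SimulationConfig, genome: SyntheticGenome, truth: TruthSet,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[MethylomeSample], list[MethylomeSample]]:
    """Draw control and tumor methylomes around the latent profile.

    Depth is truncated-Poisson (>= 1); methylated counts are binomial
    around each sample's latent fraction. Carrier tumors are shifted by
    +-effect inside planted regions (clamped to [0, 1]); non-carrier
    tumors get independent baseline noise, not copies of controls.
    """
    if not genome.latent:
        raise ConsistencyError("latent profile not built; call build_latent_profile first")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    masks = _region_masks(genome, truth)

    shifts: list[dict[str, np.ndarray]] = []
    for t in range(config.n_tumors):
        shift = {chrom: np.zeros(len(pos)) for chrom, pos in genome.positions.items()}
        for region in truth.planted_dmrs:
            if t in region.carriers:
                sgn = -1.0 if region.direction == "hypo" else 1.0
                shift[region.chrom][masks[region.region_id]] += sgn * region.effect
        shifts.append(shift)

    chroms = list(genome.positions)

    def draw(sample_id: str, noise_sd: float, shift: dict[str, np.ndarray] | None) -> MethylomeSample:
        frames = []
        for chrom in chroms:
            lat = genome.latent[chrom]
            frac = lat + rng.normal(0.0, noise_sd, size=len(lat))
            if shift is not None:
                frac = frac + shift[chrom]
            frac = np.clip(frac, 0.0, 1.0)
            depth = _truncated_poisson(rng, config.depth_mean, len(lat))
            meth = rng.binomial(depth, frac)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": genome.positions[chrom],
                "count_meth": meth,
                "count_total": depth,
            }))
        return MethylomeSample(sample_id, pd.concat(frames, ignore_index=True)).validate()

    controls = [draw(f"control_{i + 1}", config.control_noise_sd, None)
                for i in range(config.n_controls)]
    tumors = [draw(f"tumor_{t + 1}", config.tumor_noise_sd, shifts[t])
              for t in range(config.n_tumors)]
    return controls, tumors


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig, genome: SyntheticGenome, truth: TruthSet,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with promoter-methylation coupling.

    Per-gene mean scales with transcript length and a per-sample library
    factor; baseline log-rate decreases with latent promoter methylation
    (inverse coupling). Coupled genes' means are multiplied/divided by
    ``fold_change_coupled`` in carrier expression tumors (hypo -> up,
    hyper -> down).
    """
    if genome.promoter_meth is None:
        raise ConsistencyError("latent profile not built; call build_latent_profile first")
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    genes = genome.genes["gene_id"].tolist()
    missing = [g.gene_id for g in truth.coupled_genes if g.gene_id not in set(genes)]
    if missing:
        raise ConsistencyError(f"coupled genes absent from catalog: {missing}")

    n_genes = len(genes)
    lengths = pd.Series(
        rng.integers(config.gene_length_min, config.gene_length_max + 1, size=n_genes),
        index=genes, name="length_bp",
    )
    meth = genome.promoter_meth.reindex(genes).to_numpy()
    log2_rate = rng.normal(3.5, 0.8, size=n_genes) + config.expression_coupling_slope * (1.0 - meth)
    rate_per_kb = np.power(2.0, log2_rate)

    sample_ids = [f"control_{i + 1}" for i in range(config.n_controls)] + [
        f"tumor_{t + 1}" for t in range(config.n_expression_tumors)
    ]
    lib = rng.uniform(0.85, 1.15, size=len(sample_ids))

    base_mu = rate_per_kb * (lengths.to_numpy() / 1000.0)
    mu = np.outer(base_mu, lib)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for cg in truth.coupled_genes:
        gi = gene_pos[cg.gene_id]
        factor = cg.fold_change if cg.direction == "hypo" else 1.0 / cg.fold_change
        for t in cg.carriers:
            mu[gi, config.n_controls + t] *= factor

    d = config.expression_dispersion
    if d > 0:
        lam = rng.gamma(shape=1.0 / d, scale=d * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return counts_df, lengths


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Run the full generator; ``seed`` overrides the config seed."""
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    truth = plant_truth(config, genome, rng)
    genome = build_latent_profile(config, genome, truth, rng)
    controls, tumors = simulate_methylomes(config, genome, truth, rng)
    counts, lengths = simulate_expression(config, genome, truth, rng)
    return SimulatedDataset(config, genome, truth, controls, tumors, counts, lengths)


def write_dataset(ds: SimulatedDataset, outdir: str | Path,
                  pipeline: PipelineConfig | None = None) -> dict[str, Path]:
    """Write every artifact as plain text; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in ds.controls + ds.tumors:
        p = outdir / f"{sample.sample_id}.cov"
        io_formats.write_bismark_coverage(sample, p)
        paths[sample.sample_id] = p
    for category in ("promoter", "enhancer", "exon", "intron", "repeat"):
        p = outdir / f"{category}s.bed"
        io_formats.write_bed(ds.genome.catalog, p, category=category)
        paths[f"bed_{category}"] = p
    io_formats.write_counts(ds.counts, outdir / "counts.tsv")
    io_formats.write_gene_lengths(ds.gene_lengths, outdir / "gene_lengths.tsv")
    io_formats.write_truth(ds.truth, outdir / "truth_regions.tsv", outdir / "truth_genes.tsv")
    paths["counts"] = outdir / "counts.tsv"
    paths["gene_lengths"] = outdir / "gene_lengths.tsv"
    paths["truth_regions"] = outdir / "truth_regions.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    dump_config(ds.config, pipeline or PipelineConfig(), outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
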