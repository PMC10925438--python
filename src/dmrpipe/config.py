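"""Configuration objects for the simulator and the analysis pipeline.

Every threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`; the defaults are the published values the
pipeline re-implements. Both configs serialize to/from YAML.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic WGBS + RNA-seq dataset generator."""

    n_chromosomes: int = 2
    chrom_length: int = 250_000
    cpg_spacing_mean: float = 60.0

    n_controls: int = 5
    n_tumors: int = 7
    n_expression_tumors: int = 10

    depth_mean: float = 30.0

    baseline_high_meth: float = 0.85
    baseline_low_meth: float = 0.08
    frac_low_meth_promoters: float = 0.30
    frac_low_meth_islands: float = 0.20
    site_jitter_sd: float = 0.08
    control_noise_sd: float = 0.015
    tumor_noise_sd: float = 0.02

    n_planted_hypo: int = 6
    n_planted_hyper: int = 3
    planted_effect: float = 0.40
    planted_width_cpgs: int = 6
    # One entry per planted region: tuple of carrier tumor indices, or None
    # to let the simulator draw a (deterministic, seeded) schedule.
    recurrence_schedule: list | None = None

    n_genes: int = 30
    coupled_gene_fraction: float = 0.20
    expression_dispersion: float = 0.10
    fold_change_coupled: float = 10.0
    expression_coupling_slope: float = 3.0
    gene_length_min: int = 500
    gene_length_max: int = 5000

    seed: int = 0

    def validate(self) -> "SimulationConfig":
        fractions = {
            "baseline_high_meth": self.baseline_high_meth,
            "baseline_low_meth": self.baseline_low_meth,
            "frac_low_meth_promoters": self.frac_low_meth_promoters,
            "frac_low_meth_islands": self.frac_low_meth_islands,
            "coupled_gene_fraction": self.coupled_gene_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if not 0.1 <= self.planted_effect <= 0.8:
            raise ConfigError("planted_effect must be in [0.1, 0.8]")
        if self.planted_width_cpgs < 3:
            raise ConfigError("planted_width_cpgs must be >= 3")
        for n in ("n_chromosomes", "n_controls", "n_tumors", "n_expression_tumors", "n_genes"):
            if getattr(self, n) < 1:
                raise ConfigError(f"{n} must be >= 1")
        if self.expression_dispersion < 0:
            raise ConfigError("expression_dispersion must be >= 0")
        if self.fold_change_coupled <= 0:
            raise ConfigError("fold_change_coupled must be > 0")
        if self.gene_length_min <= 0 or self.gene_length_max < self.gene_length_min:
            raise ConfigError("invalid gene length range")
        if self.recurrence_schedule is not None:
            n_regions = self.n_planted_hypo + self.n_planted_hyper
            if len(self.recurrence_schedule) != n_regions:
                raise ConfigError(
                    "recurrence_schedule must have one entry per planted region "
                    f"({n_regions}), got {len(self.recurrence_schedule)}"
                )
            for entry in self.recurrence_schedule:
                if any(t < 0 or t >= self.n_tumors for t in entry):
                    raise ConfigError("recurrence_schedule entry outside tumor index range")
        return self


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults mirror the published pipeline."""

    min_depth: int = 5
    bin_edges: list = field(default_factory=lambda: [0.0, 25.0, 50.0, 75.0, 100.0])
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    dmc_min_delta: float = 10.0
    dmr_min_cpgs: int = 3
    dmr_max_gap: int = 100
    alpha: float = 0.05
    fdr: bool = False
    de_fc_threshold: float = 1.5
    de_pseudo_fpkm: float = 0.1
    core_expr_fc: float = 2.0
    recurrence_all: bool = True
    integration_min_tumors: int = 6
    integration_expr_fc: float = 2.0
    integration_expr_min_tumors: int | None = None  # default: ceil(N/2)+1
    high_expression_fpkm: float = 5.0

    def validate(self) -> "PipelineConfig":
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        edges = list(self.bin_edges)
        if len(edges) < 2 or any(b >= a for a, b in zip(edges[1:], edges[:-1])):
            raise ConfigError("bin_edges must be strictly increasing with >= 2 edges")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must be in [0, 1]")
        if self.dmr_min_cpgs < 1:
            raise ConfigError("dmr_min_cpgs must be >= 1")
        if self.dmr_max_gap < 1:
            raise ConfigError("dmr_max_gap must be >= 1")
        if self.dmc_min_delta < 0:
            raise ConfigError("dmc_min_delta must be >= 0")
        for name in ("de_fc_threshold", "core_expr_fc", "integration_expr_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        return self


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping).validate()


def load_config(path: str | Path):
    """Load a YAML config file with optional ``simulation:`` and
    ``pipeline:`` sections; missing sections get defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _from_mapping(SimulationConfig, raw.get("simulation", {}) or {})
    pipe = _from_mapping(PipelineConfig, raw.get("pipeline", {}) or {})
    return sim, pipe


def dump_config(sim: SimulationConfig, pipe: PipelineConfig, path: str | Path) -> None:
    payload = {
        "simulation": dataclasses.asdict(sim),
        "pipeline": dataclasses.asdict(pipe),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
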