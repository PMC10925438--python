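"""End-to-end orchestration: simulate -> profile -> dmr -> annotate ->
de -> signature -> integrate, with a reproducible run manifest.

A single global seed fans out to per-stage seeds by fixed offsets so
stages are individually reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as annotate_mod
from . import dmr as dmr_mod
from . import expression as expr_mod
from . import io as io_formats
from . import profile as profile_mod
from . import signature as sig_mod
from .config import PipelineConfig, SimulationConfig
from .simulate import simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)    # name -> sha256
    outputs: dict = field(default_factory=dict)   # name -> path
    stages: list = field(default_factory=list)    # per-stage log entries
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(outdir: str | Path, sim_config: SimulationConfig | None = None,
            pipe_config: PipelineConfig | None = None, seed: int | None = None,
            simulate: bool = True) -> RunManifest:
    """Run every stage on a (simulated) dataset and write all outputs.

    Returns the manifest; also writes ``manifest.json`` in ``outdir``.
    """
    if not simulate:
        raise NotImplementedError(
            "only --simulate runs are bundled; run individual subcommands on external data"
        )
    sim_config = sim_config or SimulationConfig()
    pipe_config = (pipe_config or PipelineConfig()).validate()
    if seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
    sim_config.validate()

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=sim_config.seed, config={
        "simulation": dataclasses.asdict(sim_config),
        "pipeline": dataclasses.asdict(pipe_config),
    })
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")

    def stage(name: str, **counts) -> None:
        logger.info("stage %s: %s", name, counts)
        manifest.stages.append({"stage": name, **counts})

    # --- simulate ------------------------------------------------------
    ds = simulate_dataset(sim_config)
    data_dir = outdir / "data"
    paths = write_dataset(ds, data_dir, pipe_config)
    for name, p in paths.items():
        manifest.inputs[name] = _sha256(p)
    stage("simulate", n_cpgs=ds.genome.n_cpgs, n_controls=len(ds.controls),
          n_tumors=len(ds.tumors), n_planted=len(ds.truth.planted_dmrs),
          n_coupled_genes=len(ds.truth.coupled_genes))

    # --- profile -------------------------------------------------------
    controls_f = [profile_mod.filter_by_coverage(c, pipe_config.min_depth) for c in ds.controls]
    tumors_f = [profile_mod.filter_by_coverage(t, pipe_config.min_depth) for t in ds.tumors]
    shared = profile_mod.intersect_common_cpgs(controls_f)
    pearson = profile_mod.pearson_matrix(shared * 100.0)
    pearson.to_csv(outdir / "control_pearson.tsv", sep="\t")
    manifest.outputs["control_pearson"] = str(outdir / "control_pearson.tsv")

    fpkm = expr_mod.compute_fpkm(ds.counts, ds.gene_lengths)
    prom_means = profile_mod.promoter_mean_methylation(controls_f[0], ds.genome.catalog)
    strata, strata_tests = profile_mod.methylation_expression_strata(
        prom_means, fpkm[controls_f[0].sample_id], pipe_config.bin_edges)
    strata.to_csv(outdir / "meth_expression_strata.tsv", sep="\t", index=False)
    strata_tests.to_csv(outdir / "meth_expression_strata_tests.tsv", sep="\t", index=False)
    manifest.outputs["strata"] = str(outdir / "meth_expression_strata.tsv")
    stage("profile", n_shared_cpgs=len(shared),
          n_promoters_with_cpgs=int(prom_means.notna().sum()))

    # --- dmr calling per tumor ----------------------------------------
    ctrl_profile = dmr_mod.average_controls(controls_f, pipe_config, prefiltered=True)
    per_tumor_dmrs = []
    for t in tumors_f:
        dmrs = dmr_mod.call_dmrs_with_profile(t, ctrl_profile, pipe_config)
        per_tumor_dmrs.append(dmrs)
        p = outdir / f"dmrs_{t.sample_id}.tsv"
        io_formats.write_dmrs(dmrs, p)
        manifest.outputs[f"dmrs_{t.sample_id}"] = str(p)
    stage("dmr", **{f"dmrs_{t.sample_id}": len(d)
                    for t, d in zip(tumors_f, per_tumor_dmrs)})

    # --- annotate ------------------------------------------------------
    index = annotate_mod.build_interval_index(ds.genome.catalog)
    per_tumor_annotated = []
    for t, dmrs in zip(tumors_f, per_tumor_dmrs):
        annotated, counts = annotate_mod.annotate_dmrs(dmrs, index)
        per_tumor_annotated.append(annotated)
        counts.to_csv(outdir / f"element_counts_{t.sample_id}.tsv", sep="\t")
    stage("annotate", n_tumors=len(per_tumor_annotated))

    # --- differential expression per tumor ----------------------------
    control_ids = [c.sample_id for c in ds.controls]
    expr_tumor_ids = [c for c in ds.counts.columns if c.startswith("tumor_")]
    de_results = {}
    for tid in expr_tumor_ids:
        res = expr_mod.differential_expression(ds.counts, ds.gene_lengths, tid,
                                               control_ids, pipe_config)
        de_results[tid] = res
        res.to_csv(outdir / f"de_{tid}.tsv", sep="\t", index_label="gene_id")
    stage("de", **{tid: int(r["significant"].sum()) for tid, r in de_results.items()})

    # --- signatures + integration -------------------------------------
    core = sig_mod.core_methylation_signature(per_tumor_dmrs)
    core_frame = pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "direction": r.direction}
         for r in core.regions])
    core_frame.to_csv(outdir / "core_methylation_signature.tsv", sep="\t", index=False)
    if core.regions:
        core_annot, _ = annotate_mod.annotate_dmrs(
            [dmr_mod.Dmr(r.chrom, r.start, r.end, r.direction, 3, 0.0, 0.0)
             for r in core.regions], index)
        annotate_mod.signature_element_distribution(core_annot).to_csv(
            outdir / "core_signature_elements.tsv", sep="\t")

    up, down = sig_mod.core_expression_signature(de_results, pipe_config.core_expr_fc)
    with open(outdir / "core_expression_signature.tsv", "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(up):
            fh.write(f"{g}\tup\n")
        for g in sorted(down):
            fh.write(f"{g}\tdown\n")

    freq = sig_mod.promoter_dmr_frequency(per_tumor_annotated)
    freq.to_csv(outdir / "promoter_dmr_frequency.tsv", sep="\t")
    hypo_up, hyper_down = sig_mod.integrate(freq, de_results, pipe_config)
    hypo_up.to_csv(outdir / "integrated_hypo_up.tsv", sep="\t")
    hyper_down.to_csv(outdir / "integrated_hyper_down.tsv", sep="\t")
    manifest.outputs["integrated_hypo_up"] = str(outdir / "integrated_hypo_up.tsv")
    manifest.outputs["integrated_hyper_down"] = str(outdir / "integrated_hyper_down.tsv")
    stage("signature", core_hypo=sum(1 for r in core.regions if r.direction == "hypo"),
          core_hyper=sum(1 for r in core.regions if r.direction == "hyper"),
          expr_up=len(up), expr_down=len(down),
          hypo_up=len(hypo_up), hyper_down=len(hyper_down))

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest
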