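"""End-to-end orchestration: simulate -> call -> annotate -> quantify ->
mds -> dde -> enrich -> hostcor -> coedit -> mirna, with an output manifest.

Stages exchange plain TSV/VCF/FASTA files so every intermediate is
inspectable and diffable. A stage is skipped when all of its outputs are
newer than all of its inputs, unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, calling, coedit, formats, mirna, quantify, simulate, stats

log = logging.getLogger("editome")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    outdir: Path
    seed: int = 42
    simulate: simulate.SimulationConfig = None
    calling: calling.CallingParams = None
    network: coedit.NetworkParams = None
    stage_encoding: str = "days"          # or "index"
    impute_method: str = "mean"
    mds_dims: int = 2
    mds_exclude_intergenic: bool = True
    significance_q: float = 0.05
    mappability_mask: Path | None = None

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.simulate is None:
            self.simulate = simulate.SimulationConfig(seed=self.seed)
        if self.calling is None:
            self.calling = calling.CallingParams()
        if self.network is None:
            self.network = coedit.NetworkParams()
        if self.stage_encoding not in ("days", "index"):
            raise ValueError("stage_encoding must be 'days' or 'index'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", {})
        cal = raw.pop("calling", {})
        net = raw.pop("network", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulate = simulate.SimulationConfig(
                **{**dataclasses.asdict(cfg.simulate), **sim}
            )
        if cal:
            cfg.calling = calling.CallingParams(
                **{**dataclasses.asdict(cfg.calling), **cal}
            )
        if net:
            base = dataclasses.asdict(cfg.network)
            base.update(net)
            base["powers"] = tuple(base["powers"])
            cfg.network = coedit.NetworkParams(**base)
        return cfg

    @property
    def stage_col(self) -> str:
        return "stage_days" if self.stage_encoding == "days" else "stage_index"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fresh(outputs, inputs) -> bool:
    outputs = [Path(p) for p in outputs]
    inputs = [Path(p) for p in inputs]
    if not all(p.exists() for p in outputs):
        return False
    oldest_out = min(p.stat().st_mtime for p in outputs)
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return oldest_out >= newest_in


def _require(stage: str, *paths):
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError(stage, f"missing inputs: {', '.join(missing)}")


def _sample_pileups(cfg: RunConfig) -> dict[str, Path]:
    samples = pd.read_csv(cfg.outdir / "samples.tsv", sep="\t", index_col=0)
    return {s: cfg.outdir / "rna" / f"{s}.pileup.tsv" for s in samples.index}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / p for p in
           ("genome.fa", "genes.gtf", "repeats.bed", "samples.tsv",
            "wgs.vcf", "wgbs.vcf", "dbsnp.vcf", "fpkm.tsv", "mirna.fa")]
    if not force and _fresh(out, []):
        log.info("simulate: outputs up to date, skipping")
        return out
    simulate.simulate_dataset(cfg.simulate, cfg.outdir)
    return out


def stage_call(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "sites.tsv", cfg.outdir / "clusters.tsv"]
    inputs = [cfg.outdir / p for p in
              ("genome.fa", "genes.gtf", "wgs.vcf", "wgbs.vcf", "dbsnp.vcf",
               "samples.tsv")]
    _require("call", *inputs)
    if not force and _fresh(out, inputs):
        log.info("call: outputs up to date, skipping")
        return out
    genome = formats.read_fasta(cfg.outdir / "genome.fa")
    models = formats.read_gtf(cfg.outdir / "genes.gtf")
    mask = (formats.read_bed(cfg.mappability_mask)
            if cfg.mappability_mask else None)
    table, clusters = calling.run_calling(
        _sample_pileups(cfg),
        formats.read_vcf_min(cfg.outdir / "wgs.vcf"),
        formats.read_vcf_min(cfg.outdir / "wgbs.vcf"),
        formats.read_vcf_min(cfg.outdir / "dbsnp.vcf"),
        models, genome, cfg.calling, mappability_mask=mask,
    )
    table.to_csv(out[0], sep="\t")
    pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end,
          "n_sites": len(c.members)} for c in clusters]
    ).to_csv(out[1], sep="\t", index=False)
    return out


def stage_annotate(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "annotated.tsv"]
    inputs = [cfg.outdir / p for p in
              ("sites.tsv", "genes.gtf", "genome.fa", "repeats.bed")]
    _require("annotate", *inputs)
    if not force and _fresh(out, inputs):
        return out
    sites = pd.read_csv(inputs[0], sep="\t", index_col=0,
                        keep_default_na=False)
    models = formats.read_gtf(cfg.outdir / "genes.gtf")
    genome = formats.read_fasta(cfg.outdir / "genome.fa")
    repeats = formats.read_bed(cfg.outdir / "repeats.bed")
    annotated = annotate.annotate_sites(sites, models, genome, repeats)
    annotated.to_csv(out[0], sep="\t")
    return out


def stage_quantify(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "matrix.tsv", cfg.outdir / "overall_rates.tsv"]
    inputs = [cfg.outdir / "annotated.tsv", cfg.outdir / "samples.tsv"]
    _require("quantify", *inputs)
    if not force and _fresh(out, inputs):
        return out
    annotated = pd.read_csv(inputs[0], sep="\t", index_col=0,
                            keep_default_na=False)
    samples = pd.read_csv(inputs[1], sep="\t", index_col=0)
    em = quantify.quantify_levels(annotated, _sample_pileups(cfg), samples,
                                  min_depth=cfg.calling.min_depth,
                                  read_end_exclusion_bp=cfg.calling.read_end_exclusion_bp)
    formats.write_matrix(em.levels, out[0])
    em.overall_rates().to_csv(out[1], sep="\t")
    return out


def stage_mds(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "mds.tsv"]
    inputs = [cfg.outdir / "matrix.tsv", cfg.outdir / "annotated.tsv"]
    _require("mds", *inputs)
    if not force and _fresh(out, inputs):
        return out
    levels = formats.read_level_matrix(inputs[0])
    if cfg.mds_exclude_intergenic:
        annotated = pd.read_csv(inputs[1], sep="\t", index_col=0,
                                keep_default_na=False)
        keep = annotated.index[annotated["feature"] != "intergenic"]
        levels = levels.loc[levels.index.intersection(keep)]
    levels = quantify.missingness_filter(levels)
    imputed = quantify.impute(levels, method=cfg.impute_method)
    coords, var_frac = quantify.classical_mds(imputed, cfg.mds_dims)
    for i, v in enumerate(var_frac):
        coords.attrs[f"var_frac_dim{i + 1}"] = float(v)
    header = "# variance fractions: " + ", ".join(f"{v:.4f}" for v in var_frac)
    with open(out[0], "w") as fh:
        fh.write(header + "\n")
        coords.to_csv(fh, sep="\t")
    return out


def stage_dde(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "dde.tsv"]
    inputs = [cfg.outdir / "matrix.tsv", cfg.outdir / "samples.tsv"]
    _require("dde", *inputs)
    if not force and _fresh(out, inputs):
        return out
    levels = quantify.missingness_filter(formats.read_level_matrix(inputs[0]))
    samples = pd.read_csv(inputs[1], sep="\t", index_col=0)
    res = stats.differential_editing(levels, samples, stage_col=cfg.stage_col)
    res.to_csv(out[0], sep="\t")
    return out


def stage_enrich(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "enrich_chromosome.tsv", cfg.outdir / "enrich_feature.tsv"]
    inputs = [cfg.outdir / "dde.tsv", cfg.outdir / "annotated.tsv"]
    _require("enrich", *inputs)
    if not force and _fresh(out, inputs):
        return out
    dde = pd.read_csv(inputs[0], sep="\t", index_col=0)
    annotated = pd.read_csv(inputs[1], sep="\t", index_col=0,
                            keep_default_na=False)
    annotated = annotated.loc[annotated.index.intersection(dde.index)]
    sig = dde["q_stage"] <= cfg.significance_q
    stats.enrichment_table(annotated, sig, "chrom").to_csv(out[0], sep="\t")
    stats.enrichment_table(annotated, sig, "feature").to_csv(out[1], sep="\t")
    return out


def stage_hostcor(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "hostcor.tsv"]
    inputs = [cfg.outdir / "dde.tsv", cfg.outdir / "matrix.tsv",
              cfg.outdir / "annotated.tsv", cfg.outdir / "fpkm.tsv"]
    _require("hostcor", *inputs)
    if not force and _fresh(out, inputs):
        return out
    dde = pd.read_csv(inputs[0], sep="\t", index_col=0)
    levels = formats.read_level_matrix(inputs[1])
    annotated = pd.read_csv(inputs[2], sep="\t", index_col=0,
                            keep_default_na=False)
    fpkm = formats.read_expression_matrix(inputs[3])
    sig_ids = dde.index[dde["q_stage"] <= cfg.significance_q]
    site_gene = annotated.loc[annotated.index.intersection(sig_ids), "gene_id"]
    table = stats.host_expression_correlation(levels, fpkm, site_gene)
    table.to_csv(out[0], sep="\t")
    return out


def stage_coedit(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "modules.tsv", cfg.outdir / "eigengenes.tsv",
           cfg.outdir / "module_trait.tsv"]
    inputs = [cfg.outdir / "matrix.tsv", cfg.outdir / "samples.tsv",
              cfg.outdir / "overall_rates.tsv"]
    _require("coedit", *inputs)
    if not force and _fresh(out, inputs):
        return out
    levels = formats.read_level_matrix(inputs[0])
    samples = pd.read_csv(inputs[1], sep="\t", index_col=0)
    rates = pd.read_csv(inputs[2], sep="\t", index_col=0)["overall_rate"]
    assignment = coedit.build_network(levels, cfg.network)
    assignment.labels.rename("module").to_csv(out[0], sep="\t")
    formats.write_matrix(assignment.eigengenes, out[1])
    traits = pd.DataFrame(
        {
            cfg.stage_col: samples[cfg.stage_col],
            "sex01": (samples["sex"] == "F").astype(float),
            "overall_rate": rates,
        }
    )
    coedit.module_trait_correlation(assignment.eigengenes, traits).to_csv(
        out[2], sep="\t"
    )
    return out


def stage_mirna(cfg: RunConfig, force=False) -> list[Path]:
    out = [cfg.outdir / "rewiring.tsv", cfg.outdir / "rewiring_summary.json"]
    inputs = [cfg.outdir / "annotated.tsv", cfg.outdir / "genome.fa",
              cfg.outdir / "mirna.fa"]
    _require("mirna", *inputs)
    if not force and _fresh(out, inputs):
        return out
    annotated = pd.read_csv(inputs[0], sep="\t", index_col=0,
                            keep_default_na=False)
    genome = formats.read_fasta(inputs[1])
    mirnas = formats.read_mirna_fasta(inputs[2])
    table, summary = mirna.rewire_sites(annotated, genome, mirnas)
    table.to_csv(out[0], sep="\t", index=False)
    with open(out[1], "w") as fh:
        json.dump(summary, fh, indent=1)
    return out


STAGES = {
    "simulate": stage_simulate,
    "call": stage_call,
    "annotate": stage_annotate,
    "quantify": stage_quantify,
    "mds": stage_mds,
    "dde": stage_dde,
    "enrich": stage_enrich,
    "hostcor": stage_hostcor,
    "coedit": stage_coedit,
    "mirna": stage_mirna,
}


def run_pipeline(cfg: RunConfig, force: bool = False,
                 stages=None) -> dict:
    """Run stages in dependency order and write a manifest with checksums."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for name in (stages or STAGES):
        fn = STAGES[name]
        log.info("running stage %s", name)
        try:
            outputs.extend(fn(cfg, force=force))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    manifest = {
        "seed": cfg.seed,
        "stage_encoding": cfg.stage_encoding,
        "params": {
            "simulate": dataclasses.asdict(cfg.simulate),
            "calling": dataclasses.asdict(cfg.calling),
            "network": dataclasses.asdict(cfg.network),
        },
        "outputs": [
            {"path": str(p), "sha256": _sha256(p)}
            for p in outputs if Path(p).exists()
        ],
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
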