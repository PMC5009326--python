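"""End-to-end orchestration: configuration, seeds, manifest, stages.

The pipeline runs simulate -> classify/optimize -> biomarker -> walk ->
enrich -> epistasis, each stage reading the previous stage's serialized
outputs from the run directory, so any stage can be re-run in
isolation.  All randomness flows from one global seed through named
per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tempfile
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import epistasis as epi
from . import io as nio
from . import netwalk as nw
from . import signature as sig
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed", "setup_logging"]

__version__ = "0.1.0"

STAGES = ["simulate", "classify", "biomarker", "walk", "enrich", "epistasis"]


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr; results go to files only."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters, input paths and the global seed.

    Unknown keys in a YAML config are rejected; a config round-trips
    through serialization unchanged.
    """

    seed: int = 0
    outdir: str = "netsig_run"
    log_level: str = "INFO"
    # synthetic stage (None -> use packaged defaults)
    expression: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)
    gene_sets: dict = field(default_factory=dict)
    # classifier
    n1: int = 25
    n2: int = 25
    alpha_filter: float = 0.01
    weight_exponent: float = 1.0
    n_folds: int = 10
    optimize: bool = False
    n1_grid: list = field(default_factory=lambda: [10, 25, 50])
    n2_grid: list = field(default_factory=lambda: [10, 25, 50])
    alpha_grid: list = field(default_factory=lambda: [0.001, 0.01, 0.05])
    ga_population: int = 12
    ga_generations: int = 6
    # netwalk
    restart_prob: float = 0.5
    threshold: str | float = "auto"
    # enrichment
    fdr_enrichment: float = 0.001
    # epistasis
    snp_call: float = 0.95
    maf: float = 0.05
    sample_call: float = 0.95
    mds_axes: int = 3
    genomic_control: bool = True
    fdr_epistasis: float = 0.05
    # optional external inputs (paths); empty -> simulate
    expression_prefix: str = ""
    network_path: str = ""
    gmt_path: str = ""
    cohort1_dir: str = ""
    cohort2_dir: str = ""
    boundaries_path: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Audit record of one pipeline run, written atomically at the end."""

    config: dict
    version: str
    seeds: dict
    checksums: dict
    timestamps: dict
    stages_completed: list
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        path = Path(path)
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> RunManifest:
    """Run the workflow (or a contiguous subset of stages).

    Each stage consumes the previous stage's serialized outputs from
    ``config.outdir`` and writes its own there; the manifest records
    seeds, checksums and the failed stage, if any.
    """
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        seeds=seeds,
        checksums={},
        timestamps={},
        stages_completed=[],
    )
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            _STAGE_FNS[stage](config, outdir, seeds[stage])
            manifest.timestamps[stage] = round(time.time() - t0, 3)
            manifest.stages_completed.append(stage)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(outdir / "manifest.json")
        raise
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_simulate(config: PipelineConfig, outdir: Path, seed: int) -> None:
    if config.expression_prefix:
        logger.info("external expression input given; simulate stage skipped")
        return
    expr_cfg = syn.ExprSimConfig(**{"seed": seed, **config.expression})
    ds = syn.simulate_expression(expr_cfg)
    nio.write_expression(ds, outdir / "study1")

    net_cfg = syn.NetSimConfig(**{"seed": seed + 1, **config.network})
    genes = syn.informative_genes(expr_cfg)
    network, module = syn.simulate_network(net_cfg, genes)
    nio.write_sif(network, outdir / "network.sif")
    nio.write_gene_list(module, outdir / "planted_module.txt")

    gs_cfg = dict(config.gene_sets)
    collection = syn.simulate_gene_sets(
        network, module, seed=gs_cfg.pop("seed", seed + 2), **gs_cfg
    )
    nio.write_gmt(collection, outdir / "gene_sets.gmt")

    geno_kwargs = dict(config.genotypes)
    c1 = syn.GenoSimConfig(**{"seed": seed + 3, **geno_kwargs})
    c2 = syn.GenoSimConfig(**{"seed": seed + 4, **geno_kwargs})
    coh1, coh2, interacting = syn.simulate_cohorts(c1, c2)
    nio.write_cohort(coh1, outdir / "cohort1")
    nio.write_cohort(coh2, outdir / "cohort2")
    nio.write_gene_list(interacting, outdir / "planted_interactions.txt")
    # gene boundaries covering each SNP's position for the mapping stage
    meta = coh1.snp_meta
    bounds = [
        epi.GeneBoundaries(
            gene=f"G_{s}", chrom=str(meta.loc[s, 'chrom']),
            start=max(1, int(meta.loc[s, 'pos']) - 5000),
            end=int(meta.loc[s, 'pos']) + 5000,
        )
        for s in meta.index
    ]
    nio.write_boundaries(bounds, outdir / "boundaries.tsv")


def _load_expression(config: PipelineConfig, outdir: Path) -> sig.ExpressionDataset:
    prefix = config.expression_prefix or str(outdir / "study1")
    return nio.read_expression(prefix)


def _stage_classify(config: PipelineConfig, outdir: Path, seed: int) -> None:
    ds = _load_expression(config, outdir)
    if config.optimize:
        params, report, log = sig.ga_optimize(
            ds,
            config.n1_grid, config.n2_grid, config.alpha_grid,
            settings=sig.GASettings(
                population=config.ga_population,
                generations=config.ga_generations,
            ),
            n_folds=config.n_folds,
            seed=seed,
            weight_exponent=config.weight_exponent,
        )
        pd.DataFrame(log).to_csv(outdir / "ga_log.tsv", sep="\t", index=False)
    else:
        params = sig.ClassifierParams(
            n1=config.n1, n2=config.n2, alpha_filter=config.alpha_filter,
            weight_exponent=config.weight_exponent, seed=seed,
        )
        report = sig.cross_validate(ds, params, n_folds=config.n_folds, seed=seed)
    pd.DataFrame(
        {
            "fold": range(len(report.fold_accuracy)),
            "accuracy": report.fold_accuracy,
            "precision": report.fold_precision,
            "recall": report.fold_recall,
        }
    ).to_csv(outdir / "cv_report.tsv", sep="\t", index=False)
    with open(outdir / "params.json", "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)
    logger.info(
        "CV accuracy %.3f (precision %.3f, recall %.3f) with n1=%d n2=%d alpha=%g",
        report.accuracy, report.precision, report.recall,
        params.n1, params.n2, params.alpha_filter,
    )


def _stage_biomarker(config: PipelineConfig, outdir: Path, seed: int) -> None:
    ds = _load_expression(config, outdir)
    with open(outdir / "params.json") as fh:
        params = sig.ClassifierParams(**json.load(fh))
    sigs, pmap, _ = sig.fit_signatures(ds, params)
    biomarker = sig.extract_biomarker(sigs, ds.probe_to_gene, pmap)
    nio.write_biomarker(biomarker, outdir / "biomarker.tsv")
    genes = sorted(biomarker.gene_symbols)
    nio.write_gene_list(genes, outdir / "biomarker_genes.txt")
    # gene-level p-values: best probe p per gene, for node scoring
    gene_p: dict[str, float] = {}
    for probe in biomarker.probe_ids:
        gene = ds.probe_to_gene.get(probe)
        if gene is None:
            continue
        p = biomarker.filter_pvalues.get(probe, 1.0)
        gene_p[gene] = min(p, gene_p.get(gene, 1.0))
    pd.DataFrame(
        sorted(gene_p.items()), columns=["gene", "p"]
    ).to_csv(outdir / "biomarker_gene_p.tsv", sep="\t", index=False)
    logger.info("biomarker: %d probes, %d genes", len(biomarker.probe_ids), len(genes))


def _stage_walk(config: PipelineConfig, outdir: Path, seed: int) -> None:
    network = nio.read_network(config.network_path or outdir / "network.sif")
    gene_p = pd.read_csv(outdir / "biomarker_gene_p.tsv", sep="\t")
    scores = nw.assign_node_scores(
        network, dict(zip(gene_p["gene"], gene_p["p"]))
    )
    table = nw.edge_scores(network, scores, restart_prob=config.restart_prob)
    table.to_csv(outdir / "edge_scores.tsv", sep="\t", index=False, float_format="%.10g")
    if config.threshold == "auto":
        thr, obvious = nw.detect_threshold(table["score"].to_numpy())
        if not obvious:
            logger.warning("no obvious score step; top-k fallback threshold used")
    else:
        thr = float(config.threshold)
    sub = nw.extract_subnetwork(network, table, thr)
    g = type(network)()
    g.add_edges_from([(u, v) for u, v, _ in sub.edges])
    nio.write_sif(g, outdir / "subnetwork.sif")
    nio.write_gene_list(sub.genes, outdir / "subnetwork_genes.txt")
    with open(outdir / "walk_summary.json", "w") as fh:
        json.dump(
            {
                "threshold": thr,
                "n_edges": len(sub.edges),
                "n_genes": len(sub.genes),
                "component_sizes": [len(c) for c in sub.components],
            },
            fh, indent=2,
        )
    logger.info("subnetwork: %d edges above %.3f, %d genes", len(sub.edges), thr, len(sub.genes))


def _stage_enrich(config: PipelineConfig, outdir: Path, seed: int) -> None:
    network = nio.read_network(config.network_path or outdir / "network.sif")
    collection = nio.read_gmt(
        config.gmt_path or outdir / "gene_sets.gmt", universe=set(network.nodes)
    )
    query = nio.read_gene_list(outdir / "subnetwork_genes.txt")
    result = enr.ora(query, collection, fdr_threshold=config.fdr_enrichment)
    result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info("enrichment: %d/%d sets significant", int(result["significant"].sum()), len(result))


def _stage_epistasis(config: PipelineConfig, outdir: Path, seed: int) -> None:
    coh1 = nio.read_cohort(config.cohort1_dir or outdir / "cohort1", "cohort1")
    coh2 = nio.read_cohort(config.cohort2_dir or outdir / "cohort2", "cohort2")
    boundaries = nio.read_boundaries(config.boundaries_path or outdir / "boundaries.tsv")

    metas = []
    results = []
    for coh in (coh1, coh2):
        filt, report = epi.qc(
            coh, snp_call=config.snp_call, maf=config.maf,
            sample_call=config.sample_call,
        )
        coords = epi.mds_covariates(filt, n_axes=config.mds_axes)
        res = epi.interaction_scan(filt, coords)
        results.append(res)
        metas.append(filt)
        res.to_csv(outdir / f"{coh.name}_interaction.tsv", sep="\t", float_format="%.6g")

    meta = epi.meta_analyze(
        results[0], results[1],
        n1=metas[0].n_samples, n2=metas[1].n_samples,
        genomic_control=config.genomic_control,
        snp_meta1=metas[0].snp_meta, snp_meta2=metas[1].snp_meta,
    )
    meta = epi.direction_filter(meta)
    snp_to_gene = epi.map_snps_to_genes(
        metas[0].snp_meta.loc[[s for s in meta.index]], boundaries
    )
    meta = meta[meta.index.isin(snp_to_gene)]
    fdr = epi.fdr_qvalues(meta["p_meta"], threshold=config.fdr_epistasis)
    meta = meta.assign(
        q=fdr["q"].to_numpy(),
        significant=fdr["significant"].to_numpy(),
        gene=[";".join(snp_to_gene[s]) for s in meta.index],
    )
    snp_meta = metas[0].snp_meta
    table = pd.DataFrame(
        {
            "gene": meta["gene"],
            "snp": meta.index,
            "chrom": snp_meta.loc[meta.index, "chrom"],
            "pos": snp_meta.loc[meta.index, "pos"],
            "a1": snp_meta.loc[meta.index, "a1"],
            "a2": snp_meta.loc[meta.index, "a2"],
            "n": meta["n_total"],
            "z": meta["z_meta"],
            "direction": meta["direction"],
            "p": meta["p_meta"],
            "q": meta["q"],
            "significant": meta["significant"],
        }
    ).sort_values("p")
    table.to_csv(outdir / "epistasis_meta.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info(
        "epistasis: %d SNPs analyzed, %d significant at q<%g",
        len(table), int(table["significant"].sum()), config.fdr_epistasis,
    )


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "biomarker": _stage_biomarker,
    "walk": _stage_walk,
    "enrich": _stage_enrich,
    "epistasis": _stage_epistasis,
}
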