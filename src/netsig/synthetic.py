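"""Synthetic fixtures with the statistical structure the pipeline assumes.

Four generators cover the pipeline end to end: a two-group expression
matrix with a planted set of discriminative probes (microarray-like
Gaussian log-abundances, or an RNA-seq-like negative-binomial variant);
a scale-free interaction network containing a planted connected module
that overlaps the informative genes; gene-set collections with one set
drawn mostly from that module; and a pair of genotype cohorts with
planted APOE x SNP interaction effects on age-at-onset plus mild
two-subpopulation structure.

Defaults mirror the study conditions the pipeline was designed around:
43 vs 34 samples per expression group (APOE33 vs APOE44 Alzheimer's
carriers), additive APOE4 effects on age-at-onset, and 1% missing
genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .epistasis import GenotypeCohort
from .signature import ExpressionDataset

__all__ = [
    "ExprSimConfig",
    "NetSimConfig",
    "GenoSimConfig",
    "simulate_expression",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_cohorts",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    """Two-group expression simulation settings.

    ``effect_size`` is the standardized between-group mean shift of the
    informative probes (in units of ``noise_sd``); default group sizes
    43/34 match the APOE33/APOE44 splits of a typical cortical
    microarray study.
    """

    n_probes: int = 1000
    n_samples_per_group: tuple[int, int] = (43, 34)
    n_informative: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    probes_per_gene: float = 1.06
    modality: str = "microarray"  # or "rnaseq"
    nb_dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative exceeds n_probes")
        if min(self.n_samples_per_group) < 2:
            raise ValueError("both group sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.modality not in ("microarray", "rnaseq"):
            raise ValueError("modality must be 'microarray' or 'rnaseq'")


@dataclass(frozen=True)
class NetSimConfig:
    """Scale-free network simulation with a planted connected module."""

    n_genes: int = 500
    attachment_parameter: int = 2
    planted_module_size: int = 50
    planted_overlap: float = 0.8
    module_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than the network")
        if not (0 <= self.planted_overlap <= 1):
            raise ValueError("planted_overlap must be in [0, 1]")
        if self.attachment_parameter < 1:
            raise ValueError("attachment_parameter must be >= 1")
        if not (0 <= self.module_density <= 1):
            raise ValueError("module_density must be in [0, 1]")


@dataclass(frozen=True)
class GenoSimConfig:
    """One genotype cohort with planted APOE x SNP interactions.

    Age-at-onset is generated as
    ``aao_mean + b_apoe*APOE4 + b_snp*dosage + beta_interaction*(APOE4*dosage)
    + structure offset + N(0, aao_sd)``; the structure term shifts one of
    two latent subpopulations by ``structure_strength`` years, and the
    same parameter controls allele-frequency divergence between the
    subpopulations.
    """

    n_samples: int = 600
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_interacting: int = 5
    beta_interaction: float = 0.8
    b_apoe: float = -2.5
    b_snp: float = 0.0
    aao_mean: float = 75.0
    aao_sd: float = 3.0
    structure_strength: float = 0.0
    missing_rate: float = 0.01
    apoe_probs: tuple[float, float, float] = (0.30, 0.47, 0.23)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interacting > self.n_snps:
            raise ValueError("n_interacting exceeds n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.structure_strength < 0:
            raise ValueError("structure_strength must be nonnegative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _probe_gene_map(n_probes: int, probes_per_gene: float) -> dict[str, str]:
    """Many-to-one probe -> gene map (a few genes carry two probes)."""
    n_genes = max(1, int(round(n_probes / probes_per_gene)))
    probes = [f"PRB{i:05d}" for i in range(n_probes)]
    return {p: f"GENE{i % n_genes:05d}" for i, p in enumerate(probes)}


def simulate_expression(cfg: ExprSimConfig) -> ExpressionDataset:
    """Two-group expression matrix with planted discriminative probes.

    The first ``n_informative`` probes receive a between-group mean
    difference of exactly ``effect_size * noise_sd``, alternating in
    sign so that signatures gain both top and bottom markers.  The
    microarray modality draws Gaussian log-scale abundances; the
    RNA-seq modality draws negative-binomial counts around the same
    log2 means and returns log2(count + 1).
    """
    rng = np.random.default_rng(cfg.seed)
    g1, g2 = cfg.n_samples_per_group
    n = g1 + g2
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    means = np.tile(base[:, None], (1, n))
    shift = cfg.effect_size * cfg.noise_sd
    signs = np.where(np.arange(cfg.n_informative) % 2 == 0, 1.0, -1.0)
    means[: cfg.n_informative, g1:] += signs[:, None] * shift

    if cfg.modality == "microarray":
        x = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    else:
        mu = np.maximum(2.0**means, 1e-6)
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        x = np.log2(counts + 1.0)

    probe_map = _probe_gene_map(cfg.n_probes, cfg.probes_per_gene)
    probes = list(probe_map)
    return ExpressionDataset(
        abundance=x,
        probe_ids=probes,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        group_labels=["APOE33"] * g1 + ["APOE44"] * g2,
        probe_to_gene=probe_map,
    )


def informative_probes(cfg: ExprSimConfig) -> list[str]:
    """Ids of the probes that carry the planted shift."""
    probe_map = _probe_gene_map(cfg.n_probes, cfg.probes_per_gene)
    return list(probe_map)[: cfg.n_informative]


def informative_genes(cfg: ExprSimConfig) -> list[str]:
    """Genes of the planted probes, deduplicated, order-preserving."""
    probe_map = _probe_gene_map(cfg.n_probes, cfg.probes_per_gene)
    seen: dict[str, None] = {}
    for p in informative_probes(cfg):
        seen.setdefault(probe_map[p], None)
    return list(seen)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def simulate_network(
    cfg: NetSimConfig, informative: list[str]
) -> tuple[nx.Graph, list[str]]:
    """Scale-free gene network with a planted connected module.

    Builds a Barabasi-Albert graph, selects a connected module of
    ``planted_module_size`` nodes by breadth-first growth from a random
    seed node, wires the module up to an internal edge density of
    ``module_density`` (functional modules in interaction networks are
    far denser than the scale-free background), and labels
    ``round(planted_overlap * len(informative))`` module nodes with
    informative gene symbols; remaining informative genes land outside
    the module and every other node gets a background symbol.  Returns
    ``(graph, module_gene_list)``.
    """
    if not informative:
        raise ValueError("informative gene list must be nonempty")
    n_in_module = int(round(cfg.planted_overlap * len(informative)))
    if n_in_module > cfg.planted_module_size:
        raise ValueError("module too small for the requested overlap")
    if len(informative) > cfg.n_genes:
        raise ValueError("more informative genes than network nodes")

    rng = np.random.default_rng(cfg.seed)
    g = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attachment_parameter,
        seed=np.random.RandomState(rng.integers(2**31 - 1)),
    )
    # grow a connected module by BFS from a random node
    start = int(rng.integers(cfg.n_genes))
    module_nodes: list[int] = []
    for node in nx.bfs_tree(g, start):
        module_nodes.append(node)
        if len(module_nodes) == cfg.planted_module_size:
            break

    # densify the module's internal wiring to the configured density
    k = len(module_nodes)
    mod_set = set(module_nodes)
    target = int(cfg.module_density * k * (k - 1) / 2)
    internal = sum(1 for u, v in g.edges if u in mod_set and v in mod_set)
    guard = 0
    while internal < target and guard < 100 * target + 1000:
        u, v = rng.choice(module_nodes, size=2, replace=False)
        guard += 1
        if not g.has_edge(u, v):
            g.add_edge(int(u), int(v))
            internal += 1

    in_module = list(rng.choice(module_nodes, size=n_in_module, replace=False))
    outside_pool = [v for v in g.nodes if v not in set(module_nodes)]
    n_outside = len(informative) - n_in_module
    outside = list(rng.choice(outside_pool, size=n_outside, replace=False))

    labels: dict[int, str] = {}
    inf_iter = iter(informative)
    for v in in_module + outside:
        labels[v] = next(inf_iter)
    bkg = 0
    for v in g.nodes:
        if v not in labels:
            labels[v] = f"BKG{bkg:05d}"
            bkg += 1
    g = nx.relabel_nodes(g, labels)
    module_genes = sorted(labels[v] for v in module_nodes)
    return g, module_genes


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    network: nx.Graph,
    module: list[str],
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (15, 50),
    seed: int = 0,
    true_module_fraction: float = 0.9,
) -> GeneSetCollection:
    """Gene sets over the network's gene universe.

    The first set (``SET_TRUE``) draws ``true_module_fraction`` of its
    members from the planted module; the rest are uniform draws from
    the universe.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    universe = sorted(network.nodes)
    module = [m for m in module if m in set(universe)]
    lo, hi = set_size_range
    sets: dict[str, set[str]] = {}

    size = int(rng.integers(lo, hi + 1))
    n_mod = min(int(round(true_module_fraction * size)), len(module))
    members = set(rng.choice(module, size=n_mod, replace=False))
    others = [u for u in universe if u not in members]
    members |= set(rng.choice(others, size=size - n_mod, replace=False))
    sets["SET_TRUE"] = members

    for i in range(1, n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET{i:03d}"] = set(rng.choice(universe, size=size, replace=False))
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# Genotype cohorts
# ---------------------------------------------------------------------------

def _one_cohort(
    cfg: GenoSimConfig,
    snp_ids: list[str],
    mafs: np.ndarray,
    interacting: list[str],
    snp_meta: pd.DataFrame,
    name: str,
) -> GenotypeCohort:
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, len(snp_ids)
    subpop = rng.integers(2, size=n)

    # allele-frequency divergence between the two latent subpopulations
    delta = cfg.structure_strength * 0.1 * np.sqrt(mafs * (1 - mafs))
    freq = np.empty((n, m))
    freq[subpop == 0] = np.clip(mafs - delta, 0.01, 0.99)
    freq[subpop == 1] = np.clip(mafs + delta, 0.01, 0.99)
    dosage = rng.binomial(2, freq).astype(float)

    apoe = rng.choice([0, 1, 2], size=n, p=cfg.apoe_probs).astype(float)
    aao = np.full(n, cfg.aao_mean) + cfg.b_apoe * apoe
    aao += cfg.structure_strength * (subpop - 0.5)
    inter_ix = [snp_ids.index(s) for s in interacting]
    for j in inter_ix:
        aao += cfg.b_snp * dosage[:, j]
        aao += cfg.beta_interaction * apoe * dosage[:, j]
    aao += rng.normal(0.0, cfg.aao_sd, size=n)

    if cfg.missing_rate > 0:
        mask = rng.random(size=dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    samples = [f"{name}_{i:04d}" for i in range(n)]
    return GenotypeCohort(
        dosage=pd.DataFrame(dosage, index=samples, columns=snp_ids),
        snp_meta=snp_meta.loc[snp_ids].copy(),
        pheno=pd.DataFrame({"aao": aao, "apoe4": apoe.astype(int)}, index=samples),
        name=name,
    )


def simulate_cohorts(
    cfg1: GenoSimConfig,
    cfg2: GenoSimConfig,
    shared_snps: int | None = None,
    gene_map: dict[str, tuple[str, int]] | None = None,
) -> tuple[GenotypeCohort, GenotypeCohort, list[str]]:
    """Two genotype cohorts sharing SNPs and planted interaction effects.

    The first ``shared_snps`` SNP ids (default: all of the smaller
    panel) are common to both cohorts, with per-SNP MAFs drawn once
    from ``cfg1.maf_range`` so the cohorts agree on allele frequency in
    expectation; the planted interacting SNPs are among the shared ones
    and carry the same interaction sign in both cohorts.  Returns
    ``(cohort1, cohort2, interacting_snp_ids)``.
    """
    min_snps = min(cfg1.n_snps, cfg2.n_snps)
    if shared_snps is None:
        shared_snps = min_snps
    if shared_snps > min_snps:
        raise ValueError("shared_snps exceeds a cohort's SNP count")
    n_int = max(cfg1.n_interacting, cfg2.n_interacting)
    if n_int > shared_snps:
        raise ValueError("interacting SNPs must be among the shared SNPs")
    if np.sign(cfg1.beta_interaction) != np.sign(cfg2.beta_interaction):
        raise ValueError("planted interaction sign must agree between cohorts")

    rng = np.random.default_rng(cfg1.seed * 2**16 + cfg2.seed + 17)
    total = cfg1.n_snps + cfg2.n_snps - shared_snps
    snp_ids = [f"rs{100000 + i}" for i in range(total)]
    shared = snp_ids[:shared_snps]
    cut = shared_snps + (cfg1.n_snps - shared_snps)
    ids1 = shared + snp_ids[shared_snps:cut]
    ids2 = shared + snp_ids[cut:total]
    lo, hi = cfg1.maf_range
    mafs = pd.Series(rng.uniform(lo, hi, size=total), index=snp_ids)
    interacting = list(rng.choice(shared, size=n_int, replace=False))

    chrom = rng.integers(1, 23, size=total).astype(str)
    pos = rng.integers(1, 2_000_000_00, size=total)
    alleles = rng.choice(["A", "C", "G", "T"], size=(total, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snp_meta = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "a1": alleles[:, 0], "a2": alleles[:, 1]},
        index=snp_ids,
    )
    if gene_map:
        for s, (c, p) in gene_map.items():
            if s in snp_meta.index:
                snp_meta.loc[s, ["chrom", "pos"]] = [c, p]

    c1 = _one_cohort(
        cfg1, ids1, mafs.loc[ids1].to_numpy(),
        [s for s in interacting if s in set(ids1)][: cfg1.n_interacting],
        snp_meta, "cohort1",
    )
    c2 = _one_cohort(
        cfg2, ids2, mafs.loc[ids2].to_numpy(),
        [s for s in interacting if s in set(ids2)][: cfg2.n_interacting],
        snp_meta, "cohort2",
    )
    return c1, c2, sorted(interacting)
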