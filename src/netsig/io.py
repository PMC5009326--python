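"""Readers and writers for the pipeline's text formats.

Everything is plain TSV (plus GMT and SIF) so every intermediate is
inspectable; schema violations raise errors that name the file, line
and column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .epistasis import GeneBoundaries, GenotypeCohort
from .signature import Biomarker, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_network", "write_sif",
    "read_cohort", "write_cohort",
    "read_boundaries", "write_boundaries",
    "write_gene_list", "read_gene_list",
]


class FormatError(ValueError):
    """Schema violation in an input file, with file/line context."""


def _with_ext(prefix: "str | Path", ext: str) -> "Path":
    return Path(str(prefix) + ext)


# ---------------------------------------------------------------------------
# Expression + labels + probe map
# ---------------------------------------------------------------------------

def write_expression(ds: ExpressionDataset, prefix: str | Path) -> None:
    """Write `<prefix>.expr.tsv`, `<prefix>.labels.tsv`, `<prefix>.probes.tsv`.

    The expression file has probes as rows and sample ids as header.
    """
    prefix = Path(prefix)
    pd.DataFrame(
        ds.abundance, index=pd.Index(ds.probe_ids, name="probe_id"),
        columns=ds.sample_ids,
    ).to_csv(_with_ext(prefix, ".expr.tsv"), sep="\t", float_format="%.10g")
    pd.DataFrame(
        {"sample_id": ds.sample_ids, "group": ds.group_labels}
    ).to_csv(_with_ext(prefix, ".labels.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"probe_id": list(ds.probe_to_gene), "gene": list(ds.probe_to_gene.values())}
    ).to_csv(_with_ext(prefix, ".probes.tsv"), sep="\t", index=False)


def read_expression(prefix: str | Path) -> ExpressionDataset:
    """Read the triple written by :func:`write_expression`."""
    prefix = Path(prefix)
    expr_path = _with_ext(prefix, ".expr.tsv")
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    bad = expr.columns[expr.isna().any(axis=0)]
    if len(bad):
        raise FormatError(f"{expr_path}: non-numeric or missing values in column {bad[0]!r}")
    labels = pd.read_csv(_with_ext(prefix, ".labels.tsv"), sep="\t")
    _require(labels, ["sample_id", "group"], _with_ext(prefix, ".labels.tsv"))
    probes = pd.read_csv(_with_ext(prefix, ".probes.tsv"), sep="\t")
    _require(probes, ["probe_id", "gene"], _with_ext(prefix, ".probes.tsv"))
    label_map = dict(zip(labels["sample_id"], labels["group"]))
    missing = [s for s in expr.columns if s not in label_map]
    if missing:
        raise FormatError(
            f"{_with_ext(prefix, '.labels.tsv')}: no group label for sample {missing[0]!r}"
        )
    return ExpressionDataset(
        abundance=expr.to_numpy(dtype=float),
        probe_ids=[str(p) for p in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        group_labels=[str(label_map[s]) for s in expr.columns],
        probe_to_gene=dict(zip(probes["probe_id"].astype(str), probes["gene"].astype(str))),
    )


def _require(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...).

    Duplicate genes within a line are deduplicated with a warning.  If
    ``universe`` is not given, the union of all sets is used.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], parts[2:]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, ln, name)
            sets[name] = set(genes)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, "na"] + genes) + "\n")


# ---------------------------------------------------------------------------
# Networks: SIF and 2-column edge lists
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> nx.Graph:
    """Read a SIF (`a <tab> relation <tab> b`) or 2-column edge list.

    Self-loops and duplicate edges are dropped with a warning.
    """
    path = Path(path)
    g = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                a, _, b = parts
            elif len(parts) == 2:
                a, b = parts
            else:
                raise FormatError(f"{path}:{ln}: expected 2 (edge list) or 3 (SIF) columns")
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
    if dropped:
        logger.warning("%s: %d self-loops dropped", path, dropped)
    return g


def write_sif(network: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


# ---------------------------------------------------------------------------
# Genotype cohorts
# ---------------------------------------------------------------------------

def write_cohort(cohort: GenotypeCohort, outdir: str | Path) -> None:
    """Write `dosage.tsv`, `snps.tsv`, `pheno.tsv` into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.dosage.rename_axis("sample_id").to_csv(
        outdir / "dosage.tsv", sep="\t", float_format="%g", na_rep="NA"
    )
    cohort.snp_meta.rename_axis("snp_id").to_csv(outdir / "snps.tsv", sep="\t")
    cohort.pheno.rename_axis("sample_id").to_csv(outdir / "pheno.tsv", sep="\t")


def read_cohort(indir: str | Path, name: str | None = None) -> GenotypeCohort:
    """Read the triple written by :func:`write_cohort`, validating dosages."""
    indir = Path(indir)
    dosage_path = indir / "dosage.tsv"
    dosage = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"])
    vals = dosage.to_numpy()
    try:
        vals = vals.astype(float)
    except (TypeError, ValueError):
        vals = None
    if vals is not None:
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    else:
        ok = None
    if ok is None or not ok.all():
        # locate the first offender for a line/column-precise message
        for i, row in enumerate(dosage.itertuples(index=False)):
            for j, v in enumerate(row):
                if pd.isna(v):
                    continue
                try:
                    f = float(v)
                except (TypeError, ValueError):
                    f = None
                if f not in (0.0, 1.0, 2.0):
                    raise FormatError(
                        f"{dosage_path}: line {i + 2}, column {dosage.columns[j]!r}: "
                        f"invalid dosage value {v!r} (expected 0, 1, 2 or NA)"
                    )
    snps = pd.read_csv(indir / "snps.tsv", sep="\t", index_col=0)
    _require(snps.reset_index(), ["snp_id", "chrom", "pos", "a1", "a2"], indir / "snps.tsv")
    pheno = pd.read_csv(indir / "pheno.tsv", sep="\t", index_col=0)
    _require(pheno.reset_index(), ["sample_id", "aao", "apoe4"], indir / "pheno.tsv")
    snps["chrom"] = snps["chrom"].astype(str)
    return GenotypeCohort(
        dosage=dosage.astype(float), snp_meta=snps, pheno=pheno,
        name=name or indir.name,
    )


# ---------------------------------------------------------------------------
# Gene boundaries and plain gene lists
# ---------------------------------------------------------------------------

def read_boundaries(path: str | Path) -> list[GeneBoundaries]:
    """Read a gene-boundary TSV (gene, chrom, start, end; 1-based inclusive)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene", "chrom", "start", "end"], path)
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                GeneBoundaries(
                    gene=str(row.gene), chrom=str(row.chrom),
                    start=int(row.start), end=int(row.end),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


def write_boundaries(boundaries: list[GeneBoundaries], path: str | Path) -> None:
    pd.DataFrame(
        [(b.gene, b.chrom, b.start, b.end) for b in boundaries],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_biomarker(biomarker: Biomarker, path: str | Path) -> None:
    """Biomarker probes with genes and filter p-values as TSV."""
    rows = sorted(
        (p, biomarker.filter_pvalues.get(p, np.nan)) for p in biomarker.probe_ids
    )
    pd.DataFrame(rows, columns=["probe_id", "filter_p"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
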