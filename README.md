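# netsig

Integrative transcriptomic–genomic analysis of APOE ε4-associated
Alzheimer's disease, built as a reusable, fully tested Python package:

1. **Rank-based signature classification** — each subject's expression
   profile is reduced to an ordered signature of its `n1` top- and `n2`
   bottom-ranked probes (after a Wilcoxon rank-sum pre-filter).
   Subjects are compared by a distance built from weighted
   Kolmogorov–Smirnov enrichment scores of each signature against the
   other subject's full ranking, and classified (APOE33 vs APOE44
   carriers) by the nearest-group rule on mean distance.  A genetic
   algorithm tunes `(n1, n2, α_filter)` for cross-validated accuracy
   with a parsimony penalty; the union of all per-sample signatures is
   the transcriptional biomarker.
2. **Random-walk network expansion** — biomarker genes seed a random
   walk with restart over a protein-interaction network, with restart
   mass −log₂(p) from the filter.  Edges are scored by the log₂ ratio
   of the walk's stationary flux to a uniform-restart baseline, a step
   detected in the sorted edge scores sets the retention threshold, and
   the retained edges induce the expanded disease subnetwork.
3. **Over-representation analysis** — hypergeometric tail tests of the
   subnetwork genes against GMT gene-set collections with
   Benjamini–Hochberg control (default FDR 0.001), plus the classic
   fold-change ≥ 1.5 / p < 0.02 differential-expression filter.
4. **APOE × SNP epistasis scan** — in two genotyped cohorts, per SNP:
   `AAO ~ APOE4count + dosage + APOE4count·dosage + MDS1..3` after
   call-rate/MAF/autosome QC, where AAO is the age at disease onset.
   Studies are combined by a sample-size-weighted Z meta-analysis with
   per-study genomic control; direction-concordant SNPs are mapped to
   genes by physical position and FDR-adjusted (q < 0.05).

A synthetic-data module generates every input with the planted
structure the method assumes (discriminative probes, a dense module in
a scale-free network, enriched gene sets, cohorts with planted
interaction effects and mild population structure), so the entire
workflow runs and is testable offline.

## Worked example

```python
from netsig import (
    ClassifierParams, ExprSimConfig, NetSimConfig, cross_validate,
    simulate_expression,
)
from netsig.signature import extract_biomarker, fit_signatures
from netsig.synthetic import informative_genes, simulate_network
from netsig.netwalk import (
    assign_node_scores, detect_threshold, edge_scores, extract_subnetwork,
)

cfg = ExprSimConfig(effect_size=2.0, seed=7)   # 43 vs 34 subjects
ds = simulate_expression(cfg)

params = ClassifierParams(n1=10, n2=10, alpha_filter=0.01)
report = cross_validate(ds, params, n_folds=10, seed=7)
print(f"CV accuracy {report.accuracy:.3f} "
      f"(precision {report.precision:.3f}, recall {report.recall:.3f})")

sigs, pmap, _ = fit_signatures(ds, params)
bm = extract_biomarker(sigs, ds.probe_to_gene, pmap)
print(f"biomarker: {len(bm.probe_ids)} probes, {len(bm.gene_symbols)} genes")

gene_p = {}
for probe in bm.probe_ids:
    g = ds.probe_to_gene[probe]
    gene_p[g] = min(bm.filter_pvalues.get(probe, 1.0), gene_p.get(g, 1.0))
network, module = simulate_network(NetSimConfig(seed=107), informative_genes(cfg))
scores = assign_node_scores(network, gene_p)
table = edge_scores(network, scores, restart_prob=0.5)
threshold, obvious = detect_threshold(table["score"].to_numpy())
sub = extract_subnetwork(network, table, threshold)
overlap = len(set(sub.genes) & set(module)) / len(set(sub.genes) | set(module))
print(f"subnetwork: {len(sub.edges)} edges, {len(sub.genes)} genes, "
      f"Jaccard vs planted module {overlap:.2f}")
```

Output:

```
CV accuracy 1.000 (precision 1.000, recall 1.000)
biomarker: 59 probes, 58 genes
subnetwork: 47 edges, 27 genes, Jaccard vs planted module 0.54
```

The classifier separates the two APOE groups perfectly at a planted
standardized effect of 2, the biomarker collects the probes used in at
least one signature, and the walk recovers most of the planted module
(Jaccard 0.54 in this draw; 0.60 averaged over seeds) from the biomarker seeds.

The same workflow is available from the shell:

```bash
netsig run --config config.yaml --outdir results/ --seed 7
```

which executes simulate → classify → biomarker → walk → enrich →
epistasis, writing TSV/SIF/GMT intermediates and a run manifest with
seeds and checksums.

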