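# digitalmicrobe

Versioned, gene-referenced data packages for microbial genomes and
pangenomes — and the analyses that run on them.

## The problem

Collaborative microbiology teams accumulate heterogeneous data around a
shared reference genome: curated gene calls, multi-source functional
annotations (COG, KOfam, Pfam, CAZyme, experimental curations), transcript
coverage from dozens of samples, proteome abundances, mutant inventories,
fitness scores, trees. Without a shared container these layers drift apart:
gene identifiers diverge, intermediate products are recomputed, and nobody
can tell which annotation version an analysis used.

`digitalmicrobe` implements a *digital microbe*: a self-contained,
self-describing data package anchored on a genome (or a pangenome of many
genomes), iteratively populated with checksummed data layers referenced to
individual genes. Every layer addition bumps a MAJOR.MINOR version and
appends a changelog entry; the whole package round-trips through a
universal-format export (JSON manifest + TSV/FASTA/newick) and a single
queryable SQLite file, so any group can verify, extend, and republish it.

## What the library computes

* **Expression meta-analysis** — per-sample TPM
  (`TPM_g = rate_g / Σ_h rate_h × 10⁶`, with `rate_g = count_g / length_g`
  or mean coverage), proportional expression over a gene collection
  (each gene's share of the collection total per sample), Euclidean/Ward
  clustering for heatmap display, and two-sided t-tests between sample
  groups with Benjamini–Hochberg q-values.
* **Proteomics** — normalized spectral abundance factors,
  `NSAF_p = (SpC_p/L_p) / Σ_i (SpC_i/L_i)`, summing to 1 per proteome.
* **Pangenomics** — all-vs-all protein similarity with *minbit* filtering
  (`minbit = s_ab / min(s_aa, s_bb)`, threshold 0.5), Markov clustering
  (inflation 2.0) into gene clusters, presence/absence matrices, consensus
  annotations, and fragment-based ANI (1,020-bp windows, both strands).
* **Completeness-aware core-genome classification** — a Bayesian
  likelihood-ratio label per cluster. With presence `x_gi` and genome
  completeness `c_i`:

      LL_core(g) = Σ_{x=1} ln c_i + Σ_{x=0} ln(1 − c_i)
      LL_acc(g)  = Σ_{x=1} ln p_i + Σ_{x=0} ln(1 − p_i),
      p_i = 1 − (1 − 1/G_acc)^{n_i}

  iterated to a fixed point; a cluster is core iff `LL_core − LL_acc > 0`.
  This lets a cluster missing only from incomplete MAGs still be called core.
* **CAZyme profiling** — per-genome counts by category (GH, GT, PL, CE, AA,
  CBM), normalized by the per-category maximum across genomes for
  clade-level comparison alongside a phylogeny.
* **Phylogeny utilities** — single-copy-core supermatrix concatenation with
  a partition table, newick I/O, deterministic midpoint rooting, and
  Robinson–Foulds topology distance.

Everything is testable without downloads: `digitalmicrobe.synthetic`
generates every input class (genomes with gene calls and annotations,
coverage samples, protein families, presence matrices with known
core/accessory truth) deterministically from a seed.

## Worked example

```python
import numpy as np, pandas as pd
import digitalmicrobe as dm
from digitalmicrobe import synthetic

spec = synthetic.FixtureSpec(seed=1)
sim = synthetic.simulate_genome(spec)
paths = sim.write("fixture")

pkg = dm.create_package("toy", "genome")
dm.add_genome(pkg, paths["fasta"])
dm.import_gene_calls(pkg, paths["gene_calls"], format="external_tsv")
dm.import_functional_annotations(pkg, paths["annotations_custom"], "custom")
print(dm.genome_stats(pkg))
# {'total_length': 25000, 'gc_fraction': 0.64076, 'num_genes': 30,
#  'genes_per_kbp': 1.2}

lengths = (sim.gene_calls["stop"] - sim.gene_calls["start"]).to_numpy(float)
for sid, t in synthetic.simulate_coverage_samples(spec, np.ones(30), lengths).items():
    dm.add_coverage_layer(pkg, sid, t, total_mapped_reads=spec.library_size)
tpm = dm.tpm_matrix(pkg)
print(tpm.sum(axis=1).round(3).tolist()[:2])   # [1000000.0, 1000000.0]
print(pkg.manifest.version)                    # '1.6' (1.0 + 2 annots + 4 samples)
```

The genome stats say the toy genome is 25 kb at 64.1% GC with 30 genes
(1.2 genes per kbp); each coverage layer's TPM row sums to exactly one
million, and the six registered layers have bumped the package from 1.0 to
1.6. A pangenome in three lines:

```python
genomes = synthetic.simulate_protein_families(1, n_genomes=3, n_shared=5, n_unique=2)
store = dm.build_pangenome(genomes)
print(len(store.clusters))   # 11  (5 shared triads + 6 singletons)
labels = dm.classify_pangenome(store)
```

## Command line

A `dm` console script wraps the library: `dm create/info/verify/export/import`,
`dm genes import`, `dm functions import`, `dm stats`, `dm profile add`,
`dm misc import`, `dm collection define|summarize`, `dm pan
build|ani|core|summarize`, `dm expr proportional|cluster|test`, `dm cazyme
count|normalize`, `dm phylo concat|root|attach|rf`, `dm fixtures make`.
Exit codes: 0 success, 1 domain error, 2 usage error.

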