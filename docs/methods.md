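# Methods

This note documents the models, numerical choices and limitations behind
`digitalmicrobe`, in the spirit of the methods documentation shipped with
statistical genetics and genomics packages.

## The package container

A package is a manifest plus a set of *layers*. The manifest carries a
two-component MAJOR.MINOR version: registering a layer (additive) bumps
MINOR; removing one (destructive) bumps MAJOR and resets MINOR. This gives
public version numbers additive/destructive semantics while staying
compatible with the plain "5.0"-style numbering used by data repositories.
The DOI field is metadata only — no registration network calls are made.

Checksums are SHA-256 over a canonical serialization: tabular layers are
rendered as UTF-8 TSV with the frame's column order and rows sorted
lexicographically by their serialized form; sequence sets as `>id` blocks
sorted by id; trees as the newick text itself. Row sorting makes the digest
independent of row order, so a re-imported table with permuted rows still
verifies. Floats are serialized with Python's shortest round-tripping
repr, and TSV reads use round-trip float parsing — pandas' default float
formatting and parsing are both lossy at the last digit and would break
checksum identity across an export/import cycle.

Two persistence forms exist: a single SQLite file (named tables, queryable
without loading everything) and a universal-format export directory (JSON
manifest, one TSV per tabular layer, FASTA for sequences, newick for
trees). Export∘import is the identity on the manifest and on every layer
checksum; import verifies every digest and aborts naming the first
offending layer.

## Genome spine

Internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted at the I/O boundary in both directions. Gene ids
are dense integers assigned in file order at import and stable thereafter —
every layer keys on them. Annotation sources are kept side by side and
never merged; re-importing a source without `overwrite` appends only new
(gene, accession) pairs, making imports idempotent. GC content is computed
over informative bases only (N excluded from numerator and denominator).

## Normalizations

**TPM.** `TPM_g = rate_g / Σ_h rate_h × 10⁶`. Two rate modes are provided
because count-based and coverage-based pipelines differ in where the length
normalization happens: `count` divides read counts by gene length;
`coverage` treats mean per-base coverage as an already length-normalized
rate. The mode is recorded in layer provenance. The mapping denominator
(`total_mapped_reads`) is caller-supplied; when absent it defaults to the
column sum with a logged warning. An all-zero sample yields all zeros plus
a warning rather than an exception, so batch processing of sparse sample
sets does not abort.

**NSAF.** `NSAF_p = (SpC_p/L_p) / Σ_i (SpC_i/L_i)`; an all-zero proteome is
an error (no detected proteins means there is nothing to normalize).

**Proportional expression** divides each sample's TPM by its sum over the
collection genes, so rows sum to 1 and any per-sample scaling cancels.
Conservation invariants (TPM → 10⁶ within 1e−6 relative, NSAF → 1 within
1e−9, proportional rows → 1 within 1e−9) are enforced by tests.

## Group contrasts

The default test is the two-sided Student t-test (equal variances), with
Welch available as an option; group order is the lexicographic order of
condition labels, so the sign of t is deterministic and swapping labels
negates it. Two degenerate groups with equal means return (t=0, p=1) by
convention instead of NaN. Raw p-values are the primary column;
Benjamini–Hochberg q-values are emitted alongside because a collection-wide
scan is a multiple-testing situation, but the raw column is what a
per-gene significance mark corresponds to. Display clustering uses
Euclidean distance with Ward linkage via scipy; the output is an ordering
plus a merge tree, never a rendered image — plotting is an export concern.

## Pangenome construction

The pipeline is all-vs-all amino-acid similarity → minbit filter → Markov
clustering. The built-in scorer is Smith–Waterman with BLOSUM62 and
−11/−1 gaps (Biopython `PairwiseAligner`), practical at desk scale;
externally computed search results can be imported as a table instead.
minbit normalizes each pairwise score by the smaller self-score, giving a
[0,1] homology heuristic; edges below 0.5 are dropped. All three knobs
(scorer, threshold, inflation) are exposed.

MCL is a dense numpy implementation: self-loops of weight 1, column
normalization, then alternating expansion (matrix square) and inflation
(elementwise power 2.0, renormalize) until the flow matrix is stable
(max-change < 1e−8, cap 100 iterations). Clusters are the connected
components of the converged matrix at a 1e−6 edge threshold; node order is
sorted, so the result is deterministic. No sparse pruning is applied — at
the intended scale (tens to hundreds of genes) the dense iteration is
exact and fast, and it is what the independent matrix-iteration oracle in
the test suite checks against. Every gene is a node, so genes with no
retained edge become singleton clusters and cluster member counts always
partition the gene set; exports carry an explicit singleton flag because
summary conventions differ on whether singletons are counted.

Consensus annotations take the most frequent accession per source among
member genes, breaking ties lexicographically.

## Average nucleotide identity

ANI is fragment-based: the query genome's contigs are chopped independently
into consecutive 1,020-bp windows (a contig shorter than one window
contributes itself whole; a trailing remainder of a longer contig is
dropped), each window is aligned to the best location on either strand of
the subject genome (edlib infix alignment), windows under 30% identity are
discarded, and ANI is the mean identity of retained windows × 100 with the
retained fraction reported alongside. The measure is asymmetric by
construction and is reported both ways; the matrix diagonal is exactly 100.
Chopping per contig makes the result invariant to contig order.

## Core/accessory classification

The model treats completeness `c_i` as the probability that a truly
present gene was recovered in genome i. For cluster g with binary presence
`x_gi`:

    LL_core(g) = Σ_{x=1} ln c_i + Σ_{x=0} ln(1 − c_i)
    LL_acc(g)  = Σ_{x=1} ln p_i + Σ_{x=0} ln(1 − p_i)

where `p_i = 1 − (1 − 1/G_acc)^{n_i}` is the probability genome i carries
an arbitrary accessory cluster given the current accessory pool size
`G_acc` and the genome's observed accessory repertoire `n_i`. Labels are
initialized to core for clusters present in > 95% of genomes, then
`G_acc`, `n_i`, `p_i` and the labels are recomputed until a fixed point
(cap 50 iterations; in practice 2–3 suffice). Numerical safeguards:
completeness is floored at 0.999 inside the likelihood (ln(1−c) is
undefined at c=1, and the floor is negligible elsewhere), and `p_i` is
clipped to [1e−10, 1−1e−10].

Two regimes anchor the behaviour. With all completeness = 1 the
classification is exact: any cluster present everywhere is core (its core
log-likelihood is ~0 while the accessory model must pay for every
presence) and any absence forces accessory (the core model pays
ln(0.001) ≈ −6.9 per absence, far more than the accessory model's absence
cost). Under MAG-like completeness (0.7–0.95) the simulated-recovery tests
require median core sensitivity ≥ 0.95 with ≤ 5% of accessory clusters
mislabeled core over 20 seeds; observed performance is comfortably inside
both bounds. Exact numerical agreement with any external implementation of
this model family is not claimed: initialization and prior details vary
between implementations, and only the behaviour above is guaranteed.

## CAZyme profiling

The category is the letter prefix of the accession (GH13 → GH); unknown
prefixes go to an "other" bucket with a warning. By default a gene with
hits in several categories counts once per *distinct* category (per-hit
counting is a flag) — this avoids double-counting multi-domain genes
within a category while still crediting each domain type. Normalization
divides each category column by its maximum across genomes, so the
max-attaining genome scores 1.0 and an empty category stays zero without a
division error. Row ordering can follow an attached tree's leaf order for
display beside a phylogeny.

## Phylogeny utilities

The contract deliberately starts at pre-aligned single-copy alignment
blocks and at trees already in newick form: alignment and tree inference
are performed by dedicated external tools and their outputs imported.
Supermatrix concatenation validates single-copy-ness (a genome appearing
twice in a block is an error) and rectangularity, gap-fills genomes absent
from a block with a warning, and emits a RAxML-style partition table.

Midpoint rooting enumerates all leaf pairs (brute force; trees here are
small), takes the longest path, and places the root halfway along it,
splitting the containing edge. Ties between equally long paths (within
1e−9) go to the lexicographically smallest leaf pair, making the operation
deterministic. The result satisfies the minimax property — the maximum
root-to-leaf depth equals half the tree diameter — which the tests verify
against an exhaustive search and against dendropy's independent
implementation.

Robinson–Foulds distance is computed from canonical bipartition sets (the
side not containing the overall-smallest leaf label represents each
split), counting splits present in exactly one tree, normalized by
2(n−3). RF is used as the quantitative proxy for gene-tree versus
core-genome-tree discordance; no significance is attached to any
particular RF value.

## Synthetic data

The generators define the study conditions for all tests. Each generator
draws from its own `default_rng((seed, stream_id))` stream, so adding a
generator never perturbs existing fixtures and the same seed yields
byte-identical files. Defaults: a 25 kb, two-contig genome at 64% GC
(roseobacter-like) with 30 non-overlapping genes (300–900 bp, both
strands), three transporter systems × three components
(substrate-binding / permease / ATPase) as the curated collection, CAZyme
accessions on a third of the remaining genes including one multi-domain
gene; coverage samples are multinomial draws of 10⁵ reads over
rate × length weights; the simulated pangenome has 30 genomes with
completeness ~ Uniform(0.7, 0.95), 200 core clusters present everywhere
and 800 accessory clusters with per-cluster presence probability
~ Uniform(0.05, 0.5), observed through per-genome completeness dropout.

What the generators do **not** emulate: real codon structure and operons,
sequencing error and mapping ambiguity, contamination (contamination is
carried as metadata but not simulated into presence matrices), phylogenetic
correlation among genomes, and batch effects across studies. Passing tests
therefore demonstrate correctness of the computations and recovery under
the stated generative model, not performance on real survey data.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale —
toy genomes of tens of genes, pangenomes of 3–30 genomes, 20-node
clustering graphs, trees of ≤ 8 leaves, 2,000-gene calibration runs —
chosen so the full suite completes in seconds while still exercising every
code path and invariant at sizes where brute-force oracles are exact.

## Known limitations

* The built-in pairwise scorer is quadratic in sequence count; real
  pangenome-scale inputs should import external search results instead.
* BAM ingestion is not implemented; the contract input is a per-gene
  count/coverage table (read mapping is an upstream concern).
* No divergent-fork merging: two independently extended versions of a
  package must be reconciled manually.
* The t-test operates on whichever matrix it is given; the default
  analysis path feeds it proportional values (the displayed quantity), and
  callers wanting TPM-scale tests pass the TPM matrix explicitly.
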