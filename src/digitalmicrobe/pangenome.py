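"""Pangenome construction and completeness-aware core-genome classification.

Pipeline, mirroring the conventional pangenomics workflow:

1. all-vs-all amino-acid similarity between the genes of every genome pair
   (pluggable scorer; the built-in one is Smith-Waterman/BLOSUM62 at desk
   scale, and externally computed search results can be imported instead);
2. *minbit* filtering — each pairwise score is normalized by the smaller of
   the two self-alignment scores, ``minbit = s_ab / min(s_aa, s_bb)``, and
   edges below a threshold (default 0.5) are dropped;
3. Markov clustering (MCL) of the resulting weighted graph into gene
   clusters (default inflation 2.0);
4. per-cluster presence/absence vectors over genomes, consensus annotations,
   and — via :func:`bayesian_pan_core` — a core/accessory label that takes
   each genome's estimated completeness into account, so that a gene cluster
   missing only from incomplete MAGs can still be called core.

Average nucleotide identity (ANI) between genome pairs is fragment-based:
the query genome is chopped into 1,020-bp windows, each window is aligned to
the best location on either strand of the subject genome, windows below a
minimum identity are discarded, and ANI is the mean identity of the retained
windows (in percent). The measure is asymmetric by construction and is
reported both ways.

Core/accessory model
--------------------
For cluster *g* with binary presence x_gi over genomes i with completeness
c_i (the probability that a truly present gene was recovered):

    LL_core(g) = sum_{x=1} ln c_i + sum_{x=0} ln(1 - c_i)
    LL_acc(g)  = sum_{x=1} ln p_i + sum_{x=0} ln(1 - p_i)

where p_i = 1 - (1 - 1/G_acc)^{n_i} is the chance genome i picked up an
arbitrary accessory cluster, given the current accessory pool size G_acc and
the genome's accessory repertoire size n_i. A cluster is core iff the
log-likelihood ratio LL_core - LL_acc is positive. Labels, G_acc and n_i are
iterated to a fixed point from an initial core set of clusters present in
more than 95% of genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import NotFoundError, ValidationError

logger = logging.getLogger(__name__)

NodeKey = tuple[str, str]  # (genome_id, gene_id)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeEntry:
    """One genome in a pangenome: sequences, proteins, quality metadata."""

    genome_id: str
    genome_type: str = "isolate"  # isolate | MAG
    completeness: float = 1.0
    contamination: float = 0.0
    contigs: dict = field(default_factory=dict)  # contig_id -> DNA
    proteins: dict = field(default_factory=dict)  # gene_id -> amino acids
    annotations: Optional[pd.DataFrame] = None  # gene_id, source, accession, function

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 1.0):
            raise ValidationError(
                f"genome {self.genome_id!r}: completeness must be in (0, 1]"
            )
        if self.genome_type not in ("isolate", "MAG"):
            raise ValidationError(f"genome type must be isolate or MAG")


@dataclass
class SimilarityEdge:
    gene_a: NodeKey
    gene_b: NodeKey
    score: float
    self_a: float
    self_b: float

    @property
    def minbit(self) -> float:
        denom = min(self.self_a, self.self_b)
        if denom <= 0:
            return 0.0
        return self.score / denom


@dataclass
class GeneCluster:
    cluster_id: str
    members: set  # of NodeKey
    consensus: dict = field(default_factory=dict)  # source -> (accession, function)
    label: Optional[str] = None  # core | accessory, set by classification
    llr: Optional[float] = None

    def presence(self, genome_ids: Iterable[str]) -> list[int]:
        present = {g for g, _ in self.members}
        return [1 if gid in present else 0 for gid in genome_ids]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


class PangenomeStore:
    """Gene clusters over a genome roster, with ANI matrix and attached tree."""

    def __init__(self, genomes: dict[str, GenomeEntry]):
        self.genomes = genomes
        self.clusters: dict[str, GeneCluster] = {}
        self.ani: Optional[pd.DataFrame] = None
        self.aligned_fraction: Optional[pd.DataFrame] = None
        self.tree: Optional[str] = None  # newick
        self.provenance: list[str] = []

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    def presence_matrix(self) -> pd.DataFrame:
        """Binary clusters x genomes matrix."""
        gids = self.genome_ids
        data = {
            cid: cluster.presence(gids) for cid, cluster in sorted(self.clusters.items())
        }
        return pd.DataFrame(data, index=gids).T

    def clusters_per_genome(self) -> pd.Series:
        pm = self.presence_matrix()
        return pm.sum(axis=0)

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": cid,
                "genome_id": genome,
                "gene_id": gene,
                "singleton": int(cluster.is_singleton),
                "label": cluster.label or "",
            }
            for cid, cluster in sorted(self.clusters.items())
            for genome, gene in sorted(cluster.members)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# similarity graph


def blosum62_scorer() -> Callable[[str, str], float]:
    """Built-in pairwise scorer: Smith-Waterman, BLOSUM62, gap -11/-1."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    def score(a: str, b: str) -> float:
        return float(aligner.score(a, b))

    return score


def compute_similarity_graph(
    genomes: dict[str, GenomeEntry],
    scorer: Callable[[str, str], float] | None = None,
    minbit_threshold: float = 0.5,
) -> list[SimilarityEdge]:
    """All-vs-all protein similarity edges with minbit filtering.

    Edges whose minbit falls below ``minbit_threshold`` are dropped; scorer
    failures on a pair are logged and the pair skipped.
    """
    if scorer is None:
        scorer = blosum62_scorer()
    nodes: list[tuple[NodeKey, str]] = []
    for gid in sorted(genomes):
        entry = genomes[gid]
        if not entry.proteins:
            raise ValidationError(f"genome {gid!r} has no protein sequences")
        for gene_id in sorted(entry.proteins):
            nodes.append(((gid, str(gene_id)), entry.proteins[gene_id]))

    self_scores = {key: scorer(seq, seq) for key, seq in nodes}
    edges: list[SimilarityEdge] = []
    for i in range(len(nodes)):
        key_a, seq_a = nodes[i]
        for j in range(i + 1, len(nodes)):
            key_b, seq_b = nodes[j]
            try:
                s = scorer(seq_a, seq_b)
            except Exception as exc:
                logger.warning("scorer failed on %s vs %s: %s", key_a, key_b, exc)
                continue
            edge = SimilarityEdge(key_a, key_b, max(s, 0.0),
                                  self_scores[key_a], self_scores[key_b])
            if edge.minbit >= minbit_threshold:
                edges.append(edge)
    return edges


def import_similarity_edges(
    table: pd.DataFrame, minbit_threshold: float = 0.5
) -> list[SimilarityEdge]:
    """Build edges from an external search result table.

    Expected columns: query_genome, query_gene, target_genome, target_gene,
    bitscore, self_query, self_target.
    """
    edges = []
    for row in table.itertuples(index=False):
        edge = SimilarityEdge(
            (str(row.query_genome), str(row.query_gene)),
            (str(row.target_genome), str(row.target_gene)),
            float(row.bitscore),
            float(row.self_query),
            float(row.self_target),
        )
        if edge.minbit >= minbit_threshold:
            edges.append(edge)
    return edges


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    edges: list[SimilarityEdge],
    inflation: float = 2.0,
    nodes: Iterable[NodeKey] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[set]:
    """Markov clustering of a weighted undirected graph.

    Dense flow simulation: add self-loops, column-normalize, then alternate
    expansion (matrix square) and inflation (elementwise power ``inflation``
    followed by renormalization) until the matrix is stable. Clusters are the
    connected components of the converged flow matrix; isolated nodes come
    out as singletons. Deterministic for a fixed node order (sorted keys).
    """
    if inflation < 1:
        raise ValidationError("inflation must be >= 1")
    keys: set[NodeKey] = set(nodes) if nodes is not None else set()
    for e in edges:
        keys.add(e.gene_a)
        keys.add(e.gene_b)
    if not keys:
        return []
    order = sorted(keys)
    index = {k: i for i, k in enumerate(order)}
    n = len(order)

    W = np.zeros((n, n))
    for e in edges:
        i, j = index[e.gene_a], index[e.gene_b]
        w = max(e.minbit, 0.0)
        W[i, j] = max(W[i, j], w)
        W[j, i] = W[i, j]
    np.fill_diagonal(W, 1.0)  # self-loops stabilize the flow

    M = W / W.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = inflated / colsum
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new

    # components of the attractor structure
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix((M + M.T) > 1e-6)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, set] = {}
    for key, lab in zip(order, labels):
        clusters.setdefault(lab, set()).add(key)
    # deterministic output order: by smallest member key
    return [clusters[lab] for lab in sorted(clusters, key=lambda l: min(clusters[l]))]


# ---------------------------------------------------------------------------
# pangenome assembly


def _consensus_annotations(
    members: set, genomes: dict[str, GenomeEntry]
) -> dict[str, tuple[str, str]]:
    """Most frequent accession per source among member genes; ties lexicographic."""
    votes: dict[str, dict[tuple[str, str], int]] = {}
    for genome_id, gene_id in members:
        ann = genomes[genome_id].annotations
        if ann is None or ann.empty:
            continue
        rows = ann[ann["gene_id"].astype(str) == str(gene_id)]
        for row in rows.itertuples(index=False):
            per_source = votes.setdefault(row.source, {})
            key = (str(row.accession), str(getattr(row, "function", "")))
            per_source[key] = per_source.get(key, 0) + 1
    consensus = {}
    for source, counts in votes.items():
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        consensus[source] = best
    return consensus


def build_pangenome(
    genomes: dict[str, GenomeEntry],
    scorer: Callable[[str, str], float] | None = None,
    minbit_threshold: float = 0.5,
    inflation: float = 2.0,
    edges: list[SimilarityEdge] | None = None,
) -> PangenomeStore:
    """Cluster the genes of >= 2 genomes into a pangenome store.

    Every gene becomes a node (so genes with no retained edge form singleton
    clusters); cluster ids are ``GC_00000001``-style, ordered by decreasing
    size then smallest member for determinism.
    """
    if len(genomes) < 2:
        raise ValidationError("a pangenome needs at least 2 genomes")
    for gid, entry in genomes.items():
        if not entry.proteins:
            raise ValidationError(f"genome {gid!r} has no genes")
    if edges is None:
        edges = compute_similarity_graph(genomes, scorer, minbit_threshold)
    all_nodes = [
        (gid, str(gene_id))
        for gid in sorted(genomes)
        for gene_id in sorted(genomes[gid].proteins)
    ]
    raw = mcl_cluster(edges, inflation=inflation, nodes=all_nodes)
    raw.sort(key=lambda members: (-len(members), min(members)))

    store = PangenomeStore(genomes)
    for k, members in enumerate(raw, start=1):
        cid = f"GC_{k:08d}"
        store.clusters[cid] = GeneCluster(
            cluster_id=cid,
            members=members,
            consensus=_consensus_annotations(members, genomes),
        )
    store.provenance.append(
        f"build_pangenome(minbit_threshold={minbit_threshold}, inflation={inflation}, "
        f"n_genomes={len(genomes)})"
    )
    total_genes = sum(len(g.proteins) for g in genomes.values())
    clustered = sum(len(c.members) for c in store.clusters.values())
    assert clustered == total_genes, "clusters must partition the gene set"
    return store


# ---------------------------------------------------------------------------
# average nucleotide identity


def _fragments(contigs: dict[str, str], fragment_bp: int) -> list[str]:
    """Chop each contig into consecutive full-length windows.

    A contig shorter than one window contributes itself as a single whole
    fragment; a trailing remainder of a longer contig is dropped. The result
    is invariant to contig order (contigs are processed independently and
    the fragment *set* is what matters downstream).
    """
    frags: list[str] = []
    for cid in sorted(contigs):
        seq = contigs[cid].upper()
        if len(seq) < fragment_bp:
            if seq:
                frags.append(seq)
            continue
        for off in range(0, len(seq) - fragment_bp + 1, fragment_bp):
            frags.append(seq[off : off + fragment_bp])
    return frags


def _best_identity(fragment: str, targets: list[str]) -> float:
    """Best per-base identity of *fragment* against any target, either strand."""
    import edlib

    rc = fragment.translate(_COMPLEMENT)[::-1]
    best_dist = len(fragment)
    for target in targets:
        for query in (fragment, rc):
            res = edlib.align(query, target, mode="HW", task="distance",
                              k=best_dist)
            dist = res["editDistance"]
            if dist != -1 and dist < best_dist:
                best_dist = dist
                if best_dist == 0:
                    return 1.0
    return 1.0 - best_dist / len(fragment)


def compute_ani(
    genome_a: GenomeEntry,
    genome_b: GenomeEntry,
    fragment_bp: int = 1020,
    min_frag_identity: float = 0.3,
) -> tuple[float, float]:
    """Fragment-based ANI of genome_a against genome_b.

    Returns ``(ani_percent, aligned_fraction)`` where aligned_fraction is
    the share of fragments retained (identity >= ``min_frag_identity``).
    Asymmetric: call both ways for a full matrix.
    """
    if not genome_a.contigs or not genome_b.contigs:
        raise ValidationError("both genomes need sequences for ANI")
    frags = _fragments(genome_a.contigs, fragment_bp)
    targets = [genome_b.contigs[c].upper() for c in sorted(genome_b.contigs)]
    identities = [_best_identity(f, targets) for f in frags]
    retained = [x for x in identities if x >= min_frag_identity]
    if not retained:
        return 0.0, 0.0
    return 100.0 * float(np.mean(retained)), len(retained) / len(identities)


def ani_matrix(
    genomes: dict[str, GenomeEntry],
    fragment_bp: int = 1020,
    min_frag_identity: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise ANI and aligned-fraction matrices; diagonal is exactly 100."""
    gids = sorted(genomes)
    ani = pd.DataFrame(100.0, index=gids, columns=gids)
    frac = pd.DataFrame(1.0, index=gids, columns=gids)
    for a in gids:
        for b in gids:
            if a == b:
                continue
            value, f = compute_ani(genomes[a], genomes[b], fragment_bp, min_frag_identity)
            ani.loc[a, b] = value
            frac.loc[a, b] = f
    return ani, frac


# ---------------------------------------------------------------------------
# Bayesian core/accessory classification


def bayesian_pan_core(
    presence: pd.DataFrame,
    completeness,
    init_core_prevalence: float = 0.95,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Completeness-aware core/accessory labels for each gene cluster.

    Parameters
    ----------
    presence : DataFrame
        Binary clusters x genomes matrix.
    completeness : mapping or Series
        Per-genome completeness in (0, 1]; values at exactly 1 are floored
        to 0.999 inside the likelihood for numerical safety.

    Returns
    -------
    DataFrame indexed by cluster with columns ``llr`` and ``label``.
    """
    X = presence.to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValidationError("presence matrix must be binary")
    c = pd.Series(completeness).reindex(presence.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(c)) or np.any(c <= 0) or np.any(c > 1):
        raise ValidationError("completeness must be in (0, 1] for every genome")
    c = np.minimum(c, 0.999)  # keep ln(1 - c) finite

    n_clusters, n_genomes = X.shape
    ln_c, ln_1mc = np.log(c), np.log1p(-c)
    ll_core = X @ ln_c + (1 - X) @ ln_1mc  # fixed across iterations

    core = X.mean(axis=1) > init_core_prevalence
    llr = np.zeros(n_clusters)
    for _ in range(max_iter):
        acc = ~core
        g_acc = int(acc.sum())
        if g_acc == 0:
            p = np.full(n_genomes, 1e-10)
        else:
            n_i = X[acc].sum(axis=0)  # per-genome accessory repertoire size
            p = 1.0 - np.power(1.0 - 1.0 / g_acc, n_i)
        p = np.clip(p, 1e-10, 1.0 - 1e-10)
        ll_acc = X @ np.log(p) + (1 - X) @ np.log1p(-p)
        llr = ll_core - ll_acc
        new_core = llr > 0
        if np.array_equal(new_core, core):
            core = new_core
            break
        core = new_core

    return pd.DataFrame(
        {"llr": llr, "label": np.where(core, "core", "accessory")},
        index=presence.index,
    )


def classify_pangenome(store: PangenomeStore, **kwargs) -> pd.DataFrame:
    """Run :func:`bayesian_pan_core` on a store and write labels back."""
    presence = store.presence_matrix()
    completeness = {gid: store.genomes[gid].completeness for gid in store.genome_ids}
    result = bayesian_pan_core(presence, completeness, **kwargs)
    for cid, row in result.iterrows():
        store.clusters[cid].label = row["label"]
        store.clusters[cid].llr = float(row["llr"])
    store.provenance.append("bayesian_pan_core")
    return result


# ---------------------------------------------------------------------------
# subsetting


def subset_pangenome(
    store: PangenomeStore,
    predicate: Callable[[GeneCluster], bool],
    description: str = "subset",
) -> PangenomeStore:
    """New store containing only clusters matching *predicate*.

    The genome roster is preserved; the predicate description is recorded in
    provenance. An empty result is allowed (with a warning).
    """
    sub = PangenomeStore(store.genomes)
    for cid, cluster in store.clusters.items():
        if predicate(cluster):
            sub.clusters[cid] = cluster
    if not sub.clusters:
        logger.warning("subset %r matched no clusters", description)
    sub.ani = store.ani
    sub.aligned_fraction = store.aligned_fraction
    sub.tree = store.tree
    sub.provenance = store.provenance + [f"subset: {description}"]
    return sub
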