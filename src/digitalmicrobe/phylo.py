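"""Phylogeny I/O: supermatrix assembly, midpoint rooting, tree attachment,
and Robinson-Foulds topology comparison.

Tree inference itself is out of scope — the contract starts at pre-aligned
single-copy-core gene alignment blocks (which this module concatenates into
a supermatrix with a partition table) and at trees already in newick form.
Midpoint rooting places the root halfway along the longest leaf-to-leaf
path, the convention used when no outgroup is available; ties between
equally long paths are broken deterministically (lowest-sorted leaf pair).
Robinson-Foulds (RF) distance counts the bipartitions present in exactly
one of two trees on the same leaves; it is the quantitative proxy used here
for comparing gene-tree topologies (e.g. individual CAZyme phylogenies)
against a core-genome phylogeny.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# supermatrix


@dataclass
class AlignmentBlock:
    """One pre-aligned single-copy gene cluster: one row per genome."""

    cluster_id: str
    rows: list  # of (genome_id, aligned_sequence)

    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


def concatenate_scg_alignments(
    blocks: list[AlignmentBlock], genome_roster: list[str]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate aligned blocks into a per-genome supermatrix.

    Every block must be single-copy (at most one row per genome) and
    internally rectangular. A genome absent from a block receives gap
    characters for that block's width (with a warning). Returns the
    per-genome concatenated sequences and a partition table with 1-based
    inclusive column ranges per block.
    """
    if not blocks:
        raise ValidationError("no alignment blocks given")
    concat = {g: [] for g in genome_roster}
    partitions = []
    position = 1
    for block in blocks:
        if not block.rows:
            raise ValidationError(f"block {block.cluster_id!r} is empty")
        width = len(block.rows[0][1])
        seen: dict[str, str] = {}
        for genome_id, seq in block.rows:
            if len(seq) != width:
                raise ValidationError(
                    f"block {block.cluster_id!r}: unequal row lengths "
                    f"({len(seq)} vs {width})"
                )
            if genome_id in seen:
                raise ValidationError(
                    f"block {block.cluster_id!r}: genome {genome_id!r} appears twice "
                    "(not single-copy)"
                )
            seen[genome_id] = seq
        for genome_id in genome_roster:
            if genome_id in seen:
                concat[genome_id].append(seen[genome_id])
            else:
                logger.warning(
                    "genome %s missing from block %s; gap-filled", genome_id, block.cluster_id
                )
                concat[genome_id].append("-" * width)
        partitions.append(
            {"block": block.cluster_id, "start": position, "end": position + width - 1}
        )
        position += width
    supermatrix = {g: "".join(parts) for g, parts in concat.items()}
    return supermatrix, pd.DataFrame(partitions)


def write_supermatrix(supermatrix: dict[str, str], fasta_path, partitions: pd.DataFrame,
                      partition_path) -> None:
    """Write the supermatrix FASTA and a RAxML-style partition file."""
    with open(fasta_path, "w") as fh:
        for genome in sorted(supermatrix):
            fh.write(f">{genome}\n{supermatrix[genome]}\n")
    with open(partition_path, "w") as fh:
        for row in partitions.itertuples(index=False):
            fh.write(f"PROT, {row.block} = {row.start}-{row.end}\n")


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(source: str) -> dendropy.Tree:
    """Parse a newick string (or path ending in .nwk/.newick/.tre)."""
    text = source
    if "(" not in source:  # path, not a tree literal
        with open(source) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


# ---------------------------------------------------------------------------
# midpoint rooting


def _leaf_paths(tree: dendropy.Tree):
    """All leaf pairs with their path length and edge path, via brute force."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValidationError("midpoint rooting requires branch lengths on every edge")

    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            a, b = leaves[i], leaves[j]
            # MRCA: first ancestor of a that is also an ancestor of b
            ancestors_b = set()
            node = b
            while node is not None:
                ancestors_b.add(id(node))
                node = node.parent_node
            node = a
            a_side = []
            while id(node) not in ancestors_b:
                a_side.append(node)
                node = node.parent_node
            mrca = node
            b_side = []
            node = b
            while id(node) != id(mrca):
                b_side.append(node)
                node = node.parent_node
            # path from a to b: a-side edges upward, then b-side edges downward
            edges = [n.edge for n in a_side] + [n.edge for n in reversed(b_side)]
            total = sum(e.length for e in edges)
            yield (a.taxon.label, b.taxon.label), total, edges, len(a_side)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    The two endpoint leaves of that path end up equidistant from the root.
    If several paths tie for longest (within 1e-9), the lexicographically
    lowest-sorted leaf pair wins, making the operation deterministic.
    Operates on (a clone of) the input; returns the rooted tree.
    """
    tree = tree.clone(depth=1)
    best = None
    for pair, total, edges, n_up in _leaf_paths(tree):
        if best is None or total > best[1] + 1e-9 or (
            abs(total - best[1]) <= 1e-9 and pair < best[0]
        ):
            best = (pair, total, edges, n_up)
    if best is None:
        raise ValidationError("tree has fewer than 2 leaves")
    pair, total, edges, n_up = best
    half = total / 2.0

    # walk from the first leaf of the pair along the path until we pass half
    cum = 0.0
    for k, edge in enumerate(edges):
        nxt = cum + edge.length
        if nxt >= half - 1e-12:
            within = half - cum  # distance into this edge from its path-entry end
            if k < n_up:
                # ascending edge: entered at the child (head) end
                dist_from_child = within
            else:
                # descending edge: entered at the parent (tail) end
                dist_from_child = edge.length - within
            dist_from_child = min(max(dist_from_child, 0.0), edge.length)
            tree.reroot_at_edge(
                edge,
                length1=edge.length - dist_from_child,  # toward original parent
                length2=dist_from_child,  # toward original child
                suppress_unifurcations=True,
            )
            break
        cum = nxt
    return tree


def root_to_leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


# ---------------------------------------------------------------------------
# tree attachment


def attach_tree(pkg, newick: str, role: str = "core_phylogeny") -> list[str]:
    """Store a newick tree as a versioned layer on a package.

    The tree's leaf set must be a subset of the genome roster (for a
    pangenome package) or is accepted as-is for a genome package. Returns
    the leaf order for display alignment. Re-attaching an identical tree is
    idempotent (no new layer, no version bump).
    """
    from .package_core import LayerRecord, register_layer
    from .serialize import checksum

    tree = read_newick(newick)
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValidationError("tree has duplicate leaf labels")
    if pkg.pangenome is not None:
        roster = set(pkg.pangenome.genome_ids)
        extras = sorted(set(leaves) - roster)
        if extras:
            raise ValidationError(f"tree leaves not in genome roster: {extras}")
        pkg.pangenome.tree = newick
    layer_id = f"tree:{role}"
    if pkg.has_layer(layer_id):
        if checksum(pkg.get_layer(layer_id)) == checksum(newick):
            return leaves  # idempotent re-attach
        raise ValidationError(f"a different tree is already attached as {role!r}")
    register_layer(
        pkg,
        LayerRecord(layer_id=layer_id, layer_type="tree", provenance=f"role {role}"),
        newick,
    )
    return leaves


def leaf_order(newick: str) -> list[str]:
    tree = read_newick(newick)
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _bipartitions(tree: dendropy.Tree, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree.

    Each internal edge splits the leaves in two; the side not containing the
    overall-smallest leaf label is the canonical representative, so both
    orientations (and a root bisecting an edge) collapse to one entry.
    """
    n = len(all_leaves)
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        if anchor in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def topology_distance(tree_a, tree_b) -> tuple[int, float]:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Returns ``(rf, normalized)`` with the normalization by 2(n-3), the
    maximum RF for two fully resolved unrooted trees on n leaves.
    """
    ta = tree_a if isinstance(tree_a, dendropy.Tree) else read_newick(tree_a)
    tb = tree_b if isinstance(tree_b, dendropy.Tree) else read_newick(tree_b)
    leaves_a = frozenset(l.taxon.label for l in ta.leaf_node_iter())
    leaves_b = frozenset(l.taxon.label for l in tb.leaf_node_iter())
    if leaves_a != leaves_b:
        raise ValidationError(
            f"leaf sets differ: only-in-a={sorted(leaves_a - leaves_b)[:5]}, "
            f"only-in-b={sorted(leaves_b - leaves_a)[:5]}"
        )
    n = len(leaves_a)
    sa = _bipartitions(ta, leaves_a)
    sb = _bipartitions(tb, leaves_a)
    rf = len(sa ^ sb)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)
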