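"""CAZyme category profiling across the genomes of a pangenome.

Carbohydrate-active enzyme (CAZyme) families are named by a category prefix
plus a family number (GH13, PL1, CBM48, ...). The category is the leading
letters of the accession: GH (glycoside hydrolases), GT (glycosyl
transferases), PL (polysaccharide lyases), CE (carbohydrate esterases),
AA (auxiliary activities) and CBM (carbohydrate-binding modules). Counting
per category per genome and normalizing by the per-category maximum across
genomes gives the clade-comparison profile that can be displayed beside a
phylogeny.
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from .errors import ValidationError
from .pangenome import PangenomeStore

logger = logging.getLogger(__name__)

CAZYME_CATEGORIES = ("GH", "GT", "PL", "CE", "AA", "CBM")
_PREFIX_RE = re.compile(r"^([A-Za-z]+)")


def cazyme_category(accession: str) -> str:
    """Category prefix of a CAZyme accession (letters before the digits).

    Unknown prefixes are collected under "other" with a warning.
    """
    match = _PREFIX_RE.match(str(accession))
    prefix = match.group(1).upper() if match else ""
    if prefix in CAZYME_CATEGORIES:
        return prefix
    logger.warning("unknown CAZyme category prefix in accession %r", accession)
    return "other"


def count_cazymes(
    genomes: dict,
    annotation_source: str = "CAZyme",
    per_hit: bool = False,
) -> pd.DataFrame:
    """Per-genome, per-category CAZyme counts.

    ``genomes`` maps genome_id -> GenomeEntry (with an annotations table).
    By default a gene with multiple hits counts once per *distinct* category
    (a GH13+CBM48 gene adds 1 to GH and 1 to CBM); ``per_hit=True`` counts
    every hit. Genomes with no CAZyme annotations keep an all-zero row.
    """
    any_source = False
    rows = {}
    categories = list(CAZYME_CATEGORIES)
    for gid in sorted(genomes):
        entry = genomes[gid]
        counts = {cat: 0 for cat in categories}
        ann = entry.annotations
        if ann is not None and not ann.empty:
            caz = ann[ann["source"] == annotation_source]
            if not caz.empty:
                any_source = True
            if per_hit:
                for acc in caz["accession"]:
                    cat = cazyme_category(acc)
                    counts[cat] = counts.get(cat, 0) + 1
            else:
                for _, gene_rows in caz.groupby("gene_id"):
                    for cat in sorted({cazyme_category(a) for a in gene_rows["accession"]}):
                        counts[cat] = counts.get(cat, 0) + 1
        rows[gid] = counts
    if not any_source:
        raise ValidationError(f"no annotations from source {annotation_source!r}")
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    ordered = [c for c in categories if c in table.columns] + [
        c for c in table.columns if c not in categories
    ]
    return table[ordered]


def count_cazymes_pangenome(
    store: PangenomeStore, annotation_source: str = "CAZyme", per_hit: bool = False
) -> pd.DataFrame:
    """Counts computed from the member genes of a pangenome store's clusters."""
    return count_cazymes(store.genomes, annotation_source, per_hit=per_hit)


def normalize_by_category_max(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each category column by its maximum count over genomes.

    The genome attaining the category maximum scores 1.0; a category absent
    from every genome stays all-zero (no division error).
    """
    maxima = counts.max(axis=0)
    safe = maxima.replace(0, 1)
    return counts / safe


def order_rows_by_tree(table: pd.DataFrame, leaf_order: list[str]) -> pd.DataFrame:
    """Reorder genome rows to match an attached tree's leaf order."""
    missing = [g for g in leaf_order if g not in table.index]
    if missing:
        raise ValidationError(f"tree leaves missing from table: {missing[:5]}")
    return table.loc[leaf_order]
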