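"""Expression meta-analysis over a gene collection.

Given a samples x genes TPM matrix restricted to a collection (for example
the protein components of a set of substrate-confirmed transporter systems),
this module computes *proportional expression* — each gene's share of the
collection total within its sample — clusters samples and genes for heatmap
display (Euclidean distance, Ward linkage), and tests per-gene differences
between two sample groups with a two-sided t-test (Student by default,
Welch as an option), with and without Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

logger = logging.getLogger(__name__)


def proportional_expression(
    tpm: pd.DataFrame, collection_genes: list | None = None
) -> pd.DataFrame:
    """Relativize TPM rows to proportions of the collection total.

    Each sample row is divided by its sum over the collection genes; rows
    that are all zero stay zero (warning, not an error). Scaling a sample's
    TPM by any positive constant leaves its proportional row unchanged.
    """
    if collection_genes is not None:
        if len(collection_genes) == 0:
            raise ValidationError("empty collection")
        missing = [g for g in collection_genes if g not in tpm.columns]
        if missing:
            raise ValidationError(f"collection genes not in matrix: {missing[:5]}")
        tpm = tpm[collection_genes]
    values = tpm.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    zero_rows = (totals == 0).ravel()
    if zero_rows.any():
        logger.warning("%d all-zero sample row(s); left as zeros", int(zero_rows.sum()))
    safe = np.where(totals == 0, 1.0, totals)
    return pd.DataFrame(values / safe, index=tpm.index, columns=tpm.columns)


def cluster_for_display(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "ward",
) -> dict:
    """Row and column orderings plus merge trees for heatmap display.

    Returns a dict with ``row_order`` / ``col_order`` (labels in leaf order)
    and ``row_linkage`` / ``col_linkage`` (scipy linkage matrices). Leaf
    ordering is deterministic: scipy's tie handling is fixed given the input
    order, and identical rows merge first at height 0.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = [
            (matrix.index[i], matrix.columns[j])
            for i, j in zip(*np.where(~np.isfinite(values)))
        ]
        raise ValidationError(f"non-finite cells: {bad[:10]}")

    row_link = hierarchy.linkage(pdist(values, metric=metric), method=linkage)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    out = {"row_linkage": row_link, "row_order": row_order}
    if matrix.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(values.T, metric=metric), method=linkage)
        out["col_linkage"] = col_link
        out["col_order"] = [matrix.columns[j] for j in hierarchy.leaves_list(col_link)]
    else:
        out["col_linkage"] = None
        out["col_order"] = list(matrix.columns)
    return out


def group_difference_test(
    matrix: pd.DataFrame,
    design: pd.Series | dict,
    gene,
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-sided t-test of one gene's expression between two sample groups.

    ``design`` maps sample id -> condition label and must define exactly two
    groups of >= 2 samples each among the matrix rows. Returns (t, df, p).
    Zero variance in both groups with equal means yields (0, df, 1) by
    convention rather than NaN.
    """
    design = pd.Series(design)
    design = design[design.index.isin(matrix.index)]
    groups = sorted(design.unique())  # lexicographic: group order (and t sign) is deterministic
    if len(groups) != 2:
        raise ValidationError(f"design must define exactly 2 groups, got {list(groups)}")
    a = matrix.loc[design[design == groups[0]].index, gene].to_numpy(dtype=float)
    b = matrix.loc[design[design == groups[1]].index, gene].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need at least 2 samples")
    import warnings

    with warnings.catch_warnings():
        # degenerate (near-constant) groups are handled by convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        if variant == "student":
            res = stats.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
        elif variant == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
            df = float(res.df)
        else:
            raise ValidationError(f"unknown t-test variant {variant!r}")
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(df), 1.0
        raise ValidationError("degenerate groups with unequal means")
    return t, float(df), p


def group_difference_table(
    matrix: pd.DataFrame,
    design: pd.Series | dict,
    genes: list | None = None,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-gene group tests with Benjamini-Hochberg adjusted q-values.

    The raw two-sided p-value is the primary column; ``q`` is the BH
    adjustment across the tested genes.
    """
    from statsmodels.stats.multitest import multipletests

    if genes is None:
        genes = list(matrix.columns)
    rows = []
    for gene in genes:
        t, df, p = group_difference_test(matrix, design, gene, variant=variant)
        rows.append({"gene": gene, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
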