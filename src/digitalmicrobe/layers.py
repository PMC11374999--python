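"""Gene-referenced experimental layers.

Per-sample transcript coverage (read counts and mean coverage), proteome
spectral counts with NSAF normalization, arbitrary misc gene data (mutant
availability, fitness scores, ...) and named gene collections ("bins", e.g.
the components of a set of transporter systems analyzed jointly).

Normalizations
--------------
TPM (transcripts per million) for sample *s*::

    rate_g = read_count_g / length_g      (mode="count")
    rate_g = mean_coverage_g              (mode="coverage"; already per-base)
    TPM_g  = rate_g / sum_h rate_h * 1e6

so each non-degenerate sample sums to 1e6. NSAF (normalized spectral
abundance factor) for a proteome::

    NSAF_p = (SpC_p / L_p) / sum_i (SpC_i / L_i)

which sums to 1 over detected proteins and makes spectral counts comparable
across proteomes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConflictError, NotFoundError, ValidationError
from .package_core import DigitalMicrobePackage, LayerRecord, register_layer

logger = logging.getLogger(__name__)


def _gene_universe(pkg: DigitalMicrobePackage) -> list[int]:
    if not pkg.gene_calls:
        raise ValidationError("package has no gene calls")
    return sorted(pkg.gene_calls)


def add_coverage_layer(
    pkg: DigitalMicrobePackage,
    sample_id: str,
    counts,
    total_mapped_reads: int | None = None,
) -> pd.DataFrame:
    """Register one sample's per-gene read counts / mean coverage.

    ``counts`` is a path to a TSV (gene_id, read_count[, mean_coverage]) or
    an equivalent DataFrame. Genes absent from the table are imputed as zero
    with a warning. ``total_mapped_reads`` is the sample's mapping
    denominator; if omitted it defaults to the read-count column sum (logged).
    """
    layer_id = f"coverage:{sample_id}"
    if pkg.has_layer(layer_id):
        raise ConflictError(f"sample {sample_id!r} already has a coverage layer")
    table = counts if isinstance(counts, pd.DataFrame) else pd.read_csv(counts, sep="\t")
    if "gene_id" not in table.columns or "read_count" not in table.columns:
        raise ValidationError("coverage table needs gene_id and read_count columns")
    if "mean_coverage" not in table.columns:
        table = table.assign(mean_coverage=0.0)
    if (table["read_count"] < 0).any() or (table["mean_coverage"] < 0).any():
        raise ValidationError(f"sample {sample_id!r}: negative counts/coverage")

    universe = _gene_universe(pkg)
    table = table.set_index("gene_id")
    unknown = set(table.index) - set(universe)
    if unknown:
        raise ValidationError(f"sample {sample_id!r}: unknown gene ids {sorted(unknown)[:5]}")
    missing = [g for g in universe if g not in table.index]
    if missing:
        logger.warning(
            "sample %s: %d genes missing from counts table, imputing 0", sample_id, len(missing)
        )
    full = table.reindex(universe).fillna({"read_count": 0, "mean_coverage": 0.0})
    if total_mapped_reads is None:
        total_mapped_reads = int(full["read_count"].sum())
        logger.warning(
            "sample %s: total_mapped_reads not given, using column sum %d",
            sample_id, total_mapped_reads,
        )
    if total_mapped_reads < int(full["read_count"].max()):
        raise ValidationError(
            f"sample {sample_id!r}: total_mapped_reads below a per-gene count"
        )
    layer = pd.DataFrame(
        {
            "gene_id": universe,
            "read_count": full["read_count"].astype(int).to_numpy(),
            "mean_coverage": full["mean_coverage"].astype(float).to_numpy(),
            "total_mapped_reads": total_mapped_reads,
        }
    )
    register_layer(
        pkg,
        LayerRecord(layer_id=layer_id, layer_type="coverage_sample",
                    provenance=f"sample {sample_id}"),
        layer,
    )
    return layer


def coverage_samples(pkg: DigitalMicrobePackage) -> list[str]:
    return sorted(
        rec.layer_id.split(":", 1)[1]
        for rec in pkg.manifest.layers
        if rec.layer_type == "coverage_sample"
    )


def merge_samples(
    pkg: DigitalMicrobePackage,
    sample_ids: list[str] | None = None,
    value: str = "read_count",
) -> pd.DataFrame:
    """Genes x samples matrix assembled from stored coverage layers."""
    if sample_ids is None:
        sample_ids = coverage_samples(pkg)
    universe = _gene_universe(pkg)
    data = {}
    for sid in sample_ids:
        layer_id = f"coverage:{sid}"
        if not pkg.has_layer(layer_id):
            raise NotFoundError(f"no coverage layer for sample {sid!r}")
        layer = pkg.get_layer(layer_id).set_index("gene_id")
        data[sid] = layer.loc[universe, value].to_numpy()
    return pd.DataFrame(data, index=pd.Index(universe, name="gene_id"))


def tpm_normalize(
    layer: pd.DataFrame,
    gene_lengths: dict[int, int] | pd.Series | None = None,
    mode: str = "count",
) -> pd.Series:
    """TPM per gene for one coverage layer.

    mode="count" divides read counts by gene length before scaling;
    mode="coverage" treats mean coverage as an already length-normalized
    rate. An all-zero sample yields all zeros (with a warning), not an error.
    """
    gene_ids = layer["gene_id"].to_numpy()
    if mode == "count":
        if gene_lengths is None:
            raise ValidationError("mode='count' requires gene lengths")
        lengths = pd.Series(gene_lengths).reindex(gene_ids).to_numpy(dtype=float)
        if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValidationError("gene lengths must be positive for all genes")
        rates = layer["read_count"].to_numpy(dtype=float) / lengths
    elif mode == "coverage":
        rates = layer["mean_coverage"].to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown TPM mode {mode!r}")
    total = rates.sum()
    if total == 0:
        logger.warning("all-zero sample: TPM undefined, returning zeros")
        return pd.Series(np.zeros_like(rates), index=gene_ids, name="tpm")
    return pd.Series(rates / total * 1e6, index=gene_ids, name="tpm")


def tpm_matrix(
    pkg: DigitalMicrobePackage,
    sample_ids: list[str] | None = None,
    mode: str = "count",
) -> pd.DataFrame:
    """Samples x genes TPM matrix over stored coverage layers."""
    if sample_ids is None:
        sample_ids = coverage_samples(pkg)
    lengths = {gid: gc.length for gid, gc in pkg.gene_calls.items()}
    rows = {}
    for sid in sample_ids:
        layer = pkg.get_layer(f"coverage:{sid}")
        rows[sid] = tpm_normalize(layer, lengths, mode=mode)
    return pd.DataFrame(rows).T


def nsaf_normalize(spectral_counts, lengths) -> pd.Series:
    """NSAF per protein: length-normalized spectral counts summing to 1."""
    spc = pd.Series(spectral_counts, dtype=float)
    length = pd.Series(lengths, dtype=float).reindex(spc.index)
    if (length <= 0).any() or length.isna().any():
        raise ValidationError("protein lengths must be positive for all proteins")
    if (spc < 0).any():
        raise ValidationError("spectral counts must be non-negative")
    saf = spc / length
    total = saf.sum()
    if total == 0:
        raise ValidationError("no detected proteins (all spectral counts zero)")
    out = saf / total
    out.name = "nsaf"
    return out


def add_proteome_layer(pkg: DigitalMicrobePackage, sample_id: str, table) -> pd.DataFrame:
    """Register a proteome layer (gene_id, spectral_count, length_aa) + NSAF."""
    layer_id = f"proteome:{sample_id}"
    if pkg.has_layer(layer_id):
        raise ConflictError(f"proteome {sample_id!r} already registered")
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    required = {"gene_id", "spectral_count", "length_aa"}
    if required - set(df.columns):
        raise ValidationError(f"proteome table needs columns {sorted(required)}")
    unknown = set(df["gene_id"]) - set(pkg.gene_calls)
    if unknown:
        raise ValidationError(f"proteome {sample_id!r}: unknown gene ids {sorted(unknown)[:5]}")
    nsaf = nsaf_normalize(
        df.set_index("gene_id")["spectral_count"], df.set_index("gene_id")["length_aa"]
    )
    layer = df.copy()
    layer["nsaf"] = nsaf.reindex(df["gene_id"]).to_numpy()
    register_layer(
        pkg,
        LayerRecord(layer_id=layer_id, layer_type="proteome",
                    provenance=f"proteome sample {sample_id}"),
        layer,
    )
    return layer


def import_misc_data(pkg: DigitalMicrobePackage, layer_name: str, table) -> pd.DataFrame:
    """Attach an arbitrary per-gene layer (gene_id, value)."""
    layer_id = f"misc:{layer_name}"
    if pkg.has_layer(layer_id):
        raise ConflictError(f"misc layer {layer_name!r} already registered")
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    if "gene_id" not in df.columns or "value" not in df.columns:
        raise ValidationError("misc table needs gene_id and value columns")
    for idx, gid in enumerate(df["gene_id"], start=2):
        if int(gid) not in pkg.gene_calls:
            raise ValidationError(f"misc layer {layer_name!r} row {idx}: unknown gene_id {gid}")
    register_layer(
        pkg,
        LayerRecord(layer_id=layer_id, layer_type="misc_gene_data",
                    provenance=f"misc data {layer_name}"),
        df.reset_index(drop=True),
    )
    return df


def define_collection(
    pkg: DigitalMicrobePackage,
    name: str,
    gene_ids: list[int],
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Define an ordered, named gene collection ("bin"), optionally grouped."""
    layer_id = f"collection:{name}"
    if pkg.has_layer(layer_id):
        raise ConflictError(f"collection {name!r} already defined")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"collection {name!r}: duplicate gene ids")
    for gid in gene_ids:
        if gid not in pkg.gene_calls:
            raise ValidationError(f"collection {name!r}: unknown gene_id {gid}")
    if groups is not None and len(groups) != len(gene_ids):
        raise ValidationError("groups must align 1:1 with gene_ids")
    table = pd.DataFrame(
        {
            "position": range(len(gene_ids)),
            "gene_id": gene_ids,
            "group": groups if groups is not None else [""] * len(gene_ids),
        }
    )
    register_layer(
        pkg,
        LayerRecord(layer_id=layer_id, layer_type="collection",
                    provenance=f"collection {name}"),
        table,
    )
    return table


def get_collection(pkg: DigitalMicrobePackage, name: str) -> pd.DataFrame:
    table = pkg.get_layer(f"collection:{name}")
    return table.sort_values("position").reset_index(drop=True)


def summarize_collection(
    pkg: DigitalMicrobePackage,
    collection: str,
    sample_ids: list[str] | None = None,
    tpm_mode: str = "count",
) -> pd.DataFrame:
    """One row per collection gene: group, annotations, per-sample TPM.

    Column order is deterministic (metadata first, then samples in the
    requested order), so repeated exports are byte-identical.
    """
    coll = get_collection(pkg, collection)
    if coll.empty:
        raise ValidationError(f"collection {collection!r} is empty")
    if sample_ids is None:
        sample_ids = coverage_samples(pkg)
    tpm = tpm_matrix(pkg, sample_ids, mode=tpm_mode)
    ann = pkg.annotations
    rows = []
    for rec in coll.itertuples(index=False):
        gid = int(rec.gene_id)
        gene_ann = ann[ann["gene_id"] == gid]
        funcs = "; ".join(
            sorted(f"{a.source}:{a.accession}" for a in gene_ann.itertuples(index=False))
        )
        row = {"gene_id": gid, "group": rec.group, "annotations": funcs}
        for sid in sample_ids:
            row[f"tpm_{sid}"] = float(tpm.loc[sid, gid])
        rows.append(row)
    return pd.DataFrame(rows)
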