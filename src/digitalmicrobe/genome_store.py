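"""Genome sequences, gene calls and multi-source functional annotations.

This is the coordinate spine every other layer references: contigs hold the
DNA, gene calls anchor dense integer gene ids to half-open 0-based intervals
on those contigs, and functional annotations attach (source, accession,
function, score) tuples to gene ids. Multiple annotation sources (COG, KOfam,
Pfam, CAZyme, custom curations) are kept side by side, never merged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import ConflictError, NotFoundError, ValidationError
from .package_core import DigitalMicrobePackage, LayerRecord, register_layer, update_layer

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ContigRecord:
    """One assembled sequence; uppercase DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """A gene model: 0-based half-open [start, stop) on a contig."""

    gene_id: int
    contig_id: str
    start: int
    stop: int
    strand: str
    partial: bool = False
    source: str = "external"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.stop):
            raise ValidationError(
                f"gene {self.gene_id}: invalid coordinates [{self.start}, {self.stop})"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start


def load_genome_sequences(fasta_path) -> list[ContigRecord]:
    """Read a FASTA file into contig records (lowercase normalized, ids unique)."""
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValidationError(f"duplicate contig id {entry.id!r}")
        seen.add(entry.id)
        records.append(ContigRecord(contig_id=entry.id, sequence=str(entry.seq)))
    if not records:
        raise ValidationError(f"no FASTA entries in {fasta_path}")
    return records


def add_genome(pkg: DigitalMicrobePackage, fasta_path) -> int:
    """Load a genome FASTA into the package spine. Returns contig count."""
    records = load_genome_sequences(fasta_path)
    pkg.contigs = {rec.contig_id: rec for rec in records}
    pkg.manifest.modified = pkg.manifest.modified  # spine, not a layer: no version bump
    return len(records)


def _check_bounds(pkg: DigitalMicrobePackage, gene: GeneCall, where: str) -> None:
    if gene.contig_id not in pkg.contigs:
        raise ValidationError(f"{where}: unknown contig {gene.contig_id!r}")
    clen = pkg.contigs[gene.contig_id].length
    if gene.stop > clen:
        raise ValidationError(
            f"{where}: gene {gene.gene_id} stop {gene.stop} exceeds contig length {clen}"
        )


def import_gene_calls(pkg: DigitalMicrobePackage, path, format: str = "gff3") -> int:
    """Import gene calls from GFF3 or an external-gene-calls TSV.

    GFF3 coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention. Gene ids are dense integers assigned in file order
    starting at the current maximum + 1 (0 for an empty package) for GFF3;
    the external TSV format carries explicit gene ids.
    """
    path = Path(path)
    next_id = max(pkg.gene_calls) + 1 if pkg.gene_calls else 0
    imported: list[GeneCall] = []

    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ValidationError(f"{path}:{lineno}: malformed GFF3 row")
                seqid, _src, ftype, start, stop, _score, strand, _frame = fields[:8]
                if ftype not in ("CDS", "gene"):
                    continue
                gene = GeneCall(
                    gene_id=next_id + len(imported),
                    contig_id=seqid,
                    start=int(start) - 1,  # 1-based closed -> 0-based half-open
                    stop=int(stop),
                    strand=strand,
                    source=_src,
                )
                _check_bounds(pkg, gene, f"{path}:{lineno}")
                imported.append(gene)
    elif format == "external_tsv":
        table = pd.read_csv(path, sep="\t")
        required = {"gene_id", "contig", "start", "stop", "strand"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for idx, row in enumerate(table.itertuples(index=False), start=2):
            gene = GeneCall(
                gene_id=int(row.gene_id),
                contig_id=str(row.contig),
                start=int(row.start),
                stop=int(row.stop),
                strand=str(row.strand),
                partial=bool(getattr(row, "partial", False)),
            )
            _check_bounds(pkg, gene, f"{path}:{idx}")
            imported.append(gene)
    else:
        raise ValidationError(f"unknown gene-call format {format!r}")

    for gene in imported:
        if gene.gene_id in pkg.gene_calls:
            raise ConflictError(f"gene_id {gene.gene_id} already present")
        pkg.gene_calls[gene.gene_id] = gene
    return len(imported)


def import_functional_annotations(
    pkg: DigitalMicrobePackage,
    tsv_path,
    source: str,
    overwrite: bool = False,
) -> int:
    """Import an annotation table (gene_id, accession, function[, score]).

    The rows are stored in the package annotation table and registered as an
    ``annotation:<source>`` layer. Re-importing the same source without
    ``overwrite`` appends only new (gene_id, accession) pairs; with
    ``overwrite`` the source's annotations are replaced. Returns the number
    of rows added.
    """
    table = pd.read_csv(tsv_path, sep="\t")
    if "gene_id" not in table.columns or "accession" not in table.columns:
        raise ValidationError(f"{tsv_path}: need gene_id and accession columns")
    if "function" not in table.columns:
        table["function"] = ""
    if "score" not in table.columns:
        table["score"] = 0.0
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        gid = int(row.gene_id)
        if gid not in pkg.gene_calls:
            raise ValidationError(f"{tsv_path}:{idx}: unknown gene_id {gid}")
        try:
            float(row.score)
        except (TypeError, ValueError):
            raise ValidationError(f"{tsv_path}:{idx}: malformed score {row.score!r}")

    new = pd.DataFrame(
        {
            "gene_id": table["gene_id"].astype(int),
            "source": source,
            "accession": table["accession"].astype(str),
            "function": table["function"].astype(str),
            "score": table["score"].astype(float),
        }
    )
    existing = pkg.annotations
    mask = existing["source"] == source
    if overwrite:
        others = existing[~mask]
        merged = new if others.empty else pd.concat([others, new], ignore_index=True)
        added = len(new)
    else:
        present = set(
            zip(existing.loc[mask, "gene_id"], existing.loc[mask, "accession"])
        )
        keep = new[
            ~new.apply(lambda r: (r["gene_id"], r["accession"]) in present, axis=1)
        ]
        if existing.empty:
            merged = keep.reset_index(drop=True)
        elif keep.empty:
            merged = existing
        else:
            merged = pd.concat([existing, keep], ignore_index=True)
        added = len(keep)
    pkg.annotations = merged

    layer_id = f"annotation:{source}"
    content = merged[merged["source"] == source].reset_index(drop=True)
    if pkg.has_layer(layer_id):
        if added or overwrite:
            update_layer(pkg, layer_id, content, f"re-imported annotations for {source}")
    else:
        register_layer(
            pkg,
            LayerRecord(layer_id=layer_id, layer_type="annotation_source",
                        provenance=f"imported from {tsv_path}"),
            content,
        )
    return added


def get_annotations(pkg: DigitalMicrobePackage, source: str | None = None) -> pd.DataFrame:
    if source is None:
        return pkg.annotations.copy()
    return pkg.annotations[pkg.annotations["source"] == source].reset_index(drop=True)


def orphan_annotations(pkg: DigitalMicrobePackage) -> pd.DataFrame:
    """Annotations whose gene_id has no gene call (empty on a valid package)."""
    known = set(pkg.gene_calls)
    return pkg.annotations[~pkg.annotations["gene_id"].isin(known)]


def genome_stats(pkg: DigitalMicrobePackage) -> dict:
    """Summary statistics: total length, GC fraction, gene count, genes/kbp.

    GC is computed over informative bases only (N excluded from both the
    numerator and the denominator).
    """
    if not pkg.contigs:
        raise ValidationError("no sequences loaded")
    total = sum(rec.length for rec in pkg.contigs.values())
    gc = at = 0
    for rec in pkg.contigs.values():
        gc += rec.sequence.count("G") + rec.sequence.count("C")
        at += rec.sequence.count("A") + rec.sequence.count("T")
    informative = gc + at
    num_genes = len(pkg.gene_calls)
    return {
        "total_length": total,
        "gc_fraction": gc / informative if informative else 0.0,
        "num_genes": num_genes,
        "genes_per_kbp": num_genes / (total / 1000.0),
    }


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def get_gene_sequence(pkg: DigitalMicrobePackage, gene_id: int) -> str:
    """DNA of a gene call; reverse-complemented for minus-strand genes."""
    if gene_id not in pkg.gene_calls:
        raise NotFoundError(f"unknown gene_id {gene_id}")
    gene = pkg.gene_calls[gene_id]
    seq = pkg.contigs[gene.contig_id].sequence[gene.start : gene.stop]
    return reverse_complement(seq) if gene.strand == "-" else seq


_CODON_TABLE = 11  # bacterial


def get_protein_sequence(pkg: DigitalMicrobePackage, gene_id: int) -> str:
    """Conceptual translation of a gene call (bacterial code, no stop)."""
    from Bio.Seq import Seq

    dna = get_gene_sequence(pkg, gene_id)
    dna = dna[: len(dna) - len(dna) % 3]
    return str(Seq(dna).translate(table=_CODON_TABLE)).rstrip("*")


def export_gene_calls_gff3(pkg: DigitalMicrobePackage, path) -> None:
    """Write gene calls back out as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(pkg.gene_calls.values(), key=lambda g: g.gene_id):
            fh.write(
                "\t".join(
                    [
                        gene.contig_id,
                        gene.source,
                        "CDS",
                        str(gene.start + 1),
                        str(gene.stop),
                        ".",
                        gene.strand,
                        "0",
                        f"ID=gene_{gene.gene_id}",
                    ]
                )
                + "\n"
            )
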