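"""Versioned, checksummed, self-describing data packages.

A :class:`DigitalMicrobePackage` is a self-contained data product anchored on
a single microbial genome (``kind="genome"``) or on a pangenome
(``kind="pangenome"``). It carries a manifest (name, kind, two-component
version, optional DOI, changelog) plus any number of *layers*: checksummed,
gene- or genome-referenced datasets (annotation sources, per-sample coverage,
proteomes, misc gene data, collections, trees, ANI matrices, cluster tables).

Versioning is MAJOR.MINOR: registering a layer bumps MINOR; destructive
edits (layer removal) bump MAJOR. Every mutation appends a changelog entry,
so the provenance of each layer is reconstructible from the manifest alone.

Packages persist in two forms:

* a single SQLite file (:func:`save_package` / :func:`open_package`) that can
  be queried without loading everything into memory, and
* a universal-format export directory (:func:`export_package` /
  :func:`import_package`): JSON manifest, one TSV per tabular layer, FASTA
  for sequences, newick for trees. Export then import is the identity on the
  manifest and on every layer checksum.
"""

from __future__ import annotations

import datetime
import json
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ConflictError, IntegrityError, NotFoundError, ValidationError
from .serialize import Payload, canonical_bytes, checksum

PACKAGE_KINDS = ("genome", "pangenome")
LAYER_TYPES = (
    "annotation_source",
    "coverage_sample",
    "proteome",
    "misc_gene_data",
    "collection",
    "tree",
    "ani",
    "clusters",
)


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def parse_version(version: str) -> tuple[int, int]:
    """Parse a MAJOR.MINOR version string into a pair of non-negative ints."""
    parts = version.split(".")
    if len(parts) != 2:
        raise ValidationError(f"version must be MAJOR.MINOR, got {version!r}")
    try:
        major, minor = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValidationError(f"non-integer version component in {version!r}") from exc
    if major < 0 or minor < 0:
        raise ValidationError(f"negative version component in {version!r}")
    return major, minor


@dataclass
class LayerRecord:
    """Registry entry for one layer: identity, provenance and checksum."""

    layer_id: str
    layer_type: str
    provenance: str = ""
    added_in_version: str = ""
    checksum: str = ""

    def __post_init__(self) -> None:
        if self.layer_type not in LAYER_TYPES:
            raise ValidationError(
                f"unknown layer_type {self.layer_type!r}; expected one of {LAYER_TYPES}"
            )
        if not self.layer_id:
            raise ValidationError("layer_id must be non-empty")


@dataclass
class ChangeLogEntry:
    version: str
    timestamp: str
    description: str
    layers_added: list[str] = field(default_factory=list)
    layers_removed: list[str] = field(default_factory=list)


@dataclass
class PackageManifest:
    package_name: str
    package_kind: str
    version: str = "1.0"
    doi: Optional[str] = None
    created: str = ""
    modified: str = ""
    layers: list[LayerRecord] = field(default_factory=list)
    changelog: list[ChangeLogEntry] = field(default_factory=list)

    def layer_ids(self) -> list[str]:
        return [rec.layer_id for rec in self.layers]

    def get_layer_record(self, layer_id: str) -> LayerRecord:
        for rec in self.layers:
            if rec.layer_id == layer_id:
                return rec
        raise NotFoundError(f"no layer {layer_id!r} in package")


class DigitalMicrobePackage:
    """In-memory handle on a digital-microbe data package.

    Attributes
    ----------
    manifest : PackageManifest
    contigs : dict[str, ContigRecord]
        The genome spine (filled by :mod:`digitalmicrobe.genome_store`).
    gene_calls : dict[int, GeneCall]
    annotations : pandas.DataFrame
        Long-format table (gene_id, source, accession, function, score).
    layers : dict[str, Payload]
        Layer payloads keyed by layer_id.
    pangenome : PangenomeStore or None
    """

    def __init__(self, manifest: PackageManifest):
        self.manifest = manifest
        self.contigs: dict = {}
        self.gene_calls: dict = {}
        self.annotations = pd.DataFrame(
            columns=["gene_id", "source", "accession", "function", "score"]
        )
        self.layers: dict[str, Payload] = {}
        self.pangenome = None

    # -- version bookkeeping -------------------------------------------------

    def _bump(self, which: str, description: str, added=(), removed=()) -> None:
        major, minor = parse_version(self.manifest.version)
        if which == "minor":
            minor += 1
        elif which == "major":
            major, minor = major + 1, 0
        else:  # pragma: no cover - internal misuse
            raise ValueError(which)
        self.manifest.version = f"{major}.{minor}"
        self.manifest.modified = _utcnow()
        self.manifest.changelog.append(
            ChangeLogEntry(
                version=self.manifest.version,
                timestamp=self.manifest.modified,
                description=description,
                layers_added=list(added),
                layers_removed=list(removed),
            )
        )

    def get_layer(self, layer_id: str) -> Payload:
        if layer_id not in self.layers:
            raise NotFoundError(f"no layer {layer_id!r} in package")
        return self.layers[layer_id]

    def has_layer(self, layer_id: str) -> bool:
        return layer_id in self.layers


def create_package(name: str, kind: str, doi: Optional[str] = None) -> DigitalMicrobePackage:
    """Create an empty package at version 1.0 with a 'created' changelog entry."""
    if not name:
        raise ValidationError("package name must be non-empty")
    if kind not in PACKAGE_KINDS:
        raise ValidationError(f"package kind must be one of {PACKAGE_KINDS}, got {kind!r}")
    now = _utcnow()
    manifest = PackageManifest(
        package_name=name,
        package_kind=kind,
        version="1.0",
        doi=doi,
        created=now,
        modified=now,
        changelog=[ChangeLogEntry(version="1.0", timestamp=now, description="created")],
    )
    return DigitalMicrobePackage(manifest)


def register_layer(
    pkg: DigitalMicrobePackage,
    record: LayerRecord,
    content: Payload,
) -> PackageManifest:
    """Store *content* under ``record.layer_id`` and bump the MINOR version.

    The checksum is computed here from the canonical serialization of the
    content; previously registered layers are untouched (their checksums stay
    bit-identical). Registering an already-present layer_id is a conflict.
    """
    if record.layer_id in pkg.layers:
        raise ConflictError(f"layer {record.layer_id!r} already registered")
    record.checksum = checksum(content)
    pkg.layers[record.layer_id] = content
    pkg._bump("minor", f"registered layer {record.layer_id}", added=[record.layer_id])
    record.added_in_version = pkg.manifest.version
    pkg.manifest.layers.append(record)
    return pkg.manifest


def update_layer(pkg: DigitalMicrobePackage, layer_id: str, content: Payload,
                 description: str = "") -> PackageManifest:
    """Replace an existing layer's content (curation); bumps MINOR."""
    rec = pkg.manifest.get_layer_record(layer_id)
    pkg.layers[layer_id] = content
    rec.checksum = checksum(content)
    pkg._bump("minor", description or f"updated layer {layer_id}", added=[layer_id])
    return pkg.manifest


def remove_layer(pkg: DigitalMicrobePackage, layer_id: str) -> PackageManifest:
    """Remove a layer; destructive, so bumps MAJOR."""
    pkg.manifest.get_layer_record(layer_id)  # raises if absent
    del pkg.layers[layer_id]
    pkg.manifest.layers = [r for r in pkg.manifest.layers if r.layer_id != layer_id]
    pkg._bump("major", f"removed layer {layer_id}", removed=[layer_id])
    return pkg.manifest


def verify_integrity(pkg: DigitalMicrobePackage) -> list[tuple[str, str]]:
    """Check every layer against its recorded checksum.

    Returns one ``(layer_id, status)`` pair per registered layer, where
    status is ``"ok"`` or ``"mismatch: <reason>"``.
    """
    report = []
    for rec in pkg.manifest.layers:
        if rec.layer_id not in pkg.layers:
            report.append((rec.layer_id, "mismatch: content missing"))
            continue
        try:
            actual = checksum(pkg.layers[rec.layer_id])
        except Exception as exc:  # unreadable/unserializable content
            report.append((rec.layer_id, f"mismatch: unreadable ({exc})"))
            continue
        if actual == rec.checksum:
            report.append((rec.layer_id, "ok"))
        else:
            report.append((rec.layer_id, "mismatch: checksum differs"))
    return report


# -- universal-format export / import ----------------------------------------

_PAYLOAD_EXT = {"table": ".tsv", "sequences": ".fasta", "text": ".nwk"}


def _payload_kind(content: Payload) -> str:
    if isinstance(content, pd.DataFrame):
        return "table"
    if isinstance(content, dict):
        return "sequences"
    return "text"


def _safe_filename(layer_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in layer_id)


def _write_payload(content: Payload, path: Path) -> None:
    kind = _payload_kind(content)
    if kind == "table":
        # stringify first: Python's shortest float repr survives a
        # write/parse cycle exactly, pandas' default float formatting does not
        content.astype(str).to_csv(path, sep="\t", index=False)
    elif kind == "sequences":
        with open(path, "w") as fh:
            for key in sorted(content):
                fh.write(f">{key}\n{content[key]}\n")
    else:
        path.write_text(content)


def _read_payload(path: Path, kind: str) -> Payload:
    if kind == "table":
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    if kind == "sequences":
        seqs: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip())
        if name is not None:
            seqs[name] = "".join(chunks)
        return seqs
    return path.read_text()


def _manifest_to_dict(manifest: PackageManifest) -> dict:
    return {
        "package_name": manifest.package_name,
        "package_kind": manifest.package_kind,
        "version": manifest.version,
        "doi": manifest.doi,
        "created": manifest.created,
        "modified": manifest.modified,
        "layers": [asdict(rec) for rec in manifest.layers],
        "changelog": [asdict(entry) for entry in manifest.changelog],
    }


def _manifest_from_dict(data: dict) -> PackageManifest:
    return PackageManifest(
        package_name=data["package_name"],
        package_kind=data["package_kind"],
        version=data["version"],
        doi=data.get("doi"),
        created=data.get("created", ""),
        modified=data.get("modified", ""),
        layers=[LayerRecord(**rec) for rec in data["layers"]],
        changelog=[ChangeLogEntry(**entry) for entry in data["changelog"]],
    )


def export_package(pkg: DigitalMicrobePackage, out_dir) -> list[Path]:
    """Write the package as a directory of universal formats.

    Layout: ``manifest.json`` (manifest + a file map), ``genome.fasta`` and
    ``gene_calls.tsv`` for the genome spine, and ``layers/<id>.<ext>`` per
    layer (TSV for tables, FASTA for sequence sets, newick for trees).
    """
    out = Path(out_dir)
    (out / "layers").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    file_map = {}
    for rec in pkg.manifest.layers:
        content = pkg.layers[rec.layer_id]
        kind = _payload_kind(content)
        fname = _safe_filename(rec.layer_id) + _PAYLOAD_EXT[kind]
        _write_payload(content, out / "layers" / fname)
        file_map[rec.layer_id] = {"file": f"layers/{fname}", "kind": kind}
        written.append(out / "layers" / fname)

    doc = _manifest_to_dict(pkg.manifest)
    doc["layer_files"] = file_map

    if pkg.contigs:
        with open(out / "genome.fasta", "w") as fh:
            for cid in sorted(pkg.contigs):
                fh.write(f">{cid}\n{pkg.contigs[cid].sequence}\n")
        written.append(out / "genome.fasta")
        doc["genome_file"] = "genome.fasta"
    if pkg.gene_calls:
        rows = [
            {
                "gene_id": gc.gene_id,
                "contig": gc.contig_id,
                "start": gc.start,
                "stop": gc.stop,
                "strand": gc.strand,
                "partial": int(gc.partial),
                "source": gc.source,
            }
            for gc in sorted(pkg.gene_calls.values(), key=lambda g: g.gene_id)
        ]
        pd.DataFrame(rows).to_csv(out / "gene_calls.tsv", sep="\t", index=False)
        written.append(out / "gene_calls.tsv")
        doc["gene_calls_file"] = "gene_calls.tsv"

    with open(out / "manifest.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    written.append(out / "manifest.json")
    return written


def import_package(in_dir) -> DigitalMicrobePackage:
    """Reconstruct a package from an export directory.

    Every layer's checksum is recomputed on read and verified against the
    manifest; a missing file or a digest mismatch aborts the import, naming
    the offending layer.
    """
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"no manifest.json in {src}")
    doc = json.loads(manifest_path.read_text())
    manifest = _manifest_from_dict(doc)
    pkg = DigitalMicrobePackage(manifest)

    for rec in manifest.layers:
        entry = doc["layer_files"].get(rec.layer_id)
        if entry is None:
            raise IntegrityError(f"manifest lists layer {rec.layer_id!r} but no file entry")
        path = src / entry["file"]
        if not path.exists():
            raise IntegrityError(f"layer {rec.layer_id!r}: file {entry['file']} missing")
        content = _read_payload(path, entry["kind"])
        actual = checksum(content)
        if actual != rec.checksum:
            raise IntegrityError(
                f"layer {rec.layer_id!r}: checksum mismatch on import "
                f"(expected {rec.checksum[:12]}…, got {actual[:12]}…)"
            )
        pkg.layers[rec.layer_id] = content

    if "genome_file" in doc:
        from .genome_store import ContigRecord

        seqs = _read_payload(src / doc["genome_file"], "sequences")
        pkg.contigs = {
            cid: ContigRecord(contig_id=cid, sequence=seq) for cid, seq in seqs.items()
        }
    if "gene_calls_file" in doc:
        from .genome_store import GeneCall

        table = pd.read_csv(src / doc["gene_calls_file"], sep="\t")
        for row in table.itertuples(index=False):
            pkg.gene_calls[int(row.gene_id)] = GeneCall(
                gene_id=int(row.gene_id),
                contig_id=str(row.contig),
                start=int(row.start),
                stop=int(row.stop),
                strand=str(row.strand),
                partial=bool(row.partial),
                source=str(row.source),
            )
    return pkg


# -- single-file SQLite persistence -------------------------------------------


def save_package(pkg: DigitalMicrobePackage, path) -> None:
    """Persist the package into a single SQLite file (queryable store)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        con.execute(
            "CREATE TABLE layers (layer_id TEXT PRIMARY KEY, kind TEXT, payload BLOB)"
        )
        doc = _manifest_to_dict(pkg.manifest)
        con.execute("INSERT INTO meta VALUES ('manifest', ?)", (json.dumps(doc),))
        for rec in pkg.manifest.layers:
            content = pkg.layers[rec.layer_id]
            kind = _payload_kind(content)
            if kind == "table":
                blob = content.astype(str).to_csv(sep="\t", index=False).encode("utf-8")
            else:
                blob = canonical_bytes(content)
            con.execute(
                "INSERT INTO layers VALUES (?, ?, ?)", (rec.layer_id, kind, blob)
            )
        if pkg.contigs:
            con.execute("CREATE TABLE contigs (contig_id TEXT PRIMARY KEY, sequence TEXT)")
            con.executemany(
                "INSERT INTO contigs VALUES (?, ?)",
                [(cid, rec.sequence) for cid, rec in pkg.contigs.items()],
            )
        if pkg.gene_calls:
            con.execute(
                "CREATE TABLE gene_calls (gene_id INTEGER PRIMARY KEY, contig TEXT, "
                "start INTEGER, stop INTEGER, strand TEXT, partial INTEGER, source TEXT)"
            )
            con.executemany(
                "INSERT INTO gene_calls VALUES (?, ?, ?, ?, ?, ?, ?)",
                [
                    (g.gene_id, g.contig_id, g.start, g.stop, g.strand, int(g.partial), g.source)
                    for g in pkg.gene_calls.values()
                ],
            )
        con.commit()
    finally:
        con.close()


def open_package(path) -> DigitalMicrobePackage:
    """Load a package previously written by :func:`save_package`."""
    import io as _io

    path = Path(path)
    if not path.exists():
        raise NotFoundError(f"no package file at {path}")
    con = sqlite3.connect(path)
    try:
        doc = json.loads(
            con.execute("SELECT value FROM meta WHERE key='manifest'").fetchone()[0]
        )
        pkg = DigitalMicrobePackage(_manifest_from_dict(doc))
        for layer_id, kind, blob in con.execute("SELECT * FROM layers"):
            text = blob.decode("utf-8") if isinstance(blob, bytes) else blob
            if kind == "table":
                pkg.layers[layer_id] = pd.read_csv(
                    _io.StringIO(text), sep="\t", float_precision="round_trip"
                )
            elif kind == "sequences":
                seqs: dict[str, str] = {}
                name = None
                for line in text.splitlines():
                    if line.startswith(">"):
                        name = line[1:]
                        seqs[name] = ""
                    elif name is not None:
                        seqs[name] += line
                pkg.layers[layer_id] = seqs
            else:
                pkg.layers[layer_id] = text
        tables = {
            row[0]
            for row in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        if "contigs" in tables:
            from .genome_store import ContigRecord

            for cid, seq in con.execute("SELECT * FROM contigs"):
                pkg.contigs[cid] = ContigRecord(contig_id=cid, sequence=seq)
        if "gene_calls" in tables:
            from .genome_store import GeneCall

            for gid, contig, start, stop, strand, partial, source in con.execute(
                "SELECT * FROM gene_calls"
            ):
                pkg.gene_calls[gid] = GeneCall(
                    gene_id=gid, contig_id=contig, start=start, stop=stop,
                    strand=strand, partial=bool(partial), source=source,
                )
        return pkg
    finally:
        con.close()
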