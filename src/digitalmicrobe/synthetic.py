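"""Deterministic synthetic data generators.

Every input class the toolkit consumes can be generated here at toy scale:
genomes with gene calls and multi-source annotations (including CAZyme
accessions and a transporter collection with substrate-binding / permease /
ATPase group labels), per-sample read-count tables, protein families for
pangenome clustering, and presence/absence matrices with known core and
accessory truth under completeness dropout.

All generators draw from :func:`numpy.random.default_rng` streams seeded as
``(master_seed, stream_id)`` so each generator has its own independent
stream — adding a new generator never perturbs the output of existing ones
— and the same spec always yields byte-identical files.

The defaults emulate a small marine heterotroph study: a ~25 kb two-contig
"genome" with 64% GC (roseobacter-like), 30 genes on both strands, three
transporter systems of three components each, and a 30-genome pangenome
with 200 core and 800 accessory clusters whose per-genome presence
probability is uniform on (0.05, 0.5) and whose genomes have completeness
uniform on (0.7, 0.95) — i.e. MAG-quality drafts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pangenome import GenomeEntry

_STREAMS = {
    "genome": 1,
    "coverage": 2,
    "pangenome": 3,
    "proteins": 4,
    "dna": 5,
    "proteome": 6,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CAZY_FAMILIES = (
    "GH13", "GH5", "GH3", "GT2", "GT4", "PL1", "PL7", "CE1", "AA3", "CBM48", "CBM50",
)
_TRANSPORTER_ROLES = ("substrate_binding", "permease", "ATPase")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class FixtureSpec:
    """Parameters for the synthetic generators (counts >= 0, probs in [0,1])."""

    seed: int = 0
    # genome
    n_contigs: int = 2
    genome_length: int = 25_000
    gc: float = 0.64
    n_genes: int = 30
    n_transporter_systems: int = 3
    # coverage samples
    n_samples: int = 4
    library_size: int = 100_000
    # pangenome
    n_genomes: int = 30
    n_core_clusters: int = 200
    n_accessory_clusters: int = 800
    accessory_presence_range: tuple = (0.05, 0.5)
    completeness_range: tuple = (0.7, 0.95)

    def __post_init__(self) -> None:
        for name in ("n_contigs", "genome_length", "n_genes", "n_samples",
                     "library_size", "n_genomes", "n_core_clusters",
                     "n_accessory_clusters"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError("gc must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome + annotations + collection


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@dataclass
class SimulatedGenome:
    contigs: dict
    gene_calls: pd.DataFrame  # gene_id, contig, start, stop, strand, partial
    annotations: dict  # source -> DataFrame(gene_id, accession, function, score)
    collection: pd.DataFrame  # gene_id, group (transporter system / role)

    def write(self, out_dir) -> dict[str, Path]:
        """Write files readable by the corresponding import operations."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta = out / "genome.fasta"
        with open(fasta, "w") as fh:
            for cid in sorted(self.contigs):
                fh.write(f">{cid}\n{self.contigs[cid]}\n")
        paths["fasta"] = fasta
        calls = out / "gene_calls.tsv"
        self.gene_calls.to_csv(calls, sep="\t", index=False)
        paths["gene_calls"] = calls
        for source, table in self.annotations.items():
            p = out / f"annotations_{source}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths[f"annotations_{source}"] = p
        coll = out / "collection.tsv"
        self.collection.to_csv(coll, sep="\t", index=False)
        paths["collection"] = coll
        return paths


def simulate_genome(spec: FixtureSpec) -> SimulatedGenome:
    """Toy genome: non-overlapping genes on both strands, within contigs.

    Gene lengths are multiples of 3 between 300 and 900 bp. Annotations
    comprise a curated "custom" source labelling the transporter components
    and a "CAZyme" source assigning CAZy family accessions to a subset of
    the non-transporter genes (some genes get two hits in distinct
    categories, exercising the multi-domain counting rule).
    """
    rng = _rng(spec.seed, "genome")
    lengths = _split_lengths(spec.genome_length, spec.n_contigs)
    contigs = {
        f"contig_{i + 1}": random_dna(rng, length, spec.gc)
        for i, length in enumerate(sorted(lengths, reverse=True))
    }

    rows = []
    gene_id = 0
    contig_ids = sorted(contigs)
    ci = 0
    cursor = {cid: 10 for cid in contig_ids}
    while gene_id < spec.n_genes:
        cid = contig_ids[ci % len(contig_ids)]
        glen = int(rng.integers(100, 301)) * 3
        start = cursor[cid]
        stop = start + glen
        if stop > len(contigs[cid]) - 10:
            ci += 1
            if all(cursor[c] + 309 > len(contigs[c]) - 10 for c in contig_ids):
                raise ValidationError(
                    "genome too short for requested gene count; increase genome_length"
                )
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {"gene_id": gene_id, "contig": cid, "start": start, "stop": stop,
             "strand": strand, "partial": 0}
        )
        cursor[cid] = stop + int(rng.integers(5, 40))
        gene_id += 1
        ci += 1
    gene_calls = pd.DataFrame(rows)

    # transporter collection: systems x (substrate_binding, permease, ATPase)
    n_transporter_genes = spec.n_transporter_systems * len(_TRANSPORTER_ROLES)
    if n_transporter_genes > spec.n_genes:
        raise ValidationError("more transporter components than genes")
    transporter_ids = list(range(n_transporter_genes))
    coll_rows = []
    custom_rows = []
    for s in range(spec.n_transporter_systems):
        for r, role in enumerate(_TRANSPORTER_ROLES):
            gid = transporter_ids[s * len(_TRANSPORTER_ROLES) + r]
            system = f"system_{s + 1}"
            coll_rows.append({"gene_id": gid, "group": system})
            custom_rows.append(
                {"gene_id": gid, "accession": f"TRANS{s + 1:02d}{r + 1}",
                 "function": f"{system} {role}", "score": 0.0}
            )
    collection = pd.DataFrame(coll_rows)

    # CAZyme annotations on a subset of the remaining genes
    other = [g for g in range(spec.n_genes) if g not in set(transporter_ids)]
    caz_rows = []
    n_caz = max(3, len(other) // 3)
    chosen = list(rng.choice(other, size=min(n_caz, len(other)), replace=False))
    for k, gid in enumerate(sorted(int(g) for g in chosen)):
        fam = _CAZY_FAMILIES[int(rng.integers(len(_CAZY_FAMILIES)))]
        caz_rows.append({"gene_id": gid, "accession": fam,
                         "function": f"CAZy family {fam}", "score": 1e-20})
        if k == 0:  # one multi-domain gene: GH + CBM hits
            caz_rows.append({"gene_id": gid, "accession": "CBM48",
                             "function": "CAZy family CBM48", "score": 1e-10})

    return SimulatedGenome(
        contigs=contigs,
        gene_calls=gene_calls,
        annotations={
            "custom": pd.DataFrame(custom_rows),
            "CAZyme": pd.DataFrame(caz_rows),
        },
        collection=collection,
    )


def _split_lengths(total: int, parts: int) -> list[int]:
    base = total // parts
    lengths = [base] * parts
    lengths[0] += total - base * parts
    return lengths


# ---------------------------------------------------------------------------
# coverage samples


def simulate_coverage_samples(
    spec: FixtureSpec,
    rates: np.ndarray,
    gene_lengths: np.ndarray,
    n_samples: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample read-count tables, multinomial over rates x lengths.

    ``rates`` are per-gene transcript abundances (the proportional-expression
    truth, recoverable after TPM normalization); read counts are then
    proportional to rate x gene length at the stated library size. Mean
    coverage is derived assuming 100-bp reads.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValidationError("rates must be non-negative")
    lengths = np.asarray(gene_lengths, dtype=float)
    if rates.shape != lengths.shape:
        raise ValidationError("rates and gene_lengths must align")
    rng = _rng(spec.seed, "coverage")
    n_samples = spec.n_samples if n_samples is None else n_samples
    weights = rates * lengths
    if weights.sum() == 0:
        raise ValidationError("all rates zero")
    p = weights / weights.sum()
    samples = {}
    for s in range(n_samples):
        counts = rng.multinomial(spec.library_size, p)
        samples[f"S{s + 1:02d}"] = pd.DataFrame(
            {
                "gene_id": np.arange(len(rates)),
                "read_count": counts,
                "mean_coverage": counts * 100.0 / lengths,
            }
        )
    return samples


def simulate_condition_groups(
    spec: FixtureSpec,
    base_rates: np.ndarray,
    gene_lengths: np.ndarray,
    fold_change: float,
    affected_gene: int,
    n_per_group: int,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Two sample groups differing by a fold change on one gene.

    Returns the samples plus a design Series (sample -> condition).
    """
    rng = _rng(spec.seed, "coverage")
    lengths = np.asarray(gene_lengths, dtype=float)
    samples, design = {}, {}
    for cond, mult in (("control", 1.0), ("treatment", fold_change)):
        rates = np.asarray(base_rates, dtype=float).copy()
        rates[affected_gene] *= mult
        weights = rates * lengths
        p = weights / weights.sum()
        for s in range(n_per_group):
            sid = f"{cond}_{s + 1}"
            counts = rng.multinomial(spec.library_size, p)
            samples[sid] = pd.DataFrame(
                {
                    "gene_id": np.arange(len(rates)),
                    "read_count": counts,
                    "mean_coverage": counts * 100.0 / lengths,
                }
            )
            design[sid] = cond
    return samples, pd.Series(design)


# ---------------------------------------------------------------------------
# protein families (pangenome clustering fixtures)


def random_protein(rng: np.random.Generator, length: int = 120) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def simulate_protein_families(
    seed: int,
    n_genomes: int = 3,
    n_shared: int = 5,
    n_unique: int = 2,
) -> dict[str, GenomeEntry]:
    """Genomes sharing ``n_shared`` identical protein families plus
    ``n_unique`` unrelated proteins each — the pangenome clustering ground
    truth is n_shared clusters of size n_genomes plus singletons."""
    rng = _rng(seed, "proteins")
    shared = [random_protein(rng) for _ in range(n_shared)]
    genomes = {}
    for g in range(n_genomes):
        gid = f"G{g + 1:02d}"
        proteins = {}
        for k, seq in enumerate(shared):
            proteins[f"shared_{k}"] = seq
        for u in range(n_unique):
            proteins[f"unique_{u}"] = random_protein(rng)
        genomes[gid] = GenomeEntry(genome_id=gid, proteins=proteins)
    return genomes


# ---------------------------------------------------------------------------
# pangenome presence/absence with completeness dropout


def simulate_pangenome(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Observed presence matrix + completeness + true labels.

    True presence: core clusters in every genome; accessory clusters present
    per genome with a per-cluster Bernoulli probability drawn uniformly from
    ``accessory_presence_range``. The observation applies completeness
    dropout: a truly present gene is seen with probability c_i.

    Returns ``(presence, completeness, truth)`` where truth is
    "core"/"accessory" per cluster.
    """
    rng = _rng(spec.seed, "pangenome")
    n, kc, ka = spec.n_genomes, spec.n_core_clusters, spec.n_accessory_clusters
    lo, hi = spec.completeness_range
    completeness = pd.Series(
        rng.uniform(lo, hi, size=n), index=[f"g{i + 1:03d}" for i in range(n)]
    )
    plo, phi = spec.accessory_presence_range
    acc_probs = rng.uniform(plo, phi, size=ka)

    true = np.zeros((kc + ka, n), dtype=int)
    true[:kc, :] = 1
    true[kc:, :] = rng.random((ka, n)) < acc_probs[:, None]
    dropout = rng.random((kc + ka, n)) < completeness.to_numpy()[None, :]
    observed = true * dropout

    index = [f"GC_{i + 1:08d}" for i in range(kc + ka)]
    presence = pd.DataFrame(observed, index=index, columns=completeness.index)
    truth = pd.Series(
        ["core"] * kc + ["accessory"] * ka, index=index, name="truth"
    )
    return presence, completeness, truth


# ---------------------------------------------------------------------------
# DNA fixtures for ANI


def simulate_dna_pair(
    seed: int,
    length: int = 10_200,
    gc: float = 0.5,
    substitutions_per_fragment: int = 1,
    fragment_bp: int = 1020,
) -> tuple[str, str]:
    """A random sequence and a copy with a fixed number of substitutions in
    each ``fragment_bp`` window (for exact-identity ANI checks)."""
    rng = _rng(seed, "dna")
    original = random_dna(rng, length, gc)
    mutated = list(original)
    for off in range(0, length - fragment_bp + 1, fragment_bp):
        positions = rng.choice(fragment_bp, size=substitutions_per_fragment, replace=False)
        for pos in positions:
            old = mutated[off + pos]
            mutated[off + pos] = rng.choice([b for b in "ACGT" if b != old])
    return original, "".join(mutated)
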