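"""Seeded synthetic test worlds: taxonomy, evolved genomes, query reads.

The world is a balanced taxonomy whose species each carry one reference
genome. The root genome is drawn uniformly over ACGT and every child genome
is its parent mutated by i.i.d. substitutions at a per-level rate (uniform
choice among the three alternative bases; no indels, so Hamming geometry is
exact). Queries are references mutated at a controlled nucleotide distance
— the novelty axis — from which error-bearing reads are sampled on either
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lshtax.taxonomy import TaxonomyTree

__all__ = [
    "SynthConfig",
    "SynthWorld",
    "QuerySet",
    "generate_world",
    "generate_queries",
    "write_world",
    "write_queries",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """Desk-scale defaults: 2x2x2x3 = 24 species of 100 kb, readable in
    seconds. ``levels`` lists (rank, branching factor, expected
    substitutions per site on each branch of that level), highest rank
    first; the root is a superkingdom node."""

    seed: int = 0
    levels: tuple[tuple[str, int, float], ...] = (
        ("phylum", 2, 0.20),
        ("family", 2, 0.12),
        ("genus", 2, 0.08),
        ("species", 3, 0.06),
    )
    genome_length: int = 100_000
    read_length: int = 150
    reads_per_query: int = 2000
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for rank, branching, divergence in self.levels:
            if branching < 1:
                raise ValueError(f"branching at {rank} must be >= 1")
            if not 0.0 <= divergence < 0.75:
                raise ValueError(f"divergence at {rank} must be in [0, 0.75)")
        if self.levels[-1][0] != "species":
            raise ValueError("lowest level must be species")


@dataclass
class SynthWorld:
    config: SynthConfig
    tree: TaxonomyTree
    genomes: dict[str, str]          # genome_id -> sequence
    genome_to_taxid: dict[str, int]  # external taxids


@dataclass
class QuerySet:
    query_id: str
    donor_genome: str
    requested_novelty: float
    realized_novelty: float
    reads: list[tuple[str, str]]                 # (read_id, sequence)
    truth: dict[str, str] = field(default_factory=dict)  # read_id -> donor


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-style substitution: each site flips with probability
    ``rate`` to one of the 3 alternative bases, uniformly."""
    if rate == 0.0:
        return seq_codes.copy()
    hit = rng.random(seq_codes.size) < rate
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out = seq_codes.copy()
    out[hit] = (out[hit] + shifts) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def generate_world(config: SynthConfig = SynthConfig()) -> SynthWorld:
    """Evolve reference genomes down a balanced taxonomy; deterministic
    under the config seed (byte-identical FASTA on re-run)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    root_codes = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)

    records = [(1, 1, "superkingdom", "SK_root")]
    next_taxid = [2]
    genomes: dict[str, str] = {}
    genome_to_taxid: dict[str, int] = {}

    def expand(parent_taxid: int, parent_codes: np.ndarray, level: int, path: str):
        rank, branching, divergence = config.levels[level]
        for i in range(branching):
            taxid = next_taxid[0]
            next_taxid[0] += 1
            name = f"{rank[0]}{path}{i}"
            records.append((taxid, parent_taxid, rank, name))
            child_codes = _mutate(parent_codes, divergence, rng)
            if level + 1 < len(config.levels):
                expand(taxid, child_codes, level + 1, f"{path}{i}")
            else:
                gid = f"G_{name}"
                genomes[gid] = _codes_to_str(child_codes)
                genome_to_taxid[gid] = taxid

    expand(1, root_codes, 0, "")
    tree = TaxonomyTree.from_edges(records)
    tree.attach_genomes(genome_to_taxid, {g: len(s) for g, s in genomes.items()})
    return SynthWorld(config, tree, genomes, genome_to_taxid)


def generate_queries(
    world: SynthWorld,
    novelty: float,
    n_reads: int | None = None,
    read_length: int | None = None,
    error_rate: float | None = None,
    seed: int = 0,
    donor: str | None = None,
) -> QuerySet:
    """Sample reads from a query genome at controlled novelty.

    The query genome is a chosen reference (default: the first genome id
    in sorted order) mutated at per-site rate ``novelty``; reads are
    uniform substrings drawn from either strand with i.i.d. substitution
    errors. The truth table records the donor for every read.
    """
    if not 0.0 <= novelty < 0.75:
        raise ValueError(f"novelty {novelty} unattainable (need 0 <= d < 0.75)")
    cfg = world.config
    n_reads = cfg.reads_per_query if n_reads is None else n_reads
    read_length = cfg.read_length if read_length is None else read_length
    error_rate = cfg.error_rate if error_rate is None else error_rate
    donor = sorted(world.genomes)[0] if donor is None else donor
    if donor not in world.genomes:
        raise KeyError(f"unknown donor genome {donor!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 2, int(round(novelty * 1e6))])
    )
    donor_codes = _str_to_codes(world.genomes[donor])
    query_codes = _mutate(donor_codes, novelty, rng)
    realized = float(np.mean(query_codes != donor_codes))
    if query_codes.size < read_length:
        raise ValueError("genome shorter than read length")
    starts = rng.integers(0, query_codes.size - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads, truth = [], {}
    qid = f"{donor}_d{novelty:g}"
    for i in range(n_reads):
        fragment = query_codes[starts[i] : starts[i] + read_length]
        fragment = _mutate(fragment, error_rate, rng)
        if strands[i]:
            fragment = (3 - fragment)[::-1]
        read_id = f"{qid}_r{i}"
        reads.append((read_id, _codes_to_str(fragment)))
        truth[read_id] = donor
    return QuerySet(qid, donor, novelty, realized, reads, truth)


# ------------------------------------------------------------------ writers

def write_world(world: SynthWorld, outdir: str | Path) -> None:
    """Emit one FASTA per genome, a reference list TSV
    (genome_id, taxid, fasta_path) and NCBI-dump-style taxonomy files."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    rows = []
    for gid in sorted(world.genomes):
        path = outdir / "genomes" / f"{gid}.fasta"
        seq = world.genomes[gid]
        with open(path, "w") as fh:
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        rows.append(f"{gid}\t{world.genome_to_taxid[gid]}\t{path}")
    (outdir / "references.tsv").write_text("\n".join(rows) + "\n")
    nodes_lines, names_lines = [], []
    for node in sorted(world.tree.nodes.values(), key=lambda n: n.taxid):
        parent_taxid = world.tree.nodes[node.parent].taxid
        nodes_lines.append(f"{node.taxid}\t|\t{parent_taxid}\t|\t{node.rank}\t|")
        names_lines.append(f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|")
    (outdir / "nodes.dmp").write_text("\n".join(nodes_lines) + "\n")
    (outdir / "names.dmp").write_text("\n".join(names_lines) + "\n")


def write_queries(queries: QuerySet, world: SynthWorld, outdir: str | Path) -> None:
    """Emit reads as FASTQ (uniform quality) and a truth TSV with the
    donor's full lineage and realized distance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{queries.query_id}.fastq", "w") as fh:
        for read_id, seq in queries.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    tree = world.tree
    donor_taxon = tree.genome_to_taxon[queries.donor_genome]
    lineage = ";".join(
        f"{tree.nodes[t].rank}:{tree.nodes[t].name}"
        for t in tree.lineage(donor_taxon)
    )
    with open(outdir / f"{queries.query_id}.truth.tsv", "w") as fh:
        fh.write("read_id\tdonor_genome\tdonor_taxid\tlineage\trealized_distance\n")
        for read_id, _ in queries.reads:
            fh.write(
                f"{read_id}\t{queries.donor_genome}\t"
                f"{tree.nodes[donor_taxon].taxid}\t{lineage}\t"
                f"{queries.realized_novelty:.6f}\n"
            )
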