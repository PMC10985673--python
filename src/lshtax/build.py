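"""Reference library construction: k-mer collection with genome-occurrence
counts, then probabilistic soft-LCA taxon labeling.

Every stored k-mer carries a single 2-byte taxon label. Processing the
reference genomes, the label of k-mer ``x_i`` is updated to the LCA of its
current value and the species of genome ``g`` with probability

    p_update(N_i) = min( w / max(N_i + w - s, w) + 1/s**2 , 1 )

where ``N_i`` is the number of genomes containing ``x_i`` (pre-computed).
Rare k-mers (N_i <= s) are always labeled; widely shared k-mers ignore most
genomes, so one outlier genome rarely pushes the label to a high rank, yet
the ``1/s**2`` floor keeps a nonzero labeling chance for every k-mer.

Update coins are seeded per (k-mer value, genome ID), which makes the label
assignment exactly invariant to genome processing order (LCA accumulation
over the set of successful genomes is order-free).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from lshtax.lsh import LshIndex, LshParams, HashSpec
from lshtax.seqcodec import canonical_window_values
from lshtax.taxonomy import TaxonomyTree

__all__ = [
    "SoftLcaParams",
    "p_update",
    "KmerCounts",
    "genome_kmer_values",
    "count_genome_occurrences",
    "assign_soft_lca",
    "build_library",
]


@dataclass(frozen=True)
class SoftLcaParams:
    """Shape of the label-update probability: ``w`` sets the decrease rate,
    ``s`` the offset below which updates are certain."""

    w: int = 4
    s: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w < 1 or self.s < 1:
            raise ValueError("w and s must be >= 1")


def p_update(n_genomes: int, params: SoftLcaParams = SoftLcaParams()) -> float:
    """Probability of applying a label update for a k-mer found in
    ``n_genomes`` reference genomes; non-increasing, 1 for N <= s, tending
    to 1/s**2 for very common k-mers."""
    if n_genomes < 1:
        raise ValueError("genome count must be >= 1")
    w, s = params.w, params.s
    return min(w / max(n_genomes + w - s, w) + 1.0 / s**2, 1.0)


def _p_update_vec(n: np.ndarray, params: SoftLcaParams) -> np.ndarray:
    w, s = params.w, params.s
    return np.minimum(w / np.maximum(n + w - s, w) + 1.0 / s**2, 1.0)


class KmerCounts:
    """Per-k-mer genome-occurrence counts N_i, keyed by packed value."""

    def __init__(self, values: np.ndarray, counts: np.ndarray):
        self.values = values  # sorted uint64
        self.counts = counts

    def __len__(self) -> int:
        return self.values.size

    def get(self, value: int) -> int:
        i = int(np.searchsorted(self.values, np.uint64(value)))
        if i < self.values.size and self.values[i] == np.uint64(value):
            return int(self.counts[i])
        return 0

    def lookup(self, values: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.values, values)
        pos_c = np.minimum(pos, self.values.size - 1)
        out = np.where(self.values[pos_c] == values, self.counts[pos_c], 0)
        return out.astype(np.int64)


def _as_seq_list(seqs) -> list[str]:
    return [seqs] if isinstance(seqs, str) else list(seqs)


def genome_kmer_values(seqs, params: LshParams) -> np.ndarray:
    """Distinct canonical k-mer values of one genome (per-contig windows;
    k-mers never span contig boundaries)."""
    parts = [canonical_window_values(s, params.k) for s in _as_seq_list(seqs)]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def count_genome_occurrences(genomes, params: LshParams) -> KmerCounts:
    """N_i = number of distinct genomes containing each canonical k-mer
    (repeats within one genome count once).

    ``genomes`` iterates over ``(genome_id, sequence_or_sequences)``.
    """
    per_genome = [genome_kmer_values(seqs, params) for _, seqs in genomes]
    if not per_genome:
        return KmerCounts(np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint32))
    values, counts = np.unique(np.concatenate(per_genome), return_counts=True)
    return KmerCounts(values, counts.astype(np.uint32))


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x ^ (x >> np.uint64(31))


def _coin_uniforms(kmer_values: np.ndarray, genome_id: str, seed: int) -> np.ndarray:
    """Reproducible uniforms in [0, 1), one per k-mer, independent across
    genomes and of processing order."""
    gseed = np.uint64((seed & 0xFFFFFFFF) << 32) | np.uint64(
        zlib.crc32(genome_id.encode())
    )
    mixed = _splitmix64(kmer_values ^ _splitmix64(np.full_like(kmer_values, gseed)))
    return mixed.astype(np.float64) / float(1 << 64)


def assign_soft_lca(
    index: LshIndex,
    genomes,
    counts: KmerCounts,
    tree: TaxonomyTree,
    params: SoftLcaParams = SoftLcaParams(),
) -> None:
    """Label stored k-mers in place via the probabilistic soft-LCA rule.

    ``genomes`` iterates over ``(genome_id, species_taxon, sequences)``
    with internal taxon IDs. Label 0 (unassigned) acts as the identity of
    the LCA, so the first successful update sets the species directly;
    k-mers whose every coin fails keep label 0 and never vote.
    """
    n_taxa = max(tree.nodes) if tree.nodes else 0
    for genome_id, taxon, seqs in genomes:
        if taxon not in tree.nodes:
            raise KeyError(f"genome {genome_id!r} has unknown taxon {taxon}")
        values = genome_kmer_values(seqs, index.params)
        idx = index.find_indices(values)
        stored = idx >= 0
        values, idx = values[stored], idx[stored]
        if values.size == 0:
            continue
        pu = _p_update_vec(counts.lookup(values), params)
        success = _coin_uniforms(values, genome_id, params.seed) < pu
        idx = idx[success]
        if idx.size == 0:
            continue
        # LCA with a fixed species, precomputed over all internal IDs
        lca_map = np.zeros(n_taxa + 1, dtype=np.uint16)
        lca_map[0] = taxon
        for t in tree.nodes:
            lca_map[t] = tree.lca(t, taxon)
        index.labels[idx] = lca_map[index.labels[idx]]


def build_library(
    genomes,
    tree: TaxonomyTree,
    lsh_params: LshParams,
    soft_params: SoftLcaParams = SoftLcaParams(),
    seed: int = 0,
) -> tuple[LshIndex, dict]:
    """End-to-end library build: collect k-mers, insert, count, label.

    ``genomes`` is a sequence of ``(genome_id, sequence_or_sequences)``;
    each genome_id must be registered in ``tree.genome_to_taxon``. Returns
    the labeled index and a small build report.
    """
    genomes = list(genomes)
    for gid, _ in genomes:
        if gid not in tree.genome_to_taxon:
            raise KeyError(f"genome {gid!r} missing from tree.genome_to_taxon")
    counts = count_genome_occurrences(genomes, lsh_params)
    index = LshIndex(lsh_params, HashSpec.generate(lsh_params, seed), seed=seed)
    index.bulk_insert(counts.values)
    index.set_counts(counts.values, counts.counts)
    labeled_genomes = (
        (gid, tree.genome_to_taxon[gid], seqs) for gid, seqs in genomes
    )
    assign_soft_lca(index, labeled_genomes, counts, tree, soft_params)
    labels = index.labels[: len(index)]
    by_rank: dict[str, int] = {}
    for t, n in zip(*np.unique(labels[labels > 0], return_counts=True)):
        rank = tree.nodes[int(t)].rank
        by_rank[rank] = by_rank.get(rank, 0) + int(n)
    report = {
        "num_genomes": len(genomes),
        "num_kmers": len(index),
        "num_labeled": int((labels > 0).sum()),
        "labels_by_rank": by_rank,
        "ni_histogram": {
            int(v): int(c) for v, c in zip(*np.unique(counts.counts, return_counts=True))
        },
        "seed": seed,
    }
    return index, report
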