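"""Per-read taxonomic identification by distance-weighted voting.

Each query k-mer with a best reference match at Hamming distance hd <= d_max
and a nonzero label casts a vote of mass ``(1 - hd/k)**k`` at that label.
Votes are aggregated bottom-up over the taxonomy (a vote for a child counts
toward every ancestor), the majority threshold is tau = half the maximum
aggregated vote (realized at the root), and the read is assigned the taxon
at the lowest rank whose aggregated vote strictly exceeds tau — at most one
taxon per rank can. Assignments whose total vote falls below a small
absolute floor (default 0.03, under two HD-4 matches) are discarded as
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from lshtax.lsh import LshIndex
from lshtax.seqcodec import EncodedKmer, read_to_kmers
from lshtax.taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = [
    "DEFAULT_MIN_TOTAL_VOTE",
    "VoteTable",
    "ReadClassification",
    "vote_value",
    "collect_votes",
    "classify",
    "classify_reads",
]

DEFAULT_MIN_TOTAL_VOTE = 0.03


def vote_value(hd: int, k: int = 32) -> float:
    """Vote mass of a match at Hamming distance ``hd``: (1 - hd/k)**k,
    dropping near-exponentially with distance."""
    if not 0 <= hd <= k:
        raise ValueError(f"hd must be in [0, k], got {hd}")
    return (1.0 - hd / k) ** k


class VoteTable:
    """Per-read vote state: direct votes cast at each taxon and the
    bottom-up aggregated totals (direct plus all descendants)."""

    def __init__(self, tree: TaxonomyTree):
        self.tree = tree
        self.direct: dict[int, float] = {}
        self._totals: dict[int, float] | None = None

    def add_vote(self, taxon: int, mass: float) -> None:
        if taxon not in self.tree.nodes:
            raise KeyError(f"vote for unknown taxon {taxon}")
        self.direct[taxon] = self.direct.get(taxon, 0.0) + mass
        self._totals = None

    def totals(self) -> dict[int, float]:
        """Aggregated vote per taxon; total(t) = direct(t) + sum of child
        totals. Taxa with zero mass are omitted."""
        if self._totals is None:
            agg: dict[int, float] = {}
            for taxon, mass in self.direct.items():
                for anc in self.tree.lineage(taxon):
                    agg[anc] = agg.get(anc, 0.0) + mass
            self._totals = agg
        return dict(self._totals)

    def total(self, taxon: int) -> float:
        return self.totals().get(taxon, 0.0)

    @property
    def root_total(self) -> float:
        return sum(self.direct.values())


@dataclass(frozen=True)
class ReadClassification:
    read_id: str | None
    taxon: int | None
    rank: str | None
    total_vote: float
    root_vote: float

    @property
    def classified(self) -> bool:
        return self.taxon is not None


def collect_votes(
    kmers: Iterable[EncodedKmer | int], index: LshIndex, tree: TaxonomyTree
) -> VoteTable:
    """Cast one vote per query k-mer at its minimum-distance match's label.

    A k-mer votes only when its best match lies within d_max and carries a
    nonzero label; equal-distance label ties break toward the smallest
    internal taxon ID.
    """
    values = np.array(
        [x.value if isinstance(x, EncodedKmer) else int(x) for x in kmers],
        dtype=np.uint64,
    )
    table = VoteTable(tree)
    if values.size == 0:
        return table
    dist, _, taxon = index.lookup_batch(values, tie="label")
    voting = (dist >= 0) & (taxon > 0)
    for hd, t in zip(dist[voting], taxon[voting]):
        table.add_vote(int(t), vote_value(int(hd), index.params.k))
    return table


def classify(
    votes: VoteTable,
    tree: TaxonomyTree,
    min_total_vote: float = DEFAULT_MIN_TOTAL_VOTE,
    read_id: str | None = None,
) -> ReadClassification:
    """Majority-vote rank selection with the tau rule.

    tau is half the root total; ranks are scanned from species upward and
    the first taxon with total > tau wins (strict inequality, so an exact
    half-half species split resolves at the genus). If no votes exist, no
    rank produces a winner, or the winner's total is below
    ``min_total_vote``, the read is unclassified.
    """
    totals = votes.totals()
    root_vote = votes.root_total
    if root_vote <= 0.0:
        return ReadClassification(read_id, None, None, 0.0, 0.0)
    tau = 0.5 * root_vote
    for rank in CANONICAL_RANKS:
        winner, winner_vote = None, tau
        for t in tree.taxa_at_rank(rank):
            v = totals.get(t, 0.0)
            if v > winner_vote:
                winner, winner_vote = t, v
        if winner is not None:
            if winner_vote < min_total_vote:
                return ReadClassification(read_id, None, None, winner_vote, root_vote)
            return ReadClassification(read_id, winner, rank, winner_vote, root_vote)
    return ReadClassification(read_id, None, None, 0.0, root_vote)


def classify_read(
    read: str,
    index: LshIndex,
    tree: TaxonomyTree,
    min_total_vote: float = DEFAULT_MIN_TOTAL_VOTE,
    read_id: str | None = None,
) -> ReadClassification:
    votes = collect_votes(read_to_kmers(read, index.params.k), index, tree)
    return classify(votes, tree, min_total_vote, read_id=read_id)


def classify_reads(
    reads: Sequence[tuple[str, str]],
    index: LshIndex,
    tree: TaxonomyTree,
    min_total_vote: float = DEFAULT_MIN_TOTAL_VOTE,
    collect_matches: bool = False,
):
    """Classify many ``(read_id, sequence)`` pairs.

    Returns ``(classifications, vote_tables)`` in input order (vote tables
    feed the profiler); with ``collect_matches`` also returns per-k-mer
    match records ``(read_id, kmer_index, distance, taxon)``.
    """
    from lshtax.seqcodec import canonical_window_values

    k = index.params.k
    all_values, offsets = [], [0]
    for _, seq in reads:
        vals = canonical_window_values(seq, k)
        all_values.append(vals)
        offsets.append(offsets[-1] + vals.size)
    flat = (
        np.concatenate(all_values) if all_values else np.empty(0, dtype=np.uint64)
    )
    if flat.size:
        dist, _, taxon = index.lookup_batch(flat, tie="label")
    else:
        dist = np.empty(0, dtype=np.int16)
        taxon = np.empty(0, dtype=np.uint16)
    results, tables, matches = [], [], []
    for i, (read_id, _) in enumerate(reads):
        lo, hi = offsets[i], offsets[i + 1]
        table = VoteTable(tree)
        for j in range(lo, hi):
            if dist[j] >= 0:
                if collect_matches:
                    matches.append((read_id, j - lo, int(dist[j]), int(taxon[j])))
                if taxon[j] > 0:
                    table.add_vote(int(taxon[j]), vote_value(int(dist[j]), k))
        tables.append(table)
        results.append(classify(table, tree, min_total_vote, read_id=read_id))
    if collect_matches:
        return results, tables, matches
    return results, tables
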