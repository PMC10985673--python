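"""Two-level normalized taxonomic abundance profiles.

For each rank r, a read's aggregated votes over the taxa at r are first
normalized so every read with matches contributes equally (read-level
normalization); the normalized votes are then summed over reads and
renormalized into the sample profile. In unclassified mode the read-level
denominator is the read's root total, so vote mass cast above rank r (a
match to an LCA taxon is evidence for *some* descendant, but an unknown
one) flows into an artificial "unclassified" taxon at r instead of being
redistributed among the named taxa. Genome-size correction divides by mean
genome length and renormalizes, turning read fractions into cell fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lshtax.classify import VoteTable
from lshtax.taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = [
    "RankProfile",
    "normalize_read",
    "profile_sample",
    "size_correct",
    "write_cami_profile",
    "write_profile_tsv",
]

_SUM_TOL = 1e-9


@dataclass
class RankProfile:
    """Relative abundances over the taxa of one rank plus unclassified mass."""

    rank: str
    abundances: dict[int, float]
    unclassified: float = 0.0
    read_normalized: bool = True
    size_corrected: bool = False

    @property
    def total(self) -> float:
        return sum(self.abundances.values()) + self.unclassified

    def check(self) -> None:
        if self.abundances or self.unclassified:
            if abs(self.total - 1.0) > _SUM_TOL:
                raise AssertionError(f"profile sums to {self.total}, not 1")
        if any(v < 0 for v in self.abundances.values()) or self.unclassified < 0:
            raise AssertionError("negative abundance")


def normalize_read(
    votes: VoteTable,
    rank: str,
    tree: TaxonomyTree,
    include_unclassified: bool = True,
) -> tuple[dict[int, float], float]:
    """Read-level normalized votes at one rank.

    Default denominator is the summed vote over taxa at the rank; in
    unclassified mode it is the root total, with the residual mass
    returned as the unclassified component. A read with no votes (zero
    denominator) contributes nothing.
    """
    totals = votes.totals()
    at_rank = {t: totals[t] for t in tree.taxa_at_rank(rank) if totals.get(t, 0.0) > 0.0}
    rank_sum = sum(at_rank.values())
    if include_unclassified:
        denom = votes.root_total
        residual = denom - rank_sum
    else:
        denom = rank_sum
        residual = 0.0
    if denom <= 0.0:
        return {}, 0.0
    return {t: v / denom for t, v in at_rank.items()}, residual / denom


def profile_sample(
    vote_tables: Sequence[VoteTable],
    tree: TaxonomyTree,
    ranks: Iterable[str] = CANONICAL_RANKS,
    read_normalize: bool = True,
    include_unclassified: bool = True,
) -> dict[str, RankProfile]:
    """Aggregate per-read votes into one profile per rank.

    Default mode normalizes per read first (equal read contributions);
    raw mode (``read_normalize=False``) sums aggregated votes directly, so
    reads with larger total votes weigh more. Ranks are independent.
    """
    if not vote_tables:
        raise ValueError("need at least one read")
    profiles: dict[str, RankProfile] = {}
    for rank in ranks:
        acc: dict[int, float] = {}
        unclassified_acc = 0.0
        for votes in vote_tables:
            if read_normalize:
                contrib, residual = normalize_read(
                    votes, rank, tree, include_unclassified
                )
            else:
                totals = votes.totals()
                contrib = {
                    t: totals[t]
                    for t in tree.taxa_at_rank(rank)
                    if totals.get(t, 0.0) > 0.0
                }
                residual = (
                    votes.root_total - sum(contrib.values())
                    if include_unclassified
                    else 0.0
                )
            for t, v in contrib.items():
                acc[t] = acc.get(t, 0.0) + v
            unclassified_acc += residual
        denom = sum(acc.values()) + unclassified_acc
        if denom > 0.0:
            profile = RankProfile(
                rank,
                {t: v / denom for t, v in acc.items()},
                unclassified_acc / denom,
                read_normalized=read_normalize,
            )
        else:
            profile = RankProfile(rank, {}, 0.0, read_normalized=read_normalize)
        profile.check()
        profiles[rank] = profile
    return profiles


def size_correct(profile: RankProfile, tree: TaxonomyTree) -> RankProfile:
    """Convert read fractions to cell fractions: abundances are rescaled
    proportionally to 1 / (mean genome length of the taxon) and
    renormalized. Unclassified mass has no genome length and is left
    untouched; with uniform lengths the correction is the identity.
    """
    if not profile.abundances:
        return RankProfile(
            profile.rank, {}, profile.unclassified, profile.read_normalized, True
        )
    missing = []
    weights: dict[int, float] = {}
    for t, p in profile.abundances.items():
        try:
            weights[t] = p / tree.mean_genome_length(t)
        except KeyError:
            missing.append(t)
    if missing:
        raise KeyError(f"no genome length for taxa {sorted(missing)}")
    classified_mass = sum(profile.abundances.values())
    wsum = sum(weights.values())
    corrected = {t: classified_mass * w / wsum for t, w in weights.items()}
    out = RankProfile(
        profile.rank, corrected, profile.unclassified, profile.read_normalized, True
    )
    out.check()
    return out


# ----------------------------------------------------------------- writers

_CAMI_RANK_ORDER = tuple(reversed(CANONICAL_RANKS))  # highest first


def _taxpath(tree: TaxonomyTree, taxon: int, names: bool) -> str:
    parts = []
    for anc in tree.lineage(taxon):
        node = tree.nodes[anc]
        if node.rank in CANONICAL_RANKS:
            parts.append(node.name if names else str(node.taxid))
    return "|".join(parts)


def write_cami_profile(
    profiles: dict[str, RankProfile],
    tree: TaxonomyTree,
    sample_id: str,
    fh,
) -> None:
    """Write profiles in the CAMI profiling (Bioboxes) format, percentages
    per rank, highest rank first. The unclassified component is emitted as
    a pseudo-taxon with TAXID -1 at each rank."""
    ranks = [r for r in _CAMI_RANK_ORDER if r in profiles]
    fh.write(f"@SampleID:{sample_id}\n")
    fh.write("@Version:0.9.1\n")
    fh.write(f"@Ranks:{'|'.join(ranks)}\n")
    fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
    for rank in ranks:
        profile = profiles[rank]
        for t in sorted(profile.abundances, key=lambda t: -profile.abundances[t]):
            node = tree.nodes[t]
            fh.write(
                f"{node.taxid}\t{rank}\t{_taxpath(tree, t, False)}\t"
                f"{_taxpath(tree, t, True)}\t{100.0 * profile.abundances[t]:.6f}\n"
            )
        if profile.unclassified > 0.0:
            fh.write(
                f"-1\t{rank}\t-1\tunclassified\t{100.0 * profile.unclassified:.6f}\n"
            )


def write_profile_tsv(
    profiles: dict[str, RankProfile], tree: TaxonomyTree, fh
) -> None:
    """Plain TSV mirror: rank, taxid, name, abundance."""
    fh.write("rank\ttaxid\tname\tabundance\n")
    for rank in _CAMI_RANK_ORDER:
        if rank not in profiles:
            continue
        profile = profiles[rank]
        for t in sorted(profile.abundances, key=lambda t: -profile.abundances[t]):
            node = tree.nodes[t]
            fh.write(f"{rank}\t{node.taxid}\t{node.name}\t{profile.abundances[t]:.10g}\n")
        if profile.unclassified > 0.0:
            fh.write(f"{rank}\t-1\tunclassified\t{profile.unclassified:.10g}\n")
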