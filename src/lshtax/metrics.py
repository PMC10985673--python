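"""Evaluation: per-rank read-classification contingency counts and
profile-quality metrics (Bray-Curtis, Shannon's equitability, L1 norm).

A read is evaluated independently at each rank r. If the reference set
contains the read's true taxon at r, the read is a *positive*: TP when the
predicted label at r is correct, FP when it is wrong, FN when no label was
produced at r (including assignments at ranks above r). Otherwise it is a
*negative*: TN when no label was produced at r, FP when any label was —
necessarily wrong. Reads whose true lineage lacks rank r are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from lshtax.profiling import RankProfile
from lshtax.taxonomy import TaxonomyTree

__all__ = [
    "RankContingency",
    "score_reads",
    "precision_recall_f1",
    "bray_curtis",
    "shannon_equitability",
    "l1_error",
]


@dataclass(frozen=True)
class RankContingency:
    rank: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def score_reads(
    assignments: dict[str, int | None],
    truth: dict[str, int],
    reference_taxa: set[int],
    rank: str,
    tree: TaxonomyTree,
) -> RankContingency:
    """Contingency counts at one rank.

    ``assignments`` maps read id to the assigned taxon (None =
    unclassified); ``truth`` maps read id to the true taxon (any rank at
    or below r); ``reference_taxa`` is the set of rank-r taxa represented
    in the reference library. An assignment at a rank above r counts as
    "no label at r".
    """
    tp = fp = fn = tn = 0
    for read_id, true_taxon in truth.items():
        true_at_r = tree.rank_of_lineage(true_taxon, rank)
        if true_at_r is None:  # missing rank in the truth lineage: skip
            continue
        assigned = assignments.get(read_id)
        assigned_at_r = (
            tree.rank_of_lineage(assigned, rank) if assigned is not None else None
        )
        if true_at_r in reference_taxa:
            if assigned_at_r is None:
                fn += 1
            elif assigned_at_r == true_at_r:
                tp += 1
            else:
                fp += 1
        else:
            if assigned_at_r is None:
                tn += 1
            else:
                fp += 1
    return RankContingency(rank, tp, fp, fn, tn)


def precision_recall_f1(c: RankContingency) -> tuple[float, float, float]:
    """(TP/(TP+FP), TP/(TP+FN), 2TP/(2TP+FP+FN)); 0/0 cases score 0."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else 0.0
    return precision, recall, f1


_UNCLASSIFIED_KEY = -1


def _to_vector_pair(
    p: RankProfile | dict, q: RankProfile | dict, unclassified: str = "auto"
) -> tuple[dict, dict]:
    """Union the supports of two profiles with zero fill.

    The unclassified mass participates as its own pseudo-taxon only when
    both profiles carry it (``'auto'``, the default) or always
    (``True``); otherwise it is dropped and each profile renormalized.
    """
    def parts(x):
        if isinstance(x, RankProfile):
            return dict(x.abundances), x.unclassified
        return dict(x), 0.0

    pa, pu = parts(p)
    qa, qu = parts(q)
    if unclassified == "auto":
        use = pu > 0 and qu > 0
    else:
        use = bool(unclassified)
    if use:
        pa[_UNCLASSIFIED_KEY] = pu
        qa[_UNCLASSIFIED_KEY] = qu
    else:
        for vec, u in ((pa, pu), (qa, qu)):
            total = sum(vec.values())
            if u > 0 and total > 0:
                for t in vec:
                    vec[t] /= total
    keys = set(pa) | set(qa)
    return {t: pa.get(t, 0.0) for t in keys}, {t: qa.get(t, 0.0) for t in keys}


def bray_curtis(
    p: RankProfile | dict, q: RankProfile | dict, unclassified: str = "auto"
) -> float:
    """Sum|p - q| / Sum(p + q) over the unioned support; 0 for identical
    profiles, 1 for disjoint supports."""
    pa, qa = _to_vector_pair(p, q, unclassified)
    num = sum(abs(pa[t] - qa[t]) for t in pa)
    den = sum(pa[t] + qa[t] for t in pa)
    return num / den if den else 0.0


def l1_error(
    p: RankProfile | dict, q: RankProfile | dict, unclassified: str = "auto"
) -> float:
    """Total variation style L1 distance, range [0, 2] for normalized
    profiles."""
    pa, qa = _to_vector_pair(p, q, unclassified)
    return sum(abs(pa[t] - qa[t]) for t in pa)


def shannon_equitability(p: RankProfile | dict) -> float:
    """Shannon entropy over taxa with positive mass, normalized by the log
    of their count; 1 for a uniform profile, 0 for a single taxon."""
    if isinstance(p, RankProfile):
        vec = dict(p.abundances)
        if p.unclassified > 0:
            vec[_UNCLASSIFIED_KEY] = p.unclassified
    else:
        vec = dict(p)
    masses = [v for v in vec.values() if v > 0]
    if not masses:
        raise ValueError("profile has no positive mass")
    total = sum(masses)
    masses = [v / total for v in masses]
    if len(masses) == 1:
        return 0.0
    entropy = -sum(v * math.log(v) for v in masses)
    return entropy / math.log(len(masses))
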