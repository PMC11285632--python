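"""Prototype ranked list (PRL) construction by hierarchical rank aggregation.

Replicate profiles of one compound are merged into a single representative
ranking: repeatedly find the pair of current lists closest under the
normalized Spearman footrule and replace it with their Borda (mean-rank)
merge, until one list remains.  All tie-breaking is lexicographic on
identifiers, so the result is deterministic and independent of input order.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .universe import (
    PrototypeRankedList,
    Ranking,
    ReplicateProfile,
    ValidationError,
    check_same_universe,
)

__all__ = ["footrule_distance", "borda_merge", "prototype_ranked_list"]

logger = logging.getLogger(__name__)


def footrule_distance(a: Ranking, b: Ranking, *, normalized: bool = False) -> float:
    """Spearman footrule distance between two permutations.

    Sum over genes of the absolute rank difference.  The normalized variant
    divides by ``floor(N**2 / 2)``, the maximum attainable for a universe of
    size N (attained by the exact reversal), giving a value in [0, 1].
    """
    check_same_universe(a, b)
    d = float(np.abs(a.ranks - b.ranks).sum())
    if normalized:
        n = a.universe.size
        d /= (n * n) // 2
    return d


def borda_merge(a: Ranking, b: Ranking) -> Ranking:
    """Merge two permutations by mean rank, re-sorted into a permutation.

    Each gene is scored by the mean of its two ranks; genes are re-ranked
    ascending by score, ties broken by lexicographic gene id (the canonical
    universe order).
    """
    check_same_universe(a, b)
    score = (a.ranks + b.ranks) / 2.0
    # stable sort on scores: equal scores keep universe (lexicographic) order
    order = np.argsort(score, kind="stable")
    ranks = np.empty_like(a.ranks)
    ranks[order] = np.arange(1, a.universe.size + 1)
    return Ranking(a.universe, ranks)


def _merged_label(la: str, lb: str) -> str:
    lo, hi = sorted((la, lb))
    return f"({lo}+{hi})"


def prototype_ranked_list(
    profiles: Iterable[ReplicateProfile],
) -> PrototypeRankedList:
    """Aggregate all replicate profiles of one compound into its PRL.

    Greedy hierarchical merging: at each step the pair of current lists with
    minimal normalized footrule distance is replaced by its Borda merge
    (distance ties resolved by the lexicographically smallest sorted pair of
    list labels).  Intermediate merges re-enter the pool as bare
    permutations; replicate ids seed the labels.
    """
    profs = list(profiles)
    if not profs:
        raise ValidationError("cannot build a PRL from zero replicate profiles")
    compound_ids = {p.compound_id for p in profs}
    if len(compound_ids) != 1:
        raise ValidationError(
            f"mixed compound ids in PRL input: {sorted(compound_ids)}"
        )
    compound_id = profs[0].compound_id
    labels_seen = [p.replicate_id for p in profs]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValidationError(f"duplicate replicate ids for compound {compound_id}")

    # pool sorted by label so behaviour is independent of input order
    pool: list[tuple[str, Ranking]] = sorted(
        ((p.replicate_id, p.ranking) for p in profs), key=lambda t: t[0]
    )
    for _, r in pool[1:]:
        check_same_universe(pool[0][1], r)

    while len(pool) > 1:
        best: tuple[float, tuple[str, str]] | None = None
        best_ij: tuple[int, int] = (0, 1)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                d = footrule_distance(pool[i][1], pool[j][1], normalized=True)
                key = tuple(sorted((pool[i][0], pool[j][0])))
                if best is None or (d, key) < best:
                    best = (d, key)  # type: ignore[assignment]
                    best_ij = (i, j)
        i, j = best_ij
        (la, ra), (lb, rb) = pool[i], pool[j]
        merged = (_merged_label(la, lb), borda_merge(ra, rb))
        pool = [pool[k] for k in range(len(pool)) if k not in (i, j)]
        pool.append(merged)
        pool.sort(key=lambda t: t[0])

    return PrototypeRankedList(
        compound_id=compound_id,
        ranking=pool[0][1],
        n_replicates_merged=len(profs),
    )


def merge_library(
    profiles: Sequence[ReplicateProfile],
) -> dict[str, PrototypeRankedList]:
    """Build one PRL per compound from a mixed list of replicate profiles."""
    by_compound: dict[str, list[ReplicateProfile]] = {}
    for p in profiles:
        by_compound.setdefault(p.compound_id, []).append(p)
    out = {}
    for cid in sorted(by_compound):
        out[cid] = prototype_ranked_list(by_compound[cid])
        logger.debug(
            "merged %d replicates for compound %s",
            out[cid].n_replicates_merged,
            cid,
        )
    return out
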