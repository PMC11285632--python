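"""Query signature construction and bidirectional KS connectivity scoring.

The query is a pair of disjoint up/down gene sets taken from a differential
expression table at an FDR threshold (default 0.05, direction by the sign of
the log2 fold-change).  Each compound's prototype ranked list is scored with
the classic bidirectional Kolmogorov-Smirnov running sum: the up set should
concentrate at the head of a mimicking compound's ranking and the down set
at the tail.  Compounds are ranked by descending connectivity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .universe import GeneUniverse, PrototypeRankedList, Ranking, ValidationError

__all__ = [
    "DegRecord",
    "QuerySignature",
    "ConnectivityRecord",
    "CompoundRanking",
    "build_query",
    "ks_running_sum",
    "ks_running_sum_from_positions",
    "connectivity_score",
    "rank_compounds",
]

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class DegRecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("empty gene_id in DEG record")
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValidationError(f"{name}={v} outside [0,1] for {self.gene_id}")


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down gene sets mapped into a gene universe."""

    up: frozenset[str]
    down: frozenset[str]
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    n_dropped_unmapped: int = 0

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("up and down query sets overlap")
        if not self.up or not self.down:
            raise ValidationError("both query directions must be nonempty")


@dataclass(frozen=True)
class ConnectivityRecord:
    compound_id: str
    es_up: float
    es_down: float
    score: float


@dataclass(frozen=True)
class CompoundRanking:
    """Compounds ordered by descending connectivity score, ties lexicographic."""

    compound_ids: tuple[str, ...]
    scores: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValidationError("duplicate compound ids in ranking")
        if len(self.scores) != len(self.compound_ids):
            raise ValidationError("scores and compound ids differ in length")

    @property
    def size(self) -> int:
        return len(self.compound_ids)

    def position_of(self, compound_id: str) -> int:
        """1-based rank position of a compound."""
        return self.compound_ids.index(compound_id) + 1


def build_query(
    deg_table: Sequence[DegRecord],
    universe: GeneUniverse,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> QuerySignature:
    """Derive the up/down query signature from a DEG table.

    Genes with ``padj < fdr_threshold`` enter the signature, direction by the
    sign of ``log2fc`` (zero fold-change excluded).  Genes absent from the
    library universe are dropped and counted; each direction must retain at
    least ``min_overlap`` mapped genes.
    """
    if not deg_table:
        raise ValidationError("DEG table is empty")
    if not (0.0 < fdr_threshold < 1.0):
        raise ValidationError(f"fdr_threshold={fdr_threshold} outside (0,1)")
    seen: set[str] = set()
    for rec in deg_table:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene_id in DEG table: {rec.gene_id!r}")
        seen.add(rec.gene_id)

    up_all = {r.gene_id for r in deg_table if r.padj < fdr_threshold and r.log2fc > 0}
    down_all = {r.gene_id for r in deg_table if r.padj < fdr_threshold and r.log2fc < 0}
    up = {g for g in up_all if g in universe}
    down = {g for g in down_all if g in universe}
    n_dropped = (len(up_all) - len(up)) + (len(down_all) - len(down))
    if n_dropped:
        logger.info("dropped %d query genes absent from the library universe", n_dropped)
    for name, direction, total in (("up", up, up_all), ("down", down, down_all)):
        if len(direction) < min_overlap:
            raise ValidationError(
                f"query direction {name!r} has {len(direction)} mapped genes "
                f"({len(total)} significant before mapping); "
                f"need at least {min_overlap}"
            )
    if len(up) + len(down) >= universe.size:
        raise ValidationError("query signature covers the whole gene universe")
    return QuerySignature(
        up=frozenset(up),
        down=frozenset(down),
        fdr_threshold=fdr_threshold,
        n_dropped_unmapped=n_dropped,
    )


def ks_running_sum_from_positions(positions: np.ndarray, n: int) -> float:
    """Running-sum enrichment score from 0-based hit positions in a list of n.

    Walk positions 1..N, adding 1/k at a hit and subtracting 1/(N-k) at a
    miss; return the running-sum value of maximal absolute magnitude, ties on
    magnitude resolved to the value attained at the earliest position.
    """
    k = len(positions)
    if k == 0 or k >= n:
        raise ValidationError(
            f"hit set size {k} invalid for list of size {n} (need 0 < k < N)"
        )
    steps = np.full(n, -1.0 / (n - k))
    steps[positions] = 1.0 / k
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))  # argmax takes the earliest on ties
    return float(running[idx])


def ks_running_sum(hit_set: Iterable[str], ranking: Sequence[str]) -> float:
    """Running-sum ES of a gene/compound set against an ordered list.

    ``hit_set`` must be a nonempty proper subset of the ranking's elements.
    """
    hits = set(hit_set)
    n = len(ranking)
    positions = np.array(
        [i for i, g in enumerate(ranking) if g in hits], dtype=np.int64
    )
    if len(positions) != len(hits):
        missing = hits - set(ranking)
        raise ValidationError(
            f"{len(missing)} hit elements absent from the ranking "
            f"(e.g. {sorted(missing)[:3]})"
        )
    return ks_running_sum_from_positions(positions, n)


def connectivity_score(
    query: QuerySignature,
    prl: PrototypeRankedList | Ranking,
    *,
    null_same_sign: bool = True,
) -> ConnectivityRecord:
    """Bidirectional KS connectivity of one compound's PRL with the query.

    ``score = (es_up - es_down) / 2``, set to 0 when the two ES share a
    strict sign (``null_same_sign``, default on): a compound whose ranking
    concentrates both query directions at the same end is not connected.
    """
    if isinstance(prl, PrototypeRankedList):
        compound_id, ranking = prl.compound_id, prl.ranking
    else:
        compound_id, ranking = "", prl
    order = ranking.order_indices()
    uni = ranking.universe
    up_idx = np.sort(uni.indices_of(query.up))
    down_idx = np.sort(uni.indices_of(query.down))
    pos = np.empty(uni.size, dtype=np.int64)
    pos[order] = np.arange(uni.size)
    es_up = ks_running_sum_from_positions(np.sort(pos[up_idx]), uni.size)
    es_down = ks_running_sum_from_positions(np.sort(pos[down_idx]), uni.size)
    if null_same_sign and es_up * es_down > 0:
        score = 0.0
    else:
        score = (es_up - es_down) / 2.0
    return ConnectivityRecord(
        compound_id=compound_id, es_up=es_up, es_down=es_down, score=score
    )


def rank_compounds(records: Sequence[ConnectivityRecord]) -> CompoundRanking:
    """Order compounds by descending score, ties lexicographic by id."""
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate compound ids: {dupes}")
    ordered = sorted(records, key=lambda r: (-r.score, r.compound_id))
    return CompoundRanking(
        compound_ids=tuple(r.compound_id for r in ordered),
        scores=tuple(r.score for r in ordered),
    )


def score_library(
    query: QuerySignature,
    prls: dict[str, PrototypeRankedList],
    *,
    null_same_sign: bool = True,
) -> list[ConnectivityRecord]:
    """Connectivity records for every compound in the library, by compound id."""
    return [
        connectivity_score(query, prls[cid], null_same_sign=null_same_sign)
        for cid in sorted(prls)
    ]
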