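"""Gene universe and ranked-profile containers.

A *ranking* is stored as a rank vector aligned to the canonical
(lexicographic) gene order of its :class:`GeneUniverse`: ``ranks[i]`` is the
1-based rank of ``universe.genes[i]``, with rank 1 = most up-regulated.
Every ranking in the pipeline is a full permutation of the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneUniverse",
    "Ranking",
    "ReplicateProfile",
    "PrototypeRankedList",
    "ValidationError",
]


class ValidationError(ValueError):
    """Structurally invalid input (bad permutation, mismatched universe...)."""


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of unique gene identifiers in canonical lexicographic order."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValidationError("gene universe needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g in seen:
                    raise ValidationError(f"duplicate gene identifier: {g!r}")
                seen.add(g)
        if list(self.genes) != sorted(self.genes):
            raise ValidationError("gene universe must be in lexicographic order")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    @classmethod
    def from_genes(cls, genes: Iterable[str]) -> "GeneUniverse":
        """Build a canonical universe from any iterable of unique gene ids."""
        uniq = sorted(set(genes))
        return cls(tuple(uniq))

    @property
    def size(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in universe") from None

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.index_of(g) for g in genes], dtype=np.int64)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.genes)


def _check_permutation(ranks: np.ndarray, n: int) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=np.int64)
    if ranks.shape != (n,):
        raise ValidationError(f"rank vector has length {ranks.size}, expected {n}")
    if not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
        raise ValidationError("ranking is not a bijection onto 1..N")
    return ranks


@dataclass(frozen=True)
class Ranking:
    """A full permutation of a gene universe, as a 1-based rank vector."""

    universe: GeneUniverse
    ranks: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ranks", _check_permutation(self.ranks, self.universe.size)
        )
        self.ranks.setflags(write=False)

    @classmethod
    def from_ordered_genes(
        cls, universe: GeneUniverse, ordered: Sequence[str]
    ) -> "Ranking":
        """Build from a list of gene ids given in rank order (best first)."""
        idx = universe.indices_of(ordered)
        if len(idx) != universe.size:
            raise ValidationError(
                f"ordered list has {len(idx)} genes, universe has {universe.size}"
            )
        ranks = np.empty(universe.size, dtype=np.int64)
        ranks[idx] = np.arange(1, universe.size + 1)
        return cls(universe, ranks)

    def ordered_genes(self) -> list[str]:
        """Gene ids from rank 1 to rank N."""
        order = np.argsort(self.ranks, kind="stable")
        return [self.universe.genes[i] for i in order]

    def order_indices(self) -> np.ndarray:
        """Universe indices from rank 1 to rank N."""
        return np.argsort(self.ranks, kind="stable")


def check_same_universe(a: Ranking, b: Ranking) -> None:
    """Raise a structural error naming the first mismatching gene."""
    if a.universe is b.universe or a.universe.genes == b.universe.genes:
        return
    ga, gb = a.universe.genes, b.universe.genes
    for x, y in zip(ga, gb):
        if x != y:
            raise ValidationError(
                f"gene universes differ: first mismatch {x!r} vs {y!r}"
            )
    longer = ga if len(ga) > len(gb) else gb
    raise ValidationError(
        f"gene universes differ in size ({len(ga)} vs {len(gb)}); "
        f"first extra gene {longer[min(len(ga), len(gb))]!r}"
    )


@dataclass(frozen=True)
class ReplicateProfile:
    """One ranked expression profile for one compound replicate."""

    compound_id: str
    replicate_id: str
    ranking: Ranking


@dataclass(frozen=True)
class PrototypeRankedList:
    """Merged per-compound signature (prototype ranked list, PRL)."""

    compound_id: str
    ranking: Ranking
    n_replicates_merged: int

    def __post_init__(self) -> None:
        if self.n_replicates_merged < 1:
            raise ValidationError("n_replicates_merged must be >= 1")
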