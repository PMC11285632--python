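"""Chemogenomic enrichment analysis (CEA).

Drug features — shared targets, predicted off-targets, side effects — are
tested for over-representation among the compounds most transcriptomically
similar to the query.  The statistic is the same running-sum enrichment
score used for connectivity, applied to the compound ranking; significance
comes from a permutation null of randomized member sets of matched size
(two-tailed on |ES|, add-one smoothed), with Benjamini-Hochberg adjustment
across features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectivity import CompoundRanking, ks_running_sum_from_positions
from .universe import ValidationError

__all__ = [
    "FeatureAnnotation",
    "EnrichmentRecord",
    "EnrichmentConfig",
    "NullCache",
    "feature_es",
    "permutation_p",
    "exhaustive_permutation_p",
    "bh_adjust",
    "run_enrichment",
]

logger = logging.getLogger(__name__)

Category = Literal["target", "off_target", "side_effect"]
CATEGORIES: tuple[str, ...] = ("target", "off_target", "side_effect")

DEFAULT_N_PERM = 10_000
MIN_N_PERM = 100


@dataclass(frozen=True)
class FeatureAnnotation:
    """A drug feature and the compounds annotated with it."""

    feature_id: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"feature {self.feature_id!r} has no members")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class EnrichmentRecord:
    feature_id: str
    category: str
    n_members_in_library: int
    es: float
    p_two_tailed: float
    p_adj: float


@dataclass(frozen=True)
class EnrichmentConfig:
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    bh_scope: Literal["within_category", "global"] = "within_category"

    def __post_init__(self) -> None:
        if self.n_perm < MIN_N_PERM:
            raise ValidationError(
                f"n_perm={self.n_perm} too small; need >= {MIN_N_PERM} "
                "for any reported p-value"
            )
        if self.bh_scope not in ("within_category", "global"):
            raise ValidationError(f"unknown bh_scope {self.bh_scope!r}")


def feature_es(feature: FeatureAnnotation, ranking: CompoundRanking) -> float:
    """Running-sum ES of a feature's member compounds along the ranking.

    Members outside the library are dropped (and counted in the log);
    positive ES means concentration among the most query-similar compounds.
    """
    members, n_dropped = _library_members(feature, ranking)
    if n_dropped:
        logger.info(
            "feature %s: dropped %d members absent from the library",
            feature.feature_id,
            n_dropped,
        )
    positions = _member_positions(members, ranking)
    return ks_running_sum_from_positions(positions, ranking.size)


def _library_members(
    feature: FeatureAnnotation, ranking: CompoundRanking
) -> tuple[frozenset[str], int]:
    in_lib = feature.members & set(ranking.compound_ids)
    n_dropped = len(feature.members) - len(in_lib)
    if not in_lib:
        raise ValidationError(
            f"feature {feature.feature_id!r} has no members in the library"
        )
    if len(in_lib) == ranking.size:
        raise ValidationError(
            f"feature {feature.feature_id!r} covers the whole library; "
            "ES undefined"
        )
    return frozenset(in_lib), n_dropped


def _member_positions(members: Iterable[str], ranking: CompoundRanking) -> np.ndarray:
    member_set = set(members)
    return np.array(
        [i for i, c in enumerate(ranking.compound_ids) if c in member_set],
        dtype=np.int64,
    )


def _null_es_batch(n: int, m: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_draws`` uniformly random size-m subsets of a size-n ranking."""
    out = np.empty(n_draws, dtype=np.float64)
    chunk = max(1, min(n_draws, 4_000_000 // max(n, 1)))
    start = 0
    while start < n_draws:
        b = min(chunk, n_draws - start)
        # random subsets: the m smallest entries of each row of iid uniforms
        u = rng.random((b, n))
        hit_pos = np.argpartition(u, m - 1, axis=1)[:, :m]
        steps = np.full((b, n), -1.0 / (n - m))
        np.put_along_axis(steps, hit_pos, 1.0 / m, axis=1)
        running = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        out[start : start + b] = running[np.arange(b), idx]
        start += b
    return out


class NullCache:
    """Permutation-null ES distributions, shared across features of equal size.

    Null draws are keyed on the member-set size m; each size gets its own
    seed-derived substream so results are reproducible regardless of the
    order in which sizes are requested.
    """

    def __init__(self, ranking: CompoundRanking, cfg: EnrichmentConfig) -> None:
        self.ranking = ranking
        self.cfg = cfg
        self._cache: dict[int, np.ndarray] = {}

    def null_es(self, m: int) -> np.ndarray:
        n = self.ranking.size
        if not (0 < m < n):
            raise ValidationError(f"member count m={m} out of range for library of {n}")
        if m not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.cfg.seed, spawn_key=(m,))
            )
            self._cache[m] = _null_es_batch(n, m, self.cfg.n_perm, rng)
        return self._cache[m]

    def p_value(self, es_obs: float, m: int) -> float:
        null = self.null_es(m)
        b = int(np.count_nonzero(np.abs(null) >= abs(es_obs)))
        return (1 + b) / (self.cfg.n_perm + 1)


def permutation_p(
    es_obs: float,
    m: int,
    ranking: CompoundRanking,
    cfg: EnrichmentConfig,
    *,
    cache: NullCache | None = None,
) -> float:
    """Two-tailed permutation p-value for an observed feature ES.

    B = ``cfg.n_perm`` member sets of size m are drawn uniformly without
    replacement from the library; ``p = (1 + #{|ES_null| >= |es_obs|}) / (B + 1)``.
    """
    if cache is None:
        cache = NullCache(ranking, cfg)
    return cache.p_value(es_obs, m)


def exhaustive_permutation_p(es_obs: float, m: int, ranking: CompoundRanking) -> float:
    """Exact two-tailed p by enumerating every size-m subset (small libraries).

    Intended as an oracle for the sampled estimator; cost is C(n, m)."""
    from itertools import combinations

    n = ranking.size
    if not (0 < m < n):
        raise ValidationError(f"member count m={m} out of range for library of {n}")
    count = 0
    total = 0
    for subset in combinations(range(n), m):
        es = ks_running_sum_from_positions(np.array(subset, dtype=np.int64), n)
        count += abs(es) >= abs(es_obs)
        total += 1
    return count / total


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def run_enrichment(
    features: Sequence[FeatureAnnotation],
    ranking: CompoundRanking,
    cfg: EnrichmentConfig,
) -> list[EnrichmentRecord]:
    """Score every usable feature and attach permutation and BH-adjusted p.

    Unusable features (no members in the library, or covering the whole
    library) are logged and skipped.  Output is sorted by
    (category, p_adj, feature_id).  BH adjustment pools features within each
    category by default (``cfg.bh_scope``).
    """
    cache = NullCache(ranking, cfg)
    usable: list[tuple[FeatureAnnotation, int, float, float]] = []
    n_skipped = 0
    for feat in features:
        try:
            members, _ = _library_members(feat, ranking)
        except ValidationError as exc:
            logger.warning("skipping feature %s: %s", feat.feature_id, exc)
            n_skipped += 1
            continue
        m = len(members)
        es = ks_running_sum_from_positions(
            _member_positions(members, ranking), ranking.size
        )
        p = cache.p_value(es, m)
        usable.append((feat, m, es, p))
    if n_skipped:
        logger.warning("skipped %d unusable features", n_skipped)
    if not usable:
        return []

    if cfg.bh_scope == "global":
        padj = bh_adjust([u[3] for u in usable])
    else:
        padj = [0.0] * len(usable)
        for cat in CATEGORIES:
            idx = [i for i, u in enumerate(usable) if u[0].category == cat]
            if not idx:
                continue
            adj = bh_adjust([usable[i][3] for i in idx])
            for i, q in zip(idx, adj):
                padj[i] = q

    records = [
        EnrichmentRecord(
            feature_id=feat.feature_id,
            category=feat.category,
            n_members_in_library=m,
            es=es,
            p_two_tailed=p,
            p_adj=q,
        )
        for (feat, m, es, p), q in zip(usable, padj)
    ]
    records.sort(key=lambda r: (r.category, r.p_adj, r.feature_id))
    return records
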