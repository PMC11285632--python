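"""Synthetic perturbation-library generator with known ground truth.

Emulates the statistical structure of a replicate drug-perturbation
expression library: each compound has a latent prototype ranking, replicates
are noisy copies of it (random transpositions), a planted subset of
compounds carries the query's up genes near the head and down genes near the
tail of their prototypes, and one planted drug-target feature labels exactly
those compounds among size-matched random decoys.  Every stage of the
pipeline can therefore be tested against planted truth with no external
download.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

from .chemogenomics import CATEGORIES, FeatureAnnotation
from .connectivity import QuerySignature
from .universe import GeneUniverse, Ranking, ReplicateProfile, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_library",
    "generate_null_library",
]

PLANTED_FEATURE_ID = "planted_target"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic library.

    ``noise`` is the transposition rate: each replicate is its compound's
    prototype perturbed by ``round(noise * n_genes)`` random transpositions.
    ``placement_fraction`` sets the head/tail window (as a fraction of the
    gene universe) into which planted compounds receive the query genes.
    """

    n_genes: int = 1000
    n_compounds: int = 200
    n_replicates: int = 5
    n_planted: int = 20
    query_up_size: int = 50
    query_down_size: int = 50
    placement_fraction: float = 0.05
    noise: float = 0.05
    n_decoy_features: int = 100
    seed: int = 0
    decoy_size_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ValidationError("n_genes must be >= 4")
        if self.n_compounds < 2 or self.n_replicates < 1:
            raise ValidationError("need >= 2 compounds and >= 1 replicate")
        if not (0 <= self.n_planted <= self.n_compounds):
            raise ValidationError("n_planted must lie in [0, n_compounds]")
        if not (0.0 < self.placement_fraction < 0.5):
            raise ValidationError("placement_fraction must lie in (0, 0.5)")
        if not (0.0 <= self.noise <= 1.0):
            raise ValidationError("noise must lie in [0, 1]")
        w = self.window_size
        if self.query_up_size > w or self.query_down_size > w:
            raise ValidationError(
                f"query sizes ({self.query_up_size}/{self.query_down_size}) exceed "
                f"the placement window of {w} genes; enlarge placement_fraction"
            )
        if self.query_up_size + self.query_down_size >= self.n_genes:
            raise ValidationError("query sizes must leave some background genes")
        if self.query_up_size < 1 or self.query_down_size < 1:
            raise ValidationError("query sizes must be >= 1")
        if self.decoy_size_range is not None:
            lo, hi = self.decoy_size_range
            if not (1 <= lo <= hi < self.n_compounds):
                raise ValidationError(
                    f"decoy_size_range {self.decoy_size_range} infeasible for "
                    f"{self.n_compounds} compounds"
                )

    @property
    def window_size(self) -> int:
        return math.ceil(self.placement_fraction * self.n_genes)

    @property
    def n_transpositions(self) -> int:
        return round(self.noise * self.n_genes)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated bundle."""

    planted_compounds: frozenset[str]
    planted_feature_id: Optional[str]
    latent_prototypes: dict[str, np.ndarray] = field(repr=False)
    config: SimulationConfig = field(repr=False)


@dataclass(frozen=True)
class SyntheticBundle:
    universe: GeneUniverse
    profiles: list[ReplicateProfile]
    features: dict[str, list[FeatureAnnotation]]
    query: QuerySignature
    truth: SyntheticTruth
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _compound_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"c{i:0{width}d}" for i in range(n)]


def _transpose_noise(ranks: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    """Apply t random transpositions (swaps of two distinct positions)."""
    out = ranks.copy()
    n = len(out)
    if t == 0:
        return out
    i = rng.integers(0, n, size=t)
    j = rng.integers(0, n, size=t)
    clash = i == j
    while np.any(clash):  # redraw coincident pairs
        j[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = i == j
    for a, b in zip(i, j):  # swaps are sequential, not independent
        out[a], out[b] = out[b], out[a]
    return out


def _planted_prototype(
    universe: GeneUniverse,
    up_idx: np.ndarray,
    down_idx: np.ndarray,
    window: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rank vector placing up genes in the head window, down genes in the tail."""
    n = universe.size
    ranks = np.zeros(n, dtype=np.int64)
    head = rng.permutation(window)[: len(up_idx)]
    tail = n - window + rng.permutation(window)[: len(down_idx)]
    ranks[up_idx] = head + 1
    ranks[down_idx] = tail + 1
    used = set((head + 1).tolist()) | set((tail + 1).tolist())
    free_ranks = np.array([r for r in range(1, n + 1) if r not in used])
    rest = np.setdiff1d(
        np.arange(n), np.concatenate([up_idx, down_idx]), assume_unique=False
    )
    ranks[rest] = rng.permutation(free_ranks)
    return ranks


def _decoy_sizes(cfg: SimulationConfig, count: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.decoy_size_range is not None:
        lo, hi = cfg.decoy_size_range
    elif cfg.n_planted > 0:
        # size-confound control: decoys match the planted feature's size
        return np.full(count, cfg.n_planted, dtype=np.int64)
    else:
        lo, hi = 5, max(5, min(30, cfg.n_compounds // 2))
    return rng.integers(lo, hi + 1, size=count)


def generate_library(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic bundle, deterministic in ``cfg.seed``."""
    if 2 * cfg.window_size > cfg.n_genes:
        raise ValidationError(
            "head and tail placement windows overlap; reduce placement_fraction"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
    )
    universe = GeneUniverse(tuple(_gene_ids(cfg.n_genes)))
    compounds = _compound_ids(cfg.n_compounds)

    # query signature: disjoint up/down gene sets
    sig_idx = rng.choice(
        cfg.n_genes, size=cfg.query_up_size + cfg.query_down_size, replace=False
    )
    up_idx = np.sort(sig_idx[: cfg.query_up_size])
    down_idx = np.sort(sig_idx[cfg.query_up_size :])
    query = QuerySignature(
        up=frozenset(universe.genes[i] for i in up_idx),
        down=frozenset(universe.genes[i] for i in down_idx),
    )

    planted = (
        sorted(rng.choice(compounds, size=cfg.n_planted, replace=False).tolist())
        if cfg.n_planted
        else []
    )
    planted_set = set(planted)

    prototypes: dict[str, np.ndarray] = {}
    profiles: list[ReplicateProfile] = []
    t = cfg.n_transpositions
    for cid in compounds:
        if cid in planted_set:
            proto = _planted_prototype(universe, up_idx, down_idx, cfg.window_size, rng)
        else:
            proto = rng.permutation(cfg.n_genes) + 1
        prototypes[cid] = proto
        for r in range(1, cfg.n_replicates + 1):
            profiles.append(
                ReplicateProfile(
                    compound_id=cid,
                    replicate_id=f"r{r}",
                    ranking=Ranking(universe, _transpose_noise(proto, t, rng)),
                )
            )

    features: dict[str, list[FeatureAnnotation]] = {cat: [] for cat in CATEGORIES}
    if planted:
        features["target"].append(
            FeatureAnnotation(
                feature_id=PLANTED_FEATURE_ID,
                category="target",
                members=frozenset(planted),
            )
        )
    width = len(str(max(cfg.n_decoy_features - 1, 0)))
    for cat in CATEGORIES:
        sizes = _decoy_sizes(cfg, cfg.n_decoy_features, rng)
        for d, size in enumerate(sizes):
            members = rng.choice(compounds, size=int(size), replace=False)
            features[cat].append(
                FeatureAnnotation(
                    feature_id=f"decoy_{cat}_{d:0{width}d}",
                    category=cat,
                    members=frozenset(members.tolist()),
                )
            )

    truth = SyntheticTruth(
        planted_compounds=frozenset(planted),
        planted_feature_id=PLANTED_FEATURE_ID if planted else None,
        latent_prototypes=prototypes,
        config=cfg,
    )
    return SyntheticBundle(
        universe=universe,
        profiles=profiles,
        features=features,
        query=query,
        truth=truth,
        config=cfg,
    )


def generate_null_library(cfg: SimulationConfig) -> SyntheticBundle:
    """Same bundle with no planted structure (type-I-error calibration)."""
    return generate_library(replace(cfg, n_planted=0))


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    if d["decoy_size_range"] is not None:
        d["decoy_size_range"] = list(d["decoy_size_range"])
    return d
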