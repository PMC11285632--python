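"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chemoconnect import GeneUniverse, Ranking, ReplicateProfile


def es_prefix_oracle(hit_set, ranking) -> float:
    """Independent running-sum ES: explicit walk over every prefix.

    Kept deliberately naive (pure-Python accumulation, no vectorisation) so
    it cannot share a bug with the implementation it checks.
    """
    hits = set(hit_set)
    n = len(ranking)
    k = len(hits)
    assert 0 < k < n
    s = 0.0
    best = None
    for element in ranking:
        s += 1.0 / k if element in hits else -1.0 / (n - k)
        if best is None or abs(s) > abs(best):
            best = s
    return best


def bh_stepup_oracle(pvals):
    """Hand-rolled Benjamini-Hochberg step-up, independent of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, pvals[i] * m / (pos + 1))
        q[i] = running_min
    return q


def random_ranking(universe: GeneUniverse, rng: np.random.Generator) -> Ranking:
    return Ranking(universe, rng.permutation(universe.size) + 1)


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse(tuple(f"g{i:02d}" for i in range(10)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_profiles(universe, compound_id, rankings):
    return [
        ReplicateProfile(compound_id, f"r{i+1}", Ranking(universe, np.asarray(r)))
        for i, r in enumerate(rankings)
    ]
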