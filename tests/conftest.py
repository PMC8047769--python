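"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from ddasim import (Chemical, Mixture, PeakBoundingBox, generate_mixture,
                    ground_truth_boxes)
from ddasim.optimal import BipartiteGraph, ScheduledScan
from ddasim.instrument import ScanLevel


@pytest.fixture
def two_chem_mixture() -> Mixture:
    """Two well-separated analytes eluting together mid-run."""
    chems = (
        Chemical(id="a", mz=100.0, rt_apex=30.0, max_intensity=1e6,
                 width_sigma=5.0),
        Chemical(id="b", mz=200.0, rt_apex=35.0, max_intensity=5e5,
                 width_sigma=5.0),
    )
    return Mixture(chemicals=chems, run_length=60.0)


@pytest.fixture
def small_mixture() -> Mixture:
    return generate_mixture(60, rt_range=(0.0, 120.0), seed=7)


@pytest.fixture
def small_boxes(small_mixture):
    return ground_truth_boxes(small_mixture)


def brute_force_max_matching(graph: BipartiteGraph) -> int:
    """Exhaustive maximum-matching size, independent of augmenting paths.

    Subset dynamic programme over (left node, bitmask of used right nodes):
    each slot is either skipped or matched to any free box it can reach.
    Exponential in the right side, fine for <= 8+8 nodes.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(u: int, used_mask: int) -> int:
        if u == len(graph.edges):
            return 0
        best = rec(u + 1, used_mask)  # leave slot u unmatched
        for v in graph.edges[u]:
            bit = 1 << v
            if not used_mask & bit:
                best = max(best, 1 + rec(u + 1, used_mask | bit))
        return best

    return rec(0, 0)


def random_bipartite(rng: np.random.Generator, n_left: int, n_right: int,
                     density: float) -> BipartiteGraph:
    slots = tuple(ScheduledScan(i, ScanLevel.MS2, float(i))
                  for i in range(n_left))
    boxes = tuple(PeakBoundingBox(id=f"b{j}", mz_min=j, mz_max=j + 0.5,
                                  rt_min=0.0, rt_max=1.0)
                  for j in range(n_right))
    edges = tuple(
        tuple(j for j in range(n_right) if rng.random() < density)
        for _ in range(n_left))
    return BipartiteGraph(ms2_slots=slots, boxes=boxes, edges=edges)
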