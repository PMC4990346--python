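"""Shared fixtures: phantom volumes and tracked trees, computed once per session.

Everything is generated programmatically; the heavyweight artifacts
(rasterized volumes, tracked trees) are cached so many tests can share one
tracking run.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import corotrack as ct


@lru_cache(maxsize=None)
def phantom(name: str, sigma: float = 20.0, seed: int = 0):
    """(Volume, PhantomTruth) for a standard suite phantom, cached."""
    spec = ct.standard_suite(noise_sigma=sigma, seed=seed)[name]
    return ct.rasterize(spec)


@lru_cache(maxsize=None)
def tracked(name: str, sigma: float = 20.0, active: bool = True, seed: int = 0):
    """Full tree-extraction result for a phantom, cached.

    Returns (tree, truth, segments, events).
    """
    vol, truth = phantom(name, sigma, seed)
    cfg = ct.TrackerConfig(enable_active_search=active)
    start = ct.Seed(position=truth.segments[0].points[0])
    segments, events = ct.track_tree(vol, [start], cfg)
    tree = ct.assemble(segments, events)
    return tree, truth, segments, events


def tree_points(tree) -> np.ndarray:
    return np.vstack([cl.points for cl in tree.segments])


@pytest.fixture(scope="session")
def straight_noise_free():
    return phantom("STRAIGHT", sigma=0.0)


@pytest.fixture(scope="session")
def curved_noise_free():
    return phantom("CURVED", sigma=0.0)


@pytest.fixture(scope="session")
def constant_volume():
    return ct.Volume(np.full((24, 24, 24), 55.0), (0.5, 0.5, 0.5), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def noise_only_volume():
    rng = np.random.default_rng(7)
    data = 50.0 + rng.normal(0.0, 20.0, (64, 64, 64))
    return ct.Volume(data, (0.5, 0.5, 0.5), (0.0, 0.0, 0.0))
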