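"""Shared fixtures: small synthetic pools reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import gamerge as gm


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


@pytest.fixture(scope="session")
def default_shells() -> gm.ShellScheme:
    return gm.make_shells(36.0, 2.0, 10)


@pytest.fixture(scope="session")
def planted_pool():
    """The standard planted pool: 20 isomorphous + 10 strongly perturbed."""
    cfg = gm.SynthConfig(seed=11)
    pool, truth = gm.generate_pool(cfg)
    return pool, truth


@pytest.fixture(scope="session")
def clean_pool():
    """Single isomorphous group with realistic noise."""
    cfg = gm.SynthConfig(n_subsets=10, group_spec=((10, 0.0),), seed=7)
    pool, truth = gm.generate_pool(cfg)
    return pool, truth


@pytest.fixture(scope="session")
def noiseless_pool():
    """Isomorphous, zero-noise, unit-scale pool: every statistic is ideal."""
    cfg = gm.SynthConfig(
        n_subsets=6, group_spec=((6, 0.0),), noise_a=0.0, noise_b=0.0, scale_range=(1.0, 1.0), seed=3
    )
    pool, truth = gm.generate_pool(cfg)
    return pool, truth


@pytest.fixture(scope="session")
def two_block_pool():
    """Two planted blocks with high within- and low between-correlation."""
    cfg = gm.SynthConfig(n_subsets=20, group_spec=((12, 0.0), (8, 0.6)), seed=4)
    pool, truth = gm.generate_pool(cfg)
    return pool, truth


def merge_pool(pool, scheme, seed=0, model="scale"):
    """Convenience: scale + merge + stats for a whole pool as one group."""
    scales = gm.scale_group(pool, model=model)
    merged = gm.merge_group(pool, scales, rng_seed=seed)
    stats = gm.compute_stats(merged, scheme, pool[0].space_group_number)
    return merged, stats
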