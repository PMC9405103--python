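"""Shared fixtures: tiny synthetic stacks, climates, and suitability maps."""

from __future__ import annotations

import numpy as np
import pytest

from nichetransfer.containers import EnvStack, SuitabilityMap
from nichetransfer.synthetic_world import (
    BaseClimateConfig,
    DriftSpec,
    ScenarioConfig,
    generate_scenario,
    make_climate_pair,
)


def make_env(layers: np.ndarray, names=None, mask=None, period="historical", **kw) -> EnvStack:
    layers = np.asarray(layers, dtype=float)
    if layers.ndim == 2:
        layers = layers[None]
    if names is None:
        names = [f"v{i}" for i in range(layers.shape[0])]
    if mask is None:
        mask = np.ones(layers.shape[1:], dtype=bool)
    arr = layers.copy()
    arr[:, ~mask] = np.nan
    return EnvStack(layers=arr, names=list(names), mask=mask, period=period, **kw)


def smooth_random_map(shape=(50, 60), seed=0) -> SuitabilityMap:
    """A smooth random suitability surface scaled to [0, 1]."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    z = (z - z.min()) / (z.max() - z.min())
    return SuitabilityMap(values=z, mask=np.ones(shape, dtype=bool))


@pytest.fixture
def climate_pair():
    return make_climate_pair(
        (24, 30), DriftSpec(temp_offset=1.0, noise_scale=0.1), roughness=3.0, seed=7
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but fully featured world: 2 species, moderate drift."""
    cfg = ScenarioConfig(
        shape=(60, 70),
        n_species=2,
        n_modern=80,
        range_size=(32, 32),
        seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture
def random_suitability():
    return smooth_random_map()
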