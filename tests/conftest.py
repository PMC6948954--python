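"""Shared fixtures: small, fast phantoms generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from renolymph.config import AnalysisConfig
from renolymph.phantom import (
    ClusterSpec,
    ConfounderSpec,
    NoiseParams,
    PhantomConfig,
    VesselTreeSpec,
    generate_phantom,
)


def small_phantom_config(**overrides) -> PhantomConfig:
    """A compact scene (128³ voxels, 256 µm field) for fast unit tests.

    Same construction as the default phantom, scaled down: ring plus two
    generations, a handful of clusters and confounders.
    """
    kwargs = dict(
        shape=(128, 128, 128),
        spacing=(2.0, 2.0, 2.0),
        envelope_semiaxes=(100.0, 115.0, 115.0),
        vessels=VesselTreeSpec(
            ring_radius=40.0,
            n_generations=2,
            branch_length_distribution=(55.0, 8.0),
            branch_radius_distribution=(9.0, 1.0),
        ),
        clusters=ClusterSpec(n_clusters=5),
        confounders=ConfounderSpec(n_macrophages=4, n_tubule_patches=2),
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """(stack, ground truth) with the default 10%-of-foreground noise."""
    return generate_phantom(small_phantom_config(), seed=11)


@pytest.fixture(scope="session")
def clean_phantom():
    """(stack, ground truth) without noise or confounders."""
    cfg = small_phantom_config(
        noise=NoiseParams(gaussian_sd=0.0, poisson_scale=0.0),
        confounders=ConfounderSpec(n_macrophages=0, n_tubule_patches=0),
    )
    return generate_phantom(cfg, seed=7)


@pytest.fixture()
def analysis_config():
    return AnalysisConfig(spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
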