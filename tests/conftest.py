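"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from mammometry.phantom import PhantomConfig, generate_phantom
from mammometry.pipeline import analyze_scan

#: asymmetry factors cycled through the validation batch
BATCH_ASYMMETRY = (0.0, 0.15, 0.3)
BATCH_SEEDS = tuple(range(20, 30))


@pytest.fixture(scope="session")
def sym_phantom():
    """A perfectly symmetric phantom (mesh, ground truth)."""
    return generate_phantom(PhantomConfig(seed=10))


@pytest.fixture(scope="session")
def sym_phantom_noiseless():
    """Symmetric phantom without texture noise, for exact-symmetry checks."""
    return generate_phantom(PhantomConfig(seed=10, skin_noise_sigma=0.0))


@pytest.fixture(scope="session")
def asym_phantom():
    """A moderately asymmetric phantom (mesh, ground truth)."""
    return generate_phantom(PhantomConfig(seed=3, asymmetry_factor=0.15))


@pytest.fixture(scope="session")
def sym_analyzed(sym_phantom):
    """(mesh, truth, landmark set, measurement table) for the symmetric phantom."""
    mesh, truth = sym_phantom
    lset, table = analyze_scan(mesh)
    return mesh, truth, lset, table


@pytest.fixture(scope="session")
def asym_analyzed(asym_phantom):
    mesh, truth = asym_phantom
    lset, table = analyze_scan(mesh)
    return mesh, truth, lset, table


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten phantoms across seeds and asymmetry levels, fully analyzed.

    Returns a list of (config, mesh, truth, lset, table) tuples; shared by
    the landmark-recovery, measurement-recovery and symmetry checks.
    """
    batch = []
    for i, seed in enumerate(BATCH_SEEDS):
        config = PhantomConfig(seed=seed,
                               asymmetry_factor=BATCH_ASYMMETRY[i % 3])
        mesh, truth = generate_phantom(config)
        lset, table = analyze_scan(mesh)
        batch.append((config, mesh, truth, lset, table))
    return batch


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
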