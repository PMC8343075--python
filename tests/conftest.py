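"""Shared fixtures: small synthetic cohorts and bundles, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tractsvm import EffectSpec, SimConfig, generate_bundle, generate_cohort


@pytest.fixture(scope="session")
def small_effect_cohort():
    """13-subject, 12-node cohort with a strong localized MD effect (nodes 4-6)."""
    cfg = SimConfig(
        n_C=6,
        n_NC=7,
        tracts=("left_ilf",),
        properties=("MD",),
        n_nodes=12,
        correlation_length=2.0,
        effects=(EffectSpec("left_ilf", "MD", (4, 6), 2.5),),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_cohort():
    """13-subject, 12-node cohort with no group effect."""
    cfg = SimConfig(
        n_C=6,
        n_NC=7,
        tracts=("left_ilf",),
        properties=("MD",),
        n_nodes=12,
        correlation_length=2.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def straight_centerline():
    """Straight 100-unit centerline along x."""
    t = np.linspace(0.0, 100.0, 50)
    return np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])


@pytest.fixture()
def clean_base_bundle(straight_centerline):
    """100 well-behaved fibers around the straight centerline."""
    return generate_bundle(
        100, straight_centerline, dispersion_sd=1.0, length_jitter=0.03, seed=5
    )


def make_blobs(n: int, d: float, n_features: int = 4, seed: int = 0):
    """Two Gaussian classes separated by ``d`` SDs along every feature."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(size=(n, n_features))
    y = np.zeros(n, dtype=int)
    y[:half] = 1
    X[y == 1] += d
    return X, y
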