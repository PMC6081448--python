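"""Shared phantom fixtures.

Phantom generation and whole-volume classification take seconds each, so the
expensive bundles are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungquant import (
    build_zone_map,
    classify_parenchyma,
    generate_labeled_boxes,
    segment_lungs,
    train_signatures,
)
from lungquant.phantom import LesionSpec, PhantomSpec, generate_phantom


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|)."""
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def plain_bundle():
    """Default thorax, no lesions, default noise."""
    return generate_phantom(PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free thorax with uniform lungs: every lung voxel at the lung mean."""
    return generate_phantom(PhantomSpec(seed=0, noise_sd_hu=0.0, body_sd_hu=0.0))


@pytest.fixture(scope="session")
def ggo_bundle():
    """Thorax with 30% ground-glass burden."""
    return generate_phantom(PhantomSpec(seed=7, lesions=(LesionSpec("ggo", 0.30),)))


@pytest.fixture(scope="session")
def ggo_organ(ggo_bundle):
    return segment_lungs(ggo_bundle.ct)


@pytest.fixture(scope="session")
def ggo_zones(ggo_organ):
    return build_zone_map(ggo_organ)


@pytest.fixture(scope="session")
def ggo_signatures(ggo_bundle):
    return train_signatures(generate_labeled_boxes(ggo_bundle, n_per_class=30))


@pytest.fixture(scope="session")
def ggo_pattern_map(ggo_bundle, ggo_organ, ggo_signatures):
    return classify_parenchyma(ggo_bundle.ct, ggo_organ, ggo_signatures)
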