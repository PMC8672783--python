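"""Shared fixtures: one segmented clean phantom reused across tests."""

import numpy as np
import pytest

from bonemorph.lcn import (
    SegmentationConfig,
    count_canaliculi_all,
    local_threshold,
    segment_lacunae,
)
from bonemorph.synthetic import LCNPhantomParams, generate_lcn_stack


@pytest.fixture(scope="session")
def phantom_cfg():
    """Segmentation config sized for the default phantom lacunae
    (24-92 um^3 ellipsoids; the class defaults target real-bone scale)."""
    return SegmentationConfig(
        min_lacuna_volume=10.0, max_lacuna_volume=500.0, opening_radius=0.8
    )


@pytest.fixture(scope="session")
def clean_phantom():
    params = LCNPhantomParams(seed=7)
    stack, truth = generate_lcn_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def segmented_phantom(clean_phantom, phantom_cfg):
    _, stack, truth = clean_phantom
    binary = local_threshold(stack, phantom_cfg)
    records, labels = segment_lacunae(binary, stack.spacing, phantom_cfg)
    counts = count_canaliculi_all(binary, labels, phantom_cfg)
    return binary, records, labels, counts


def match_to_truth(record, truth):
    """Nearest ground-truth interior lacuna for a segmented record."""
    interior = [l for l in truth.lacunae if not l.touches_border]
    c = np.asarray(record.centroid)
    return min(interior, key=lambda l: np.linalg.norm(np.asarray(l.center) - c))
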