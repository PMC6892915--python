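"""Shared fixtures: a small synthetic compendium and its decomposition.

The small fixture (600 genes x 40 samples, 5 planted modules) keeps unit
tests fast; acceptance tests build the full-size default compendium
themselves.
"""

import warnings

import numpy as np
import pytest

from imodkit import (
    center_to_reference,
    generate_compendium,
    robust_components,
)

warnings.filterwarnings("ignore", message="FastICA did not converge")

SMALL = dict(
    n_genes=600,
    n_samples=40,
    n_modules=5,
    module_size=(8, 15),
    n_decoy_regulons=5,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """(centered Compendium, GroundTruth, RegulonTable) for the small fixture."""
    compendium, truth, trn = generate_compendium(**SMALL)
    centered = center_to_reference(
        compendium.values, compendium.reference_samples, compendium.metadata
    )
    return centered, truth, trn


@pytest.fixture(scope="session")
def small_decomposition(small_world):
    centered, _, _ = small_world
    return robust_components(
        centered.values, n_restarts=6, n_repetitions=2, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
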