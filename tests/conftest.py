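"""Shared fixtures: synthetic studies at the scales the tests need."""

from dataclasses import replace

import numpy as np
import pytest

from eemkit.preprocess import build_scatter_mask, preprocess_sample
from eemkit.synthetic import (
    EEMDataset,
    EEMGrid,
    NoiseSpec,
    StudyDesign,
    default_bovine_specs,
    default_coconut_specs,
    generate_study,
    make_pure_profile,
)


@pytest.fixture(scope="session")
def grid():
    return EEMGrid.default()


@pytest.fixture(scope="session")
def bovine_profile(grid):
    return make_pure_profile(default_bovine_specs(), grid)


@pytest.fixture(scope="session")
def coconut_profile(grid):
    return make_pure_profile(default_coconut_specs(), grid)


@pytest.fixture(scope="session")
def zero_coconut_specs():
    """Coconut background switched off: mixtures span only the two bovine
    fluorophores, so the sample stack is trilinear rank 2."""
    return [replace(s, amplitude=0.0) for s in default_coconut_specs()]


@pytest.fixture(scope="session")
def noiseless_rank2_study(zero_coconut_specs):
    return generate_study(
        StudyDesign(seed=101), coconut_specs=zero_coconut_specs,
        noise=NoiseSpec.noiseless(),
    )


@pytest.fixture(scope="session")
def default_study():
    return generate_study(StudyDesign(seed=202))


@pytest.fixture(scope="session")
def scatter_mask(grid):
    return build_scatter_mask(grid)


@pytest.fixture(scope="session")
def clean_default_study(default_study, scatter_mask):
    return EEMDataset(
        [preprocess_sample(s, scatter_mask) for s in default_study]
    )
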