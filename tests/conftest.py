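"""Shared fixtures: tiny hand-built datasets and seeded synthetic worlds."""

from __future__ import annotations

import numpy as np
import pytest

from trialtensor import synthetic
from trialtensor.data_model import (
    AugmentedTensor,
    EntityRegistry,
    OutcomeMatrix,
    TargetAttributes,
    assemble_tensor,
)


@pytest.fixture()
def tiny_registry() -> EntityRegistry:
    return EntityRegistry(
        targets=("T0000", "T0001", "T0002"),
        indications=("D0000", "D0001"),
        evidence_sources=("S00", "S01"),
    )


@pytest.fixture()
def tiny_tensor(tiny_registry) -> AugmentedTensor:
    """3 targets x 2 indications x (2 evidence + outcome) with 5 cells."""
    evidence = AugmentedTensor(
        tiny_registry,
        i=np.array([0, 1, 2]),
        j=np.array([0, 1, 0]),
        k=np.array([0, 0, 1]),
        values=np.array([1, 0, 1]),
        has_outcome_slice=False,
    )
    outcomes = OutcomeMatrix(
        tiny_registry,
        i=np.array([0, 1]),
        j=np.array([1, 0]),
        values=np.array([1, 0]),
    )
    return assemble_tensor(evidence, outcomes)


@pytest.fixture()
def tiny_attrs(tiny_registry) -> TargetAttributes:
    mat = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
    cols = (("loc", "membrane"), ("loc", "nucleus"), ("loc", "cytosol"))
    return TargetAttributes(tiny_registry.targets, mat, cols)


@pytest.fixture(scope="session")
def default_world() -> synthetic.SyntheticWorld:
    """The canonical desk-scale study world, generated once per session."""
    return synthetic.make_world(synthetic.WorldConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_world() -> synthetic.SyntheticWorld:
    return synthetic.make_world(synthetic.WorldConfig(seed=11, noise_sd=0.0))
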