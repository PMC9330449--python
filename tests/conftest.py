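"""Shared fixtures: reference parameters, patients, and cached steady states."""

from __future__ import annotations

import numpy as np
import pytest

from hptsim import (
    ModelParameters,
    PatientProfile,
    initial_condition,
    personalize,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def ref_female() -> PatientProfile:
    """The reference euthyroid normal-weight female (1.67 m, 63 kg, BMI 22.6)."""
    return PatientProfile("female", 1.67, 63.0)


@pytest.fixture(scope="session")
def ref_female_model(params, ref_female) -> ModelParameters:
    return personalize(params, ref_female)


@pytest.fixture(scope="session")
def ref_female_ic(ref_female_model) -> np.ndarray:
    return initial_condition(ref_female_model)


@pytest.fixture(scope="session")
def ref_ic(params) -> np.ndarray:
    """Euthyroid steady state of the unpersonalized calibration reference."""
    return initial_condition(params)
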