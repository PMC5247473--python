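"""Shared fixtures: small synthetic spines and solved models."""

from __future__ import annotations

import numpy as np
import pytest

from spineload.model import build_model
from spineload.synthetic import SpineRecipe, generate_hips, generate_spine


@pytest.fixture(scope="session")
def straight_recipe() -> SpineRecipe:
    return SpineRecipe(sacral_slope_deg=0.0, lordosis_deg=0.0, kyphosis_deg=0.0, cobb_deg=0.0)


@pytest.fixture(scope="session")
def straight_spine(straight_recipe):
    return generate_spine(straight_recipe)


@pytest.fixture(scope="session")
def physiological_recipe() -> SpineRecipe:
    """A representative mildly scoliotic standing subject."""
    return SpineRecipe(
        cobb_deg=12.0,
        apex_level="T9",
        sacral_slope_deg=40.0,
        lordosis_deg=45.0,
        kyphosis_deg=35.0,
    )


@pytest.fixture(scope="session")
def physiological_spine(physiological_recipe):
    return generate_spine(physiological_recipe)


@pytest.fixture(scope="session")
def physiological_hips(physiological_recipe, physiological_spine):
    return generate_hips(physiological_recipe, physiological_spine)


@pytest.fixture(scope="session")
def default_model(physiological_spine):
    return build_model(physiological_spine, mass_kg=47.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
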