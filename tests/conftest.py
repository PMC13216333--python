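"""Shared fixtures: one predictor, default config, and session-scoped
fixture libraries / databases so expensive builds happen once."""

import pytest

from nmrcase import SolverConfig, build_db, generate_library
from nmrcase.predictor import ToyShiftPredictor


@pytest.fixture(scope="session")
def predictor():
    return ToyShiftPredictor()


@pytest.fixture(scope="session")
def config():
    return SolverConfig()


@pytest.fixture(scope="session")
def library100(predictor):
    return generate_library(100, seed=7)


@pytest.fixture(scope="session")
def library500(predictor):
    return generate_library(500, seed=7)


@pytest.fixture(scope="session")
def db500(library500, predictor, config):
    return build_db(library500, predictor, config)
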