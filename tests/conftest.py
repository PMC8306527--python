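"""Shared fixtures.

Heavy cohort simulations used by several acceptance checks are session-scoped
so their runs are shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from asyncgc.gc_engine import GCParams
from asyncgc.hypotheses import DEFAULT_EPITOPES, default_config, run_scenario
from asyncgc.shape_space import Epitope, FounderSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_epitope():
    return DEFAULT_EPITOPES


@pytest.fixture
def random_founders():
    return FounderSpec(mode="random")


@pytest.fixture
def fast_params():
    """Cheap engine parameterization for unit tests: short horizon, small
    antigen stock; kinetics are irrelevant to the contracts under test."""
    return GCParams(duration=240.0, antigen_per_fdc=300.0)


# session-scoped cohort simulations shared by the acceptance suite


@pytest.fixture(scope="session")
def h1_cohort():
    """Baseline scenario: 8 representatives formed within 12 days, identical
    reference parameters, 10 repeats."""
    return run_scenario(default_config("H1"), master_seed=11, repeats=10)


@pytest.fixture(scope="session")
def h2_cohort():
    """Extended-formation scenario: 15 representatives over ~35 days,
    identical per-GC parameters, 10 repeats."""
    return run_scenario(default_config("H2"), master_seed=12, repeats=10)


@pytest.fixture(scope="session")
def h3_cohort():
    """Antigen-decay scenario (initiation-time-dependent loading), 10 repeats."""
    return run_scenario(default_config("H3"), master_seed=13, repeats=10)


@pytest.fixture(scope="session")
def h5_cohort():
    """Random-antigen scenario, 50 repeats (per-representative means)."""
    return run_scenario(default_config("H5"), master_seed=15, repeats=50)
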