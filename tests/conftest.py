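"""Shared fixtures: small synthetic study and derived tables.

Expensive objects are session-scoped; all randomness is seeded so the
suite is deterministic.
"""

import warnings

import numpy as np
import pytest

from elkrsf.design import build_third_order_table
from elkrsf.homerange import estimate_home_range
from elkrsf.synthetic import generate_landscapes, simulate_study, simulate_used_available
from elkrsf.telemetry import filter_foraging_locations, subsample_daily


@pytest.fixture(scope="session")
def landscapes():
    return generate_landscapes(shape=(128, 128), cell_size=250.0, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """8 individuals on a 128^2 landscape — enough for pipeline plumbing."""
    return simulate_study(
        n_individuals=8, n_fixes=400, shape=(128, 128), hr_radius=2500.0, seed=7
    )


@pytest.fixture(scope="session")
def small_home_ranges(small_study):
    daily = subsample_daily(small_study.telemetry)
    return {
        str(ind): estimate_home_range(grp, owner=str(ind))
        for ind, grp in daily.groupby("animal_id")
    }


@pytest.fixture(scope="session")
def small_third_order(small_study, small_home_ranges):
    forage = filter_foraging_locations(small_study.telemetry)
    with warnings.catch_warnings():
        # the calibrated lion-DE landscape correlation (~0.6) intentionally
        # trips the collinearity diagnostic
        warnings.simplefilter("ignore", UserWarning)
        table, constants = build_third_order_table(
            forage, small_home_ranges, small_study.de, small_study.lion,
            small_study.wolf, seed=8,
        )
    return table, constants


@pytest.fixture(scope="session")
def model_table():
    """Used–available table drawn directly from the hierarchical RSF."""
    table, gamma = simulate_used_available(
        n_individuals=12, n_used=150, ratio=10, seed=31
    )
    return table, gamma
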