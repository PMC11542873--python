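"""Shared fixtures: simulated bundles and the study-scale cascade example."""

from __future__ import annotations

import pytest

from lichen_census.examples import run_study_cascade
from lichen_census.simulate import SimulationConfig, generate_bundle

# re-exported for tests that exercise the example directly
run_cascade_fixture = run_study_cascade


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-sample simulated bundle shared across tests."""
    return generate_bundle(
        SimulationConfig(seed=11, n_samples=40, n_duplicate_pairs=3, n_misidentified=3)
    )


@pytest.fixture(scope="session")
def cascade_summary():
    return run_study_cascade()
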