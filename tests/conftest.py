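"""Shared fixtures: canonical synthetic scenarios run once per session."""

import pytest

from firetrack.config import TrackerConfig
from firetrack.geometry import AlbersEqualArea
from firetrack.pipeline import run_tracking
from firetrack.synthetic import (
    ScenarioBundle,
    default_scenario,
    merge_scenario,
    static_scenario,
)


@pytest.fixture(scope="session")
def proj() -> AlbersEqualArea:
    return AlbersEqualArea()


def _run(bundle: ScenarioBundle):
    state, history = run_tracking(
        records=bundle.records,
        roi=bundle.roi,
        start=bundle.start,
        end=bundle.end,
        config=TrackerConfig(),
        lct_grid=bundle.lct_grid,
        fm_field=bundle.fm_field,
    )
    return bundle, state, history


@pytest.fixture(scope="session")
def default_run():
    """(bundle, final state, history) for the single-fire scenario."""
    return _run(default_scenario(seed=0))


@pytest.fixture(scope="session")
def static_run():
    """(bundle, final state, history) for the spreading-fire + static-hotspot scenario."""
    return _run(static_scenario(seed=0))


@pytest.fixture(scope="session")
def merge_run():
    """(bundle, final state, history) for the converging two-fire scenario."""
    return _run(merge_scenario(seed=0))
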