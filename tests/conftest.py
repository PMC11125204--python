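import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kelpmorph.lineage import track_series
from kelpmorph.segio import read_segmentation
from kelpmorph.simulator import (
    SimulationConfig,
    ablated_config,
    intact_config,
    render_snapshots,
    simulate_embryo,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


ALL_CONDITIONS = {
    "CT": intact_config(),
    "AE2": ablated_config("apical", 2),
    "AE4": ablated_config("apical", 4),
    "AE8": ablated_config("apical", 8),
    "BE2": ablated_config("basal", 2),
    "BE4": ablated_config("basal", 4),
    "BE8": ablated_config("basal", 8),
}


def simulate_roundtrip(config: SimulationConfig, calibration: float = 0.5):
    """Simulate, render to SVG, re-read, and track lineage — the full
    pipeline path used throughout the suite."""
    series = simulate_embryo(config)
    svg = render_snapshots(
        series, calibration=calibration, embryo_id="t", condition="CT8"
    )
    ts = read_segmentation(svg, calibration, "CT8", "t")
    maps = track_series(ts)
    return series, ts, maps


@pytest.fixture(scope="session")
def intact_series():
    return simulate_embryo(intact_config())


@pytest.fixture(scope="session")
def intact_roundtrip():
    return simulate_roundtrip(intact_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240613)


def noisy_config(base: SimulationConfig, seed: int) -> SimulationConfig:
    """Default observation-noise regime: growth CV 0.1, jitter 0.2 µm."""
    return dataclasses.replace(
        base, noise_growth_cv=0.1, vertex_jitter_sd=0.2, seed=seed
    )
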