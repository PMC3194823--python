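import logging

import numpy as np
import pytest

import territoria as tt
from territoria import evaluate as ev

logging.getLogger("territoria").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def circle_territory():
    return tt.make_virtual_territory("circle")


@pytest.fixture(scope="session")
def circle_trials(circle_territory):
    """Full simulated trial set on the circle (360 central + 360 edge points)."""
    return tt.simulate_trialset(circle_territory, 1)


@pytest.fixture(scope="session")
def six_shape_dh_series():
    """Mean DH area per trial count k for all six stock shapes, over all
    equiangular offsets (the estimator-benchmark accumulation curves)."""
    series = {}
    tables = {}
    for shape in ("ellipse", "star", "triangle", "angle", "circle", "irregular"):
        terr = tt.make_virtual_territory(shape)
        trials = tt.simulate_trialset(terr, 1)
        tab = ev.accumulation_table(terr, trials, "DH")
        tables[shape] = tab
        series[shape] = dict(zip(tab.k, tab.mean_area))
    return series, tables


@pytest.fixture(scope="session")
def fixture_cohort():
    """15 synthetic territory holders with 12-direction trial sets."""
    from shapely.geometry import Polygon

    from territoria.simulate import generate_fixture_individuals

    rng = np.random.default_rng(3)
    arena = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
    return generate_fixture_individuals(15, arena, rng)
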