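import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import metaga as m


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort from the default generator."""
    cohort, truth = m.generate_cohort(m.SimConfig(n=5000, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Build/validation split with both models fitted on the build half."""
    cohort, _ = default_cohort
    build, val = m.split_cohort(cohort, 0.5, 7)
    screen = m.screen_all(build, 0.01)
    spec1 = m.select_terms(screen, build, 0.05)
    coef1 = m.fit_model(build, spec1)
    coef2 = m.fit_model(build, spec1.with_birthweight())
    return {
        "build": build,
        "val": val,
        "screen": screen,
        "spec1": spec1,
        "coef1": coef1,
        "coef2": coef2,
    }


@pytest.fixture(scope="session")
def holdout_predictions(fitted):
    p1 = m.predict_ga(fitted["val"], fitted["coef1"])
    p2 = m.predict_ga(fitted["val"], fitted["coef2"])
    return p1, p2


def make_prediction_set(ga_true, ga_pred, region=None, sga=None, cutoff=37.0):
    """Assemble a PredictionSet from bare arrays (test convenience)."""
    ga_true = np.asarray(ga_true, dtype=float)
    n = len(ga_true)
    return m.PredictionSet(
        ids=np.array([f"r{i}" for i in range(n)]),
        ga_ultrasound=ga_true,
        ga_predicted=np.asarray(ga_pred, dtype=float),
        region=np.asarray(region) if region is not None else np.full(n, "x"),
        sga=np.asarray(sga, dtype=bool) if sga is not None else np.zeros(n, bool),
        preterm_cutoff=cutoff,
    )
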