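import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pinealclock import (SuperfusionParams, build_experiment_schedule,
                         default_params, simulate_culture)
from pinealclock.headline import derived_seeds, headline_quantities


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def dd_series_noisefree(params):
    """Noise-free 5-day continuous-darkness culture (4 glands)."""
    sched = build_experiment_schedule("I", "V")
    sp = SuperfusionParams(seed=11, ria_cv=0.0)
    return simulate_culture(params, sp, sched), sched


@pytest.fixture(scope="session")
def ld_series(params):
    """Noisy entrained 12L:12D culture (4 glands)."""
    sched = build_experiment_schedule("I", "I")
    sp = SuperfusionParams(seed=11)
    return simulate_culture(params, sp, sched), sched


@pytest.fixture(scope="session")
def headline():
    """The headline quantities at the study conditions (4 glands, CV 8%,
    5 seeds) used by the acceptance checks."""
    return headline_quantities(derived_seeds(1, 5))
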