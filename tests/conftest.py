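import numpy as np
import pytest
from dataclasses import replace

from deadspacepk.simulate import default_params_calibrated, simulate_cohort, simulate_subject
from deadspacepk.profiles import ConcProfile


@pytest.fixture(scope="session")
def noise_free_subject():
    """One reference 75-kg subject, no assay noise, with its dense-grid truth."""
    params = replace(default_params_calibrated(), noise_cv=0.0)
    return simulate_subject(params, "pig01")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject noisy cohort (2 per weight band), deterministic seed."""
    return simulate_cohort(n_per_group=2, seed=42)


def random_profile(rng: np.random.Generator, n_min: int = 4, n_max: int = 10,
                   span: float = 60.0, cmax: float = 20.0) -> ConcProfile:
    """Random strictly-increasing-time profile with non-negative concentrations."""
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.uniform(0.0, span, size=n))
    while np.any(np.diff(times) < 1e-3):
        times = np.sort(rng.uniform(0.0, span, size=n))
    # concentrations bounded away from 0⁺ (tiny positives make the log rule's
    # oracle quadrature ill-conditioned), with exact zeros sprinkled in to
    # exercise the zero-touching linear rule
    concs = rng.uniform(0.5, cmax, size=n)
    concs[rng.random(n) < 0.15] = 0.0
    return ConcProfile("s", "plasma", times, concs)
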