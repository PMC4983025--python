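import hypothesis
import numpy as np
import pandas as pd
import pytest

from pmpotency.design import IN_VITRO, EndpointSpec, StudyDesign
from pmpotency.simulate import ParticleSpec, simulate_measurements

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")

DOSES = (0.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@pytest.fixture
def small_design():
    """One unit, three endpoints (pro cytokine, viability, anti cytokine)."""
    endpoints = (
        EndpointSpec("U", "CYT", "pro_inflammatory", 100.0, "pg/mL", 0.2),
        EndpointSpec("U", "VIA", "viability", 100.0, "AU", 0.2),
        EndpointSpec("U", "ANTI", "anti_inflammatory", 50.0, "pg/mL", 0.2),
    )
    return StudyDesign(IN_VITRO, endpoints, DOSES, 3, 3)


@pytest.fixture
def noise_free_design(small_design):
    endpoints = tuple(
        EndpointSpec(e.unit, e.name, e.role, e.baseline, e.baseline_units, 0.0)
        for e in small_design.endpoints
    )
    return StudyDesign(IN_VITRO, endpoints, DOSES, 2, 2)


@pytest.fixture
def two_particles():
    betas = {"U/CYT": 0.12, "U/VIA": -0.08, "U/ANTI": -0.03}
    return [
        ParticleSpec("PM-A", "urban_coarse", betas, 50.0),
        ParticleSpec("PM-B", "mineral", {k: v / 2 for k, v in betas.items()}, None),
    ]


@pytest.fixture
def noise_free_dataset(noise_free_design, two_particles):
    return simulate_measurements(noise_free_design, two_particles, seed=11)


def power_law_fe(beta, doses=DOSES):
    """Exact fold-effect records for one series, no noise."""
    d = np.asarray(doses, dtype=float)
    return pd.DataFrame(
        {
            "particle": "P",
            "unit": "U",
            "endpoint": "E",
            "dose_ug": d,
            "fe": (d + 1.0) ** beta,
        }
    )
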