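import numpy as np
import pytest

import strokecap as sc
from strokecap.config import LOSModel, PathwayConfig, PatientClassSpec


@pytest.fixture(scope="session")
def default_config():
    return sc.build_default_config()


def single_class_config(rate: float, los_model: LOSModel) -> PathwayConfig:
    """A stationary one-class, acute-only pathway (an infinite-server ward)."""
    return PathwayConfig(
        classes=[
            PatientClassSpec(
                name="stroke",
                interarrival_mean=1.0 / rate,
                esd_eligible_prob=0.0,
                routing={"acute": {"exit": 1.0}},
                los={("acute", False): los_model},
            )
        ]
    )


def two_stream_config(
    lam_a: float, lam_r: float, mean_a: float, mean_r: float
) -> PathwayConfig:
    """Two independent exponential-stay streams, one per ward (a classical
    two-class loss system when capacity is imposed)."""
    return PathwayConfig(
        classes=[
            PatientClassSpec(
                name="stroke",
                interarrival_mean=1.0 / lam_a,
                esd_eligible_prob=0.0,
                routing={"acute": {"exit": 1.0}},
                los={("acute", False): LOSModel("exponential", {"mean": mean_a})},
            ),
            PatientClassSpec(
                name="tia",
                interarrival_mean=1.0 / lam_r,
                esd_eligible_prob=0.0,
                routing={"rehab": {"exit": 1.0}},
                los={("rehab", False): LOSModel("exponential", {"mean": mean_r})},
                entry_ward="rehab",
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_run(default_config):
    """Moderate-scale replicated run of the calibrated default pathway,
    shared by tests that only need a representative occupancy sample."""
    spec = sc.RunSpec(warmup=365.0, run_length=730.0, n_reps=30, base_seed=7)
    return spec, sc.run_experiment(default_config, spec)


def product_poisson_joint(mean_a: float, mean_r: float) -> sc.JointOccupancyPMF:
    pa = sc.poisson_pmf(mean_a).p
    pr = sc.poisson_pmf(mean_r).p
    grid = np.outer(pa, pr)
    return sc.JointOccupancyPMF(grid / grid.sum(), n_days=0)
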