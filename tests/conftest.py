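import numpy as np
import pytest

from clusterdose.survival import ClusterDosePoint
from clusterdose.synthetic import generate_survival, make_library, scenario_presets


@pytest.fixture(scope="session")
def aerobic_scenario():
    return scenario_presets("aerobic_like", seed=11)


@pytest.fixture(scope="session")
def aerobic_library(aerobic_scenario):
    return make_library(aerobic_scenario)


@pytest.fixture(scope="session")
def aerobic_points(aerobic_scenario):
    points, truth = generate_survival(aerobic_scenario)
    return points, truth


def make_cluster_dose_points(g, survival, dataset="d", particle="p", energy=1.0, k=5):
    """Plain helper: wrap parallel g/S arrays as ClusterDosePoints."""
    return [
        ClusterDosePoint(
            dataset=dataset,
            particle=particle,
            energy=energy,
            k=k,
            g=float(gi),
            survival=float(si),
        )
        for gi, si in zip(g, survival)
    ]


def lq_dataset(rng, alpha=0.3, beta=0.02, noise_sd=0.1, n=60, g_max=12.0):
    """Synthetic LQ dataset on a log-spaced cluster-dose grid."""
    g = np.geomspace(0.05 * g_max, g_max, n)
    lns = -alpha * g - beta * g**2 + rng.normal(0.0, noise_sd, size=n)
    return g, np.exp(lns)
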