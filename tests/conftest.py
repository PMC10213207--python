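"""Shared fixtures: phantoms and small cohorts, generated at test time."""

import numpy as np
import pytest

from octva import PhantomSpec, generate_phantom
from octva.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free symmetric phantom with its closed-form truth."""
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    img, truth = generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sd=6.0, tilt=0.05, seed=1)
    img, truth = generate_phantom(spec)
    return spec, img, truth


def random_phantom_spec(rng: np.random.Generator, seed: int, noise_sd: float = 6.0):
    """One draw from the phantom-geometry distribution used in recovery sweeps."""
    return PhantomSpec(
        noise_sd=noise_sd,
        tilt=float(rng.normal(0.0, 0.05)),
        rim_thickness_t=float(rng.uniform(300.0, 420.0)),
        rim_thickness_n=float(rng.uniform(300.0, 420.0)),
        center_thickness=float(rng.uniform(160.0, 280.0)),
        pit_halfwidth_t=float(rng.uniform(40.0, 90.0)),
        pit_halfwidth_n=float(rng.uniform(40.0, 90.0)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small labelled cohort with in-memory phantoms (no disk I/O)."""
    return generate_cohort(CohortSpec(n_eyes=24, seed=5))
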