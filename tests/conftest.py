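import numpy as np
import pytest

from leafspec.synthetic import SyntheticDesign, build_synthetic_library, generate_cohort


@pytest.fixture(scope="session")
def library():
    return build_synthetic_library(0)


@pytest.fixture(scope="session")
def cohort():
    """Default 72-leaf campaign (2 cultivars x 2 PFDs x 2 spectra x 3 days x 3 reps)."""
    return generate_cohort(SyntheticDesign(seed=1))


@pytest.fixture(scope="session")
def noiseless_day1_cohort():
    """Small noise-free cohort for round-trip recovery checks."""
    design = SyntheticDesign(
        days=(1,), replicates=1, seed=3,
        rt_noise_sd=0.0, absorbance_noise_sd=0.0, fluor_noise_sd=0.0,
    )
    return generate_cohort(design)


def random_biophysics(rng: np.random.Generator):
    """One random valid parameter vector spanning the default box."""
    from leafspec.types import LeafBiophysics

    cab = rng.uniform(5.0, 80.0)
    return LeafBiophysics(
        n=rng.uniform(1.0, 3.0),
        cab=cab,
        ccar=cab / rng.uniform(3.0, 8.0),
        canth=rng.uniform(0.0, 10.0),
        cx=rng.uniform(0.0, 1.0),
        cbrown=rng.uniform(0.0, 0.5),
        cw=rng.uniform(1e-4, 0.03),
        cm=rng.uniform(1e-3, 0.012),
    )
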