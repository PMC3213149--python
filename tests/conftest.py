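import numpy as np
import pytest

from allomplast import AllometrySimParams, OrganSpec, dataset_from_arrays, simulate_allometry


def sma_consistent_xy(rng, n, slope=0.55, intercept=0.0, body_sd=0.2, x_noise=0.06):
    """Bivariate log-size sample whose SMA slope estimand equals ``slope``.

    Noise loads both axes in the ratio |slope| so that sd(y)/sd(x) -> |slope|.
    """
    z = rng.normal(0.0, body_sd, n)
    x = z + rng.normal(0.0, x_noise, n)
    y = intercept + slope * z + rng.normal(0.0, abs(slope) * x_noise, n)
    return x, y


def random_raw_dataset(rng, n=20, organs=("wing", "genital")):
    body = np.exp(rng.normal(0.0, 0.2, n))
    organ_sizes = {o: np.exp(rng.normal(0.0, 0.2, n)) for o in organs}
    return dataset_from_arrays(
        body,
        organ_sizes,
        group=[rng.choice(["control", "mutant"]) for _ in range(n)],
        temperature=list(rng.choice([17.0, 23.0], n)),
        treatment=[str(t) for t in rng.choice(["fed", "starved"], n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def genital_dataset():
    """Log-scale dataset with a genital-like organ of true slope 0.55, n = 60."""
    from allomplast import log_transform

    params = AllometrySimParams(
        organs={"genital": OrganSpec(0.55)}, n_per_cell=60, seed=101
    )
    return log_transform(simulate_allometry(params))
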