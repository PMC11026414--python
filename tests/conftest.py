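import numpy as np
import pytest

from vsprofile.synthetic import SyntheticConfig, simulate_dataset
from vsprofile.variogram import VariogramModel


@pytest.fixture(scope="session")
def exp_truth() -> VariogramModel:
    """Exponential ground truth used across simulation-based tests."""
    return VariogramModel("exponential", 0.05, 1.0, 0.3)


@pytest.fixture(scope="session")
def small_panel(exp_truth):
    """A 60-variant synthetic panel on a 418-residue chain."""
    return simulate_dataset(SyntheticConfig(n_variants=60, seed=11,
                                            variogram=exp_truth))


@pytest.fixture(scope="session")
def small_points(small_panel):
    from vsprofile.data import select_spatial

    pts = select_spatial(small_panel, "monomer", "activity", "vehicle")
    return (pts["x"].to_numpy(), pts["y"].to_numpy(), pts["z"].to_numpy())


def random_model(rng) -> VariogramModel:
    family = rng.choice(["spherical", "exponential", "gaussian"])
    return VariogramModel(str(family), float(rng.uniform(0, 0.3)),
                          float(rng.uniform(0.2, 2.0)),
                          float(rng.uniform(0.05, 1.0)))


def random_points(rng, n):
    x = rng.uniform(0, 1, n)
    y = rng.uniform(0, 1, n)
    z = rng.normal(0.5, 0.5, n)
    return x, y, z
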